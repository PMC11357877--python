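"""Whole-recording Phi dynamics: sliding windows, z(log Phi), aggregates.

A recording is cut into overlapping windows (length Td, shift 500 frames in
the study profile); each window yields the full-system Phi_MIP and its cut
location, plus Phi_MIP for every subsystem and the window's main complexes.
Per-window log Phi values are z-scored against a pre-task baseline so that
the baseline has mean 0 / sd 1 exactly, and the per-window sum and maximum
of z(log Phi) over the current main complexes summarize how entangled the
system is at each moment.  Frequency shifts of the MIP cut location and of
the dominant main complex between phases, and a Monte-Carlo rank-pattern
test across conditions, are the cohort-level summaries.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .complex_search import find_main_complexes
from .exceptions import DegenerateModelError, SegmentLengthError
from .iit_core import estimate_lagged_gaussian, find_mip

__all__ = [
    "WindowingPlan",
    "Window",
    "PhiSeries",
    "BaselineStats",
    "FrequencyShift",
    "RankPatternResult",
    "sliding_windows",
    "select_tau",
    "compute_phi_series",
    "zscore_log_phi",
    "aggregate_main_complex_z",
    "frequency_shift",
    "moving_average",
    "rank_pattern_test",
    "subset_label",
]


def subset_label(subset) -> str:
    """Canonical label of a node subset, e.g. ``"Cz+Pz"``."""
    return "+".join(sorted(subset))


@dataclass(frozen=True)
class WindowingPlan:
    """Window length / shift in frames; the study set uses Td in
    {1000, 2000, 3000} with a 500-frame shift."""

    td_frames: int = 1000
    shift_frames: int = 500
    zero_pad_head: bool = True

    def __post_init__(self):
        if not (self.td_frames >= self.shift_frames > 0):
            raise ValueError("require td_frames >= shift_frames > 0")


@dataclass(frozen=True)
class Window:
    index: int
    end_frame: int
    segment: np.ndarray = field(repr=False)
    padded: bool


def _recording_array(recording):
    """(values, channels, fps) from a time_s + channels DataFrame."""
    if not hasattr(recording, "columns"):
        raise TypeError("recording must be a DataFrame with a time_s column")
    cols = list(recording.columns)
    if "time_s" not in cols:
        raise ValueError("recording must have a time_s column")
    chans = [c for c in cols if c != "time_s"]
    t = recording["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    fps = 1.0 / float(np.median(dt))
    return recording[chans].to_numpy(dtype=float), tuple(chans), fps


def sliding_windows(recording, plan: WindowingPlan) -> list[Window]:
    """Overlapping windows ending every ``shift_frames``.

    With ``zero_pad_head`` the initial partial windows are left-padded with
    zeros so the series starts at the first shift; exactly
    ``td/shift - 1`` head windows actually contain padding and are flagged.
    """
    values, _, _ = _recording_array(recording)
    n = values.shape[0]
    if n < plan.shift_frames:
        raise SegmentLengthError(
            f"recording ({n} frames) shorter than the window shift"
        )
    out = []
    idx = 0
    for end in range(plan.shift_frames, n + 1, plan.shift_frames):
        start = end - plan.td_frames
        if start < 0:
            if not plan.zero_pad_head:
                continue
            seg = np.vstack(
                [np.zeros((-start, values.shape[1])), values[:end]]
            )
            padded = True
        else:
            seg = values[start:end]
            padded = False
        out.append(Window(index=idx, end_frame=end, segment=seg, padded=padded))
        idx += 1
    return out


@dataclass(frozen=True)
class BaselineStats:
    """Pre-task mean/sd of log Phi per tracked quantity (column label)."""

    mean_log_phi: dict
    sd_log_phi: dict
    baseline_windows: np.ndarray

    def __post_init__(self):
        for k, s in self.sd_log_phi.items():
            if not s > 0:
                raise ValueError(f"baseline sd must be > 0 (quantity {k})")


@dataclass
class PhiSeries:
    """Per-window Phi structures along one recording.

    ``subset_phi`` holds Phi_MIP for every subsystem (columns labelled
    ``"Cz+Pz"`` style; the full-system column included), NaN where missing;
    z-columns appear after :func:`zscore_log_phi`.
    """

    channels: tuple[str, ...]
    tau: int
    plan: WindowingPlan
    fps: float
    window_times: np.ndarray  # seconds at window end
    phi_mip: np.ndarray  # full system, NaN where missing
    mip_cut: list  # cut label or None
    mip_partition: list  # Bipartition or None
    main_complexes: list  # tuple of subset labels per window
    subset_phi: pd.DataFrame
    subset_mip_cut: pd.DataFrame  # per-window cut label of each subsystem
    padded: np.ndarray
    missing: np.ndarray
    z_log_phi: np.ndarray | None = None
    z_subsets: pd.DataFrame | None = None
    sum_z: np.ndarray | None = None
    max_z: np.ndarray | None = None
    baseline: BaselineStats | None = None

    @property
    def n_windows(self) -> int:
        return len(self.window_times)

    @property
    def full_label(self) -> str:
        return subset_label(self.channels)

    def phase_mask(self, start_s: float, end_s: float) -> np.ndarray:
        """Windows whose end time falls in (start_s, end_s]."""
        return (self.window_times > start_s) & (self.window_times <= end_s)

    def to_frame(self) -> pd.DataFrame:
        """The per-window tabular output (one row per window)."""
        return pd.DataFrame(
            {
                "window_end_s": self.window_times,
                "phi_mip": self.phi_mip,
                "mip_cut": [c if c is not None else "" for c in self.mip_cut],
                "z_log_phi": self.z_log_phi
                if self.z_log_phi is not None
                else np.full(self.n_windows, np.nan),
                "sum_z": self.sum_z
                if self.sum_z is not None
                else np.full(self.n_windows, np.nan),
                "max_z": self.max_z
                if self.max_z is not None
                else np.full(self.n_windows, np.nan),
                "main_complexes": [";".join(m) for m in self.main_complexes],
                "missing_flag": self.missing.astype(int),
            }
        )

    def subsets_to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (window, subsystem) with Phi_MIP,
        the subsystem's MIP cut, and a degeneracy flag."""
        rows = []
        for col in self.subset_phi.columns:
            phi = self.subset_phi[col].to_numpy(dtype=float)
            cut = self.subset_mip_cut[col].tolist()
            for i in range(self.n_windows):
                rows.append(
                    (
                        self.window_times[i],
                        col,
                        phi[i],
                        cut[i] if cut[i] else "",
                        int(not np.isfinite(phi[i])),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["window_end_s", "subset", "phi_mip", "mip_cut", "degenerate_flag"],
        )


def compute_phi_series(
    recording,
    plan: WindowingPlan,
    tau: int,
    min_size: int = 2,
    ridge: float = 0.0,
    beta_max: float = 10.0,
    on_overlap: str = "keep",
) -> PhiSeries:
    """Per-window MIP search and main-complex identification.

    Windows whose covariance estimation or full-system MIP is degenerate are
    marked missing (never dropped), mirroring the study's window-exclusion
    style.  The subset sweep runs through the batched engine (numerically
    identical to the scalar path, amortizing linear algebra across windows).
    """
    from ._batch import phi_subset_table
    from .complex_search import PhiSubsetMap, SubsetPhi, enumerate_subsystems

    values, chans, fps = _recording_array(recording)
    wins = sliding_windows(recording, plan)
    n_w = len(wins)
    subsets = enumerate_subsystems(chans, min_size)
    cols = [subset_label(s) for s in subsets]
    phi_tab = pd.DataFrame(np.nan, index=range(n_w), columns=cols)
    cut_tab = pd.DataFrame("", index=range(n_w), columns=cols, dtype=object)
    full_lab = subset_label(chans)
    full_key = frozenset(chans)
    phi_mip = np.full(n_w, np.nan)
    mip_cut: list = [None] * n_w
    mip_part: list = [None] * n_w
    mains: list = [()] * n_w
    missing = np.zeros(n_w, dtype=bool)
    padded = np.array([w.padded for w in wins])
    times = np.array([w.end_frame / fps for w in wins])

    models, good_idx = [], []
    for i, w in enumerate(wins):
        try:
            models.append(
                estimate_lagged_gaussian(w.segment, tau, ridge=ridge, nodes=chans)
            )
            good_idx.append(i)
        except (DegenerateModelError, SegmentLengthError):
            missing[i] = True
    if models:
        subs, phi_arr, mips = phi_subset_table(
            models, min_size=min_size, beta_max=beta_max
        )
        for m_i, i in enumerate(good_idx):
            entries = {}
            for s_i, subset in enumerate(subs):
                key = frozenset(subset)
                mip = mips[(m_i, s_i)]
                if mip is None:
                    entries[key] = SubsetPhi(key, None, None, degenerate=True)
                else:
                    val = float(phi_arr[m_i, s_i])
                    entries[key] = SubsetPhi(key, val, mip)
                    phi_tab.iloc[i, s_i] = val
                    cut_tab.iloc[i, s_i] = mip.cut_label
            full_entry = entries[full_key]
            if full_entry.degenerate:
                missing[i] = True
                continue
            phi_mip[i] = full_entry.phi
            mip_cut[i] = full_entry.mip.cut_label
            mip_part[i] = full_entry.mip
            pmap = PhiSubsetMap(nodes=chans, entries=entries, min_size=min_size)
            cset = find_main_complexes(pmap, on_overlap=on_overlap)
            mains[i] = tuple(subset_label(m) for m in cset.main_complexes)
    assert full_lab in phi_tab.columns
    return PhiSeries(
        channels=chans,
        tau=tau,
        plan=plan,
        fps=fps,
        window_times=times,
        phi_mip=phi_mip,
        mip_cut=mip_cut,
        mip_partition=mip_part,
        main_complexes=mains,
        subset_phi=phi_tab,
        subset_mip_cut=cut_tab,
        padded=padded,
        missing=missing,
    )


def default_baseline_windows(
    series: PhiSeries, pre_task_end_s: float, guard_windows: int = 10
) -> np.ndarray:
    """Indices of baseline windows: fully inside the pre-task phase, not
    zero-padded, minus a guard at the phase boundary."""
    start_s = series.window_times - series.plan.td_frames / series.fps
    inside = (start_s >= -1e-9) & (series.window_times <= pre_task_end_s + 1e-9)
    inside &= ~series.padded
    idx = np.flatnonzero(inside)
    if guard_windows > 0:
        idx = idx[:-guard_windows] if guard_windows < len(idx) else idx[:0]
    return idx


def zscore_log_phi(
    series: PhiSeries,
    baseline_windows=None,
    pre_task_end_s: float | None = None,
    guard_windows: int = 10,
) -> PhiSeries:
    """Standardize log Phi against the pre-task baseline.

    z = (log Phi - mean_baseline) / sd_baseline per tracked quantity (the
    full system and every subsystem), so the baseline windows have sample
    mean 0 and sample sd 1 exactly.  Windows with nonpositive or missing Phi
    are NaN for that quantity.  ``baseline_windows`` may be an explicit index
    array or a 1-based inclusive ``(first, last)`` window range (the study's
    literal t in [1, 537] override); otherwise the baseline is derived from
    ``pre_task_end_s`` with a ``guard_windows`` guard at the boundary.

    The z series is invariant to the logarithm base (an affine change).
    """
    if baseline_windows is None:
        if pre_task_end_s is None:
            raise ValueError("need baseline_windows or pre_task_end_s")
        idx = default_baseline_windows(series, pre_task_end_s, guard_windows)
    elif (
        isinstance(baseline_windows, tuple)
        and len(baseline_windows) == 2
        and np.isscalar(baseline_windows[0])
    ):
        first, last = baseline_windows
        idx = np.arange(int(first) - 1, int(last))
        idx = idx[(idx >= 0) & (idx < series.n_windows)]
    else:
        idx = np.asarray(baseline_windows, dtype=int)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_tab = np.log(series.subset_phi.to_numpy(dtype=float))
    log_tab[~np.isfinite(log_tab)] = np.nan
    log_frame = pd.DataFrame(log_tab, columns=series.subset_phi.columns)

    means, sds = {}, {}
    z_frame = pd.DataFrame(
        np.nan, index=range(series.n_windows), columns=series.subset_phi.columns
    )
    for col in log_frame.columns:
        base = log_frame[col].to_numpy()[idx]
        base = base[np.isfinite(base)]
        if len(base) < 2:
            continue  # quantity has no usable baseline; stays NaN
        m = float(base.mean())
        s = float(base.std(ddof=1))
        if not s > 0:
            raise ValueError(f"zero baseline variance for {col}")
        means[col] = m
        sds[col] = s
        z_frame[col] = (log_frame[col] - m) / s

    full = series.full_label
    if full not in means:
        raise ValueError(
            "full-system baseline unusable "
            f"({len(idx)} baseline windows, too few with positive Phi)"
        )
    stats = BaselineStats(mean_log_phi=means, sd_log_phi=sds, baseline_windows=idx)
    out = replace(series)
    out.z_subsets = z_frame
    out.z_log_phi = z_frame[full].to_numpy(dtype=float)
    out.baseline = stats
    return out


def aggregate_main_complex_z(series: PhiSeries) -> PhiSeries:
    """Per-window sum and max of z(log Phi) over the window's main complexes.

    Windows that are missing, have no main complex, or whose main-complex z
    values are undefined are NaN in both aggregates.
    """
    if series.z_subsets is None:
        raise ValueError("run zscore_log_phi first")
    n = series.n_windows
    sum_z = np.full(n, np.nan)
    max_z = np.full(n, np.nan)
    z = series.z_subsets
    for i in range(n):
        if series.missing[i] or not series.main_complexes[i]:
            continue
        vals = z.loc[i, list(series.main_complexes[i])].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            continue
        sum_z[i] = vals.sum()
        max_z[i] = vals.max()
    out = replace(series)
    out.sum_z = sum_z
    out.max_z = max_z
    return out


@dataclass(frozen=True)
class FrequencyShift:
    """Per-label relative frequency in two phases and their difference."""

    label_kind: str
    labels: tuple[str, ...]
    freq_task: np.ndarray
    freq_pretask: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.freq_task - self.freq_pretask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "freq_pretask": self.freq_pretask,
                "freq_task": self.freq_task,
                "diff": self.diff,
            }
        )


def _window_labels(series: PhiSeries, label_kind: str) -> list:
    if label_kind == "mip_cut":
        return list(series.mip_cut)
    if label_kind == "argmax_main_complex":
        if series.z_subsets is None:
            raise ValueError("argmax_main_complex labels need z scores")
        labels = []
        for i in range(series.n_windows):
            mains = series.main_complexes[i]
            if series.missing[i] or not mains:
                labels.append(None)
                continue
            vals = series.z_subsets.loc[i, list(mains)].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                labels.append(None)
                continue
            labels.append(mains[int(np.argmax(vals))])
        return labels
    raise ValueError("label_kind must be 'mip_cut' or 'argmax_main_complex'")


def frequency_shift(
    series: PhiSeries,
    pretask_range: tuple[float, float],
    task_range: tuple[float, float],
    label_kind: str = "mip_cut",
) -> FrequencyShift:
    """Freq(label | Task) - Freq(label | PreTask).

    Frequencies are relative within each phase (they sum to 1 over defined
    windows); labels absent from both phases are omitted.
    """
    labels = _window_labels(series, label_kind)

    def phase_freq(rng):
        mask = series.phase_mask(*rng)
        labs = [labels[i] for i in np.flatnonzero(mask) if labels[i] is not None]
        if not labs:
            raise ValueError(f"no usable windows in phase range {rng}")
        vc = pd.Series(labs).value_counts(normalize=True)
        return vc

    f_pre = phase_freq(pretask_range)
    f_task = phase_freq(task_range)
    all_labels = tuple(sorted(set(f_pre.index) | set(f_task.index)))
    return FrequencyShift(
        label_kind=label_kind,
        labels=all_labels,
        freq_task=np.array([f_task.get(l, 0.0) for l in all_labels]),
        freq_pretask=np.array([f_pre.get(l, 0.0) for l in all_labels]),
    )


def moving_average(values, window_spacing_s: float, width_seconds: float = 50.0):
    """Centered moving mean over a regularly spaced series, NaN-aware.

    Edge windows use the available support; NaN entries are ignored rather
    than propagated.
    """
    if width_seconds < window_spacing_s:
        raise ValueError("width must be at least the window spacing")
    k = max(1, int(round(width_seconds / window_spacing_s)))
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=k, center=True, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# tau selection
# ---------------------------------------------------------------------------


def select_tau(
    recordings,
    taus=range(0, 501, 50),
    plan: WindowingPlan | None = None,
    ridge: float = 0.0,
    window_step: int = 1,
    flat_rel_tol: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Lag maximizing the mean full-system Phi_MIP across recordings.

    Evaluates the documented grid ``taus`` (windows may be subsampled with
    ``window_step`` for speed) and returns the argmax plus the full profile.
    A flat profile -- relative range below ``flat_rel_tol`` -- triggers a
    warning, since the argmax is then meaningless (e.g. white noise).
    """
    if plan is None:
        plan = WindowingPlan()
    taus = list(taus)
    if not taus:
        raise ValueError("empty tau grid")
    rows = []
    for tau in taus:
        vals = []
        for rec in recordings:
            values, chans, _ = _recording_array(rec)
            wins = sliding_windows(rec, plan)[::window_step]
            for w in wins:
                if w.padded:
                    continue
                try:
                    model = estimate_lagged_gaussian(
                        w.segment, tau, ridge=ridge, nodes=chans
                    )
                    vals.append(find_mip(model).phi_mip)
                except (DegenerateModelError, SegmentLengthError):
                    continue
        if vals:
            rows.append(
                (tau, np.mean(vals), np.std(vals) / np.sqrt(len(vals)), len(vals))
            )
        else:
            rows.append((tau, np.nan, np.nan, 0))
    profile = pd.DataFrame(rows, columns=["tau", "mean_phi_mip", "se", "n_windows"])
    if profile["mean_phi_mip"].isna().all():
        raise DegenerateModelError("every tau produced only degenerate windows")
    means = profile["mean_phi_mip"].to_numpy()
    best = int(profile.loc[np.nanargmax(means), "tau"])
    # a profile whose spread is within sampling noise has no stable maximum
    spread = np.nanmax(means) - np.nanmin(means)
    noise = 2.0 * np.nanmean(profile["se"].to_numpy())
    if spread < max(noise, flat_rel_tol * abs(np.nanmax(means))):
        warnings.warn(
            "flat Phi_MIP(tau) profile; selected tau is not meaningful",
            stacklevel=2,
        )
    return best, profile


# ---------------------------------------------------------------------------
# rank-pattern Monte Carlo test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankPatternResult:
    """Condition-ordering pattern counts and their Monte-Carlo uniformity test."""

    conditions: tuple[str, ...]
    patterns: tuple[tuple[str, ...], ...]  # descending orderings
    counts: np.ndarray  # participants per pattern
    frequencies: np.ndarray
    chi_square: float
    p_value: float
    n_participants: int
    window_pattern_freq: np.ndarray  # pooled over participant-windows


def rank_pattern_test(
    sum_z_by_condition: dict,
    n_mc: int = 10**7,
    seed=None,
    rng: np.random.Generator | None = None,
) -> RankPatternResult:
    """Monte-Carlo test of condition-ordering patterns against uniformity.

    Each participant contributes one pattern: the descending ordering of the
    per-condition mean of their sum-z series (windows aligned across
    conditions; NaN windows are ignored in the means; an exact tie drops the
    participant).  The Pearson chi-square of the pattern counts against the
    uniform distribution over the k! orderings is compared with ``n_mc``
    multinomial draws under uniformity.  Pooled per-window pattern
    frequencies are reported as a diagnostic.
    """
    conditions = tuple(sum_z_by_condition)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    mats = [np.atleast_2d(np.asarray(sum_z_by_condition[c], dtype=float)) for c in conditions]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("condition arrays must be aligned (participants x windows)")
    stack = np.stack(mats)  # (k, P, W)
    k, n_part, _ = stack.shape
    perms = list(itertools.permutations(range(k)))
    n_pat = len(perms)
    perm_index = {p: i for i, p in enumerate(perms)}

    # pooled per-window patterns (diagnostic)
    win_counts = np.zeros(n_pat)
    ok = np.all(np.isfinite(stack), axis=0)  # (P, W)
    order = np.argsort(-stack, axis=0)  # descending
    for p in range(n_part):
        for w in np.flatnonzero(ok[p]):
            col = stack[:, p, w]
            if len(np.unique(col)) < k:
                continue  # tied window: dropped from tallies
            win_counts[perm_index[tuple(order[:, p, w])]] += 1
    win_freq = win_counts / win_counts.sum() if win_counts.sum() else win_counts

    # one pattern per participant: ordering of task-mean sum z
    counts = np.zeros(n_pat)
    n_used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(stack, axis=2)  # (k, P)
    for p in range(n_part):
        col = means[:, p]
        if not np.all(np.isfinite(col)) or len(np.unique(col)) < k:
            continue
        counts[perm_index[tuple(np.argsort(-col))]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no participant produced a usable rank pattern")
    expected = n_used / n_pat
    chi2 = float(((counts - expected) ** 2 / expected).sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = 10**6
    done = 0
    p_uni = np.full(n_pat, 1.0 / n_pat)
    while done < n_mc:
        m = min(chunk, n_mc - done)
        sims = rng.multinomial(n_used, p_uni, size=m)
        chi2_sim = ((sims - expected) ** 2 / expected).sum(axis=1)
        n_ge += int(np.sum(chi2_sim >= chi2 - 1e-12))
        done += m
    p_val = (1 + n_ge) / (1 + n_mc)

    patterns = tuple(tuple(conditions[i] for i in perm) for perm in perms)
    return RankPatternResult(
        conditions=conditions,
        patterns=patterns,
        counts=counts,
        frequencies=counts / n_used,
        chi_square=chi2,
        p_value=float(p_val),
        n_participants=n_used,
        window_pattern_freq=win_freq,
    )
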