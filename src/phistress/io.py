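"""File formats, run configuration and the end-to-end pipeline driver.

Interchange is plain comma-separated text with a header row, UTF-8, "."
decimal: recordings are one row per frame with columns ``time_s`` plus the
channel labels; ratings are tidy rows of (participant, condition, phase,
item, value).  Output files embed the configuration hash and the package
version in ``#``-prefixed header comments, so any two runs can be checked
for comparability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import PhiStressError, ReliabilityError
from .pipeline import (
    PhiSeries,
    WindowingPlan,
    aggregate_main_complex_z,
    compute_phi_series,
    frequency_shift,
    rank_pattern_test,
    select_tau,
    zscore_log_phi,
)
from .scores import correlate_scores, phi_feeling_score, rating_deltas, valence_composites

__all__ = [
    "CANONICAL_CHANNELS",
    "RunConfig",
    "read_recording",
    "write_recording",
    "read_ratings",
    "write_ratings",
    "read_config",
    "config_hash",
    "run_pipeline",
]

CANONICAL_CHANNELS = ("Fz", "Cz", "Pz", "ECG", "EDA")


def read_recording(path, channels=CANONICAL_CHANNELS) -> pd.DataFrame:
    """Read a recording file; returns time_s + channels in canonical order.

    Errors name the offending column or row: a missing expected channel, a
    non-numeric cell, or duplicated timestamps all abort the parse.  Pass
    ``channels=None`` to accept any channel set as-is.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    if "time_s" not in frame.columns:
        raise ValueError(f"{path.name}: missing required column 'time_s'")
    if channels is not None:
        missing = [c for c in channels if c not in frame.columns]
        if missing:
            raise ValueError(f"{path.name}: missing channel column(s) {missing}")
        frame = frame[["time_s", *channels]]
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path.name}: non-numeric value in column '{col}' at row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"{path.name}: missing value in column '{col}' at row {row}")
        frame[col] = coerced.astype(float)
    t = frame["time_s"].to_numpy()
    if pd.Series(t).duplicated().any():
        dup = float(pd.Series(t)[pd.Series(t).duplicated()].iloc[0])
        raise ValueError(f"{path.name}: duplicated timestamp {dup}")
    return frame


def write_recording(frame: pd.DataFrame, path, header_comment: str | None = None):
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def read_ratings(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    required = ["participant", "condition", "phase", "item", "value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing ratings column(s) {missing}")
    frame["value"] = pd.to_numeric(frame["value"])
    return frame[required]


def write_ratings(frame: pd.DataFrame, path, header_comment: str | None = None):
    write_recording(frame, path, header_comment)  # same tabular envelope


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a cohort run needs; file values are overridable by CLI flags."""

    recordings_dir: str = "."
    ratings_file: str | None = None
    out_dir: str = "phistress_out"
    tau: str | int = "auto"
    td_frames: int = 1000
    shift_frames: int = 500
    pre_task_end_s: float = 600.0
    task_end_s: float = 2400.0
    guard_windows: int = 10
    baseline_windows: str | None = None  # "first,last" 1-based override
    baseline_condition: str = "Moderate"
    seed: int = 0
    ridge: float = 0.0
    exclude_degenerate_frac: float = 0.1
    scale_profile: str = "reduced"  # simulate-time only: reduced | full

    _INT = ("td_frames", "shift_frames", "guard_windows", "seed")
    _FLOAT = ("pre_task_end_s", "task_end_s", "ridge", "exclude_degenerate_frac")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        cfg = cls()
        for key, value in mapping.items():
            if not hasattr(cfg, key) or key.startswith("_"):
                raise ValueError(f"unknown configuration key '{key}'")
            if key in cls._INT:
                value = int(value)
            elif key in cls._FLOAT:
                value = float(value)
            elif key == "tau" and value != "auto":
                value = int(value)
            setattr(cfg, key, value)
        return cfg

    def as_mapping(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if not k.startswith("_")}


def read_config(path) -> RunConfig:
    """Parse a ``key = value`` configuration file (``#`` comments allowed)."""
    mapping = {}
    for ln, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {ln} is not 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        mapping[key] = value
    return RunConfig.from_mapping(mapping)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.as_mapping(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# in-memory cohort analysis
# ---------------------------------------------------------------------------


def analyze_cohort(
    cohort,
    tau: int = 1,
    plan: WindowingPlan | None = None,
    guard_windows: int = 2,
    baseline_condition: str = "Moderate",
    n_mc: int = 10**5,
    seed=0,
) -> dict:
    """Run the full windowed analysis on an in-memory synthetic cohort.

    Phase boundaries come from the cohort's generator settings.  Returns the
    per-recording series, per-condition task-phase mean sum-z, the
    rank-pattern test, and the feeling scores joined with the Boring-item
    rating deltas (the planted coupling target).
    """
    from .scores import correlate_scores, phi_feeling_score, rating_deltas

    spec = cohort.spec
    pre_end = spec.phases[0][2]
    task_range = (spec.phases[1][1], spec.phases[1][2])
    if plan is None:
        plan = WindowingPlan(
            td_frames=int(10 * spec.fps), shift_frames=int(5 * spec.fps)
        )
    series = {}
    for key, frame in cohort.recordings.items():
        s = compute_phi_series(frame, plan, tau)
        s = zscore_log_phi(s, pre_task_end_s=pre_end, guard_windows=guard_windows)
        series[key] = aggregate_main_complex_z(s)

    participants = cohort.planted["participants"]
    conditions = tuple(cohort.effect.task_multipliers)
    per_cond, mean_sum_z = {}, {}
    for c in conditions:
        rows = []
        for p in participants:
            s = series[(p, c)]
            rows.append(s.sum_z[s.phase_mask(*task_range)])
        per_cond[c] = np.vstack(rows)
        mean_sum_z[c] = float(np.nanmean(per_cond[c]))
    rank = rank_pattern_test(per_cond, n_mc=n_mc, seed=seed)

    deltas = rating_deltas(cohort.ratings, baseline_condition=baseline_condition)
    scores = {}
    for c in conditions:
        if c == baseline_condition:
            continue
        si = []
        for p in participants:
            si.append(
                phi_feeling_score(
                    series[(p, c)], series[(p, baseline_condition)], *task_range
                ).si
            )
        scores[c] = np.array(si)

    def item_corr(condition, item):
        d = (
            deltas[(deltas.condition == condition) & (deltas.item == item)]
            .set_index("participant")["dr"]
            .loc[list(participants)]
            .to_numpy()
        )
        return correlate_scores(scores[condition], d)

    return {
        "series": series,
        "mean_sum_z": mean_sum_z,
        "rank": rank,
        "si": scores,
        "deltas": deltas,
        "item_corr": item_corr,
        "task_range": task_range,
    }


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def _discover_recordings(directory: Path) -> dict:
    """{(participant, condition): path} from files named P_Condition.csv."""
    out = {}
    for path in sorted(directory.glob("*.csv")):
        stem = path.stem
        if "_" not in stem:
            continue
        participant, condition = stem.rsplit("_", 1)
        out[(participant, condition)] = path
    return out


def process_recording(frame: pd.DataFrame, config: RunConfig, tau: int) -> PhiSeries:
    """Windowed Phi series, z-scored and aggregated, for one recording."""
    plan = WindowingPlan(config.td_frames, config.shift_frames)
    series = compute_phi_series(frame, plan, tau, ridge=config.ridge)
    baseline = None
    if config.baseline_windows:
        first, last = (int(x) for x in str(config.baseline_windows).split(","))
        baseline = (first, last)
    series = zscore_log_phi(
        series,
        baseline_windows=baseline,
        pre_task_end_s=config.pre_task_end_s,
        guard_windows=config.guard_windows,
    )
    return aggregate_main_complex_z(series)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the result bundle to disk.

    Stages: tau selection (if ``auto``) -> per-recording Phi series ->
    z-scoring -> main-complex aggregates -> MIP-cut / main-complex frequency
    shifts -> rank-pattern test -> feeling scores and rating correlations.
    Every excluded window or recording is logged with its reason; an
    ``INCOMPLETE`` marker file exists in the output directory for the
    duration of the run and is removed on success.
    """
    rec_dir = Path(config.recordings_dir)
    if not rec_dir.is_dir():
        raise FileNotFoundError(f"recordings directory not found: {rec_dir}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    chash = config_hash(config)
    comment = f"phistress {__version__} config_hash={chash}"
    log: list[str] = []

    paths = _discover_recordings(rec_dir)
    if not paths:
        raise FileNotFoundError(f"no recordings (*.csv) found in {rec_dir}")
    recordings = {key: read_recording(p) for key, p in paths.items()}

    if config.tau == "auto":
        tau, profile = select_tau(
            list(recordings.values()),
            plan=WindowingPlan(config.td_frames, config.shift_frames),
            ridge=config.ridge,
            window_step=4,
        )
        profile.to_csv(out_dir / "tau_profile.csv", index=False)
        log.append(f"tau=auto selected tau={tau}")
    else:
        tau = int(config.tau)

    series_by_key: dict = {}
    excluded: list = []
    for key, frame in recordings.items():
        participant, condition = key
        try:
            series = process_recording(frame, config, tau)
        except (PhiStressError, ValueError) as exc:
            excluded.append(key)
            log.append(f"EXCLUDED recording {key}: {exc}")
            continue
        base_idx = series.baseline.baseline_windows
        frac_bad = float(series.missing[base_idx].mean()) if len(base_idx) else 1.0
        if frac_bad > config.exclude_degenerate_frac:
            excluded.append(key)
            log.append(
                f"EXCLUDED recording {key}: {frac_bad:.0%} degenerate baseline windows"
            )
            continue
        n_miss = int(series.missing.sum())
        if n_miss:
            log.append(f"recording {key}: {n_miss} missing windows")
        series_by_key[key] = series
        write_recording(
            series.to_frame(), out_dir / f"series_{participant}_{condition}.csv", comment
        )
        write_recording(
            series.subsets_to_frame(),
            out_dir / f"subsets_{participant}_{condition}.csv",
            comment,
        )

    # frequency shifts per recording, both label kinds
    pre_rng = (0.0, config.pre_task_end_s)
    task_rng = (config.pre_task_end_s, config.task_end_s)
    shift_rows = []
    for (participant, condition), series in series_by_key.items():
        for kind in ("mip_cut", "argmax_main_complex"):
            try:
                fs = frequency_shift(series, pre_rng, task_rng, label_kind=kind)
            except ValueError as exc:
                log.append(f"frequency_shift skipped for {(participant, condition)}: {exc}")
                continue
            tab = fs.to_frame()
            tab.insert(0, "label_kind", kind)
            tab.insert(0, "condition", condition)
            tab.insert(0, "participant", participant)
            shift_rows.append(tab)
    if shift_rows:
        write_recording(
            pd.concat(shift_rows, ignore_index=True),
            out_dir / "frequency_shifts.csv",
            comment,
        )

    # rank-pattern test over conditions present for every participant
    conditions = sorted({c for (_, c) in series_by_key})
    participants = sorted(
        {p for (p, _) in series_by_key}
    )
    complete = [
        p for p in participants if all((p, c) in series_by_key for c in conditions)
    ]
    rank_result = None
    if len(conditions) >= 2 and complete:
        per_cond = {}
        for c in conditions:
            rows = []
            for p in complete:
                s = series_by_key[(p, c)]
                mask = s.phase_mask(*task_rng)
                rows.append(np.where(mask, s.sum_z, np.nan)[mask])
            width = min(len(r) for r in rows)
            per_cond[c] = np.vstack([r[:width] for r in rows])
        try:
            rank_result = rank_pattern_test(per_cond, n_mc=10**5, seed=config.seed)
        except ValueError as exc:
            log.append(f"rank_pattern_test skipped: {exc}")
    if rank_result is not None:
        with open(out_dir / "rank_patterns.txt", "w") as fh:
            fh.write(f"# {comment}\n")
            for pat, cnt in zip(rank_result.patterns, rank_result.counts):
                fh.write(f"{'>'.join(pat)}\t{int(cnt)}\n")
            fh.write(f"chi_square\t{rank_result.chi_square:.6g}\n")
            fh.write(f"p_value\t{rank_result.p_value:.6g}\n")

    # feeling scores and rating correlations
    scores_tab = None
    if config.ratings_file:
        ratings = read_ratings(config.ratings_file)
        deltas = rating_deltas(ratings, baseline_condition=config.baseline_condition)
        comps = valence_composites(deltas)
        score_rows = []
        for p in participants:
            base_key = (p, config.baseline_condition)
            if base_key not in series_by_key:
                continue
            for c in conditions:
                if c == config.baseline_condition or (p, c) not in series_by_key:
                    continue
                try:
                    sc = phi_feeling_score(
                        series_by_key[(p, c)],
                        series_by_key[base_key],
                        *task_rng,
                        participant=p,
                        condition=c,
                    )
                except (ReliabilityError, ValueError) as exc:
                    log.append(f"score skipped for {(p, c)}: {exc}")
                    continue
                score_rows.append(
                    (p, c, sc.si, sc.n_windows_used, sc.n_windows_skipped)
                )
        scores_tab = pd.DataFrame(
            score_rows,
            columns=[
                "participant",
                "condition",
                "si",
                "n_windows_used",
                "n_windows_skipped",
            ],
        )
        write_recording(scores_tab, out_dir / "scores.csv", comment)

        corr_rows = []
        items = sorted(deltas["item"].unique())
        for c in [x for x in conditions if x != config.baseline_condition]:
            sub = scores_tab[scores_tab["condition"] == c].set_index("participant")["si"]
            for item in items:
                d = (
                    deltas[(deltas["condition"] == c) & (deltas["item"] == item)]
                    .set_index("participant")["dr"]
                )
                joined = pd.concat([sub, d], axis=1, join="inner").dropna()
                if len(joined) < 3:
                    continue
                res = correlate_scores(joined["si"], joined["dr"])
                corr_rows.append((c, item, res.t, res.r, res.p, res.n))
            cc = comps[comps["condition"] == c].set_index("participant")
            for comp in ("positive", "negative"):
                joined = pd.concat([sub, cc[comp]], axis=1, join="inner").dropna()
                if len(joined) < 3:
                    continue
                res = correlate_scores(joined["si"], joined[comp])
                corr_rows.append((c, f"valence_{comp}", res.t, res.r, res.p, res.n))
        corrs = pd.DataFrame(
            corr_rows, columns=["condition", "item", "t", "r", "p", "n"]
        )
        write_recording(corrs, out_dir / "correlations.csv", comment)

    meta = out_dir / "run_metadata.txt"
    with open(meta, "w") as fh:
        fh.write(f"phistress_version = {__version__}\n")
        fh.write(f"config_hash = {chash}\n")
        for k, v in config.as_mapping().items():
            fh.write(f"{k} = {v}\n")
        fh.write(f"tau_used = {tau}\n")
        fh.write(f"n_recordings = {len(series_by_key)}\n")
        fh.write(f"n_excluded = {len(excluded)}\n")
        for line in log:
            fh.write(f"log: {line}\n")
    marker.unlink()
    return {
        "tau": tau,
        "series": series_by_key,
        "excluded": excluded,
        "rank_result": rank_result,
        "scores": scores_tab,
        "out_dir": out_dir,
        "log": log,
    }
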