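"""Subjective-rating deltas and the Phi-based feeling score.

Ratings are visual-analogue-scale (VAS) values in [0, 100] per participant,
condition (Easy / Moderate / Difficult), phase (Pre / Task / Post) and item.
The analysis works on baseline-adjusted deltas

    r_i^I       = r_Task,i^I - r_Pre,i^I
    dr_i^{I,X}  = r_i^{I,X} - r_i^{I,Moderate}

and couples them to the Phi-based subjective-feeling score: the summed
difference, over task windows, between a condition's main-complex
sum-z(log Phi) series and the Moderate baseline condition's,

    s_i^X = sum_t [ sum_z^X(t) - sum_z^Moderate(t) ].

The inner sum runs over each condition's *own* main complexes at every
window (main-complex sets generally differ across conditions, so no
cross-condition matching of subsets is attempted), which reduces s_i^X to a
windowed difference of the two sum-z series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ReliabilityError
from .pipeline import PhiSeries

__all__ = [
    "SubjectiveScore",
    "CorrelationResult",
    "rating_deltas",
    "phi_feeling_score",
    "valence_composites",
    "correlate_scores",
    "binned_phase_means",
    "POSITIVE_VALENCE",
    "NEGATIVE_VALENCE",
]

POSITIVE_VALENCE = ("Exciting", "Effort", "Tiredness")
NEGATIVE_VALENCE = ("Irritation", "Boring")

_REQUIRED_COLS = {"participant", "condition", "phase", "item", "value"}


@dataclass(frozen=True)
class SubjectiveScore:
    """Phi-based feeling score of one participant in one condition."""

    participant: str | None
    condition: str | None
    si: float
    window_range: tuple[float, float]
    n_windows_used: int
    n_windows_skipped: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t statistic and two-sided p."""

    r: float
    t: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def _validate_ratings(table: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED_COLS - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    dup = table.duplicated(subset=["participant", "condition", "phase", "item"])
    if dup.any():
        raise ValueError("duplicate (participant, condition, phase, item) rows")
    vals = table["value"].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("VAS values must lie in [0, 100]")
    return table


def rating_deltas(
    table: pd.DataFrame, baseline_condition: str = "Moderate"
) -> pd.DataFrame:
    """Per (participant, condition, item): r = Task - Pre, dr = r - r_baseline.

    Missing phases or conditions yield explicit NaN, never silent zeros.
    The baseline condition's own dr is identically 0 wherever defined.
    Returns a tidy frame with columns participant, condition, item, r, dr.
    """
    table = _validate_ratings(table)
    wide = table.pivot_table(
        index=["participant", "condition", "item"],
        columns="phase",
        values="value",
        aggfunc="first",
    )
    for phase in ("Task", "Pre"):
        if phase not in wide.columns:
            wide[phase] = np.nan
    r = (wide["Task"] - wide["Pre"]).rename("r").reset_index()
    base = (
        r[r["condition"] == baseline_condition]
        .set_index(["participant", "item"])["r"]
        .rename("r_base")
    )
    out = r.join(base, on=["participant", "item"])
    out["dr"] = out["r"] - out["r_base"]
    return out[["participant", "condition", "item", "r", "dr"]]


def phi_feeling_score(
    series_x: PhiSeries,
    series_baseline: PhiSeries,
    t1: float,
    t2: float,
    participant: str | None = None,
    condition: str | None = None,
    max_skip_frac: float = 0.5,
) -> SubjectiveScore:
    """s_i^X over the window range [t1, t2] (seconds, inclusive).

    Both series must share the window grid over the range.  Windows missing
    in either series are skipped and counted; more than ``max_skip_frac``
    skipped raises :class:`ReliabilityError`.  Antisymmetric under swapping
    the two series, and invariant to adding a common constant to both sum-z
    series over the range.
    """
    mask_x = (series_x.window_times >= t1 - 1e-9) & (series_x.window_times <= t2 + 1e-9)
    mask_b = (series_baseline.window_times >= t1 - 1e-9) & (
        series_baseline.window_times <= t2 + 1e-9
    )
    tx = series_x.window_times[mask_x]
    tb = series_baseline.window_times[mask_b]
    if len(tx) != len(tb) or not np.allclose(tx, tb):
        raise ValueError("series do not share a window grid on [t1, t2]")
    if len(tx) == 0:
        raise ValueError("no windows in the requested range")
    if series_x.sum_z is None or series_baseline.sum_z is None:
        raise ValueError("run aggregate_main_complex_z on both series first")
    zx = series_x.sum_z[mask_x]
    zb = series_baseline.sum_z[mask_b]
    ok = np.isfinite(zx) & np.isfinite(zb)
    n_used = int(ok.sum())
    n_skipped = int(len(zx) - n_used)
    if n_used == 0 or n_skipped / len(zx) > max_skip_frac:
        raise ReliabilityError(
            f"{n_skipped}/{len(zx)} windows unusable in [{t1}, {t2}]"
        )
    si = float(np.sum(zx[ok] - zb[ok]))
    return SubjectiveScore(
        participant=participant,
        condition=condition,
        si=si,
        window_range=(float(t1), float(t2)),
        n_windows_used=n_used,
        n_windows_skipped=n_skipped,
    )


def valence_composites(deltas: pd.DataFrame) -> pd.DataFrame:
    """Positive (Exciting + Effort + Tiredness) and negative
    (Irritation + Boring) valence composites of dr, per participant and
    condition.  A missing component makes the composite NaN."""
    wide = deltas.pivot_table(
        index=["participant", "condition"], columns="item", values="dr", aggfunc="first"
    )
    out = pd.DataFrame(index=wide.index)

    def strict_sum(items):
        cols = [wide[i] if i in wide.columns else pd.Series(np.nan, index=wide.index) for i in items]
        return sum(cols)  # NaN-propagating

    out["positive"] = strict_sum(POSITIVE_VALENCE)
    out["negative"] = strict_sum(NEGATIVE_VALENCE)
    return out.reset_index()


def correlate_scores(si_values, dr_values) -> CorrelationResult:
    """Pearson r between the feeling scores and rating deltas, with
    t = r sqrt((n-2)/(1-r^2)) and a two-sided p.

    Pairs with NaN on either side are dropped; fewer than 3 pairs is an
    error; zero variance on either side yields an undefined (NaN) result
    rather than an exception."""
    x = np.asarray(si_values, dtype=float)
    y = np.asarray(dr_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=np.nan, t=np.nan, p=np.nan, n=n)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) < 1.0:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    else:
        t = np.inf * np.sign(r)
    return CorrelationResult(r=r, t=float(t), p=float(res.pvalue), n=n)


def binned_phase_means(
    values,
    times,
    bin_seconds: float = 150.0,
    baseline_range: tuple[float, float] = (0.0, 600.0),
) -> pd.DataFrame:
    """Per-bin means of a scalar series, z-scored against the pre-task phase.

    Standardization uses the mean and sd (ddof=1) of the raw series inside
    ``baseline_range``; zero baseline variance (e.g. a constant series) is an
    error.  Returns columns bin_start_s, bin_end_s, mean, z.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and times must align")
    if len(v) == 0:
        raise ValueError("empty series")
    base = v[(t >= baseline_range[0]) & (t < baseline_range[1])]
    base = base[np.isfinite(base)]
    if len(base) < 2:
        raise ValueError("baseline phase has fewer than 2 samples")
    m, s = float(base.mean()), float(base.std(ddof=1))
    if not s > 0:
        raise ValueError("zero variance in the baseline phase")
    t0 = float(t.min())
    edges = np.arange(t0, float(t.max()) + bin_seconds, bin_seconds)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            continue
        mu = float(np.nanmean(v[sel]))
        rows.append((lo, hi, mu, (mu - m) / s))
    return pd.DataFrame(rows, columns=["bin_start_s", "bin_end_s", "mean", "z"])
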