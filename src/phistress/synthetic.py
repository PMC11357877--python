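"""Surrogate physiological recordings and ratings with planted structure.

The generator emulates the second-order statistical skeleton of a three-phase
stress experiment: five channels (three EEG sites Fz/Cz/Pz, an ECG lead and
an electrodermal channel) sampled at a fixed frame rate through a pre-task
rest, a task and a post-task rest.  Each phase evolves as a stationary
Gaussian VAR(1)

    X(t) = A_phase X(t-1) + e(t),        e ~ N(0, Q)

whose cross-channel coupling (the off-diagonal of A) is scaled per condition
during the task phase, so conditions differ in how entangled the channels
become under load.  The stationary covariance of each phase solves the
discrete Lyapunov equation S = A S A^T + Q, which makes every integrated-
information quantity analytically available (:func:`ground_truth`) -- the
oracle side of every planted-recovery test.

What is deliberately *not* modelled: waveform morphology (QRS shapes,
skin-conductance response curves, alpha rhythms).  The analysis consumes
lagged second-order structure only, and that is what the generator plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .complex_search import ComplexSet, PhiSubsetMap, find_main_complexes, phi_subset_map
from .iit_core import LaggedGaussianModel, MipResult, find_mip

__all__ = [
    "CHANNELS",
    "CONDITIONS",
    "RATING_ITEMS",
    "ArtifactSpec",
    "SyntheticSpec",
    "EffectModel",
    "GroundTruth",
    "PhaseTruth",
    "CohortData",
    "generate_recording",
    "ground_truth",
    "generate_cohort",
]

CHANNELS = ("Fz", "Cz", "Pz", "ECG", "EDA")
CONDITIONS = ("Easy", "Moderate", "Difficult")
PHASES = ("Pre", "Task", "Post")
RATING_ITEMS = (
    "Exciting",
    "Effort",
    "Concentration",
    "Tiredness",
    "Boring",
    "Irritation",
    "Annoying",
)


def _default_transition() -> np.ndarray:
    """Baseline VAR(1) transition: moderate self-memory per channel, a
    mutually coupled EEG block, weaker EEG-EDA and EEG-ECG links."""
    a = np.diag([0.50, 0.50, 0.50, 0.60, 0.70])
    eeg = (0, 1, 2)
    for i in eeg:
        for j in eeg:
            if i != j:
                a[i, j] = 0.08
    for i in eeg:  # EEG <-> EDA
        a[i, 4] = 0.05
        a[4, i] = 0.05
    for i in eeg:  # EEG <-> ECG (weakest link)
        a[i, 3] = 0.02
        a[3, i] = 0.02
    a[3, 4] = a[4, 3] = 0.01
    return a


def _default_innovation() -> np.ndarray:
    """Innovation covariance: unit variances with mildly correlated noise
    within the EEG block (exercises Phi*'s sensitivity to correlated
    external noise)."""
    q = np.eye(5)
    for i in (0, 1, 2):
        for j in (0, 1, 2):
            if i != j:
                q[i, j] = 0.1
    return q


def _scale_offdiag(a: np.ndarray, mult: float) -> np.ndarray:
    out = np.diag(np.diag(a)) + mult * (a - np.diag(np.diag(a)))
    return out


@dataclass(frozen=True)
class ArtifactSpec:
    """Square pulses added to every channel at a fixed period, emulating the
    periodic protocol disturbance (saliva sampling) left unfiltered in the
    raw signals."""

    period_s: float = 500.0
    amplitude: float = 5.0
    width_s: float = 2.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Defaults are the study-scale conditions: 500 frames/s and a
    600 s / 1800 s / 900 s phase schedule.  ``reduced()`` gives the 1:10
    test-scale profile (50 fps, 60/180/90 s) used throughout the test suite.
    """

    channels: tuple[str, ...] = CHANNELS
    fps: float = 500.0
    phases: tuple[tuple[str, float, float], ...] = (
        ("Pre", 0.0, 600.0),
        ("Task", 600.0, 2400.0),
        ("Post", 2400.0, 3300.0),
    )
    transition: np.ndarray = field(default_factory=_default_transition)
    innovation: np.ndarray = field(default_factory=_default_innovation)
    #: off-diagonal coupling multiplier applied during the task phase
    task_multipliers: dict = field(
        default_factory=lambda: {"Easy": 1.5, "Moderate": 1.0, "Difficult": 1.3}
    )
    artifact: ArtifactSpec | None = None

    def __post_init__(self):
        n = len(self.channels)
        a = np.asarray(self.transition, dtype=float)
        q = np.asarray(self.innovation, dtype=float)
        if a.shape != (n, n) or q.shape != (n, n):
            raise ValueError("transition/innovation must match channel count")
        object.__setattr__(self, "transition", a)
        object.__setattr__(self, "innovation", 0.5 * (q + q.T))
        if np.any(np.linalg.eigvalsh(self.innovation) <= 0):
            raise ValueError("innovation covariance must be positive definite")
        prev_end = 0.0
        for name, start, end in self.phases:
            if not np.isclose(start, prev_end) or end <= start:
                raise ValueError("phases must be contiguous and non-overlapping")
            prev_end = end
        for cond in self.task_multipliers:
            for phase, _, _ in self.phases:
                m = self.phase_transition(phase, cond)
                rho = float(np.max(np.abs(np.linalg.eigvals(m))))
                if rho >= 1.0:
                    raise ValueError(
                        f"unstable transition (spectral radius {rho:.3f}) "
                        f"for phase={phase}, condition={cond}"
                    )

    @classmethod
    def reduced(cls, **overrides) -> "SyntheticSpec":
        """Test-scale profile: 50 fps and 60/180/90 s phases (1:10)."""
        kw = dict(
            fps=50.0,
            phases=(("Pre", 0.0, 60.0), ("Task", 60.0, 240.0), ("Post", 240.0, 330.0)),
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def full(cls, **overrides) -> "SyntheticSpec":
        return cls(**overrides)

    def phase_transition(self, phase: str, condition: str) -> np.ndarray:
        """Transition matrix in force during ``phase`` for ``condition``."""
        mult = self.task_multipliers.get(condition, 1.0) if phase == "Task" else 1.0
        return _scale_offdiag(self.transition, mult)

    @property
    def duration_s(self) -> float:
        return self.phases[-1][2]

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _simulate_var(a, chol_q, n_steps, x0, rng):
    n = a.shape[0]
    eps = rng.standard_normal((n_steps, n)) @ chol_q.T
    out = np.empty((n_steps, n))
    x = x0
    for t in range(n_steps):
        x = a @ x + eps[t]
        out[t] = x
    return out


def generate_recording(
    spec: SyntheticSpec,
    condition: str,
    seed=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One recording: frames x channels DataFrame with a ``time_s`` column.

    Phase switches carry the state over but insert a burn-in of at least ten
    autocorrelation times under the new dynamics before recorded frames, so
    each phase's retained samples are (near-)stationary.  Reproducible from
    ``seed``; optional artifact pulses are added last.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chol_q = np.linalg.cholesky(spec.innovation)
    pieces = []
    x = np.zeros(len(spec.channels))
    for name, start, end in spec.phases:
        a = spec.phase_transition(name, condition)
        rho = float(np.max(np.abs(np.linalg.eigvals(a))))
        t_ac = -1.0 / np.log(rho) if 0 < rho < 1 else 1.0
        n_burn = int(np.clip(10.0 * t_ac, 20, 5000))
        x = _simulate_var(a, chol_q, n_burn, x, rng)[-1]
        n_frames = int(round((end - start) * spec.fps))
        block = _simulate_var(a, chol_q, n_frames, x, rng)
        x = block[-1]
        pieces.append(block)
    data = np.vstack(pieces)
    t = np.arange(data.shape[0]) / spec.fps
    if spec.artifact is not None:
        art = spec.artifact
        pulse = np.zeros(data.shape[0])
        k = 1
        while k * art.period_s < spec.duration_s:
            on = (t >= k * art.period_s) & (t < k * art.period_s + art.width_s)
            pulse[on] = art.amplitude
            k += 1
        data = data + pulse[:, None]
    frame = pd.DataFrame(data, columns=list(spec.channels))
    frame.insert(0, "time_s", t)
    return frame


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseTruth:
    """Exact second-order statistics and Phi structure of one phase."""

    phase: str
    transition: np.ndarray
    innovation: np.ndarray
    sigma: np.ndarray
    cov_cross: np.ndarray
    model: LaggedGaussianModel
    mip: MipResult
    phi_map: PhiSubsetMap
    complexes: ComplexSet


@dataclass(frozen=True)
class GroundTruth:
    """Per-phase analytic truth for one condition of a :class:`SyntheticSpec`."""

    condition: str
    tau: int
    phases: dict[str, PhaseTruth]


def ground_truth(spec: SyntheticSpec, condition: str, tau: int) -> GroundTruth:
    """Analytic Phi*/MIP/main complexes from the exact phase covariances.

    The stationary covariance solves S = A S A^T + Q and the lag-tau
    cross-covariance (past rows, present columns) is S (A^tau)^T; the same
    machinery used on estimated windows is then run on the exact matrices.
    """
    out = {}
    for name, _, _ in spec.phases:
        a = spec.phase_transition(name, condition)
        q = spec.innovation
        sigma = solve_discrete_lyapunov(a, q)
        sigma = 0.5 * (sigma + sigma.T)
        cross = sigma @ np.linalg.matrix_power(a, tau).T
        model = LaggedGaussianModel(
            nodes=tuple(spec.channels),
            tau=tau,
            cov_present=sigma.copy(),
            cov_past=sigma.copy(),
            cov_cross=cross,
            n_samples=10**9,
        )
        mip = find_mip(model)
        pmap = phi_subset_map(model=model)
        cset = find_main_complexes(pmap)
        out[name] = PhaseTruth(
            phase=name,
            transition=a,
            innovation=q,
            sigma=sigma,
            cov_cross=cross,
            model=model,
            mip=mip,
            phi_map=pmap,
            complexes=cset,
        )
    return GroundTruth(condition=condition, tau=tau, phases=out)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectModel:
    """Planted cohort-level effects.

    ``si_driver_sd`` spreads a per-participant latent u_i onto the Easy-task
    coupling multiplier, so participants genuinely differ in how entangled
    the Easy condition makes them; ``rating_loadings`` then couples a rating
    item to that same latent with population correlation ``rho`` -- the
    recoverable link between the Phi-based feeling score and the ratings.
    """

    task_multipliers: dict = field(
        default_factory=lambda: {"Easy": 1.5, "Moderate": 1.0, "Difficult": 1.3}
    )
    participant_sd: float = 0.04
    si_driver_sd: float = 0.2
    si_driver_condition: str = "Easy"
    #: item -> (condition, rho, scale)
    rating_loadings: dict = field(
        default_factory=lambda: {"Boring": ("Easy", 0.6, 20.0)}
    )
    rating_base: float = 50.0
    rating_noise_sd: float = 2.0

    @classmethod
    def null(cls) -> "EffectModel":
        """No condition differences, no rating coupling."""
        return cls(
            task_multipliers={c: 1.0 for c in CONDITIONS},
            participant_sd=0.0,
            si_driver_sd=0.0,
            rating_loadings={},
        )


@dataclass
class CohortData:
    """A pipeline-ready synthetic dataset plus its planted parameters."""

    recordings: dict  # (participant, condition) -> DataFrame
    ratings: pd.DataFrame
    planted: dict
    spec: SyntheticSpec
    effect: EffectModel


def generate_cohort(
    spec: SyntheticSpec,
    n_participants: int = 18,
    conditions=CONDITIONS,
    effect: EffectModel | None = None,
    seed=None,
) -> CohortData:
    """Recordings and a ratings table for a full within-subject cohort.

    Each participant gets one recording per condition; the participant's
    latent u_i perturbs the task coupling of ``effect.si_driver_condition``
    and loads onto the rating items in ``effect.rating_loadings``.  Warns if
    more than 20% of ratings hit the [0, 100] rails (scale saturation
    distorts planted correlations).
    """
    if effect is None:
        effect = EffectModel()
    rng = np.random.default_rng(seed)
    participants = [f"P{i+1:02d}" for i in range(n_participants)]
    u = rng.standard_normal(n_participants)
    recordings = {}
    multipliers = pd.DataFrame(index=participants, columns=list(conditions), dtype=float)
    for i, p in enumerate(participants):
        for cond in conditions:
            mult = effect.task_multipliers.get(cond, 1.0)
            mult += effect.participant_sd * rng.standard_normal()
            if cond == effect.si_driver_condition:
                mult += effect.si_driver_sd * u[i]
            mult = max(mult, 0.0)
            multipliers.loc[p, cond] = mult
            spec_i = replace(
                spec, task_multipliers={**spec.task_multipliers, cond: mult}
            )
            recordings[(p, cond)] = generate_recording(spec_i, cond, rng=rng)

    rows = []
    n_clipped = 0
    for i, p in enumerate(participants):
        for cond in conditions:
            for phase in PHASES:
                for item in RATING_ITEMS:
                    val = effect.rating_base + effect.rating_noise_sd * rng.standard_normal()
                    loading = effect.rating_loadings.get(item)
                    if loading is not None and phase == "Task" and cond == loading[0]:
                        _, rho, scale = loading
                        val = effect.rating_base + scale * (
                            rho * u[i] + np.sqrt(1.0 - rho**2) * rng.standard_normal()
                        )
                    clipped = float(np.clip(val, 0.0, 100.0))
                    n_clipped += clipped != val
                    rows.append((p, cond, phase, item, clipped))
    ratings = pd.DataFrame(
        rows, columns=["participant", "condition", "phase", "item", "value"]
    )
    frac = n_clipped / len(rows)
    if frac > 0.2:
        warnings.warn(
            f"{frac:.0%} of ratings clipped at the scale rails; planted "
            "correlations will be attenuated",
            stacklevel=2,
        )
    planted = {"u": u, "multipliers": multipliers, "participants": participants}
    return CohortData(
        recordings=recordings, ratings=ratings, planted=planted, spec=spec, effect=effect
    )
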