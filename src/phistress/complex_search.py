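"""Complexes and main complexes of a node set.

For every subsystem T (|T| >= 2) the MIP search yields Phi_MIP^T.  A
*complex* is a subsystem whose Phi_MIP strictly exceeds that of every strict
superset; a *main complex* is a complex whose Phi_MIP additionally strictly
exceeds that of every strict subset of size >= 2 -- a local maximum of
Phi_MIP over the subset lattice.  Main complexes are the informational cores
of the system; theory predicts that two main complexes never overlap, but
arbitrary Phi maps (and noisy estimates) can violate that prediction, so
overlap handling is explicit (``on_overlap``).

Singletons are excluded throughout: Phi of a single node is undefined under
bipartition, and the smallest meaningful subsystem is a pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .exceptions import DegenerateModelError, ExclusivityError
from .iit_core import Bipartition, LaggedGaussianModel, MipResult, find_mip

__all__ = [
    "SubsetPhi",
    "PhiSubsetMap",
    "ComplexSet",
    "enumerate_subsystems",
    "phi_subset_map",
    "find_complexes",
    "find_main_complexes",
]


@dataclass(frozen=True)
class SubsetPhi:
    """Phi_MIP of one subsystem; ``degenerate`` marks unusable estimates."""

    subset: frozenset[str]
    phi: float | None
    mip: Bipartition | None
    degenerate: bool = False


@dataclass(frozen=True)
class PhiSubsetMap:
    """Phi_MIP for every subsystem (size >= min_size) of a node set."""

    nodes: tuple[str, ...]
    entries: dict[frozenset[str], SubsetPhi]
    min_size: int = 2

    def __post_init__(self):
        expected = {frozenset(s) for s in enumerate_subsystems(self.nodes, self.min_size)}
        if set(self.entries) != expected:
            missing = expected - set(self.entries)
            extra = set(self.entries) - expected
            raise ValueError(f"incomplete subset map (missing={missing}, extra={extra})")

    def phi_of(self, subset) -> float | None:
        return self.entries[frozenset(subset)].phi

    @property
    def usable(self) -> dict[frozenset[str], float]:
        return {
            s: e.phi for s, e in self.entries.items() if not e.degenerate
        }


@dataclass(frozen=True)
class ComplexSet:
    """Complexes and main complexes with their Phi_MIP values."""

    complexes: tuple[frozenset[str], ...]
    main_complexes: tuple[frozenset[str], ...]
    phi_of: dict[frozenset[str], float] = field(repr=False)

    def __post_init__(self):
        main = set(self.main_complexes)
        if not main <= set(self.complexes):
            raise ValueError("every main complex must be a complex")


def enumerate_subsystems(nodes, min_size: int = 2) -> list[tuple[str, ...]]:
    """All subsets of ``nodes`` with size >= ``min_size``, in canonical order
    (increasing size, lexicographic within a size).  For 5 nodes and
    min_size 2 there are 2^5 - 5 - 1 = 26 of them."""
    labels = sorted(str(n) for n in nodes)
    if len(labels) < min_size:
        raise ValueError(f"need at least {min_size} nodes")
    out = []
    for r in range(min_size, len(labels) + 1):
        out.extend(itertools.combinations(labels, r))
    return out


def phi_subset_map(
    segment=None,
    tau: int | None = None,
    min_size: int = 2,
    *,
    model: LaggedGaussianModel | None = None,
    ridge: float = 0.0,
    nodes=None,
    beta_max: float = 10.0,
) -> PhiSubsetMap:
    """Phi_MIP of every subsystem, from a segment or a pre-estimated model.

    The full model is estimated once and restricted per subset (restriction
    of an empirical lagged covariance equals the empirical covariance of the
    restricted channels, so nothing is lost).  Degenerate subsets are flagged
    in place, never silently dropped.
    """
    from .iit_core import estimate_lagged_gaussian  # local to avoid cycle noise

    if model is None:
        if segment is None or tau is None:
            raise ValueError("provide either a segment and tau, or model=")
        model = estimate_lagged_gaussian(segment, tau, ridge=ridge, nodes=nodes)
    entries: dict[frozenset[str], SubsetPhi] = {}
    for subset in enumerate_subsystems(model.nodes, min_size):
        key = frozenset(subset)
        try:
            sub = model.restrict(subset)
            mip: MipResult = find_mip(sub, beta_max=beta_max)
            entries[key] = SubsetPhi(key, mip.phi_mip, mip.mip)
        except DegenerateModelError:
            entries[key] = SubsetPhi(key, None, None, degenerate=True)
    return PhiSubsetMap(nodes=tuple(model.nodes), entries=entries, min_size=min_size)


def find_complexes(pmap: PhiSubsetMap) -> list[frozenset[str]]:
    """Subsets whose Phi_MIP strictly exceeds every strict superset's.

    The full node set has no strict superset and therefore always qualifies
    (vacuously).  Degenerate subsets are excluded as candidates and skipped
    as comparators.
    """
    usable = pmap.usable
    out = []
    for cand, phi in usable.items():
        ok = True
        for other, phi_o in usable.items():
            if cand < other and not (phi > phi_o):
                ok = False
                break
        if ok:
            out.append(cand)
    return sorted(out, key=lambda s: (len(s), tuple(sorted(s))))


def find_main_complexes(
    pmap: PhiSubsetMap, on_overlap: str = "keep"
) -> ComplexSet:
    """Complexes that are local maxima of Phi_MIP over the subset lattice.

    A main complex strictly exceeds every strict superset (it is a complex)
    and every strict subset of size >= ``min_size``.  ``on_overlap`` controls
    what happens if two main complexes intersect -- ``"keep"`` returns them
    all (the default; real windowed estimates do produce more than two, hence
    overlapping, main complexes), ``"raise"`` enforces the theoretical
    exclusivity prediction by raising :class:`ExclusivityError`.
    """
    if on_overlap not in ("keep", "raise"):
        raise ValueError("on_overlap must be 'keep' or 'raise'")
    usable = pmap.usable
    complexes = find_complexes(pmap)
    mains = []
    for cand in complexes:
        phi = usable[cand]
        ok = True
        for other, phi_o in usable.items():
            if other < cand and not (phi > phi_o):
                ok = False
                break
        if ok:
            mains.append(cand)
    mains = sorted(mains, key=lambda s: (len(s), tuple(sorted(s))))
    if on_overlap == "raise":
        for a, b in itertools.combinations(mains, 2):
            if a & b:
                raise ExclusivityError(
                    f"main complexes overlap: {sorted(a)} and {sorted(b)}"
                )
    phi_of = {s: usable[s] for s in complexes}
    return ComplexSet(
        complexes=tuple(complexes), main_complexes=tuple(mains), phi_of=phi_of
    )
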