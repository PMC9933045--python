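"""Tandem MIDs and positional-isotopomer deconvolution.

A tandem MID is the joint distribution T[j, k] of precursor mass shift j and
fragment mass shift k for one MS2 fragment. Because a fragment retains a
known subset of the parent's tracer atoms, each candidate positional
isotopomer s of a given precursor shift predicts a deterministic fragment
shift |s ∩ fragment atoms|; the observed conditional fragment spectrum at
shift j is then a mixture of these predictions, and the isotopomer weights
are recovered by constrained linear deconvolution. Classic example: the two
first-turn TCA isotopomers of M+2 glutamate (1,2-13C2 via pyruvate
dehydrogenase, 3,4-13C2 via pyruvate carboxylase) are separated by the
m+1/m+2 ratio of the c2–c5 fragment, while the c4–c5 fragment adds the
constraint that neither isotopomer can produce an m+2 fragment peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .chem_model import ConfigError, FragmentDef, Isotopomer, MetaboliteDef
from .mid_enrichment import MIDVector

__all__ = [
    "TandemMID",
    "IsotopomerSolution",
    "assemble_tandem_mid",
    "predict_fragment_shift",
    "enumerate_isotopomers",
    "resolve_isotopomer_fractions",
    "tandem_mid_report",
]

_SUM_TOL = 1e-9

# Weight on the simplex equality row appended to the stacked NNLS system;
# large enough that Σw = 1 holds to ~1e-12 without swamping conditioning.
_SIMPLEX_WEIGHT = 1e4


@dataclass(frozen=True)
class TandemMID:
    """Joint precursor × fragment mass-shift distribution for one fragment.

    Row sums equal the precursor MID; rows for precursor shifts with no
    acquired fragment spectrum are zero and listed in `missing_rows`.
    """

    fragment: FragmentDef
    T: np.ndarray  # shape (n+1, k+1)
    missing_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if (T < -_SUM_TOL).any():
            raise ValueError("tandem MID entries must be non-negative")
        if abs(T.sum() - 1.0) > 1e-6 and not self.missing_rows:
            raise ValueError(f"tandem MID sums to {T.sum()}, expected 1")
        object.__setattr__(self, "T", T)

    @property
    def precursor_mid(self) -> np.ndarray:
        return self.T.sum(axis=1)

    def conditional(self, j: int) -> np.ndarray:
        """Fragment-shift distribution given precursor shift j."""
        row = self.T[j]
        s = row.sum()
        if s <= 0.0:
            raise ValueError(f"no fragment signal at precursor shift {j}")
        return row / s


def predict_fragment_shift(s: Isotopomer, frag: FragmentDef) -> int:
    """Fragment mass shift produced by isotopomer *s*: the number of its
    labeled positions retained in the fragment."""
    return len(s.positions & frag.atom_subset)


def assemble_tandem_mid(
    precursor_mid: MIDVector,
    conditionals: Mapping[int, MIDVector],
    fragment: FragmentDef,
) -> TandemMID:
    """Combine a precursor MID with per-precursor-shift conditional fragment
    MIDs by the product rule T[j, k] = M_j · P(k | j).

    Precursor shifts carrying mass but lacking an acquired conditional
    spectrum give zero rows, reported in `missing_rows`.
    """
    n = precursor_mid.n
    k = fragment.k
    T = np.zeros((n + 1, k + 1))
    missing = []
    for j in range(n + 1):
        pj = precursor_mid[j]
        if j in conditionals:
            cond = conditionals[j]
            if cond.n != k:
                raise ValueError(
                    f"conditional MID at shift {j} has length {cond.n + 1}, "
                    f"fragment {fragment.name} needs {k + 1}"
                )
            T[j] = pj * cond.fractions
        elif pj > _SUM_TOL:
            missing.append(j)
    return TandemMID(fragment=fragment, T=T, missing_rows=tuple(missing))


def enumerate_isotopomers(
    met: MetaboliteDef,
    j: int,
    candidates: Optional[Sequence[Isotopomer]] = None,
) -> tuple[Isotopomer, ...]:
    """Candidate positional isotopomers for precursor shift j.

    Declared candidates (biochemical prior knowledge, e.g. first-turn TCA
    patterns) are used when given; otherwise all C(n, j) position subsets are
    enumerated in deterministic lexicographic order. Exhaustive enumeration
    is almost always rank-deficient for the solver and will be flagged as
    unidentifiable.
    """
    if not 0 <= j <= met.n:
        raise ConfigError(f"precursor shift {j} outside 0..{met.n} for {met.name}")
    if candidates is not None:
        for c in candidates:
            if c.shift != j:
                raise ConfigError(
                    f"declared candidate {c.label()} has {c.shift} positions, "
                    f"expected {j}"
                )
            if not c.positions <= met.atom_set:
                raise ConfigError(
                    f"candidate {c.label()} uses atoms outside {met.name}"
                )
        return tuple(candidates)
    return tuple(
        Isotopomer(frozenset(subset))
        for subset in combinations(met.atom_labels, j)
    )


@dataclass(frozen=True)
class IsotopomerSolution:
    """Non-negative simplex-constrained weights over candidate isotopomers."""

    metabolite: str
    precursor_shift: int
    candidates: tuple[Isotopomer, ...]
    weights: np.ndarray
    identifiable: bool
    residual: float
    rank: int

    def as_dict(self) -> dict[str, float]:
        return {c.label(): float(w) for c, w in zip(self.candidates, self.weights)}


def _design_matrix(
    candidates: Sequence[Isotopomer], fragments: Sequence[FragmentDef]
) -> np.ndarray:
    """Stacked indicator matrix: one row per (fragment, fragment shift k),
    A[(f,k), s] = 1 iff isotopomer s yields shift k in fragment f."""
    rows = []
    for frag in fragments:
        block = np.zeros((frag.k + 1, len(candidates)))
        for s_idx, cand in enumerate(candidates):
            block[predict_fragment_shift(cand, frag), s_idx] = 1.0
        rows.append(block)
    return np.vstack(rows)


def resolve_isotopomer_fractions(
    tandem_mids: Sequence[TandemMID],
    j: int,
    candidates: Sequence[Isotopomer],
    metabolite: str = "",
) -> IsotopomerSolution:
    """Resolve positional-isotopomer weights at precursor shift j from one or
    more fragments' conditional MIDs.

    All fragments are solved jointly in a single stacked system
    min ‖A·w − b‖² s.t. w ≥ 0, Σw = 1 (the simplex constraint enters as a
    strongly weighted equality row of the NNLS system, then w is
    renormalized). Rank deficiency never raises: the solution is returned
    with ``identifiable=False`` and no uniqueness claim.
    """
    if not candidates:
        raise ConfigError("isotopomer resolution needs at least one candidate")
    if not tandem_mids:
        raise ConfigError("isotopomer resolution needs at least one tandem MID")
    fragments = [t.fragment for t in tandem_mids]
    A = _design_matrix(candidates, fragments)
    b = np.concatenate([t.conditional(j) for t in tandem_mids])

    ones = np.ones((1, len(candidates)))
    A_aug = np.vstack([A, _SIMPLEX_WEIGHT * ones])
    b_aug = np.concatenate([b, [_SIMPLEX_WEIGHT]])
    w, _ = nnls(A_aug, b_aug)
    total = w.sum()
    if total > 0:
        w = w / total
    rank = int(np.linalg.matrix_rank(np.vstack([A, ones])))
    return IsotopomerSolution(
        metabolite=metabolite,
        precursor_shift=j,
        candidates=tuple(candidates),
        weights=w,
        identifiable=rank >= len(candidates),
        residual=float(np.linalg.norm(A @ w - b)),
        rank=rank,
    )


def tandem_mid_report(
    solutions: Sequence[IsotopomerSolution],
    precursor_mids: Mapping[str, MIDVector],
) -> pd.DataFrame:
    """Isotopomer-resolved MID table: each precursor isotopologue fraction is
    split into named positional-isotopomer fractions M_j · w_s.

    The per-metabolite rows at shift j sum back to the precursor fraction
    M_j (conservation)."""
    rows = []
    for sol in solutions:
        mid = precursor_mids[sol.metabolite]
        mj = mid[sol.precursor_shift]
        for cand, w in zip(sol.candidates, sol.weights):
            rows.append(
                {
                    "metabolite": sol.metabolite,
                    "precursor_shift": sol.precursor_shift,
                    "isotopomer": cand.label(),
                    "fraction": mj * float(w),
                    "identifiable": sol.identifiable,
                    "residual": sol.residual,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite",
            "precursor_shift",
            "isotopomer",
            "fraction",
            "identifiable",
            "residual",
        ],
    )
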