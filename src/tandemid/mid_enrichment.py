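"""Mass-isotopologue distributions, mean isotopic enrichment, and
labeled-fraction summaries.

Mean enrichment (ME) is the average fraction of tracer atoms that are
labeled: ME = Σ_{i=1..n} M_i · i / n, where M_i is the fraction of molecules
carrying i heavy tracer atoms out of n. A fully unlabeled pool has ME = 0, a
fully labeled one ME = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MIDVector",
    "EnrichmentResult",
    "normalize_mid",
    "mean_enrichment",
    "labeled_fraction",
    "moiety_weighted_enrichment",
    "enrichment_percent",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MIDVector:
    """Isotopologue fractions M0..Mn over mass shifts, summing to one."""

    fractions: np.ndarray
    provenance: str = "raw"  # raw | corrected

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size < 1:
            raise ValueError("MID must be a non-empty 1-D vector")
        if (f < -_SUM_TOL).any():
            raise ValueError("MID fractions must be non-negative")
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"MID fractions sum to {f.sum()}, expected 1")
        object.__setattr__(self, "fractions", np.clip(f, 0.0, None))

    @property
    def n(self) -> int:
        return self.fractions.size - 1

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i])


@dataclass(frozen=True)
class EnrichmentResult:
    """Mean enrichment of a metabolite or one of its moiety fragments."""

    me: float
    n: int
    source: str = "intact"

    def __post_init__(self) -> None:
        if not -_SUM_TOL <= self.me <= 1.0 + _SUM_TOL:
            raise ValueError(f"mean enrichment {self.me} outside [0, 1]")
        object.__setattr__(self, "me", float(min(max(self.me, 0.0), 1.0)))


def normalize_mid(areas: Sequence[float], provenance: str = "raw") -> MIDVector:
    """Turn raw isotopologue areas into fractions summing to one."""
    a = np.asarray(areas, dtype=float)
    total = a.sum()
    if total <= 0.0:
        raise ValueError("all-zero signal: cannot normalize MID")
    return MIDVector(a / total, provenance=provenance)


def mean_enrichment(mid: MIDVector, source: str = "intact") -> EnrichmentResult:
    """ME = Σ_{i=1..n} M_i · i / n."""
    n = mid.n
    if n == 0:
        raise ValueError("mean enrichment undefined for a molecule with 0 tracer atoms")
    i = np.arange(n + 1)
    return EnrichmentResult(me=float((mid.fractions * i).sum() / n), n=n, source=source)


def labeled_fraction(mid: MIDVector) -> float:
    """Fraction of molecules carrying at least one tracer atom: 1 − M0."""
    return float(1.0 - mid[0])


def moiety_weighted_enrichment(
    parts: Sequence[tuple[EnrichmentResult, int]],
    expected_n: int | None = None,
) -> EnrichmentResult:
    """Atom-weighted mean enrichment of a moiety partition:
    ME_intact = Σ_f ME_f · n_f / Σ_f n_f.

    When fragments tile the intact molecule's tracer atoms (e.g. glutathione
    F1 glutamate moiety + F2 glycine-cysteine moiety covering all 10
    carbons), this equals the intact enrichment. `expected_n`, if given, is
    checked against the summed atom counts to catch non-partition fragment
    sets.
    """
    if not parts:
        raise ValueError("moiety enrichment needs at least one fragment")
    total_atoms = sum(n_f for _, n_f in parts)
    if expected_n is not None and total_atoms != expected_n:
        raise ValueError(
            f"fragment atom counts sum to {total_atoms}, not the intact "
            f"molecule's {expected_n}; declare the fragments as a partition "
            "(partition flag) covering all tracer atoms"
        )
    me = sum(er.me * n_f for er, n_f in parts) / total_atoms
    return EnrichmentResult(me=me, n=total_atoms, source="moiety-weighted")


def enrichment_percent(me: float, rule: str = "floor") -> int:
    """Integer-percent rendering used in report tables.

    Default is floor (21.5% prints as 21); pass rule="round" for
    round-half-even.
    """
    if rule == "floor":
        return int(math.floor(me * 100.0 + 1e-12))
    if rule == "round":
        return int(round(me * 100.0))
    raise ValueError(f"unknown rounding rule {rule!r}")
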