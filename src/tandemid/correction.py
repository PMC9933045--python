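"""Natural-abundance and tracer-purity correction of mass isotopologue
distributions.

The forward model is linear: if ``x`` is the true tracer-labeling
distribution over mass shifts 0..n (the fraction of molecules with exactly j
nominally labeled tracer atoms), the expected observed isotopologue
distribution is ``m = F @ x`` where ``F`` convolves in (a) heavy isotopes
occurring naturally at the n−j unlabeled tracer positions and (b) tracer
impurity, i.e. nominally labeled atoms that are actually light. Correction
inverts this map by non-negative least squares, never by raw matrix
inversion, so noisy inputs cannot produce negative fractions.

Two modes are provided. ``high_resolution_tracer_only`` (default) assumes
the instrument resolves the tracer-element isotopologues from isobaric
interferences of other elements, as on a high-resolution TOF.
``low_resolution_full_formula`` additionally convolves the nominal-mass
isotope patterns of every non-tracer element of the molecular formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from math import comb

import numpy as np
from scipy.optimize import nnls

from .chem_model import ConfigError, ElementalFormula, ISOTOPE_PATTERNS, TracerSpec

__all__ = [
    "CorrectionMatrix",
    "CorrectionResult",
    "build_natural_abundance_matrix",
    "build_purity_matrix",
    "combined_correction_matrix",
    "correct_mid",
    "HIGH_RES",
    "LOW_RES",
]

logger = logging.getLogger(__name__)

HIGH_RES = "high_resolution_tracer_only"
LOW_RES = "low_resolution_full_formula"

_COLSUM_TOL = 1e-12


@dataclass(frozen=True)
class CorrectionMatrix:
    """Column-stochastic forward map from true labeling distribution to the
    expected observed isotopologue distribution."""

    F: np.ndarray
    mode: str
    tracer: TracerSpec
    n: int

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (self.n + 1, self.n + 1):
            raise ValueError(f"matrix shape {F.shape} != ({self.n + 1}, {self.n + 1})")
        if (F < -_COLSUM_TOL).any():
            raise ValueError("correction matrix has negative entries")
        colsums = F.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"columns not stochastic: sums {colsums}")
        object.__setattr__(self, "F", F)

    def __matmul__(self, other):
        if isinstance(other, CorrectionMatrix):
            if other.n != self.n:
                raise ValueError("size mismatch in matrix composition")
            return CorrectionMatrix(
                self.F @ other.F, mode=self.mode, tracer=self.tracer, n=self.n
            )
        return self.F @ np.asarray(other, dtype=float)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.F, delimiter=",")


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial pmf over k = 0..n, computed directly (robust for the tiny
    probabilities natural abundances can take)."""
    k = np.arange(n + 1)
    if p <= 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p >= 1.0:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    coef = np.array([comb(n, int(i)) for i in k], dtype=float)
    return coef * p**k * (1.0 - p) ** (n - k)


def _element_pattern(element: str, count: int) -> np.ndarray:
    """Isotope pattern of `count` natural atoms of `element` over nominal
    mass shifts, by repeated convolution of the single-atom pattern."""
    out = np.array([1.0])
    single = np.asarray(ISOTOPE_PATTERNS[element], dtype=float)
    for _ in range(count):
        out = np.convolve(out, single)
    return out


def build_natural_abundance_matrix(
    n: int,
    tracer: TracerSpec,
    mode: str = HIGH_RES,
    formula: Optional[ElementalFormula] = None,
) -> CorrectionMatrix:
    """Forward convolution matrix for natural heavy-isotope abundance.

    In high-resolution mode column j is the binomial distribution of heavy
    isotopes among the n−j unlabeled tracer positions:
    ``F[i, j] = C(n−j, i−j) a^(i−j) (1−a)^(n−i)`` for i ≥ j. In
    low-resolution mode each column is additionally convolved with the
    combined isotope pattern of the formula's non-tracer atoms, truncated at
    shift n and renormalized to keep columns stochastic.
    """
    if n < 1:
        raise ConfigError("natural-abundance matrix needs n >= 1 tracer atoms")
    if mode not in (HIGH_RES, LOW_RES):
        raise ConfigError(f"unknown correction mode {mode!r}")
    a = tracer.natural_abundance
    F = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        F[j:, j] = _binom_pmf(n - j, a)
    if mode == LOW_RES:
        F = _convolve_formula_pattern(F, n, tracer, formula)
    return CorrectionMatrix(F, mode=mode, tracer=tracer, n=n)


def _convolve_formula_pattern(F, n, tracer, formula):
    if formula is None:
        raise ConfigError("low-resolution mode requires the molecular formula")
    pattern = np.array([1.0])
    for elem, count in formula.counts.items():
        natural = count - (n if elem == tracer.element else 0)
        if natural < 0:
            raise ConfigError(f"formula has {count} {elem} atoms but n={n} tracer atoms")
        if natural:
            pattern = np.convolve(pattern, _element_pattern(elem, natural))
    full = np.zeros_like(F)
    for j in range(n + 1):
        col = np.convolve(F[:, j], pattern)[: n + 1]
        full[:, j] = col / col.sum()
    return full


def build_purity_matrix(n: int, tracer: TracerSpec) -> CorrectionMatrix:
    """Forward matrix for tracer impurity: each nominally labeled atom is
    heavy with probability p (the isotopic purity), so
    ``P[i, j] = C(j, i) p^i (1−p)^(j−i)`` for i ≤ j."""
    if n < 1:
        raise ConfigError("purity matrix needs n >= 1 tracer atoms")
    p = tracer.purity
    if p <= 0.0:
        raise ConfigError("tracer purity 0 gives a degenerate correction matrix")
    P = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        P[: j + 1, j] = _binom_pmf(j, p)
    return CorrectionMatrix(P, mode=HIGH_RES, tracer=tracer, n=n)


def combined_correction_matrix(
    n: int,
    tracer: TracerSpec,
    mode: str = HIGH_RES,
    formula: Optional[ElementalFormula] = None,
) -> CorrectionMatrix:
    """Total forward map for natural abundance plus tracer impurity.

    Column j is the exact convolution Binom(j, purity) ⊛ Binom(n−j,
    abundance): each of the j nominally labeled atoms is heavy with the
    purity probability, each of the n−j unlabeled tracer positions with the
    natural-abundance probability. This matches brute-force enumeration of
    all 2^n atom states exactly; note it is *not* the matrix product
    ``F_nat @ F_purity``, which would re-expose atoms that failed labeling
    to natural abundance a second time (an O(a·(1−p)) error).
    """
    if n < 1:
        raise ConfigError("correction matrix needs n >= 1 tracer atoms")
    a = tracer.natural_abundance
    p = tracer.purity
    if p <= 0.0:
        raise ConfigError("tracer purity 0 gives a degenerate correction matrix")
    F = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        F[:, j] = np.convolve(_binom_pmf(j, p), _binom_pmf(n - j, a))
    if mode == LOW_RES:
        F = _convolve_formula_pattern(F, n, tracer, formula)
    elif mode != HIGH_RES:
        raise ConfigError(f"unknown correction mode {mode!r}")
    return CorrectionMatrix(F, mode=mode, tracer=tracer, n=n)


@dataclass(frozen=True)
class CorrectionResult:
    """Corrected labeling fractions plus inversion diagnostics."""

    fractions: np.ndarray
    residual: float  # relative L2 residual ||F x - m|| / ||m||
    high_residual: bool
    clamped_negatives: bool


def correct_mid(
    measured: np.ndarray,
    matrix: CorrectionMatrix,
    residual_threshold: float = 0.05,
) -> CorrectionResult:
    """Recover the true tracer-labeling distribution from measured
    isotopologue areas.

    Solves ``min ||F x − m||²`` subject to ``x ≥ 0`` and renormalizes x to
    sum 1. Negative measured areas (baseline-subtraction artifacts) are
    clamped to zero with a logged warning. A relative residual above
    `residual_threshold` sets a warning flag on the result instead of
    raising.
    """
    m = np.asarray(measured, dtype=float)
    if m.shape != (matrix.n + 1,):
        raise ValueError(
            f"measured vector length {m.shape} does not match n={matrix.n}"
        )
    if not np.isfinite(m).all():
        raise ValueError("measured areas must be finite")
    clamped = bool((m < 0).any())
    if clamped:
        logger.warning("clamping %d negative measured areas to zero", (m < 0).sum())
        m = np.clip(m, 0.0, None)
    total = m.sum()
    if total <= 0.0:
        raise ValueError("all-zero measured signal: nothing to correct")
    m = m / total
    x, rnorm = nnls(matrix.F, m)
    s = x.sum()
    if s <= 0.0:
        raise ValueError("correction produced an all-zero solution")
    residual = float(rnorm)  # m is normalized, so this is already relative
    return CorrectionResult(
        fractions=x / s,
        residual=residual,
        high_residual=residual > residual_threshold,
        clamped_negatives=clamped,
    )
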