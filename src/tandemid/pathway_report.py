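"""Study-level analytics: protein normalization, labeled/unlabeled channel
pools, GSH/GSSG ratios, combined labeled fractions, enrichment summaries and
two-group significance testing.

The "unlabeled channel" of a metabolite is operationalized as the corrected
M0 fraction times its total area, and the "labeled channel" as (1 − M0)
times the area — the two complementary pools of pre-existing versus
tracer-containing molecules after natural-abundance correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem_model import StudyConfig
from .mid_enrichment import MIDVector, mean_enrichment, normalize_mid

__all__ = [
    "StudyTable",
    "GroupComparison",
    "normalize_by_protein",
    "channel_pools",
    "gsh_gssg_ratio",
    "combined_labeled_fraction",
    "compare_groups",
    "enrichment_summary",
    "estimate_de_novo_fraction",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample", "metabolite", "fragment", "precursor_index", "iso_index", "area"]
META_COLUMNS = ["group", "protein_ug"]

# Mean ME below this, after correction, is reported as "no incorporation"
# (e.g. cysteine under either tracer, glycine under 15N).
NO_INCORPORATION_THRESHOLD = 0.01


@dataclass
class StudyTable:
    """Long-format per-sample peak areas with group/protein metadata.

    One row per (sample, metabolite, fragment, precursor_index, iso_index).
    Intact-metabolite rows have empty fragment/precursor_index. The column
    ``corrected_fraction`` is filled by the correction stage.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"study table missing columns: {missing}")
        for col in META_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        if "corrected_fraction" not in self.data.columns:
            self.data["corrected_fraction"] = np.nan
        bad_protein = self.data["protein_ug"].dropna() <= 0
        if bad_protein.any():
            raise ValueError("protein content must be positive where present")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    def intact(self) -> pd.DataFrame:
        return self.data[self.data["fragment"].isna()]

    def intact_areas(self, sample: str, metabolite: str) -> np.ndarray:
        sub = self.intact()
        sub = sub[(sub["sample"] == sample) & (sub["metabolite"] == metabolite)]
        sub = sub.sort_values("iso_index")
        return sub["area"].to_numpy(dtype=float)

    def intact_mid(self, sample: str, metabolite: str, corrected: bool = True) -> MIDVector:
        sub = self.intact()
        sub = sub[(sub["sample"] == sample) & (sub["metabolite"] == metabolite)]
        sub = sub.sort_values("iso_index")
        if corrected:
            vals = sub["corrected_fraction"].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(
                    f"corrected fractions absent for {sample}/{metabolite}; "
                    "run the correction stage first"
                )
            return MIDVector(vals, provenance="corrected")
        return normalize_mid(sub["area"].to_numpy(dtype=float))

    def fragment_areas(
        self, sample: str, metabolite: str, fragment: str, precursor_index: int
    ) -> np.ndarray:
        d = self.data
        sub = d[
            (d["sample"] == sample)
            & (d["metabolite"] == metabolite)
            & (d["fragment"] == fragment)
            & (d["precursor_index"] == precursor_index)
        ].sort_values("iso_index")
        return sub["area"].to_numpy(dtype=float)

    def fragment_precursor_shifts(
        self, sample: str, metabolite: str, fragment: str
    ) -> list[int]:
        d = self.data
        sub = d[
            (d["sample"] == sample)
            & (d["metabolite"] == metabolite)
            & (d["fragment"] == fragment)
        ]
        return sorted(int(j) for j in sub["precursor_index"].dropna().unique())

    def group_of(self, sample: str) -> str:
        vals = self.data.loc[self.data["sample"] == sample, "group"].dropna().unique()
        return str(vals[0]) if len(vals) else ""

    def total_intact_area(self, sample: str, metabolite: str) -> float:
        return float(self.intact_areas(sample, metabolite).sum())


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-group comparison of one summary statistic."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    statistic: float
    p_value: float
    significant: bool
    alpha: float


def normalize_by_protein(area: float, protein_ug: float) -> float:
    """Peak area per µg of sample protein."""
    if protein_ug is None or not math.isfinite(protein_ug) or protein_ug <= 0:
        raise ValueError("protein content must be a positive, finite value")
    return area / protein_ug


def channel_pools(mid: MIDVector, total_area: float) -> tuple[float, float]:
    """Split a metabolite's total area into (unlabeled, labeled) pools:
    unlabeled = M0 · area, labeled = (1 − M0) · area. Pools conserve the
    total exactly."""
    unlabeled = mid[0] * total_area
    return unlabeled, total_area - unlabeled


def gsh_gssg_ratio(gsh_pool: float, gssg_pool: float) -> Optional[float]:
    """Same-channel GSH/GSSG peak-area ratio; None (missing) on a zero
    denominator rather than infinity."""
    if gssg_pool <= 0.0:
        logger.warning("GSSG pool is zero; ratio reported as missing")
        return None
    return gsh_pool / gssg_pool


def combined_labeled_fraction(
    areas_and_mids: Sequence[tuple[float, MIDVector]],
) -> tuple[float, float]:
    """(unlabeled, labeled) fraction of a pooled set of metabolites
    (typically GSH + GSSG), weighting each metabolite's labeled fraction by
    its corrected area: labeled = Σ (1−M0_m)·area_m / Σ area_m."""
    pairs = [(a, m) for a, m in areas_and_mids if a > 0]
    if not pairs:
        raise ValueError("no metabolite areas to pool")
    if len(pairs) < len(areas_and_mids):
        logger.warning("pooling computed on a subset: some metabolites had zero area")
    total = sum(a for a, _ in pairs)
    labeled = sum((1.0 - m[0]) * a for a, m in pairs) / total
    return 1.0 - labeled, labeled


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> Optional[GroupComparison]:
    """Two-sided Welch's t-test between two groups of replicate values.

    Returns None (test skipped) when either group has fewer than two values.
    Degenerate zero-variance comparisons of identical groups report p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        logger.warning("group comparison skipped: fewer than 2 values per group")
        return None
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(p):
        # both groups constant: identical means -> no evidence of difference
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
        stat = 0.0 if p == 1.0 else math.inf
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def enrichment_summary(
    study: StudyTable,
    config: StudyConfig,
    alpha: float = 0.05,
    adjust: Optional[str] = None,
) -> pd.DataFrame:
    """Per-metabolite, per-group mean ± SD of mean enrichment, with the
    between-group Welch comparison — the machine-readable pathway map of
    tracer atom flow (glucose → glutamate / serine / glycine → GSH → GSSG).

    Metabolites whose pooled mean ME falls below 1% are flagged
    ``no_incorporation`` (the behaviour expected of cysteine under either
    tracer and of glycine under the nitrogen tracer). `adjust="bh"` applies
    Benjamini–Hochberg across metabolites; default is unadjusted per-panel
    flags.
    """
    intact = study.intact()
    rows = []
    groups = sorted(g for g in intact["group"].dropna().unique())
    # unlabeled control cultures (suffix "_control") are summarized but kept
    # out of the two-group significance test and the incorporation flag
    labeled_groups = [g for g in groups if not str(g).endswith("_control")]
    for met in study.metabolites:
        if met not in config.metabolites:
            continue
        per_group: dict[str, list[float]] = {g: [] for g in groups}
        for sample in study.samples:
            g = study.group_of(sample)
            if g not in per_group:
                continue
            try:
                mid = study.intact_mid(sample, met, corrected=True)
            except ValueError:
                continue
            per_group[g].append(mean_enrichment(mid).me)
        labeled_me = [v for g in labeled_groups for v in per_group[g]]
        if not labeled_me:
            continue
        row: dict = {"metabolite": met, "n_atoms": config.metabolites[met].n}
        for g in groups:
            vals = np.asarray(per_group[g])
            row[f"me_mean_{g}"] = float(vals.mean()) if vals.size else np.nan
            row[f"me_sd_{g}"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        row["no_incorporation"] = bool(np.mean(labeled_me) < NO_INCORPORATION_THRESHOLD)
        if len(labeled_groups) == 2:
            ga, gb = labeled_groups
            cmp = compare_groups(per_group[ga], per_group[gb], alpha)
            row["delta_me"] = row[f"me_mean_{gb}"] - row[f"me_mean_{ga}"]
            row["p_value"] = cmp.p_value if cmp else np.nan
            row["significant"] = cmp.significant if cmp else False
        rows.append(row)
    out = pd.DataFrame(rows)
    if adjust == "bh" and "p_value" in out.columns and len(out):
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = np.isfinite(p).sum()
    order = np.argsort(p)
    adj = np.full_like(p, np.nan, dtype=float)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


def estimate_de_novo_fraction(moiety_me: float, precursor_me: float) -> float:
    """De novo synthesis fraction of a product pool from the enrichment of
    one of its moieties relative to the free precursor: a product assembled
    entirely from the labeled precursor pool would show the precursor's
    enrichment in that moiety, so f_syn ≈ ME_moiety / ME_precursor."""
    if precursor_me <= 0:
        raise ValueError("precursor enrichment must be positive to estimate f_syn")
    return min(moiety_me / precursor_me, 1.0)
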