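"""Forward simulator for the glutathione tracer study.

Generates ground-truth positional-isotopomer distributions for the
glucose → glutamate / serine / glycine → GSH → GSSG network under a 13C or
15N tracer, then pushes them through the same linear measurement model the
correction stage inverts: natural-abundance and tracer-purity convolution,
scaling by metabolite abundance and per-sample protein content, and
multiplicative lognormal noise. Every quantity the pipeline estimates
(corrected MIDs, enrichments, isotopomer weights, channel pools) therefore
has a known truth for parameter-recovery testing.

Scope of the truth model: first-turn TCA labeling only. Glutamate carries
mass at M+0, M+2 (split between the 1,2- and 3,4-positional isotopomers,
i.e. the pyruvate-dehydrogenase and pyruvate-carboxylase entry routes) and
M+5 (molecules assembled entirely from labeled carbon, standing in for the
heavily labeled fraction of the pool at isotopic steady state). Glycine is
M+2 via de novo serine synthesis, serine M+3, cysteine always unlabeled.
GSH is a mixture: a de novo fraction f_syn assembled from the current
precursor pools, the rest pre-existing and unlabeled. GSSG, the disulfide
dimer, has the self-convolution of the GSH MID.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chem_model import ConfigError, StudyConfig, default_config
from .correction import combined_correction_matrix
from .pathway_report import StudyTable
from .tandem_isotopomer import predict_fragment_shift
from .chem_model import Isotopomer

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_measurement",
    "generate_study",
    "healthy_preset",
    "rotenone_preset",
]

# Fraction of the precursor ion current carried into each MS2 fragment
# spectrum; only a scale factor, cancelled by per-spectrum normalization.
_FRAGMENT_YIELD = 0.5

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth and measurement-noise parameters for one study group.

    Labeling state (all fractions in [0, 1]):

    - ``glu_m2`` / ``glu_m5``: glutamate M+2 and M+5 isotopologue fractions.
      The default healthy state (0.25, 0.50) gives a mean enrichment of
      (2·0.25 + 5·0.50)/5 = 0.60.
    - ``pdh_fraction`` (φ): share of the glutamate M+2 mass carried by the
      1,2-labeled isotopomer (pyruvate-dehydrogenase route) versus the
      3,4-labeled one (pyruvate-carboxylase route).
    - ``ser_labeled`` / ``gly_labeled``: M+3 serine and M+2 glycine
      fractions (de novo serine pathway); their ME equals these fractions.
    - ``glu_n_labeled`` / ``ser_n_labeled``: 15N-mode amide-nitrogen
      labeling of glutamate and serine; glycine and cysteine carry no 15N.
    - ``f_syn``: de novo fraction of the glutathione pool assembled from
      the labeled precursor pools during the tracing window.
    - ``oxidized_share``: fraction of glutathione units oxidized to GSSG
      (two GSH per GSSG); sets the GSH/GSSG ratio.
    - ``substrate_labeled_fraction``: global multiplier on all labeling
      fractions; 0 gives an unlabeled control culture.

    Measurement model: per-metabolite base abundance (area per µg protein),
    lognormal noise CV, protein content mean/CV (µg), replicates per group.
    """

    tracer_element: str = "C"
    glu_m2: float = 0.25
    glu_m5: float = 0.50
    pdh_fraction: float = 0.70
    akg_m2: float = 0.20
    akg_m5: float = 0.54
    ser_labeled: float = 0.11
    gly_labeled: float = 0.07
    glu_n_labeled: float = 0.23
    ser_n_labeled: float = 0.05
    f_syn: float = 0.67
    oxidized_share: float = 1.0 / 6.0
    substrate_labeled_fraction: float = 1.0
    glutathione_pool: float = 4.0e5
    abundance: Mapping[str, float] = field(
        default_factory=lambda: {
            "glutamate": 5.0e5,
            "ketoglutarate": 1.0e5,
            "serine": 2.0e5,
            "glycine": 3.0e5,
            "cysteine": 5.0e4,
        }
    )
    noise_cv: float = 0.10
    protein_mean_ug: float = 38.0
    protein_cv: float = 0.10
    replicates: int = 5

    def __post_init__(self) -> None:
        for name in (
            "glu_m2",
            "glu_m5",
            "pdh_fraction",
            "akg_m2",
            "akg_m5",
            "ser_labeled",
            "gly_labeled",
            "glu_n_labeled",
            "ser_n_labeled",
            "f_syn",
            "oxidized_share",
            "substrate_labeled_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.glu_m2 + self.glu_m5 > 1.0 or self.akg_m2 + self.akg_m5 > 1.0:
            raise ConfigError("isotopologue fractions exceed 1")
        if self.noise_cv < 0 or self.protein_cv < 0:
            raise ConfigError("CVs must be non-negative")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")
        if self.tracer_element not in ("C", "N"):
            raise ConfigError(f"unsupported tracer element {self.tracer_element!r}")

    def unlabeled_control(self) -> "SimulationParams":
        return replace(self, substrate_labeled_fraction=0.0)


def healthy_preset() -> SimulationParams:
    """Healthy mid-brain neuron conditions: glutamate ME 0.60, GSH ME ≈ 0.21,
    PDH-dominant M+2 split, GSH/GSSG area ratio ≈ 10."""
    return SimulationParams()


def rotenone_preset() -> SimulationParams:
    """Complex-I-inhibited conditions: reduced TCA entry (lower glutamate
    labeling and φ), reduced de novo GSH synthesis, higher oxidized share
    (GSH/GSSG ratio well below 10), smaller glutathione pool."""
    return SimulationParams(
        glu_m2=0.18,
        glu_m5=0.32,
        pdh_fraction=0.55,
        akg_m2=0.15,
        akg_m5=0.36,
        ser_labeled=0.10,
        gly_labeled=0.06,
        glu_n_labeled=0.22,
        ser_n_labeled=0.05,
        f_syn=0.45,
        oxidized_share=0.40,
        glutathione_pool=3.0e5,
    )


@dataclass
class GroundTruth:
    """True positional-isotopomer distributions per metabolite, plus derived
    MIDs for metabolites (GSSG) whose truth is only defined at MID level."""

    config: StudyConfig
    isotopomers: dict[str, dict[frozenset, float]]
    mids: dict[str, np.ndarray]
    params: SimulationParams

    def mid(self, metabolite: str) -> np.ndarray:
        return self.mids[metabolite]

    def fragment_conditional(self, metabolite: str, fragment_name: str, j: int) -> np.ndarray:
        """True fragment-shift distribution given precursor shift j, from the
        positional isotopomers."""
        frag = next(
            f for f in self.config.fragments_of(metabolite) if f.name == fragment_name
        )
        dist = self.isotopomers[metabolite]
        cond = np.zeros(frag.k + 1)
        total = 0.0
        for positions, p in dist.items():
            if len(positions) != j or p <= 0:
                continue
            cond[predict_fragment_shift(Isotopomer(positions), frag)] += p
            total += p
        if total <= 0:
            raise ValueError(f"no truth mass at precursor shift {j} for {metabolite}")
        return cond / total

    def isotopomer_weights(self, metabolite: str, j: int) -> dict[frozenset, float]:
        """Normalized isotopomer weights within precursor shift j."""
        dist = self.isotopomers[metabolite]
        sub = {pos: p for pos, p in dist.items() if len(pos) == j and p > 0}
        total = sum(sub.values())
        return {pos: p / total for pos, p in sub.items()}

    def mean_enrichment(self, metabolite: str) -> float:
        mid = self.mids[metabolite]
        n = mid.size - 1
        return float((mid * np.arange(n + 1)).sum() / n)

    def to_json(self) -> str:
        payload = {
            "isotopomers": {
                met: {"+".join(sorted(pos)) or "unlabeled": p for pos, p in dist.items()}
                for met, dist in self.isotopomers.items()
            },
            "mids": {met: list(map(float, mid)) for met, mid in self.mids.items()},
        }
        return json.dumps(payload, indent=1)


def _mid_from_isotopomers(dist: Mapping[frozenset, float], n: int) -> np.ndarray:
    mid = np.zeros(n + 1)
    for positions, p in dist.items():
        mid[len(positions)] += p
    return mid


def generate_ground_truth(
    params: SimulationParams, config: Optional[StudyConfig] = None
) -> GroundTruth:
    """Build the true labeling state of the network for one condition."""
    if config is None:
        config = default_config(params.tracer_element)
    if config.tracer.element != params.tracer_element:
        raise ConfigError(
            f"config tracer {config.tracer.element} != params tracer "
            f"{params.tracer_element}"
        )
    s = params.substrate_labeled_fraction
    iso: dict[str, dict[frozenset, float]] = {}

    if params.tracer_element == "C":
        glu = _carbon_glutamate_like(
            params.glu_m2 * s, params.glu_m5 * s, params.pdh_fraction, prefix="c"
        )
        iso["glutamate"] = glu
        iso["ketoglutarate"] = _carbon_glutamate_like(
            params.akg_m2 * s, params.akg_m5 * s, params.pdh_fraction, prefix="c"
        )
        ser = params.ser_labeled * s
        iso["serine"] = {
            frozenset(): 1.0 - ser,
            frozenset({"c1", "c2", "c3"}): ser,
        }
        gly_dist = {
            frozenset(): 1.0 - params.gly_labeled * s,
            frozenset({"c1", "c2"}): params.gly_labeled * s,
        }
        iso["glycine"] = gly_dist
        iso["cysteine"] = {frozenset(): 1.0}
        # de novo GSH: glutamate moiety gc1..gc5, glycine moiety gc6,gc7,
        # cysteine moiety gc8..gc10 (always unlabeled)
        gsh: dict[frozenset, float] = {frozenset(): 1.0 - params.f_syn}
        glu_mapped = {
            frozenset(f"g{a}" for a in pos): p for pos, p in glu.items()
        }
        gly_mapped = {
            frozenset(): 1.0 - params.gly_labeled * s,
            frozenset({"gc6", "gc7"}): params.gly_labeled * s,
        }
        for gpos, gp in glu_mapped.items():
            for ypos, yp in gly_mapped.items():
                key = gpos | ypos
                gsh[key] = gsh.get(key, 0.0) + params.f_syn * gp * yp
        iso["GSH"] = gsh
    else:
        glu_n = params.glu_n_labeled * s
        iso["glutamate"] = {frozenset(): 1.0 - glu_n, frozenset({"n1"}): glu_n}
        ser_n = params.ser_n_labeled * s
        iso["serine"] = {frozenset(): 1.0 - ser_n, frozenset({"n1"}): ser_n}
        iso["glycine"] = {frozenset(): 1.0}
        iso["cysteine"] = {frozenset(): 1.0}
        # only the glutamate-moiety nitrogen (gn1) of de novo GSH is labeled
        gsh = {
            frozenset(): 1.0 - params.f_syn * glu_n,
            frozenset({"gn1"}): params.f_syn * glu_n,
        }
        iso["GSH"] = gsh

    mids = {
        met: _mid_from_isotopomers(dist, config.metabolites[met].n)
        for met, dist in iso.items()
        if met in config.metabolites
    }
    # GSSG = GSH disulfide dimer: MID is the self-convolution of the GSH MID
    if "GSSG" in config.metabolites:
        mids["GSSG"] = np.convolve(mids["GSH"], mids["GSH"])
    return GroundTruth(config=config, isotopomers=iso, mids=mids, params=params)


def _carbon_glutamate_like(
    m2: float, m5: float, phi: float, prefix: str
) -> dict[frozenset, float]:
    dist = {
        frozenset(): 1.0 - m2 - m5,
        frozenset({f"{prefix}1", f"{prefix}2"}): m2 * phi,
        frozenset({f"{prefix}3", f"{prefix}4"}): m2 * (1.0 - phi),
        frozenset(f"{prefix}{i}" for i in range(1, 6)): m5,
    }
    return {k: v for k, v in dist.items() if v > 0 or not k}


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _draw_protein(rng: np.random.Generator, params: SimulationParams) -> float:
    """Per-sample protein content: normal truncated at zero."""
    sd = params.protein_mean_ug * params.protein_cv
    while True:
        v = rng.normal(params.protein_mean_ug, sd)
        if v > 0:
            return float(v)


def _base_abundance(params: SimulationParams, metabolite: str) -> float:
    if metabolite == "GSH":
        return params.glutathione_pool * (1.0 - params.oxidized_share)
    if metabolite == "GSSG":
        return params.glutathione_pool * params.oxidized_share / 2.0
    return params.abundance.get(metabolite, 1.0e5)


def simulate_measurement(
    truth: GroundTruth,
    params: SimulationParams,
    rng: np.random.Generator,
    sample: str,
    group: str,
) -> pd.DataFrame:
    """One sample's long-format peak table: intact isotopologue areas for
    every metabolite and, for metabolites with declared fragments, one MS2
    conditional spectrum per precursor shift that carries true labeling mass.

    Observed distributions are the truth pushed through the combined
    natural-abundance × purity forward matrix (precursors with their own
    tracer-atom count, fragments with theirs), scaled by abundance × protein
    content and multiplied by
    lognormal noise per integrated peak. Deterministic given the generator
    state.
    """
    config = truth.config
    tracer = config.tracer
    protein = _draw_protein(rng, params)
    rows = []
    for met, mdef in config.metabolites.items():
        if met not in truth.mids:
            continue
        mid_true = truth.mids[met]
        F = combined_correction_matrix(mdef.n, tracer)
        mid_obs = F @ mid_true
        scale = _base_abundance(params, met) * protein
        noise = _lognormal_factors(rng, params.noise_cv, mdef.n + 1)
        for i in range(mdef.n + 1):
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "protein_ug": protein,
                    "metabolite": met,
                    "fragment": None,
                    "precursor_index": None,
                    "iso_index": i,
                    "area": scale * mid_obs[i] * noise[i],
                }
            )
        for frag in config.fragments_of(met):
            Ff = combined_correction_matrix(frag.k, tracer)
            for j in range(mdef.n + 1):
                if mid_true[j] <= _MASS_TOL:
                    continue
                cond_true = truth.fragment_conditional(met, frag.name, j)
                cond_obs = Ff @ cond_true
                block_scale = scale * _FRAGMENT_YIELD * mid_obs[j]
                fnoise = _lognormal_factors(rng, params.noise_cv, frag.k + 1)
                for k in range(frag.k + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "protein_ug": protein,
                            "metabolite": met,
                            "fragment": frag.name,
                            "precursor_index": j,
                            "iso_index": k,
                            "area": block_scale * cond_obs[k] * fnoise[k],
                        }
                    )
    return pd.DataFrame(rows)


def generate_study(
    healthy: Optional[SimulationParams] = None,
    perturbed: Optional[SimulationParams] = None,
    seed: int = 0,
    config: Optional[StudyConfig] = None,
    include_controls: bool = True,
    group_names: tuple[str, str] = ("healthy", "rotenone"),
) -> tuple[StudyTable, dict[str, GroundTruth]]:
    """Two-group labeled study (default: five replicates per group, healthy
    vs rotenone-like presets) plus one unlabeled control culture per group.

    Returns the long-format study table and the per-group ground truths
    (controls keyed as ``<group>_control``).
    """
    healthy = healthy or healthy_preset()
    perturbed = perturbed or rotenone_preset()
    rng = np.random.default_rng(seed)
    frames = []
    truths: dict[str, GroundTruth] = {}
    for group, params in zip(group_names, (healthy, perturbed)):
        truth = generate_ground_truth(params, config)
        truths[group] = truth
        for r in range(1, params.replicates + 1):
            frames.append(
                simulate_measurement(truth, params, rng, f"{group}_{r}", group)
            )
        if include_controls:
            ctrl = params.unlabeled_control()
            ctrl_truth = generate_ground_truth(ctrl, config)
            truths[f"{group}_control"] = ctrl_truth
            frames.append(
                simulate_measurement(
                    ctrl_truth, ctrl, rng, f"{group}_control", f"{group}_control"
                )
            )
    table = pd.concat(frames, ignore_index=True)
    return StudyTable(table), truths
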