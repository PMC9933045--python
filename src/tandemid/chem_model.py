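"""Domain types for tracer metabolomics: formulas, tracers, metabolites,
fragments and positional isotopomers.

Atom positions of the tracer element are named explicitly (``c1`` .. ``cn``
for carbon, ``n1`` .. for nitrogen) rather than inferred from molecular
structure; fragment definitions list which parent positions survive
fragmentation, which is all the tandem deconvolution needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ElementalFormula",
    "TracerSpec",
    "MetaboliteDef",
    "FragmentDef",
    "Isotopomer",
    "StudyConfig",
    "parse_formula",
    "tracer_atom_count",
    "validate_fragment",
    "load_config",
    "default_config",
    "DEFAULT_NATURAL_ABUNDANCE",
    "ISOTOPE_PATTERNS",
]


class ConfigError(ValueError):
    """Raised for malformed chemical or study configuration."""


# Natural heavy-isotope probability of the +1 isotope of the tracer element,
# standard terrestrial values (IUPAC representative isotopic composition).
DEFAULT_NATURAL_ABUNDANCE = {"C": 0.0107, "N": 0.00364}

# Nominal-mass-shift isotope patterns for the elements appearing in the
# metabolites handled here; index = mass shift in Da. Used only by the
# low-resolution full-formula correction mode.
ISOTOPE_PATTERNS: Mapping[str, Sequence[float]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "P": (1.0,),
}

_KNOWN_ELEMENTS = frozenset(ISOTOPE_PATTERNS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → atom-count map, e.g. glutamate ``C5H9NO4``."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ConfigError("formula must contain at least one element")
        for elem, cnt in self.counts.items():
            if cnt < 0:
                raise ConfigError(f"negative count for element {elem!r}")
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def to_string(self) -> str:
        """Hill notation: C first, H second, the rest alphabetical."""
        parts = []
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        for elem in order:
            cnt = self.counts.get(elem, 0)
            if cnt == 0:
                continue
            parts.append(elem if cnt == 1 else f"{elem}{cnt}")
        return "".join(parts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return {k: v for k, v in self.counts.items() if v} == {
            k: v for k, v in other.counts.items() if v
        }

    def __hash__(self) -> int:
        return hash(tuple(sorted((k, v) for k, v in self.counts.items() if v)))


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation chemical formula string.

    >>> parse_formula("C5H9NO4").counts
    {'C': 5, 'H': 9, 'N': 1, 'O': 4}
    """
    if not text or not text.strip():
        raise ConfigError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ConfigError(
                f"malformed formula {text!r}: unexpected token at {text[pos:]!r}"
            )
        elem, digits = m.group(1), m.group(2)
        if elem not in _KNOWN_ELEMENTS:
            raise ConfigError(f"unknown element symbol {elem!r} in formula {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


@dataclass(frozen=True)
class TracerSpec:
    """A stable-isotope tracer channel.

    purity
        Probability that a nominally labeled tracer atom is actually heavy
        (e.g. 0.99 for 13C6-glucose, 0.98 for 15N2-glutamine).
    natural_abundance
        Probability of the heavy isotope at an unlabeled position of the
        tracer element.
    """

    element: str
    purity: float = 1.0
    natural_abundance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise ConfigError(f"unsupported tracer element {self.element!r}")
        if not 0.0 <= self.purity <= 1.0:
            raise ConfigError("tracer purity must lie in [0, 1]")
        na = self.natural_abundance
        if na is None:
            object.__setattr__(
                self, "natural_abundance", DEFAULT_NATURAL_ABUNDANCE[self.element]
            )
        elif not 0.0 <= na <= 1.0:
            raise ConfigError("natural abundance must lie in [0, 1]")


@dataclass(frozen=True)
class MetaboliteDef:
    """A metabolite with an ordered set of tracer-atom labels.

    ``atom_labels`` follow the c1..cn positional convention; ``n`` (the
    tracer-atom count) must match the tracer-element count in the formula.
    """

    name: str
    formula: ElementalFormula
    tracer_element: str
    atom_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ConfigError(f"{self.name}: duplicate atom labels")
        expected = self.formula[self.tracer_element]
        if len(self.atom_labels) != expected:
            raise ConfigError(
                f"{self.name}: {len(self.atom_labels)} atom labels but formula "
                f"{self.formula.to_string()} has {expected} {self.tracer_element} atoms"
            )

    @property
    def n(self) -> int:
        return len(self.atom_labels)

    @property
    def atom_set(self) -> frozenset[str]:
        return frozenset(self.atom_labels)


def tracer_atom_count(met: MetaboliteDef, tracer: TracerSpec) -> int:
    """Number of tracer-element atoms available for labeling in *met*."""
    count = met.formula[tracer.element]
    if count == 0:
        raise ConfigError(
            f"{met.name} contains no {tracer.element} atoms and cannot be traced"
        )
    if met.tracer_element != tracer.element:
        raise ConfigError(
            f"{met.name} is configured for {met.tracer_element} tracing, "
            f"not {tracer.element}"
        )
    return count


@dataclass(frozen=True)
class FragmentDef:
    """An MS2 fragment retaining a subset of the parent's tracer atoms.

    ``partition_key``: fragments sharing a non-None key must tile the parent's
    tracer atoms disjointly (e.g. glutathione F1 + F2 cover all 10 carbons);
    used by moiety-weighted enrichment.
    """

    name: str
    parent: str
    atom_subset: frozenset[str]
    formula: Optional[ElementalFormula] = None
    partition_key: Optional[str] = None
    complement: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.atom_subset:
            raise ConfigError(f"fragment {self.name}: empty atom subset")

    @property
    def k(self) -> int:
        """Tracer-atom count of the fragment."""
        return len(self.atom_subset)


def validate_fragment(frag: FragmentDef, parent: MetaboliteDef) -> FragmentDef:
    """Check the fragment against its parent and fill in the complement
    (tracer atoms lost on fragmentation)."""
    if frag.parent != parent.name:
        raise ConfigError(
            f"fragment {frag.name} declares parent {frag.parent!r}, got {parent.name!r}"
        )
    extra = frag.atom_subset - parent.atom_set
    if extra:
        raise ConfigError(
            f"fragment {frag.name}: atoms {sorted(extra)} not in parent {parent.name}"
        )
    return FragmentDef(
        name=frag.name,
        parent=frag.parent,
        atom_subset=frag.atom_subset,
        formula=frag.formula,
        partition_key=frag.partition_key,
        complement=parent.atom_set - frag.atom_subset,
    )


@dataclass(frozen=True)
class Isotopomer:
    """A positional isotopomer: the set of labeled tracer-atom positions."""

    positions: frozenset[str]

    @property
    def shift(self) -> int:
        """Precursor mass shift this isotopomer explains."""
        return len(self.positions)

    def label(self) -> str:
        return "+".join(sorted(self.positions, key=_atom_sort_key)) or "unlabeled"


def _atom_sort_key(atom: str) -> tuple[str, int]:
    m = re.match(r"([a-zA-Z]+)(\d+)$", atom)
    if m:
        return (m.group(1), int(m.group(2)))
    return (atom, 0)


@dataclass
class StudyConfig:
    """Everything the pipeline needs to know about the chemistry of a study:
    the tracer, metabolite definitions, validated fragments, and declared
    candidate isotopomer sets per (metabolite, precursor shift)."""

    tracer: TracerSpec
    metabolites: dict[str, MetaboliteDef]
    fragments: dict[str, list[FragmentDef]]  # parent name -> fragments
    candidate_isotopomers: dict[tuple[str, int], tuple[Isotopomer, ...]]

    def __post_init__(self) -> None:
        self._validate_partitions()

    def _validate_partitions(self) -> None:
        for parent, frags in self.fragments.items():
            met = self.metabolites[parent]
            groups: dict[str, list[FragmentDef]] = {}
            for f in frags:
                if f.partition_key is not None:
                    groups.setdefault(f.partition_key, []).append(f)
            for key, members in groups.items():
                union: set[str] = set()
                total = 0
                for f in members:
                    union |= f.atom_subset
                    total += len(f.atom_subset)
                if union != set(met.atom_set) or total != met.n:
                    raise ConfigError(
                        f"{parent}: fragments in partition {key!r} do not tile "
                        f"the {met.n} tracer atoms disjointly"
                    )

    def fragments_of(self, metabolite: str) -> list[FragmentDef]:
        return self.fragments.get(metabolite, [])

    def partition_fragments(self, metabolite: str) -> list[FragmentDef]:
        """Fragments forming a declared moiety partition of *metabolite*
        (empty list if none declared)."""
        frags = [f for f in self.fragments_of(metabolite) if f.partition_key]
        return frags

    def candidates_for(self, metabolite: str, shift: int):
        return self.candidate_isotopomers.get((metabolite, shift))


def _atoms(prefix: str, n: int, start: int = 1) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(start, start + n))


def default_config(tracer_element: str = "C") -> StudyConfig:
    """The glutathione de novo synthesis panel: glutamate, ketoglutarate,
    serine, glycine, cysteine, GSH and GSSG, with the glutamate Frag_1/Frag_2
    and glutathione F1/F2 fragments.

    For carbon tracing the tracer is 13C6-glucose (99% isotopic purity); for
    nitrogen tracing, 15N2-glutamine (98% purity). GSSG, the glutathione
    disulfide dimer, carries twice the tracer atoms of GSH (20 C / 6 N).
    """
    if tracer_element == "C":
        tracer = TracerSpec("C", purity=0.99)
        mets = {
            "glutamate": MetaboliteDef(
                "glutamate", parse_formula("C5H9NO4"), "C", _atoms("c", 5)
            ),
            "ketoglutarate": MetaboliteDef(
                "ketoglutarate", parse_formula("C5H6O5"), "C", _atoms("c", 5)
            ),
            "serine": MetaboliteDef(
                "serine", parse_formula("C3H7NO3"), "C", _atoms("c", 3)
            ),
            "glycine": MetaboliteDef(
                "glycine", parse_formula("C2H5NO2"), "C", _atoms("c", 2)
            ),
            "cysteine": MetaboliteDef(
                "cysteine", parse_formula("C3H7NO2S"), "C", _atoms("c", 3)
            ),
            "GSH": MetaboliteDef(
                "GSH", parse_formula("C10H17N3O6S"), "C", _atoms("gc", 10)
            ),
            "GSSG": MetaboliteDef(
                "GSSG", parse_formula("C20H32N6O12S2"), "C", _atoms("gc", 20)
            ),
        }
        fragments = {
            "glutamate": [
                FragmentDef("Frag_1", "glutamate", frozenset(_atoms("c", 4, 2))),
                FragmentDef("Frag_2", "glutamate", frozenset(_atoms("c", 2, 4))),
            ],
            "GSH": [
                # F1 = glutamate moiety (5 C), F2 = glycine-cysteine moiety (5 C)
                FragmentDef(
                    "F1", "GSH", frozenset(_atoms("gc", 5)), partition_key="moieties"
                ),
                FragmentDef(
                    "F2", "GSH", frozenset(_atoms("gc", 5, 6)), partition_key="moieties"
                ),
            ],
        }
        candidates = {
            # first-turn TCA entry: PDH labels c1,c2; PC labels c3,c4
            ("glutamate", 2): (
                Isotopomer(frozenset({"c1", "c2"})),
                Isotopomer(frozenset({"c3", "c4"})),
            ),
            # GSH M+2: either the glutamate moiety carries the first-turn pair
            # or the glycine moiety is fully labeled
            ("GSH", 2): (
                Isotopomer(frozenset({"gc1", "gc2"})),
                Isotopomer(frozenset({"gc3", "gc4"})),
                Isotopomer(frozenset({"gc6", "gc7"})),
            ),
        }
    elif tracer_element == "N":
        tracer = TracerSpec("N", purity=0.98)
        mets = {
            "glutamate": MetaboliteDef(
                "glutamate", parse_formula("C5H9NO4"), "N", _atoms("n", 1)
            ),
            "serine": MetaboliteDef(
                "serine", parse_formula("C3H7NO3"), "N", _atoms("n", 1)
            ),
            "glycine": MetaboliteDef(
                "glycine", parse_formula("C2H5NO2"), "N", _atoms("n", 1)
            ),
            "cysteine": MetaboliteDef(
                "cysteine", parse_formula("C3H7NO2S"), "N", _atoms("n", 1)
            ),
            "GSH": MetaboliteDef(
                "GSH", parse_formula("C10H17N3O6S"), "N", _atoms("gn", 3)
            ),
            "GSSG": MetaboliteDef(
                "GSSG", parse_formula("C20H32N6O12S2"), "N", _atoms("gn", 6)
            ),
        }
        fragments = {
            "GSH": [
                # gn1 = glutamate-moiety N; gn2, gn3 = cysteine / glycine N
                FragmentDef(
                    "F1", "GSH", frozenset({"gn1"}), partition_key="moieties"
                ),
                FragmentDef(
                    "F2", "GSH", frozenset({"gn2", "gn3"}), partition_key="moieties"
                ),
            ],
        }
        candidates = {}
    else:
        raise ConfigError(f"unsupported tracer element {tracer_element!r}")

    fragments = {
        parent: [validate_fragment(f, mets[parent]) for f in frags]
        for parent, frags in fragments.items()
    }
    return StudyConfig(tracer, mets, fragments, candidates)


def load_config(path) -> StudyConfig:
    """Load a study configuration from YAML.

    Schema::

        tracer: {element: C, purity: 0.99, natural_abundance: 0.0107}
        metabolites:
          glutamate: {formula: C5H9NO4, atoms: [c1, c2, c3, c4, c5]}
        fragments:
          glutamate:
            - {name: Frag_1, atoms: [c2, c3, c4, c5]}
            - {name: F1, atoms: [...], partition: moieties, formula: ...}
        candidate_isotopomers:
          glutamate:
            2: [[c1, c2], [c3, c4]]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    def _require(d: dict, key: str, ctx: str):
        if key not in d:
            raise ConfigError(f"{path}: missing {key!r} in {ctx}")
        return d[key]

    traw = _require(raw, "tracer", "config")
    tracer = TracerSpec(
        element=_require(traw, "element", "tracer"),
        purity=float(traw.get("purity", 1.0)),
        natural_abundance=traw.get("natural_abundance"),
    )

    mets: dict[str, MetaboliteDef] = {}
    for name, mraw in _require(raw, "metabolites", "config").items():
        mets[name] = MetaboliteDef(
            name=name,
            formula=parse_formula(_require(mraw, "formula", f"metabolite {name}")),
            tracer_element=tracer.element,
            atom_labels=tuple(_require(mraw, "atoms", f"metabolite {name}")),
        )

    fragments: dict[str, list[FragmentDef]] = {}
    for parent, frags in (raw.get("fragments") or {}).items():
        if parent not in mets:
            raise ConfigError(f"{path}: fragment parent {parent!r} not declared")
        out = []
        for fraw in frags:
            frag = FragmentDef(
                name=_require(fraw, "name", f"fragment of {parent}"),
                parent=parent,
                atom_subset=frozenset(_require(fraw, "atoms", f"fragment of {parent}")),
                formula=(
                    parse_formula(fraw["formula"]) if fraw.get("formula") else None
                ),
                partition_key=fraw.get("partition"),
            )
            out.append(validate_fragment(frag, mets[parent]))
        fragments[parent] = out

    candidates: dict[tuple[str, int], tuple[Isotopomer, ...]] = {}
    for met_name, by_shift in (raw.get("candidate_isotopomers") or {}).items():
        if met_name not in mets:
            raise ConfigError(f"{path}: candidates for undeclared {met_name!r}")
        for shift, sets in by_shift.items():
            isos = []
            for positions in sets:
                iso = Isotopomer(frozenset(positions))
                if iso.shift != int(shift):
                    raise ConfigError(
                        f"{path}: candidate {sorted(positions)} for {met_name} "
                        f"shift {shift} has {iso.shift} positions"
                    )
                if not iso.positions <= mets[met_name].atom_set:
                    raise ConfigError(
                        f"{path}: candidate {sorted(positions)} uses atoms outside "
                        f"{met_name}"
                    )
                isos.append(iso)
            candidates[(met_name, int(shift))] = tuple(isos)

    return StudyConfig(tracer, mets, fragments, candidates)
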