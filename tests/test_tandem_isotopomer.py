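"""Tandem MID assembly and positional-isotopomer deconvolution."""

import numpy as np
import pytest

from tandemid.chem_model import ConfigError, FragmentDef, Isotopomer, validate_fragment
from tandemid.mid_enrichment import MIDVector
from tandemid.tandem_isotopomer import (
    assemble_tandem_mid,
    enumerate_isotopomers,
    predict_fragment_shift,
    resolve_isotopomer_fractions,
    tandem_mid_report,
)

PDH = Isotopomer(frozenset({"c1", "c2"}))
PC = Isotopomer(frozenset({"c3", "c4"}))


@pytest.fixture
def glu(carbon_config):
    return carbon_config.metabolites["glutamate"]


@pytest.fixture
def frag1(carbon_config):
    return carbon_config.fragments["glutamate"][0]  # c2-c5


@pytest.fixture
def frag2(carbon_config):
    return carbon_config.fragments["glutamate"][1]  # c4-c5


def test_predict_fragment_shift(frag1, frag2):
    assert predict_fragment_shift(PDH, frag1) == 1  # only c2 retained
    assert predict_fragment_shift(PC, frag1) == 2  # fully inside c2-c5
    assert predict_fragment_shift(PDH, frag2) == 0  # disjoint


def test_enumerate_isotopomers(glu, carbon_config):
    declared = enumerate_isotopomers(glu, 2, carbon_config.candidates_for("glutamate", 2))
    assert [c.label() for c in declared] == ["c1+c2", "c3+c4"]
    assert enumerate_isotopomers(glu, 0)[0].positions == frozenset()
    assert len(enumerate_isotopomers(glu, 2)) == 10  # C(5,2)
    with pytest.raises(ConfigError, match="positions"):
        enumerate_isotopomers(glu, 2, [Isotopomer(frozenset({"c1"}))])


def test_assemble_tandem_mid_product_rule(frag1):
    precursor = MIDVector(np.array([0.4, 0.0, 0.3, 0.0, 0.0, 0.3]))
    conds = {
        0: MIDVector(np.array([1.0, 0, 0, 0, 0])),
        2: MIDVector(np.array([0.0, 0.6, 0.4, 0.0, 0.0])),
        5: MIDVector(np.array([0.0, 0, 0, 0, 1.0])),
    }
    t = assemble_tandem_mid(precursor, conds, frag1)
    assert t.T[2, 1] == pytest.approx(0.18)
    assert t.T[2, 2] == pytest.approx(0.12)
    assert np.allclose(t.precursor_mid, precursor.fractions)
    assert t.missing_rows == ()


def test_assemble_flags_missing_rows(frag1):
    precursor = MIDVector(np.array([0.5, 0.0, 0.5, 0.0, 0.0, 0.0]))
    t = assemble_tandem_mid(precursor, {0: MIDVector(np.array([1.0, 0, 0, 0, 0]))}, frag1)
    assert t.missing_rows == (2,)


def test_assemble_rejects_wrong_length(frag2):
    precursor = MIDVector(np.array([1.0, 0, 0, 0, 0, 0]))
    with pytest.raises(ValueError, match="length"):
        assemble_tandem_mid(precursor, {0: MIDVector(np.array([1.0, 0, 0, 0]))}, frag2)


def _tandem_from_conditional(frag, j, cond, n=5):
    mid = np.zeros(n + 1)
    mid[j] = 1.0
    return assemble_tandem_mid(MIDVector(mid), {j: MIDVector(np.asarray(cond))}, frag)


def test_resolve_two_candidate_ratio(frag1):
    """The m+1/m+2 ratio of the c2-c5 fragment at precursor M+2 splits the
    PDH- and PC-route isotopomers directly."""
    t = _tandem_from_conditional(frag1, 2, [0.0, 0.6, 0.4, 0.0, 0.0])
    sol = resolve_isotopomer_fractions([t], 2, [PDH, PC])
    assert np.allclose(sol.weights, [0.6, 0.4], atol=1e-9)
    assert sol.identifiable
    assert sol.residual < 1e-9


def test_single_candidate_gets_weight_one(frag1):
    t = _tandem_from_conditional(frag1, 2, [0.3, 0.3, 0.4, 0.0, 0.0])
    sol = resolve_isotopomer_fractions([t], 2, [PDH])
    assert sol.weights[0] == pytest.approx(1.0)


def test_impossible_fragment_signal_flags_high_residual(frag2):
    """Neither first-turn M+2 isotopomer can put two labels into the c4-c5
    fragment, so observed m+2 mass there is unexplainable."""
    t = _tandem_from_conditional(frag2, 2, [0.2, 0.3, 0.5])
    sol = resolve_isotopomer_fractions([t], 2, [PDH, PC])
    assert sol.residual > 0.3


def test_joint_fragments_add_information(frag1, frag2):
    t1 = _tandem_from_conditional(frag1, 2, [0.0, 0.25, 0.75, 0.0, 0.0])
    t2 = _tandem_from_conditional(frag2, 2, [0.25, 0.75, 0.0])
    sol = resolve_isotopomer_fractions([t1, t2], 2, [PDH, PC])
    assert np.allclose(sol.weights, [0.25, 0.75], atol=1e-9)
    assert sol.residual < 1e-9


def test_indistinguishable_candidates_flagged_unidentifiable(frag1):
    """Candidates with identical predicted shifts in every declared fragment
    cannot be separated and must not claim uniqueness."""
    c34 = Isotopomer(frozenset({"c3", "c4"}))
    c45 = Isotopomer(frozenset({"c4", "c5"}))  # both fully inside c2-c5
    t = _tandem_from_conditional(frag1, 2, [0.0, 0.0, 1.0, 0.0, 0.0])
    sol = resolve_isotopomer_fractions([t], 2, [c34, c45])
    assert not sol.identifiable
    assert sol.weights.sum() == pytest.approx(1.0)


def test_empty_candidates_rejected(frag1):
    t = _tandem_from_conditional(frag1, 2, [0.0, 1.0, 0.0, 0.0, 0.0])
    with pytest.raises(ConfigError):
        resolve_isotopomer_fractions([t], 2, [])


def grid_search_weights(A, b, m, step=1e-3):
    """Exhaustive simplex search oracle for up to 3 candidates."""
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if m == 2:
        W = np.stack([ticks, 1.0 - ticks], axis=1)
    elif m == 3:
        w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
        mask = w1 + w2 <= 1.0 + 1e-12
        W = np.stack([w1[mask], w2[mask], 1.0 - w1[mask] - w2[mask]], axis=1)
    else:
        raise ValueError(m)
    resid = np.linalg.norm(A @ W.T - b[:, None], axis=0)
    return W[np.argmin(resid)]


def test_solver_matches_grid_search_oracle(frag1, frag2):
    from tandemid.tandem_isotopomer import _design_matrix

    rng = np.random.default_rng(7)
    cands = [PDH, PC, Isotopomer(frozenset({"c4", "c5"}))]
    A = _design_matrix(cands, [frag1, frag2])
    for _ in range(5):
        w_true = rng.dirichlet(np.ones(3))
        b = A @ w_true + rng.normal(0, 0.01, size=A.shape[0])
        t1 = _tandem_from_conditional(
            frag1, 2, np.clip(b[:5], 0, None) / np.clip(b[:5], 0, None).sum()
        )
        t2 = _tandem_from_conditional(
            frag2, 2, np.clip(b[5:], 0, None) / np.clip(b[5:], 0, None).sum()
        )
        b_used = np.concatenate([t1.conditional(2), t2.conditional(2)])
        sol = resolve_isotopomer_fractions([t1, t2], 2, cands)
        w_grid = grid_search_weights(A, b_used, 3)
        assert np.abs(sol.weights - w_grid).max() < 2e-3


def test_report_conserves_precursor_fractions(frag1):
    precursor = MIDVector(np.array([0.55, 0.0, 0.3, 0.0, 0.0, 0.15]))
    conds = {2: MIDVector(np.array([0.0, 0.6, 0.4, 0.0, 0.0]))}
    t = assemble_tandem_mid(precursor, conds, frag1)
    sol = resolve_isotopomer_fractions([t], 2, [PDH, PC], metabolite="glutamate")
    rep = tandem_mid_report([sol], {"glutamate": precursor})
    assert rep["fraction"].sum() == pytest.approx(precursor[2], abs=1e-9)
    by_iso = rep.set_index("isotopomer")["fraction"]
    assert by_iso["c1+c2"] == pytest.approx(0.18)
    assert by_iso["c3+c4"] == pytest.approx(0.12)
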