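"""Formula parsing, isotope patterns, correction matrices, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirmkit.isotopes import (
    CorrectionMatrix,
    FormulaError,
    IsotopePattern,
    MIDVector,
    build_correction_matrix,
    convolve,
    correct_mid,
    correction_matrices,
    element_pattern,
    fractional_enrichment,
    natural_pattern,
    parse_formula,
)
from conftest import enumerate_natural_pattern


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C", {"C": 1}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("C11H26NO3Si2", {"C": 11, "H": 26, "N": 1, "O": 3, "Si": 2}),
        ("C17H38O6PSi3", {"C": 17, "H": 38, "O": 6, "P": 1, "Si": 3}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).counts == expected


@pytest.mark.parametrize("bad", ["", "Xx3", "C6Zz", "c6h12", "C-3"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_formula_counts_must_be_positive_ints():
    from sirmkit.isotopes import ElementalFormula

    with pytest.raises(FormulaError):
        ElementalFormula({"C": 0})
    with pytest.raises(FormulaError):
        ElementalFormula({"Q": 2})


def test_element_pattern_closed_forms():
    assert np.allclose(element_pattern("C", 0, 3).abundances, [1, 0, 0, 0])
    p = element_pattern("C", 1, 1).abundances
    assert np.allclose(p, [0.9893, 0.0107])
    # two Si atoms: M+1 = 2 * a29 * a28
    p = element_pattern("Si", 2, 2).abundances
    a28, a29 = 1 - 0.04685 - 0.03092, 0.04685
    assert p[1] == pytest.approx(2 * a29 * a28, rel=1e-12)


def test_element_pattern_unknown_element():
    with pytest.raises(FormulaError):
        element_pattern("Xe", 1, 2)


def test_convolve_identity_binomial_and_split():
    x = element_pattern("Si", 1, 2)
    ident = IsotopePattern(np.array([1.0, 0, 0]))
    assert np.allclose(convolve(x, ident).abundances, x.abundances)
    half = IsotopePattern(np.array([0.5, 0.5, 0.0]))
    assert np.allclose(convolve(half, half).abundances, [0.25, 0.5, 0.25])
    # C3 * C3 = C6
    a = element_pattern("C", 3, 6)
    b = element_pattern("C", 6, 6)
    assert np.allclose(convolve(a, a).abundances, b.abundances, atol=1e-12)
    with pytest.raises(ValueError):
        convolve(element_pattern("C", 1, 2), element_pattern("C", 1, 3))


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
)
def test_convolve_commutative_associative(a, b, c):
    def pat(v):
        v = np.array(v)
        return IsotopePattern(v / v.sum())

    pa, pb, pc = pat(a), pat(b), pat(c)
    ab = convolve(pa, pb).abundances
    ba = convolve(pb, pa).abundances
    assert np.allclose(ab, ba, atol=1e-12)
    lhs = convolve(convolve(pa, pb), pc).abundances
    rhs = convolve(pa, convolve(pb, pc)).abundances
    assert np.allclose(lhs, rhs, atol=1e-12)


@pytest.mark.parametrize("formula", ["C6", "C3Si1", "CHSi", "C2H2OS", "N2O2"])
def test_natural_pattern_matches_enumeration(formula):
    f = parse_formula(formula)
    assert f.n_atoms() <= 12
    K = 4
    got = natural_pattern(f, K).abundances
    want = enumerate_natural_pattern(f, K)
    assert np.allclose(got, want, atol=1e-12)


def test_natural_pattern_binomial_and_empty():
    from sirmkit.isotopes import ElementalFormula

    p = natural_pattern(parse_formula("C6"), 6).abundances
    assert p[1] == pytest.approx(6 * 0.0107 * 0.9893**5, rel=1e-12)
    empty = natural_pattern(ElementalFormula({}), 3).abundances
    assert np.allclose(empty, [1, 0, 0, 0])


def test_correction_matrix_structure():
    f = parse_formula("C6Si")
    cm = build_correction_matrix(f, 3)
    assert cm.matrix.shape == (7, 4)  # K = n_backbone + 3
    assert np.all(cm.matrix >= 0)
    # column sums <= 1 (truncation)
    assert np.all(cm.matrix.sum(axis=0) <= 1 + 1e-12)
    # column 0 is the plain natural pattern
    assert np.allclose(cm.matrix[:, 0], natural_pattern(f, 6).abundances)
    # every entry matches enumeration with j carbons pinned as 13C
    for j in range(4):
        reduced = f.minus_carbons(j)
        want = np.zeros(7)
        pat = enumerate_natural_pattern(reduced, 6 - j)
        want[j : j + pat.size] = pat
        assert np.allclose(cm.matrix[:, j], want, atol=1e-12)


def test_correction_matrix_degenerate_cases():
    f = parse_formula("C3")
    cm0 = build_correction_matrix(f, 0)
    assert cm0.matrix.shape[1] == 1
    cm3 = build_correction_matrix(f, 3, K=3)
    # fully labeled column: no carbons left to draw natural isotopes
    assert np.allclose(cm3.matrix[:, 3], [0, 0, 0, 1])
    with pytest.raises(ValueError):
        build_correction_matrix(f, 4)


def test_correct_mid_unlabeled_sample(fragment_library):
    cms = correction_matrices(fragment_library)
    lib = fragment_library.set_index("metabolite")
    for met, cm in cms.items():
        y = natural_pattern(lib.loc[met, "formula_obj"], cm.K).abundances
        mid = correct_mid(y, cm, metabolite=met)
        assert mid.fractions[0] == pytest.approx(1.0, abs=1e-8)
        assert fractional_enrichment(mid) < 0.005


def test_correct_mid_round_trip(fragment_library):
    rng = np.random.default_rng(42)
    cms = correction_matrices(fragment_library)
    for met, cm in cms.items():
        for _ in range(5):
            x = rng.dirichlet(np.ones(cm.n_backbone + 1))
            mid = correct_mid(cm.matrix @ x, cm, metabolite=met)
            assert np.abs(mid.fractions - x).max() < 1e-8
            assert np.all(mid.fractions >= 0)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)


def test_correct_mid_noisy_recovery(fragment_library):
    """1% multiplicative noise: entries recovered within 0.02 for ~95% of trials."""
    rng = np.random.default_rng(7)
    cm = correction_matrices(fragment_library)["glutamate"]
    errs = []
    x = rng.dirichlet(np.ones(cm.n_backbone + 1))
    clean = cm.matrix @ x
    for _ in range(1000):
        y = clean * (1 + 0.01 * rng.standard_normal(clean.size))
        mid = correct_mid(np.clip(y, 0, None), cm)
        errs.append(np.abs(mid.fractions - x))
    errs = np.array(errs)
    assert (errs < 0.02).mean() > 0.95


def test_correct_mid_input_validation(fragment_library):
    cm = correction_matrices(fragment_library)["lactate"]
    with pytest.raises(ValueError):
        correct_mid(np.zeros(cm.K + 1), cm)
    with pytest.raises(ValueError):
        correct_mid(np.ones(cm.K), cm)


@pytest.mark.parametrize(
    "fractions,n,expected",
    [([1, 0, 0, 0], 3, 0.0), ([0, 0, 0, 1], 3, 1.0), ([0.5, 0, 0, 0.5], 3, 0.5)],
)
def test_fractional_enrichment(fractions, n, expected):
    mid = MIDVector("m", "f", n, np.array(fractions, dtype=float))
    assert fractional_enrichment(mid, "atom") == pytest.approx(expected)


def test_enrichment_conventions_differ_for_partial_labeling():
    mid = MIDVector("m", "f", 3, np.array([0.5, 0.5, 0, 0]))
    assert fractional_enrichment(mid, "atom") == pytest.approx(1 / 6)
    assert fractional_enrichment(mid, "labeled") == pytest.approx(0.5)
    with pytest.raises(ValueError):
        fractional_enrichment(MIDVector("m", "f", 0, np.array([1.0])), "atom")
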