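"""LRTs, Akaike weights, and the model-screening procedures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dupsel import (
    CodonModelSpec,
    akaike_weights,
    duplication_model_screen,
    fixed_omega_comparison,
    lrt,
    parse_newick,
    partition_branches,
    simulate_codon_alignment,
)

FIT_FAST = dict(seed=0, n_starts=1, compute_se=False)


def test_lrt_equal_likelihoods():
    stat, p = lrt(-100.0, -100.0, df=1)
    assert stat == 0.0 and p == 1.0


@pytest.mark.parametrize("stat,df", [(3.84, 1), (5.99, 2)])
def test_lrt_chi_square_critical_values(stat, df):
    _, p = lrt(-100.0, -100.0 + stat / 2, df=df)
    assert p == pytest.approx(0.05, abs=5e-4)


def test_lrt_contract_violations():
    with pytest.raises(ValueError, match="df"):
        lrt(-10.0, -9.0, df=0)
    with pytest.raises(ValueError, match="warm-start"):
        lrt(-9.0, -10.0, df=1)


def test_akaike_weights_identical_models():
    np.testing.assert_allclose(akaike_weights([(-50.0, 2), (-50.0, 2)]), [0.5, 0.5])


def test_akaike_weights_delta_aic_10():
    # lnL difference of 5 at equal k -> dAIC = 10
    w = akaike_weights([(-45.0, 2), (-50.0, 2)])
    np.testing.assert_allclose(w, [0.99331, 0.00669], atol=5e-6)


def test_akaike_weights_three_model_closed_form():
    models = [(-100.0, 2), (-99.0, 3), (-98.0, 5)]
    aic = np.array([2 * k - 2 * l for l, k in models])
    expected = np.exp(-(aic - aic.min()) / 2)
    expected /= expected.sum()
    np.testing.assert_allclose(akaike_weights(models), expected, atol=1e-12)


@given(st.floats(-1000, 1000))
def test_akaike_weights_invariant_to_lnl_shift(shift):
    base = [(-120.0, 2), (-118.5, 3), (-117.0, 4)]
    shifted = [(l + shift, k) for l, k in base]
    np.testing.assert_allclose(akaike_weights(shifted), akaike_weights(base), atol=1e-12)
    assert akaike_weights(shifted).sum() == pytest.approx(1.0, abs=1e-12)


def test_akaike_weights_empty_rejected():
    with pytest.raises(ValueError):
        akaike_weights([])


# -- fixed-omega cross-subclade comparison -----------------------------------


@pytest.fixture(scope="module")
def m0_dataset(fixtures):
    gene_tree = fixtures["gene_tree"]
    spec = CodonModelSpec(family="M0", kappa=2.0, omega=0.01, freq_model="UNIFORM")
    aln, _ = simulate_codon_alignment(gene_tree, None, spec, 400, seed=11)
    return aln, gene_tree


def test_fixed_omega_at_own_mle_wins_on_parsimony(m0_dataset):
    aln, tree = m0_dataset
    from dupsel import CodonModel

    free = CodonModel(aln, tree, family="M0", freq_model="UNIFORM").fit(**FIT_FAST)
    comps = fixed_omega_comparison(
        aln, tree, {"self": free.params["omega"]}, freq_model="UNIFORM",
        free_fit=free, **FIT_FAST,
    )
    comp = comps["self"]
    assert comp.weights.sum() == pytest.approx(1.0, abs=1e-12)
    # same lnL, one fewer parameter -> the fixed model is preferred
    assert comp.weight("fixed@self") > 0.5


def test_foreign_omega_strongly_rejected(m0_dataset):
    """Data at one subclade's slow rate reject a fast subclade's rate."""
    aln, tree = m0_dataset  # simulated at omega = 0.01
    comps = fixed_omega_comparison(
        aln, tree, {"fast_subclade": 0.14}, freq_model="UNIFORM", **FIT_FAST
    )
    w_free = comps["fast_subclade"].weight("free")
    assert round(w_free, 3) == 1.000


# -- duplication model screen -------------------------------------------------


def test_screen_prefers_true_all_descendants_model(fixtures):
    gene_tree = fixtures["gene_tree"]
    truth = partition_branches(gene_tree, [fixtures["focal_clade"]], mode="all_descendants")
    spec = CodonModelSpec(family="BRANCH", kappa=2.0, omega=[0.13, 0.5], freq_model="UNIFORM")
    aln, _ = simulate_codon_alignment(gene_tree, truth, spec, 600, seed=12)
    comp = duplication_model_screen(
        aln, gene_tree, [fixtures["focal_clade"]], freq_model="UNIFORM", **FIT_FAST
    )
    assert comp.best == "All descendants"
    # nesting: M0 is a special case of both branch models
    lnl = dict(zip(comp.names, comp.lnls))
    assert lnl["M0"] <= lnl["Immediate"] + 1e-6
    assert lnl["M0"] <= lnl["All descendants"] + 1e-6


def test_screen_on_m0_data_prefers_m0_usually(fixtures):
    """The k-penalty keeps the simplest model ahead under the null."""
    gene_tree = fixtures["gene_tree"]
    wins = 0
    for seed in range(100, 110):
        spec = CodonModelSpec(family="M0", kappa=2.0, omega=0.2, freq_model="UNIFORM")
        aln, _ = simulate_codon_alignment(gene_tree, None, spec, 300, seed=seed)
        comp = duplication_model_screen(
            aln, gene_tree, [fixtures["focal_clade"]], freq_model="UNIFORM", **FIT_FAST
        )
        wins += comp.best == "M0"
    assert wins >= 8


def test_screen_degenerate_without_duplications(fixtures):
    gene_tree = fixtures["gene_tree"]
    spec = CodonModelSpec(family="M0", kappa=2.0, omega=0.2, freq_model="UNIFORM")
    aln, _ = simulate_codon_alignment(gene_tree, None, spec, 100, seed=13)
    comp = duplication_model_screen(aln, gene_tree, [], freq_model="UNIFORM", **FIT_FAST)
    assert comp.degenerate and comp.names == ["M0"]
    assert comp.weights[0] == 1.0


def test_branch_lrt_type_one_error_calibrated():
    """LRT p-values are approximately uniform when the null (M0) is true."""
    tree = parse_newick("((A:0.25,B:0.3)I:0.15,(C:0.2,D:0.35)J:0.1);")
    part = partition_branches(tree, ["I"], mode="immediate")
    from dupsel import CodonModel

    pvals = []
    for seed in range(200, 230):
        spec = CodonModelSpec(family="M0", kappa=2.0, omega=0.3, freq_model="UNIFORM")
        aln, _ = simulate_codon_alignment(tree, None, spec, 150, seed=seed)
        m0 = CodonModel(aln, tree, family="M0", freq_model="UNIFORM").fit(**FIT_FAST)
        warm = {"kappa": m0.params["kappa"], "omega0": m0.params["omega"], "omega1": m0.params["omega"]}
        alt = CodonModel(aln, tree, part, family="BRANCH", freq_model="UNIFORM").fit(
            start=warm, **FIT_FAST
        )
        pvals.append(lrt(m0.llf, alt.llf, df=1)[1])
    pvals = np.asarray(pvals)
    # at alpha=0.05 and n=30, more than 7 rejections falls far outside the
    # exact binomial range (P(X >= 8 | p=0.05) < 1e-4)
    assert (pvals < 0.05).sum() <= 7
    assert pvals.min() > 0.0
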