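"""Maximum-likelihood codon fitting: recovery, nesting, and optimizer contracts."""

import numpy as np
import pytest

from dupsel import CodonModel, CodonModelSpec, parse_newick, simulate_codon_alignment

FIT_FAST = dict(seed=0, n_starts=1, compute_se=False)


def _sim_m0(tree, omega, nsites, seed, kappa=2.0):
    spec = CodonModelSpec(family="M0", kappa=kappa, omega=omega, freq_model="UNIFORM")
    return simulate_codon_alignment(tree, None, spec, nsites, seed)[0]


@pytest.mark.parametrize("omega_true", [0.12, 1.0])
def test_m0_recovery_median_bias_under_5_percent(gene_tree, omega_true):
    """Simulate-and-refit closes the loop for the single-ratio model."""
    estimates = []
    for seed in range(1, 6):
        aln = _sim_m0(gene_tree, omega_true, 500, seed)
        fit = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM").fit(**FIT_FAST)
        estimates.append(fit.params["omega"])
    median = float(np.median(estimates))
    assert abs(median - omega_true) / omega_true < 0.05


def test_gradient_vanishes_at_mle(gene_tree):
    aln = _sim_m0(gene_tree, 0.14, 500, seed=1)
    model = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM")
    fit = model.fit(seed=0, n_starts=2, compute_se=True)
    w = fit.params["omega"]
    h = 1e-5 * w
    up, dn = dict(fit.params), dict(fit.params)
    up["omega"] = w + h
    dn["omega"] = w - h
    grad = (model.loglike(up) - model.loglike(dn)) / (2 * h)
    assert abs(grad) < 1e-4
    # SEs from the observed information are positive and finite
    assert 0 < fit.bse["omega"] < 0.1
    assert fit.k == 2 and fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)


def test_loglike_at_mles_reproduces_fitted_lnl_exactly(gene_tree):
    aln = _sim_m0(gene_tree, 0.2, 200, seed=2)
    model = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM")
    fit = model.fit(**FIT_FAST)
    assert model.loglike(fit.params) == fit.llf


def test_refit_from_mles_is_stable(gene_tree):
    aln = _sim_m0(gene_tree, 0.2, 200, seed=3)
    fit = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM").fit(**FIT_FAST)
    again = fit.refit(**FIT_FAST)
    assert abs(again.llf - fit.llf) < 1e-6


def test_fixed_parameters_respected_and_bounded(gene_tree):
    aln = _sim_m0(gene_tree, 0.2, 150, seed=4)
    model = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM")
    fit = model.fit(fixed={"omega": 0.12}, **FIT_FAST)
    assert fit.params["omega"] == 0.12
    assert fit.k == 1  # only kappa free
    with pytest.raises(ValueError, match="bounds"):
        model.fit(fixed={"omega": 50.0}, **FIT_FAST)


def test_m8a_nested_in_m8_with_warm_start(gene_tree):
    spec = CodonModelSpec(
        family="M8", kappa=2.0, p0=0.9, p=0.8, q=2.0, omega_s=3.0, freq_model="UNIFORM"
    )
    aln, _ = simulate_codon_alignment(gene_tree, None, spec, 150, seed=5)
    null = CodonModel(aln, gene_tree, family="M8A", freq_model="UNIFORM").fit(**FIT_FAST)
    warm = dict(null.params)
    warm["omega_s"] = 1.0 + 1e-6
    alt = CodonModel(aln, gene_tree, family="M8", freq_model="UNIFORM").fit(start=warm, **FIT_FAST)
    assert alt.llf >= null.llf - 1e-6
    assert null.k == 4 and alt.k == 5


def test_branch_length_estimation_recovers_lengths():
    tree = parse_newick("((A:0.2,B:0.4)I:0.15,(C:0.3,D:0.1)J:0.25);")
    aln = _sim_m0(tree, 0.3, 400, seed=6)
    fit = CodonModel(aln, tree, family="M0", freq_model="UNIFORM").fit(
        estimate_branch_lengths=True, **FIT_FAST
    )
    est = np.array([fit.params[f"bl:{tree.names[v]}"] for v in range(1, tree.n_nodes)])
    true = tree.lengths[1:]
    assert np.abs(est - true).max() < 0.08
    assert fit.k == 2 + len(true)  # branch lengths counted as free parameters


def test_nonconvergence_is_flagged_not_silent(gene_tree):
    aln = _sim_m0(gene_tree, 0.2, 100, seed=7)
    model = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM")
    with pytest.warns(RuntimeWarning, match="converge"):
        fit = model.fit(maxiter=1, **FIT_FAST)
    assert not fit.converged


def test_summary_lists_estimates(gene_tree):
    aln = _sim_m0(gene_tree, 0.2, 100, seed=8)
    fit = CodonModel(aln, gene_tree, family="M0", freq_model="UNIFORM").fit(seed=0, n_starts=1)
    text = fit.summary()
    assert "omega" in text and "lnL" in text
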