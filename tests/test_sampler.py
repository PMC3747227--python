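"""MCMC correctness: conjugate sub-cases, recovery, determinism, limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plnqpcr import (
    CountDataset,
    LogAbundanceDataset,
    MCMCSettings,
    ModelSpec,
    build_design,
    build_priors,
    coral_preset,
    cq_to_counts,
    cq_to_log_abundance,
    fit_lognormal_glmm,
    fit_pln_glmm,
    simulate_dataset,
    summarize_effects,
)
from plnqpcr.design import INTERCEPT


def _pin_residual(priors, v0: float, strength: float = 5e5):
    """Clamp the residual variance posterior at ~v0 via a sharp prior."""
    priors.residual = {"kind": "ig", "shape": strength, "scale": strength * v0}
    return priors


def _intercept_only_la(values: np.ndarray) -> LogAbundanceDataset:
    trials = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(len(values))],
            "tech_rep": 1,
            "gene": "g",
            "la": values,
            "cq_corrected": -values / np.log(2),
        }
    )
    return LogAbundanceDataset(trials, [], ["g"])


def test_conjugate_gaussian_posterior_matches_analytic():
    """With fixed residual variance and a flat prior, the intercept posterior
    is the textbook normal; the sampler's marginal must match it (KS)."""
    rng = np.random.default_rng(7)
    v0, n = 0.25, 60
    y = 1.0 + np.sqrt(v0) * rng.standard_normal(n)
    data = _intercept_only_la(y)
    spec = ModelSpec(fixed_factors=[], include_loading=False)
    design = build_design(spec, data)
    priors = _pin_residual(build_priors(spec, design), v0)
    post = fit_lognormal_glmm(
        data, design, priors, MCMCSettings(nitt=1300, burnin=300, thin=1, seed=3)
    )
    draws = post.column("g", INTERCEPT)
    prec = n / v0 + 1e-8
    mean = (y.sum() / v0) / prec
    sd = 1.0 / np.sqrt(prec)
    ks = stats.kstest(draws, lambda x: stats.norm.cdf(x, mean, sd))
    assert ks.statistic < 0.05


def test_pln_intercept_recovers_log_mean():
    """Constant counts of 20 with near-zero log-variance: the intercept
    posterior concentrates at ln 20."""
    n = 40
    trials = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "tech_rep": 1,
            "gene": "g",
            "count": 20,
        }
    )
    data = CountDataset(trials, [], ["g"])
    spec = ModelSpec(fixed_factors=[], include_loading=False)
    design = build_design(spec, data)
    priors = _pin_residual(build_priors(spec, design), 0.01)
    post = fit_pln_glmm(
        data, design, priors, MCMCSettings(nitt=2300, burnin=300, thin=2, seed=5)
    )
    assert post.column("g", INTERCEPT).mean() == pytest.approx(np.log(20), abs=0.05)


@pytest.fixture(scope="module")
def small_sim():
    truth = coral_preset(
        seed=17,
        n_genes=4,
        n_groups=0,
        samples_per_cell=4,
        effects={("gene03", "condition=heat"): np.log(3.0)},
        intercepts=None,
    )
    # moderate abundances only, to keep this fixture fast and well-behaved
    truth.intercepts = {g: v for g, v in zip(truth.genes, np.log([50, 200, 800, 3000]))}
    return simulate_dataset(truth)


@pytest.fixture(scope="module")
def small_fit(small_sim):
    _, counts, _ = small_sim
    spec = ModelSpec(
        fixed_factors=["condition", "timepoint"],
        interactions=[("condition", "timepoint")],
    )
    design = build_design(spec, counts)
    priors = build_priors(spec, design)
    settings = MCMCSettings(nitt=2600, burnin=600, thin=2, seed=11)
    return fit_pln_glmm(counts, design, priors, settings), design, priors, settings


def test_fixed_seed_bitwise_reproducible(small_sim, small_fit):
    _, counts, _ = small_sim
    post1, design, priors, settings = small_fit
    post2 = fit_pln_glmm(counts, design, priors, settings)
    assert np.array_equal(post1.beta, post2.beta)
    assert np.array_equal(post1.variances.to_numpy(), post2.variances.to_numpy())


def test_true_effect_recovered_and_ess_reported(small_sim, small_fit):
    post = small_fit[0]
    s = summarize_effects(post)
    row = s.row("gene03", "condition=heat")
    assert row["lower"] < np.log(3.0) < row["upper"]
    ess = post.effective_sample_size()
    assert (ess > 50).all()


def test_lognormal_null_recovery():
    """Pure gene-mean noise: every effect posterior is centred at zero."""
    truth = coral_preset(
        seed=23, n_genes=3, n_groups=0, samples_per_cell=4,
        loading_sd=0.0, sample_sd=0.0, resid_var=0.01,
    )
    truth.intercepts = {g: float(np.log(2000)) for g in truth.genes}
    cq, _, _ = simulate_dataset(truth)
    la = cq_to_log_abundance(cq, truth.efficiency_table())
    spec = ModelSpec(
        fixed_factors=["condition", "timepoint"],
        interactions=[("condition", "timepoint")],
        include_loading=False,
    )
    design = build_design(spec, la)
    priors = build_priors(spec, design)
    post = fit_lognormal_glmm(
        la, design, priors, MCMCSettings(nitt=2600, burnin=600, thin=2, seed=29)
    )
    s = summarize_effects(post).effects_only()
    z = (s["mean"] / ((s["upper"] - s["lower"]) / 4.0)).abs()
    assert (z < 3.0).all()


def test_pln_matches_lognormal_at_high_abundance():
    """Counts > 500: the PLN posterior converges to the lognormal one."""
    truth = coral_preset(
        seed=31, n_genes=3, n_groups=0, samples_per_cell=4,
        factors={"condition": ["control", "heat"]}, interactions=[],
        effects={("gene02", "condition=heat"): np.log(2.0)},
        resid_var=0.04,
    )
    truth.intercepts = {g: v for g, v in zip(truth.genes, np.log([2000, 3000, 5000]))}
    cq, counts, _ = simulate_dataset(truth)
    assert (counts.trials["count"] > 500).all()
    spec = ModelSpec(fixed_factors=["condition"])
    settings = MCMCSettings(nitt=2600, burnin=600, thin=2, seed=37)

    d1 = build_design(spec, counts)
    p1 = fit_pln_glmm(counts, d1, build_priors(spec, d1), settings)
    la = cq_to_log_abundance(cq, truth.efficiency_table())
    d2 = build_design(spec, la)
    p2 = fit_lognormal_glmm(la, d2, build_priors(spec, d2), settings)

    for g in truth.genes:
        b1 = p1.column(g, "condition=heat").mean()
        b2 = p2.column(g, "condition=heat").mean()
        assert b1 == pytest.approx(b2, abs=0.05)


def test_zero_bounded_gene_finite_negative_with_wider_ci():
    """A gene silenced into the no-amplification zone still gets a finite,
    negative effect estimate, with a wider interval than a well-measured one."""
    truth = coral_preset(
        seed=41, n_genes=2, n_groups=0, samples_per_cell=6,
        factors={"condition": ["control", "heat"]}, interactions=[],
        effects={
            ("gene00", "condition=heat"): -np.log(8.0),
            ("ctrl", "condition=heat"): -np.log(8.0),
        },
    )
    truth.intercepts = {"gene00": float(np.log(3.0)), "ctrl": float(np.log(2000.0))}
    _, counts, _ = simulate_dataset(truth)
    heat = counts.trials.query("gene == 'gene00' and condition == 'heat'")
    assert (heat["count"] == 0).any()  # the scenario exercised zero counts
    spec = ModelSpec(fixed_factors=["condition"])
    design = build_design(spec, counts)
    post = fit_pln_glmm(
        counts, design, build_priors(spec, design),
        MCMCSettings(nitt=2600, burnin=600, thin=2, seed=43),
    )
    s = summarize_effects(post)
    low = s.row("gene00", "condition=heat")
    high = s.row("ctrl", "condition=heat")
    assert np.isfinite(low["mean"]) and low["mean"] < 0
    assert (low["upper"] - low["lower"]) > (high["upper"] - high["lower"])


def test_non_integer_counts_rejected(small_sim):
    _, counts, _ = small_sim
    bad = counts.trials.copy()
    spec = ModelSpec(fixed_factors=["condition", "timepoint"])
    design = build_design(spec, counts)
    design.obs = bad.assign(count=bad["count"] + 0.5)
    with pytest.raises(TypeError):
        fit_pln_glmm(counts, design, build_priors(spec, design), MCMCSettings(seed=1))


def test_all_zero_gene_warns(small_sim):
    _, counts, _ = small_sim
    t = counts.trials.copy()
    t.loc[t["gene"] == "gene00", "count"] = 0
    data = CountDataset(t, counts.factor_names, counts.genes)
    spec = ModelSpec(fixed_factors=["condition", "timepoint"])
    design = build_design(spec, data)
    with pytest.warns(UserWarning, match="all-zero"):
        fit_pln_glmm(
            data, design, build_priors(spec, design),
            MCMCSettings(nitt=1300, burnin=300, thin=1, seed=2),
        )
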