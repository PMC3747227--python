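"""Design expansion and prior-regime construction."""

import numpy as np
import pytest
from scipy import integrate, stats

from plnqpcr import ModelSpec, build_design, build_priors, coral_preset, simulate_dataset, stability_sigma
from plnqpcr._exceptions import ConfigurationError, DesignError
from plnqpcr.design import DIFFUSE_VAR, INTERCEPT, PINNED_VAR, combination_weights


@pytest.fixture(scope="module")
def coral_counts():
    truth = coral_preset(seed=5, n_genes=15)
    _, counts, _ = simulate_dataset(truth)
    return counts


@pytest.fixture(scope="module")
def coral_spec():
    return ModelSpec(
        fixed_factors=["condition", "timepoint"],
        interactions=[("condition", "timepoint")],
        grouping_factors=["group"],
        control_genes=["ctrl"],
    )


class TestBuildDesign:
    def test_coral_fixed_effect_combinatorics(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        terms = [t for (_, t) in design.x_labels]
        assert design.X.shape[1] == 15 * 4  # 15 intercepts + 15 x 3 effects
        assert terms.count(INTERCEPT) == 15
        assert sum(t != INTERCEPT for t in terms) == 45

    def test_single_gene_single_factor(self):
        truth = coral_preset(
            seed=1, n_genes=2, factors={"condition": ["control", "heat"]},
            interactions=[], n_groups=0, samples_per_cell=3,
        )
        _, counts, _ = simulate_dataset(truth)
        counts = type(counts)(
            counts.trials[counts.trials["gene"] == "gene00"].reset_index(drop=True),
            counts.factor_names,
            ["gene00"],
        )
        spec = ModelSpec(fixed_factors=["condition"], grouping_factors=[])
        design = build_design(spec, counts)
        assert design.X.shape[1] == 2

    def test_reference_combination_maps_to_intercept_alone(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        w = combination_weights(design, {"condition": "control", "timepoint": "one"})
        assert w[0] == 1.0 and w[1:].sum() == 0.0

    def test_interaction_cell_includes_main_and_interaction(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        w = combination_weights(design, {"condition": "heat", "timepoint": "two"})
        assert w.sum() == 4.0  # intercept + 2 mains + interaction

    def test_no_tech_reps_drops_sample_gene_block(self):
        truth = coral_preset(seed=2, n_genes=4, tech_reps=1)
        _, counts, _ = simulate_dataset(truth)
        spec = ModelSpec(
            fixed_factors=["condition", "timepoint"], grouping_factors=["group"]
        )
        design = build_design(spec, counts)
        names = [b.name for b in design.blocks]
        assert "sample_gene" not in names and not design.has_tech_reps

    def test_tech_reps_include_sample_gene_block(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        assert "sample_gene" in [b.name for b in design.blocks]

    def test_single_level_factor_is_design_error(self, coral_counts):
        sub = coral_counts.trials.query("condition == 'heat'").reset_index(drop=True)
        data = type(coral_counts)(sub, coral_counts.factor_names, coral_counts.genes)
        spec = ModelSpec(fixed_factors=["condition"])
        with pytest.raises(DesignError):
            build_design(spec, data)

    def test_unknown_control_gene_is_configuration_error(self, coral_counts):
        spec = ModelSpec(fixed_factors=["condition"], control_genes=["nope"])
        with pytest.raises(ConfigurationError):
            build_design(spec, coral_counts)

    def test_fixed_columns_linearly_independent(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        X = design.X.toarray()
        assert np.linalg.matrix_rank(X) == X.shape[1]


class TestStabilityPriors:
    def test_stability_sigma_gives_mean_absolute_fold_change(self):
        m = 1.2
        sigma = stability_sigma(m)
        assert sigma == pytest.approx(0.2285, abs=2e-4)
        # E|B| for B ~ N(0, sigma^2) must equal ln(m), by quadrature
        mean_abs, _ = integrate.quad(
            lambda b: abs(b) * stats.norm.pdf(b, scale=sigma), -np.inf, np.inf
        )
        assert mean_abs == pytest.approx(np.log(m), rel=1e-6)

    def test_alternative_sd_scale_selectable(self):
        assert stability_sigma(1.5, scale="sd") == pytest.approx(np.log(1.5))

    def test_perfect_stability_limit(self, coral_spec, coral_counts):
        spec = ModelSpec(**{**coral_spec.to_dict(), "stability": 1.0})
        design = build_design(spec, coral_counts)
        priors = build_priors(spec, design)
        ctrl_effects = [
            i for i, (g, t) in enumerate(design.x_labels)
            if g == "ctrl" and t != INTERCEPT
        ]
        assert all(priors.beta_var[i] == PINNED_VAR for i in ctrl_effects)

    def test_naive_regime_all_diffuse(self, coral_counts):
        spec = ModelSpec(
            fixed_factors=["condition", "timepoint"], grouping_factors=["group"]
        )
        design = build_design(spec, coral_counts)
        priors = build_priors(spec, design)
        assert (priors.beta_var == DIFFUSE_VAR).all()

    def test_regime_variance_ordering(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        informed = build_priors(coral_spec, design)
        fixed_spec = ModelSpec(
            **{**coral_spec.to_dict(), "fix_control_fixed_effects": True}
        )
        fixed = build_priors(fixed_spec, design)
        i = next(
            i for i, (g, t) in enumerate(design.x_labels)
            if g == "ctrl" and t != INTERCEPT
        )
        assert fixed.beta_var[i] < informed.beta_var[i] < DIFFUSE_VAR
        # control intercepts stay diffuse: stability concerns changes, not level
        j = design.x_labels.index(("ctrl", INTERCEPT))
        assert informed.beta_var[j] == DIFFUSE_VAR

    def test_fix_control_variances_propagates_to_blocks(self, coral_spec, coral_counts):
        spec = ModelSpec(**{**coral_spec.to_dict(), "fix_control_variances": 0.02})
        design = build_design(spec, coral_counts)
        priors = build_priors(spec, design)
        assert priors.block_priors["sample_gene"]["fixed_genes"] == {"ctrl": 0.02}
        assert priors.block_priors["group:group"]["fixed_genes"] == {"ctrl": 0.02}

    def test_stability_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(fixed_factors=["c"], stability=0.8)


class TestCombinationWeights:
    def test_unknown_level_is_configuration_error(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        with pytest.raises(ConfigurationError):
            combination_weights(design, {"condition": "cold", "timepoint": "one"})

    def test_missing_factor_is_configuration_error(self, coral_spec, coral_counts):
        design = build_design(coral_spec, coral_counts)
        with pytest.raises(ConfigurationError):
            combination_weights(design, {"condition": "heat"})
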