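"""The "classic" pipeline: multi-gene normalization + lognormal mixed model.

This is the Bayesian single-model counterpart of the traditional workflow:
efficiency-corrected log abundances are normalized by the geometric mean of
designated control genes (per amplification trial group), then fitted with
the same joint mixed model as the count-based analysis, minus the loading
term t_k — normalization is assumed to have subtracted that variation out.
Unlike the count model it cannot use failed amplifications (log of zero)
and it trusts the control genes' average stability absolutely, but when the
loading varies systematically with condition it is the only regime that
remains unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from ._exceptions import ConfigurationError, NormalizationError
from .design import ModelSpec, build_design, build_priors
from .qpcr_io import LogAbundanceDataset
from .sampler import MCMCSettings, Posterior, fit_lognormal_glmm

__all__ = ["NormalizedDataset", "normalize_multigene", "fit_classic"]

_GROUP = ["sample", "tech_rep"]


@dataclass
class NormalizedDataset(LogAbundanceDataset):
    """Log abundances after control-gene normalization.

    ``normalizers`` records the per-(sample, tech_rep) value subtracted from
    every gene — the log geometric mean of the control genes' abundances.
    """

    normalizers: pd.DataFrame = field(default_factory=pd.DataFrame)
    control_genes: list[str] = field(default_factory=list)


def normalize_multigene(
    data: LogAbundanceDataset, control_genes: list[str]
) -> NormalizedDataset:
    """Subtract the control genes' mean log abundance within each trial group.

    On the natural scale this divides every abundance by the geometric mean
    of the control-gene abundances measured in the same (sample, technical
    replicate) — with a single control gene it reduces to the classic
    delta-Ct against that gene.  Normalization is per trial group rather
    than per sample so technical-replicate loading noise is removed too.
    """
    if not control_genes:
        raise ConfigurationError("normalization needs at least one control gene")
    unknown = [g for g in control_genes if g not in data.genes]
    if unknown:
        raise ConfigurationError(f"control genes absent from data: {unknown}")
    t = data.trials
    ctrl = t[t["gene"].isin(control_genes)]
    norm = ctrl.groupby(_GROUP, observed=True).agg(
        normalizer=("la", "mean"), n_controls=("la", "size")
    )
    incomplete = norm[norm["n_controls"] < len(control_genes)]
    groups = t[_GROUP].drop_duplicates()
    missing = groups.merge(norm, on=_GROUP, how="left")
    bad = pd.concat(
        [missing[missing["normalizer"].isna()], incomplete.reset_index()]
    )
    if len(bad):
        raise NormalizationError(
            "control-gene abundances missing in trial groups: "
            f"{bad[_GROUP].values.tolist()[:5]}"
        )
    out = t.merge(norm["normalizer"], on=_GROUP, how="left")
    out["la"] = out["la"] - out["normalizer"]
    out = out.drop(columns=["normalizer"])
    return NormalizedDataset(
        trials=out,
        factor_names=list(data.factor_names),
        genes=list(data.genes),
        drop_report=dict(data.drop_report),
        normalizers=norm.reset_index(),
        control_genes=list(control_genes),
    )


def fit_classic(
    data: LogAbundanceDataset, spec: ModelSpec, settings: MCMCSettings
) -> Posterior:
    """Normalize by the spec's control genes, then fit the no-loading model.

    The control genes stay in the fit; their (near-zero) effect estimates
    act as a sanity indicator of the normalization.  Any trials already
    dropped during the log transform (failed amplifications) are reported
    via the dataset's drop report — their loss is inherent to log-scale
    analysis.
    """
    if not spec.control_genes:
        raise ConfigurationError("the classic model requires control genes")
    dropped = data.drop_report.get("no_amp_dropped", 0)
    if dropped:
        warnings.warn(
            f"{dropped} no-amplification trials were dropped before the "
            "log-scale classic fit; consider the count-based model if "
            "low-abundance genes matter"
        )
    norm = normalize_multigene(data, spec.control_genes)
    spec_nl = spec.without_loading()
    design = build_design(spec_nl, norm)
    priors = build_priors(spec_nl, design)
    return fit_lognormal_glmm(norm, design, priors, settings)
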