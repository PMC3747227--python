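"""Posterior summaries: effects, credible intervals, p-values, contrasts.

Point estimates are posterior means on the natural-log fold-change scale;
intervals are highest-posterior-density (HPD) by default, with equal-tailed
quantile intervals selectable.  Two tail-area statistics are reported per
effect:

* ``p_mcmc`` — twice the fraction of draws on the opposite side of zero
  from the posterior mean, floored at 2/M (the smallest non-zero value a
  chain of M draws can resolve);
* ``p_z`` — a Bayesian z-test: the two-sided standard-normal tail of
  (posterior mean) / (posterior SD), which extends below the 2/M floor
  under an approximately normal posterior.

Benjamini-Hochberg FDR adjustment is applied to the z-test p-values across
all (gene, term) tests of a model jointly; contrasts form their own family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import ConfigurationError, DegenerateSampleError
from .design import INTERCEPT, ModelSpec, combination_weights
from .sampler import Posterior

__all__ = [
    "posterior_pvalues",
    "bh_adjust",
    "hpd_interval",
    "summarize_effects",
    "pairwise_contrasts",
    "predict_abundances",
]


def posterior_pvalues(sample: np.ndarray) -> dict:
    """Tail-area and z-test p-values for one vector of posterior draws."""
    x = np.asarray(sample, float)
    if len(x) < 100 or not np.isfinite(x).all():
        raise DegenerateSampleError("need >= 100 finite draws")
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSampleError("zero-variance posterior sample")
    M = len(x)
    crossing = int((x < 0).sum() if m > 0 else (x > 0).sum())
    p_mcmc = min(max(2.0 * crossing / M, 2.0 / M), 1.0)
    p_z = min(max(2.0 * stats.norm.sf(abs(m) / sd), np.finfo(float).tiny), 1.0)
    return {"p_mcmc": p_mcmc, "p_z": p_z}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hpd_interval(sample: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Shortest interval holding 1 - alpha posterior mass."""
    import arviz as az

    lo, hi = az.hdi(np.asarray(sample, float), hdi_prob=1.0 - alpha)
    return float(lo), float(hi)


def _quantile_interval(sample, alpha):
    lo, hi = np.quantile(sample, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _summary_rows(draws: np.ndarray, labels, alpha: float, interval: str):
    rows = []
    for j, lab in enumerate(labels):
        x = draws[:, j]
        lo, hi = (
            hpd_interval(x, alpha) if interval == "hpd" else _quantile_interval(x, alpha)
        )
        pv = posterior_pvalues(x)
        rows.append(
            {**lab, "mean": float(x.mean()), "lower": lo, "upper": hi, **pv}
        )
    return rows


@dataclass
class EffectSummary:
    """Per (gene, term) posterior summary table."""

    table: pd.DataFrame

    def row(self, gene: str, term: str) -> pd.Series:
        hit = self.table[(self.table["gene"] == gene) & (self.table["term"] == term)]
        if hit.empty:
            raise ConfigurationError(f"no summary row for ({gene!r}, {term!r})")
        return hit.iloc[0]

    def effects_only(self) -> pd.DataFrame:
        return self.table[self.table["term"] != INTERCEPT].reset_index(drop=True)


def summarize_effects(
    post: Posterior, alpha: float = 0.05, interval: str = "hpd"
) -> EffectSummary:
    """Summarize every fixed effect of a fitted model.

    Columns: gene, term, mean, lower, upper, p_mcmc, p_z, p_adj, is_intercept.
    The BH adjustment runs over all rows jointly.
    """
    labels = [{"gene": g, "term": t} for (g, t) in post.beta_labels]
    rows = _summary_rows(post.beta, labels, alpha, interval)
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_z"].to_numpy())
    df["is_intercept"] = df["term"] == INTERCEPT
    return EffectSummary(df)


def _prediction_draws(post: Posterior, combo: dict, genes=None) -> pd.DataFrame:
    """Draw-wise predicted log abundance per gene under a factor combination."""
    design = post.design
    w = combination_weights(design, combo)
    genes = list(genes) if genes is not None else list(design.genes)
    n_terms = len(w)
    out = {}
    for g in genes:
        gi = design.genes.index(g)
        cols = slice(gi * n_terms, (gi + 1) * n_terms)
        out[g] = post.beta[:, cols] @ w
    return pd.DataFrame(out)


@dataclass
class ContrastSummary:
    """Per (gene, condition pair) posterior differences."""

    table: pd.DataFrame


def _combo_name(combo: dict) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(combo.items()))


def pairwise_contrasts(
    post: Posterior,
    spec: ModelSpec,
    pairs: list[tuple[dict, dict]],
    alpha: float = 0.05,
    interval: str = "hpd",
) -> ContrastSummary:
    """Posterior differences between pairs of factor combinations.

    Each pair (c1, c2) yields, per gene and per draw, the difference of
    predicted log abundances c1 - c2 — the natural-log fold change of c1
    over c2.  Useful when factors have more than two levels, where single
    coefficients do not cover every comparison.  BH adjustment runs within
    the contrast family.
    """
    rows = []
    for c1, c2 in pairs:
        d1 = _prediction_draws(post, c1)
        d2 = _prediction_draws(post, c2)
        diff = d1 - d2
        labels = [
            {"gene": g, "contrast": f"({_combo_name(c1)}) - ({_combo_name(c2)})"}
            for g in diff.columns
        ]
        for j, lab in enumerate(labels):
            x = diff.iloc[:, j].to_numpy()
            if x.std(ddof=1) == 0.0:  # e.g. a combination contrasted with itself
                rows.append(
                    {**lab, "mean": 0.0, "lower": 0.0, "upper": 0.0,
                     "p_mcmc": 1.0, "p_z": 1.0}
                )
                continue
            lo, hi = (
                hpd_interval(x, alpha)
                if interval == "hpd"
                else _quantile_interval(x, alpha)
            )
            pv = posterior_pvalues(x)
            rows.append({**lab, "mean": float(x.mean()), "lower": lo, "upper": hi, **pv})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p_z"].to_numpy())
    return ContrastSummary(df)


def predict_abundances(
    post: Posterior,
    spec: ModelSpec,
    combinations: list[dict],
    alpha: float = 0.05,
    interval: str = "hpd",
) -> pd.DataFrame:
    """Posterior mean and interval of log abundance per (gene, combination).

    The prediction is the draw-wise sum of the gene intercept and every
    treatment effect active under the combination (loading and grouping
    effects integrate out at their prior mean of zero).
    """
    rows = []
    for combo in combinations:
        draws = _prediction_draws(post, combo)
        for g in draws.columns:
            x = draws[g].to_numpy()
            lo, hi = (
                hpd_interval(x, alpha)
                if interval == "hpd"
                else _quantile_interval(x, alpha)
            )
            rows.append(
                {
                    "gene": g,
                    "combination": _combo_name(combo),
                    "mean": float(x.mean()),
                    "lower": lo,
                    "upper": hi,
                }
            )
    return pd.DataFrame(rows)
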