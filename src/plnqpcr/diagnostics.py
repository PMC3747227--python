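"""Goodness-of-fit diagnostics for a fitted posterior.

Four complementary checks, computed per observation:

* **linearity** — lognormal residuals (log-scale observation minus the
  linear predictor eta) against predicted values; a mean trend indicates a
  misspecified mean structure;
* **homoscedasticity** — scale-location plot, sqrt(|standardized residual|)
  against predicted; a slope indicates variance not captured by the
  gene-specific residual terms (for counts, typically a wrong Cq1);
* **normality** — QQ pairs of standardized lognormal residuals against
  standard-normal quantiles;
* **count distribution** — randomized probability-integral-transform (PIT)
  values of each observed count under its sampled Poisson rate exp(psi),
  paired with uniform order statistics; under a correct model these are
  uniform, confirming that the extra variance at high Cq is Poisson
  sampling noise.

The PIT needs the latent log-rates of an individual MCMC draw, so the model
must have been fitted with ``retain_latents=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import StateError
from .sampler import Posterior

__all__ = ["DiagnosticsBundle", "compute_diagnostics", "plot_diagnostics"]


@dataclass
class DiagnosticsBundle:
    """Per-observation diagnostics plus summary statistics."""

    table: pd.DataFrame  # predicted, resid, std_resid, sqrt_abs_std_resid, pit
    qq: pd.DataFrame  # theoretical vs observed quantiles of std resid
    pit_pairs: pd.DataFrame  # uniform order stats vs sorted PIT values
    draw_index: int

    def summary(self) -> dict:
        t = self.table
        resid_fit = stats.linregress(t["predicted"], t["resid"])
        scale_fit = stats.linregress(t["predicted"], t["sqrt_abs_std_resid"])
        qq_corr = float(np.corrcoef(self.qq["theoretical"], self.qq["observed"])[0, 1])
        ks = stats.kstest(t["pit"].dropna(), "uniform")
        return {
            "resid_trend_slope": float(resid_fit.slope),
            "resid_trend_p": float(resid_fit.pvalue),
            "scale_trend_slope": float(scale_fit.slope),
            "scale_trend_p": float(scale_fit.pvalue),
            "qq_correlation": qq_corr,
            "pit_ks_stat": float(ks.statistic),
            "pit_ks_p": float(ks.pvalue),
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_diagnostics(
    post: Posterior,
    data=None,
    draw_policy="posterior_mean",
    seed: int = 0,
) -> DiagnosticsBundle:
    """Build the diagnostics bundle from a fitted posterior.

    ``draw_policy`` is ``"posterior_mean"`` (residuals against the
    posterior-mean fit; PIT from the middle retained draw) or
    ``("single_draw", index)`` (everything from one retained draw).  For a
    count fit, the log-scale observation proxy is log(y + 0.5) — zero-safe,
    so failed amplifications appear in the residual plots too.
    """
    design = post.design
    obs = design.obs
    n = design.n_obs
    gene_codes = design.gene_codes
    A = _full_matrix(design)

    if isinstance(draw_policy, tuple) and draw_policy[0] == "single_draw":
        idx = int(draw_policy[1])
        theta = np.concatenate([post.beta[idx], post.u[idx]])
        v_g = post.residual_variances().iloc[idx].to_numpy()
    elif draw_policy == "posterior_mean":
        idx = post.n_draws // 2
        theta = np.concatenate([post.beta.mean(axis=0), post.u.mean(axis=0)])
        v_g = post.residual_variances().mean(axis=0).to_numpy()
    else:
        raise ValueError(f"unknown draw_policy {draw_policy!r}")

    eta = A @ theta
    if post.family == "pln":
        y = obs["count"].to_numpy(float)
        proxy = np.log(y + 0.5)
        # the log-count proxy carries Poisson noise with log-scale variance
        # ~ 1/rate on top of the lognormal residual; fold it into the
        # standardization so low-abundance genes are not over-dispersed
        proxy_var = v_g[gene_codes] + 1.0 / (np.exp(eta) + 0.5)
        if post.latents is None:
            raise StateError(
                "Poisson PIT diagnostics need retained latents; refit with "
                "retain_latents=True"
            )
        rate = np.exp(post.latents[idx])
        rng = np.random.default_rng(seed)
        lo = stats.poisson.cdf(y - 1.0, rate)
        pit = lo + rng.random(n) * stats.poisson.pmf(y, rate)
    else:
        proxy = obs["la"].to_numpy(float)
        proxy_var = v_g[gene_codes]
        pit = np.full(n, np.nan)

    resid = proxy - eta
    std = resid / np.sqrt(proxy_var)
    table = pd.DataFrame(
        {
            "gene": obs["gene"].to_numpy(),
            "predicted": eta,
            "resid": resid,
            "std_resid": std,
            "sqrt_abs_std_resid": np.sqrt(np.abs(std)),
            "pit": pit,
        }
    )
    order = np.sort(std)
    qq = pd.DataFrame(
        {
            "theoretical": stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n),
            "observed": order,
        }
    )
    finite_pit = np.sort(pit[~np.isnan(pit)])
    pit_pairs = pd.DataFrame(
        {
            "uniform": (np.arange(1, len(finite_pit) + 1)) / (len(finite_pit) + 1.0),
            "pit": finite_pit,
        }
    )
    return DiagnosticsBundle(table=table, qq=qq, pit_pairs=pit_pairs, draw_index=idx)


def _full_matrix(design):
    import scipy.sparse as sp

    if design.Z is None:
        return design.X.tocsr()
    return sp.hstack([design.X, design.Z], format="csr")


def plot_diagnostics(bundle: DiagnosticsBundle, path) -> None:
    """Write the four-panel diagnostics figure to ``path`` (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = bundle.table
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    ax = axes[0, 0]
    ax.scatter(t["predicted"], t["resid"], s=8, alpha=0.5)
    ax.axhline(0.0, color="red", lw=1)
    ax.set_xlabel("predicted log value")
    ax.set_ylabel("lognormal residual")
    ax.set_title("linearity")

    ax = axes[0, 1]
    ax.scatter(t["predicted"], t["sqrt_abs_std_resid"], s=8, alpha=0.5)
    ax.set_xlabel("predicted log value")
    ax.set_ylabel(r"$\sqrt{|std.\ resid|}$")
    ax.set_title("scale-location")

    ax = axes[1, 0]
    ax.scatter(bundle.qq["theoretical"], bundle.qq["observed"], s=8, alpha=0.5)
    lim = bundle.qq.abs().to_numpy().max()
    ax.plot([-lim, lim], [-lim, lim], color="red", lw=1)
    ax.set_xlabel("normal quantiles")
    ax.set_ylabel("standardized residuals")
    ax.set_title("normal QQ")

    ax = axes[1, 1]
    if len(bundle.pit_pairs):
        ax.scatter(bundle.pit_pairs["uniform"], bundle.pit_pairs["pit"], s=8, alpha=0.5)
        ax.plot([0, 1], [0, 1], color="red", lw=1)
    ax.set_xlabel("theoretical probability")
    ax.set_ylabel("Poisson residual probability")
    ax.set_title("randomized PIT")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
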