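"""Generative simulation with known truth, and subtract-and-shuffle nulls.

``simulate_dataset`` draws data from the exact generative process the count
model assumes: per-trial log rate = gene intercept + active treatment
effects + sample loading + gene-specific grouping and sample effects +
gene-specific trial noise, then a Poisson count, then back-conversion to a
quantification cycle (zero counts become no-amplification trials).  The
default preset mimics a realistic stress-experiment layout: 8 genotype
groups crossed with a 2x2 condition-by-timepoint factorial, one biological
sample per (group, cell), duplicate technical replicates, and gene
intercepts spanning ~5 to ~5000 starting molecules so that zero-bounded
low-abundance genes occur.

``make_null_dataset`` builds null data from a real (or simulated) dataset
and its fitted posterior: the inferred fixed effects are subtracted from
the efficiency-corrected Cq values and whole samples are then shuffled
across experimental conditions, preserving the design layout while
destroying any real treatment signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import log

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .design import INTERCEPT
from .qpcr_io import NO_AMP, NOT_MEASURED, OK, CqDataset, CountDataset, EfficiencyTable
from .sampler import Posterior

__all__ = [
    "SimulationTruth",
    "pln_draws",
    "simulate_dataset",
    "make_null_dataset",
    "coral_preset",
    "unit_efficiencies",
]


def pln_draws(mu: float, v: float, n: int, rng) -> np.ndarray:
    """Draws from the Poisson-lognormal observation model PLN(mu, v).

    Counts are Poisson with a lognormal rate: ``y ~ Poisson(exp(mu + z))``,
    ``z ~ N(0, v)``.  Their mean is ``exp(mu + v/2)`` and their variance is
    ``mean + mean^2 (e^v - 1)`` — overdispersed relative to the Poisson,
    collapsing to it as v -> 0.
    """
    if v < 0:
        raise ConfigurationError("log-variance v must be non-negative")
    z = np.sqrt(v) * rng.standard_normal(n)
    return rng.poisson(np.exp(mu + z))

LN2 = log(2.0)
MAX_LOG_RATE = 700.0  # exp() overflow guard


@dataclass
class SimulationTruth:
    """Everything the generative process needs, including the true effects.

    ``effects`` maps (gene, term) to a natural-log effect size, with terms
    named as in the fitted design, e.g. ``("hsp", "condition=heat")`` or
    ``("hsp", "condition=heat:timepoint=two")``.  SDs are on the natural-log
    scale; ``resid_var`` is the trial-level log-variance v_g (scalar or per
    gene).  ``n_groups = 0`` drops the grouping factor; otherwise every
    (group, factor-cell) pair contributes ``samples_per_cell`` biological
    samples.
    """

    genes: list[str]
    intercepts: dict
    effects: dict = field(default_factory=dict)
    factors: dict = field(default_factory=lambda: {"condition": ["control", "heat"]})
    interactions: list[tuple] = field(default_factory=list)
    n_groups: int = 0
    samples_per_cell: int = 3
    tech_reps: int = 2
    loading_sd: float = 0.7
    group_sd: float = 0.3
    sample_sd: float = 0.3
    resid_var: float | dict = 0.05
    efficiencies: dict | None = None
    cq1: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.loading_sd, self.group_sd, self.sample_sd) < 0:
            raise ConfigurationError("SDs must be non-negative")
        cells = 1
        for lv in self.factors.values():
            cells *= len(lv)
        n_samples_per_cell = self.samples_per_cell * max(self.n_groups, 1)
        if n_samples_per_cell < 2:
            raise ConfigurationError("need >= 2 samples per factor cell")
        if self.efficiencies is None:
            self.efficiencies = {g: 2.0 for g in self.genes}
        if self.cq1 is None:
            self.cq1 = {g: 37.0 for g in self.genes}

    def v_g(self, gene: str) -> float:
        if isinstance(self.resid_var, dict):
            return float(self.resid_var[gene])
        return float(self.resid_var)

    def efficiency_table(self) -> EfficiencyTable:
        return EfficiencyTable.from_dict(self.efficiencies, self.cq1)

    def to_jsonable(self) -> dict:
        d = self.__dict__.copy()
        d["effects"] = {f"{g}|{t}": v for (g, t), v in self.effects.items()}
        d["interactions"] = [list(t) for t in self.interactions]
        return d


def _term_active(term: str, combo: dict) -> bool:
    return all(
        str(combo[f]) == lvl for f, lvl in (p.split("=", 1) for p in term.split(":"))
    )


def _layout(truth: SimulationTruth) -> pd.DataFrame:
    """One row per biological sample: sample id, group (optional), factors."""
    cells = [
        dict(zip(truth.factors.keys(), lvls))
        for lvls in product(*truth.factors.values())
    ]
    rows = []
    groups = range(truth.n_groups) if truth.n_groups else [None]
    i = 0
    for grp in groups:
        for cell in cells:
            for _ in range(truth.samples_per_cell):
                row = {"sample": f"s{i:03d}", **cell}
                if grp is not None:
                    row["group"] = f"g{grp:02d}"
                rows.append(row)
                i += 1
    return pd.DataFrame(rows)


def simulate_dataset(
    truth: SimulationTruth,
) -> tuple[CqDataset, CountDataset, SimulationTruth]:
    """Draw one dataset from the generative model; deterministic under seed."""
    rng = np.random.default_rng(truth.seed)
    samples = _layout(truth)
    genes = truth.genes
    factor_names = list(truth.factors.keys()) + (["group"] if truth.n_groups else [])

    t_k = dict(zip(samples["sample"], truth.loading_sd * rng.standard_normal(len(samples))))
    a_jg = {}
    if truth.n_groups:
        for grp in samples["group"].unique():
            for g in genes:
                a_jg[(grp, g)] = truth.group_sd * rng.standard_normal()
    s_kg = {
        (k, g): truth.sample_sd * rng.standard_normal()
        for k in samples["sample"]
        for g in genes
    }

    records = []
    for _, srow in samples.iterrows():
        combo = {f: srow[f] for f in truth.factors}
        for g in genes:
            base = truth.intercepts[g] + t_k[srow["sample"]] + s_kg[(srow["sample"], g)]
            if truth.n_groups:
                base += a_jg[(srow["group"], g)]
            for (eg, term), val in truth.effects.items():
                if eg == g and _term_active(term, combo):
                    base += val
            for r in range(1, truth.tech_reps + 1):
                lr = base + np.sqrt(truth.v_g(g)) * rng.standard_normal()
                if lr > MAX_LOG_RATE:
                    raise ValueError(
                        f"log rate {lr:.1f} for gene {g!r} overflows; "
                        "check intercepts/effects"
                    )
                y = int(rng.poisson(np.exp(lr)))
                rec = {"sample": srow["sample"], "tech_rep": r}
                for f in factor_names:
                    rec[f] = srow[f]
                rec.update(gene=g, count=y)
                records.append(rec)
    trials = pd.DataFrame.from_records(records)

    # back-convert counts to quantification cycles
    e = trials["gene"].map(truth.efficiencies).to_numpy(float)
    cq1 = trials["gene"].map(truth.cq1).to_numpy(float)
    y = trials["count"].to_numpy(float)
    with np.errstate(divide="ignore"):
        cq = cq1 - np.log(np.maximum(y, 1.0)) / np.log(e)
    status = np.where(y > 0, OK, NO_AMP)
    if ((y > 0) & ((cq <= 0) | (cq >= 100))).any():
        raise ValueError("simulated counts exceed the valid Cq range; lower intercepts")
    cq_trials = trials.drop(columns="count").assign(
        cq=np.where(y > 0, cq, np.nan), status=status
    )
    cq_ds = CqDataset(cq_trials, factor_names, list(genes))
    count_ds = CountDataset(trials, factor_names, list(genes))
    return cq_ds, count_ds, truth


def coral_preset(
    seed: int = 0,
    n_genes: int = 15,
    effects: dict | None = None,
    efficiencies: dict | None = None,
    **overrides,
) -> SimulationTruth:
    """Stress-experiment preset: 8 groups x (2x2 factorial) x 2 tech reps.

    Gene intercepts are log-spaced between ~5 and ~5000 starting molecules,
    so the lowest-abundance genes produce no-amplification zeros in part of
    their trials.  Gene names are ``gene00`` (least abundant) upward;
    ``ctrl`` replaces the middle gene as a designated stable control.
    """
    genes = [f"gene{i:02d}" for i in range(n_genes)]
    genes[n_genes // 2] = "ctrl"
    levels = np.exp(np.linspace(np.log(5.0), np.log(5000.0), n_genes))
    intercepts = {g: float(np.log(l)) for g, l in zip(genes, levels)}
    kw = dict(
        genes=genes,
        intercepts=intercepts,
        effects=effects or {},
        factors={"condition": ["control", "heat"], "timepoint": ["one", "two"]},
        interactions=[("condition", "timepoint")],
        n_groups=8,
        samples_per_cell=1,
        tech_reps=2,
        loading_sd=0.7,
        group_sd=0.3,
        sample_sd=0.3,
        resid_var=0.05,
        efficiencies=efficiencies,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationTruth(**kw)


def unit_efficiencies(genes: list[str], cq1: float = 37.0) -> EfficiencyTable:
    """Efficiency table for corrected-scale data: E = 2 for every gene."""
    return EfficiencyTable.from_dict(
        {g: 2.0 for g in genes}, {g: cq1 for g in genes}
    )


def make_null_dataset(
    data: CqDataset, post: Posterior, eff: EfficiencyTable, seed: int = 0
) -> CqDataset:
    """Subtract fitted fixed effects from corrected Cq, then shuffle samples.

    The corrected cycle ``Cq log2 E`` puts every gene on the perfect-doubling
    scale; each trial's inferred treatment effects (posterior means, natural
    log) are converted to cycles (divided by ln 2) and added back — removing
    the estimated signal.  Whole samples are then permuted uniformly across
    the fixed-factor combinations, preserving per-cell sample counts.  The
    result is on the corrected scale: analyze it with E = 2 for every gene
    (see :func:`unit_efficiencies`).
    """
    rng = np.random.default_rng(seed)
    genes = data.genes
    missing = [g for g in genes if (g, INTERCEPT) not in post.beta_labels]
    if missing:
        raise ConfigurationError(
            f"posterior was not fitted on these genes: {missing}"
        )
    fixed_factors = list(post.design.factor_levels.keys())
    for f in fixed_factors:
        if f not in data.factor_names:
            raise ConfigurationError(f"dataset lacks fitted factor {f!r}")

    beta_mean = dict(zip(post.beta_labels, post.beta.mean(axis=0)))
    eff_terms = [(g, t) for (g, t) in post.beta_labels if t != INTERCEPT]

    t = data.trials.copy()
    e = t["gene"].map({g: eff.efficiency(g) for g in genes}).to_numpy(float)
    cq_corr = t["cq"].to_numpy(float) * np.log2(e)

    b_total = np.zeros(len(t))
    for (g, term), val in ((lt, beta_mean[lt]) for lt in eff_terms):
        mask = (t["gene"] == g).to_numpy()
        if not mask.any():
            continue
        combo_mask = np.ones(len(t), bool)
        for f, lvl in (p.split("=", 1) for p in term.split(":")):
            combo_mask &= (t[f].astype(str) == lvl).to_numpy()
        b_total += np.where(mask & combo_mask, val, 0.0)

    new_cq = cq_corr + b_total / LN2
    ok = (t["status"] == OK).to_numpy()
    t["cq"] = np.where(ok, new_cq, np.nan)

    # permute fixed-factor combinations across samples
    sample_ids = pd.unique(t["sample"])
    combos = (
        t.drop_duplicates("sample").set_index("sample").loc[sample_ids, fixed_factors]
    )
    perm = rng.permutation(len(sample_ids))
    shuffled = combos.iloc[perm].set_index(pd.Index(sample_ids, name="sample"))
    for f in fixed_factors:
        t[f] = t["sample"].map(shuffled[f])

    return CqDataset(t.reset_index(drop=True), list(data.factor_names), list(genes))
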