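"""Reading and deterministic transforms of raw qPCR quantification-cycle data.

A qPCR run yields, per amplification trial, a quantification cycle Cq — the
PCR cycle at which fluorescence crosses the detection threshold.  Cq is
proportional to the negative logarithm of the number of target molecules
that entered the reaction, with the per-cycle amplification factor E as the
base.  Two deterministic transforms are supported:

* **counts** — the estimated initial molecule count ``round(E**(Cq1 - Cq))``,
  where Cq1 is the cycle at which a single starting molecule would be
  detected.  Failed amplifications ("no amplification") are informative
  zeros; unmeasured wells are dropped.
* **log relative abundance** — ``la = -Cq * ln(E)``, the natural-log scale
  response of the classic lognormal analysis.  Any per-gene additive
  constant (e.g. ``Cq1 * ln(E)``) is immaterial downstream because all
  reported quantities are within-gene contrasts or are normalized.

Status of every trial is tracked explicitly: ``ok`` (numeric Cq),
``no_amp`` (reaction ran, nothing amplified) or ``not_measured``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import (
    EfficiencyLookupError,
    ConfigurationError,
    ParseError,
    SchemaError,
    UniquenessError,
)

__all__ = [
    "OK",
    "NO_AMP",
    "NOT_MEASURED",
    "CqDataset",
    "EfficiencyTable",
    "CountDataset",
    "LogAbundanceDataset",
    "read_cq_table",
    "read_efficiency_table",
    "estimate_cq1",
    "cq_to_counts",
    "cq_to_log_abundance",
]

# trial status tokens
OK = "ok"
NO_AMP = "no_amp"
NOT_MEASURED = "not_measured"

#: empirical linear relation between single-molecule cycle and efficiency:
#: Cq1 = CQ1_INTERCEPT + CQ1_SLOPE * E (fitted on over-extended dilution series)
CQ1_INTERCEPT = 79.0
CQ1_SLOPE = -21.5

#: anchor of the single-efficiency PCR model: a perfectly doubling target
#: (E = 2) detects one molecule at cycle 36
CQ1_AT_E2 = 36.0

_KEY_COLS = ["sample", "tech_rep"]


@dataclass
class CqDataset:
    """Long-form table of amplification trials.

    ``trials`` columns: ``sample``, ``tech_rep``, one column per declared
    factor, ``gene``, ``cq`` (float; NaN unless status is ``ok``) and
    ``status`` in {ok, no_amp, not_measured}.
    """

    trials: pd.DataFrame
    factor_names: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = _KEY_COLS + self.factor_names + ["gene", "cq", "status"]
        missing = [c for c in required if c not in self.trials.columns]
        if missing:
            raise SchemaError(f"trial table lacks columns: {missing}")
        dup = self.trials.duplicated(subset=_KEY_COLS + ["gene"])
        if dup.any():
            rows = self.trials.loc[dup, _KEY_COLS + ["gene"]].head(3)
            raise UniquenessError(
                f"duplicate (sample, tech_rep, gene) trials, e.g.\n{rows}"
            )
        for f in self.factor_names:
            per_sample = self.trials.groupby("sample", observed=True)[f].nunique()
            bad = per_sample[per_sample > 1]
            if len(bad):
                raise SchemaError(
                    f"factor {f!r} is not constant within samples: "
                    f"{list(bad.index[:3])}"
                )
            if self.trials[f].isna().any():
                raise SchemaError(f"factor {f!r} has missing levels")
        ok = self.trials["status"] == OK
        cq = self.trials.loc[ok, "cq"]
        if cq.isna().any() or not ((cq > 0) & (cq < 100)).all():
            raise ParseError("numeric Cq values must lie in (0, 100)")
        unknown = set(self.trials["status"]) - {OK, NO_AMP, NOT_MEASURED}
        if unknown:
            raise ParseError(f"unknown trial status tokens: {unknown}")

    def status_counts(self) -> dict[str, int]:
        return self.trials["status"].value_counts().to_dict()

    def subset_genes(self, genes: list[str]) -> "CqDataset":
        """Dataset restricted to ``genes`` (order preserved)."""
        keep = self.trials[self.trials["gene"].isin(genes)].reset_index(drop=True)
        return CqDataset(keep, list(self.factor_names), [g for g in self.genes if g in genes])


@dataclass
class EfficiencyTable:
    """Per-gene amplification efficiency E (and optional single-molecule Cq1).

    E is the amplification factor per cycle; E = 2 is perfect doubling.
    Stored as a DataFrame indexed by gene with columns ``efficiency`` and
    (optionally NaN) ``cq1``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "efficiency" not in self.table.columns:
            raise SchemaError("efficiency table needs an 'efficiency' column")
        if "cq1" not in self.table.columns:
            self.table = self.table.assign(cq1=np.nan)
        e = self.table["efficiency"]
        if not ((e > 1.0) & (e <= 2.2)).all():
            bad = self.table.index[(e <= 1.0) | (e > 2.2)].tolist()
            raise ParseError(f"efficiencies must lie in (1, 2.2]: {bad}")

    @classmethod
    def from_dict(
        cls, eff: dict[str, float], cq1: dict[str, float] | None = None
    ) -> "EfficiencyTable":
        df = pd.DataFrame({"efficiency": pd.Series(eff, dtype=float)})
        df["cq1"] = pd.Series(cq1 or {}, dtype=float)
        df.index.name = "gene"
        return cls(df)

    def efficiency(self, gene: str) -> float:
        try:
            return float(self.table.at[gene, "efficiency"])
        except KeyError:
            raise EfficiencyLookupError(f"no efficiency entry for gene {gene!r}")

    def cq1(self, gene: str) -> float:
        v = self.table.at[gene, "cq1"] if gene in self.table.index else np.nan
        if np.isnan(v):
            raise ConfigurationError(
                f"gene {gene!r} has no Cq1 entry (required by cq1_policy='per_gene')"
            )
        return float(v)

    def require(self, genes: list[str]) -> None:
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise EfficiencyLookupError(f"no efficiency entry for genes: {missing}")


@dataclass
class CountDataset:
    """Molecule counts per trial; the response of the Poisson-lognormal model.

    ``no_amp`` trials carry count 0 (an observed zero, never dropped);
    ``not_measured`` trials are absent and tallied in ``drop_report``.
    """

    trials: pd.DataFrame  # sample, tech_rep, factors..., gene, count
    factor_names: list[str]
    genes: list[str]
    drop_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.trials["count"]
        if not (c == c.astype(int)).all() or (c < 0).any():
            raise ParseError("counts must be non-negative integers")
        self.trials = self.trials.assign(count=c.astype(int))


@dataclass
class LogAbundanceDataset:
    """Natural-log relative abundances per trial (classic / lognormal models).

    Carries ``la = -Cq ln E`` and the efficiency-corrected cycle
    ``cq_corrected = Cq log2 E`` (the Cq that would have been observed had
    every gene amplified with efficiency exactly 2).  Non-numeric trials are
    dropped and tallied in ``drop_report``.
    """

    trials: pd.DataFrame  # sample, tech_rep, factors..., gene, la, cq_corrected
    factor_names: list[str]
    genes: list[str]
    drop_report: dict = field(default_factory=dict)


def read_cq_table(
    path,
    factor_names: list[str],
    gene_names: list[str],
    no_amp_token: str = "ND",
) -> CqDataset:
    """Read a wide CSV of Cq values into a long-form :class:`CqDataset`.

    The file has one row per (sample, technical replicate): a ``sample``
    column, an optional ``tech_rep`` column (defaults to 1), the declared
    factor columns and one column per gene.  An empty cell means the well
    was not measured; ``no_amp_token`` (default ``"ND"``) marks a reaction
    that ran but never amplified — an informative zero, kept distinct from
    a missing measurement.
    """
    wide = pd.read_csv(path, dtype=str, keep_default_na=False)
    wide.columns = [c.strip() for c in wide.columns]
    if "sample" not in wide.columns:
        raise SchemaError("missing required column 'sample'")
    for col in factor_names + gene_names:
        if col not in wide.columns:
            raise SchemaError(f"missing declared column {col!r}")
    if "tech_rep" not in wide.columns:
        wide["tech_rep"] = "1"
    try:
        wide["tech_rep"] = wide["tech_rep"].astype(int)
    except ValueError as err:
        raise ParseError(f"tech_rep column is not integer: {err}")
    dup = wide.duplicated(subset=_KEY_COLS)
    if dup.any():
        raise UniquenessError(
            f"duplicate (sample, tech_rep) rows: {wide.loc[dup, _KEY_COLS].values.tolist()}"
        )

    records = []
    for idx, row in wide.iterrows():
        for gene in gene_names:
            raw = str(row[gene]).strip()
            if raw == "":
                status, cq = NOT_MEASURED, np.nan
            elif raw == no_amp_token:
                status, cq = NO_AMP, np.nan
            else:
                try:
                    cq = float(raw)
                except ValueError:
                    raise ParseError(
                        f"cell at row {idx + 2}, column {gene!r} is neither "
                        f"numeric, empty, nor the no-amplification token "
                        f"{no_amp_token!r}: {raw!r}"
                    )
                status = OK
            rec = {"sample": row["sample"], "tech_rep": int(row["tech_rep"])}
            for f in factor_names:
                rec[f] = row[f]
            rec.update(gene=gene, cq=cq, status=status)
            records.append(rec)
    trials = pd.DataFrame.from_records(records)
    return CqDataset(trials, list(factor_names), list(gene_names))


def read_efficiency_table(path) -> EfficiencyTable:
    """Read a CSV with columns gene, efficiency[, cq1]."""
    df = pd.read_csv(path)
    if "gene" not in df.columns:
        raise SchemaError("efficiency table needs a 'gene' column")
    df = df.set_index("gene")
    return EfficiencyTable(df)


def estimate_cq1(efficiency: float, method: str = "empirical") -> float:
    """Single-molecule quantification cycle for a given efficiency.

    ``empirical``
        Linear regression of dilution-series Cq1 estimates on efficiency:
        ``Cq1 = 79 - 21.5 E``.
    ``single_efficiency_model``
        The exponential-amplification model pinned at Cq1 = 36 for E = 2:
        a single molecule needs ``36 ln 2 / ln E`` cycles to reach the same
        product amount.
    """
    if efficiency <= 1.0:
        raise ValueError(
            f"efficiency {efficiency} <= 1 means no amplification; Cq1 undefined"
        )
    if efficiency > 2.2:
        raise ValueError(f"efficiency {efficiency} > 2.2 is not physical")
    if method == "empirical":
        return CQ1_INTERCEPT + CQ1_SLOPE * efficiency
    if method == "single_efficiency_model":
        return CQ1_AT_E2 * math.log(2.0) / math.log(efficiency)
    raise ValueError(f"unknown Cq1 method {method!r}")


def _resolve_cq1(gene: str, eff: EfficiencyTable, cq1_policy) -> float:
    if cq1_policy == "per_gene":
        return eff.cq1(gene)
    if cq1_policy == "empirical":
        return estimate_cq1(eff.efficiency(gene), "empirical")
    if isinstance(cq1_policy, (int, float)):
        return float(cq1_policy)
    raise ConfigurationError(
        f"cq1_policy must be 'per_gene', 'empirical' or a uniform number, "
        f"got {cq1_policy!r}"
    )


def cq_to_counts(
    data: CqDataset, eff: EfficiencyTable, cq1_policy=37.0
) -> CountDataset:
    """Convert Cq values to molecule counts, ``count = round(E**(Cq1 - Cq))``.

    A detected amplification implies at least one template molecule, so
    numeric-Cq trials are clamped to count >= 1 (otherwise very high Cq
    would alias with true zeros).  ``no_amp`` trials become count 0;
    ``not_measured`` trials are dropped.  The default policy assumes the
    same Cq1 = 37 for every gene, which in practice changes inference
    imperceptibly relative to gene-specific values.
    """
    eff.require(data.genes)
    cq1 = {g: _resolve_cq1(g, eff, cq1_policy) for g in data.genes}
    e = {g: eff.efficiency(g) for g in data.genes}

    t = data.trials
    dropped = int((t["status"] == NOT_MEASURED).sum())
    keep = t[t["status"] != NOT_MEASURED].copy()
    gene_e = keep["gene"].map(e).to_numpy(float)
    gene_cq1 = keep["gene"].map(cq1).to_numpy(float)
    with np.errstate(over="raise"):
        raw = gene_e ** (gene_cq1 - keep["cq"].to_numpy(float))
    counts = np.maximum(np.rint(raw), 1.0)
    counts[(keep["status"] == NO_AMP).to_numpy()] = 0.0
    keep["count"] = counts.astype(int)
    keep = keep.drop(columns=["cq", "status"]).reset_index(drop=True)
    report = {
        "not_measured_dropped": dropped,
        "no_amp_zeros": int((keep["count"] == 0).sum()),
        "cq1": cq1,
    }
    return CountDataset(keep, list(data.factor_names), list(data.genes), report)


def cq_to_log_abundance(
    data: CqDataset, eff: EfficiencyTable
) -> LogAbundanceDataset:
    """Efficiency-corrected natural-log relative abundances.

    ``la = -Cq ln E`` and ``cq_corrected = Cq log2 E``.  Both no-amplification
    and unmeasured trials are outside the log transform's domain and are
    dropped (counted in the drop report) — this loss of the informative
    zeros is precisely what the count-based model avoids.
    """
    eff.require(data.genes)
    e = {g: eff.efficiency(g) for g in data.genes}
    t = data.trials
    report = {
        "no_amp_dropped": int((t["status"] == NO_AMP).sum()),
        "not_measured_dropped": int((t["status"] == NOT_MEASURED).sum()),
    }
    keep = t[t["status"] == OK].copy()
    ln_e = keep["gene"].map(e).to_numpy(float)
    cq = keep["cq"].to_numpy(float)
    keep["la"] = -cq * np.log(ln_e)
    keep["cq_corrected"] = cq * np.log2(ln_e)
    keep = keep.drop(columns=["cq", "status"]).reset_index(drop=True)
    return LogAbundanceDataset(keep, list(data.factor_names), list(data.genes), report)


def write_long_table(ds, path) -> None:
    """Write a CountDataset/LogAbundanceDataset to CSV with a JSON drop report."""
    ds.trials.to_csv(path, index=False)
    report = getattr(ds, "drop_report", {})
    with open(str(path) + ".drops.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
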