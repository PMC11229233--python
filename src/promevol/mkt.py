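"""Standard McDonald-Kreitman tests on per-gene count tables.

For a gene with nonsynonymous/synonymous divergence (Dn, Ds; fixed between
species) and polymorphism (Pn, Ps; segregating within the focal population)
the neutrality index is NI = (Pn/Ps) / (Dn/Ds) and the adaptive fraction
estimate is alpha = 1 - NI.  Significance is a two-sided Fisher's exact test
on [[Dn, Ds], [Pn, Ps]]; gene panels are BH-FDR corrected per population and
a gene is called under positive selection when the corrected p <= 0.05 *and*
alpha > 0 (an adaptive excess in the Dn direction).  No divergence or
low-frequency-polymorphism corrections are applied (Standard MKT only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as sps

from .ingest import InputError
from .stats import adjust_pvalues

__all__ = ["MKTable", "MKTResult", "standard_mkt", "pooled_group_mkt", "mkt_panel"]


@dataclass(frozen=True)
class MKTable:
    """Per-gene polymorphism/divergence counts for one population."""

    gene_id: str
    population: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int

    def __post_init__(self) -> None:
        if min(self.Dn, self.Ds, self.Pn, self.Ps) < 0:
            raise InputError(f"{self.gene_id}: MKT counts must be non-negative")


@dataclass
class MKTResult:
    gene_id: str
    population: str
    alpha: float  # NaN when undefined
    neutrality_index: float  # NaN when undefined
    fisher_p: float
    p_adj: float = math.nan
    positive_selection: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.alpha)


def standard_mkt(table: MKTable) -> MKTResult:
    """Standard MKT for one gene: NI, alpha and two-sided Fisher's exact p.

    NI and alpha are undefined (NaN, flagged via :attr:`MKTResult.defined`)
    when a required denominator (Ds, Ps, or Dn for the NI ratio) is zero; the
    Fisher p is still computed from the raw 2x2 table.
    """
    if table.Ds > 0 and table.Ps > 0 and table.Dn > 0:
        ni = (table.Pn / table.Ps) / (table.Dn / table.Ds)
        alpha = 1.0 - ni
    else:
        ni = alpha = math.nan
    _, p = sps.fisher_exact([[table.Dn, table.Ds], [table.Pn, table.Ps]], alternative="two-sided")
    return MKTResult(table.gene_id, table.population, alpha, ni, float(p))


def pooled_group_mkt(tables: Sequence[MKTable], group_id: str = "pooled") -> MKTResult:
    """Element-wise sum the counts of a gene group, then run the Standard MKT."""
    if not tables:
        raise InputError("cannot pool an empty group")
    pops = {t.population for t in tables}
    if len(pops) != 1:
        raise InputError(f"cannot pool across populations {sorted(pops)}")
    pooled = MKTable(
        group_id,
        tables[0].population,
        sum(t.Dn for t in tables),
        sum(t.Ds for t in tables),
        sum(t.Pn for t in tables),
        sum(t.Ps for t in tables),
    )
    return standard_mkt(pooled)


def mkt_panel(results: Sequence[MKTResult], alpha_level: float = 0.05) -> pd.DataFrame:
    """BH-FDR adjust Fisher p-values per population and flag positive selection."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "population": [r.population for r in results],
            "NI": [r.neutrality_index for r in results],
            "alpha": [r.alpha for r in results],
            "fisher_p": [r.fisher_p for r in results],
        }
    )
    df["p_adj"] = math.nan
    for pop, idx in df.groupby("population").groups.items():
        df.loc[idx, "p_adj"] = adjust_pvalues(df.loc[idx, "fisher_p"].to_numpy(), "bh_fdr")
    df["positive_selection"] = (df["p_adj"] <= alpha_level) & (df["alpha"] > 0)
    for r, (_, row) in zip(results, df.iterrows()):
        r.p_adj = float(row["p_adj"])
        r.positive_selection = bool(row["positive_selection"])
    return df
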