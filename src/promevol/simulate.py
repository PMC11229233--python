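"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes, not
Drosophila biology: a star phylogeny (each non-reference lineage evolves
independently from the reference sequence) with region-specific per-site
substitution and indel rates; iid Gaussian per-base conservation scores with
a promoter-window shift for fast-promoter genes; two-species negative
binomial count matrices with log-normal gene means, a species effect for DE
genes and per-gene annotation-length divergence; and Poisson
polymorphism/divergence tables under neutral or positive-selection regimes.

Every generator is a pure function of its :class:`SimulationConfig`:
identical configs give identical outputs, and each generator draws from its
own seed stream so results do not depend on call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coords import DEFAULT_WINDOW, AnalysisWindow
from .ingest import ConservationTrack, ReferenceAnchoredAlignment, write_alignment_fasta
from .mkt import MKTable

__all__ = [
    "SimulationConfig",
    "SPECIES",
    "simulate_alignment_set",
    "simulate_conservation",
    "simulate_counts",
    "simulate_mkt_tables",
]

#: Default species panel: reference first, four close relatives.
SPECIES = ("dmel", "dsim", "dsec", "dyak", "dere")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators (defaults = study conditions).

    Alignment rates are per-site, per-branch probabilities over the whole
    divergence between the reference and one non-reference species; the
    promoter interval of ``fast_promoter`` genes uses every rate multiplied
    by ``promoter_rate_multiplier``.
    """

    seed: int = 0
    # alignments
    n_genes_per_group: int = 12
    species: tuple[str, ...] = SPECIES
    window: AnalysisWindow = field(default=DEFAULT_WINDOW)
    substitution_rate: float = 0.08
    deletion_rate: float = 0.01
    insertion_rate: float = 0.01
    indel_mean_length: float = 2.0
    promoter_rate_multiplier: float = 3.0
    # conservation tracks
    conservation_mean: float = 1.0
    conservation_sd: float = 1.0
    conservation_effect: float = 1.0  # downward promoter shift for fast genes
    # expression counts
    n_expression_genes: int = 1000
    n_samples_per_species: int = 4
    nb_dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    expression_meanlog: float = float(np.log(150.0))
    expression_sdlog: float = 1.0
    length_divergence_sdlog: float = 0.1
    library_size_spread: float = 0.3
    # MKT tables
    n_mkt_genes: int = 1000
    # means chosen so the nonsynonymous divergence (mean * ratio = 60) and the
    # synonymous polymorphism (120) counts keep the Jensen bias of the
    # ratio-of-ratios alpha estimator (~1/E[Dn] + 1/E[Ps]) well under 0.05
    mkt_divergence_mean: float = 200.0
    mkt_polymorphism_mean: float = 120.0
    mkt_nonsyn_ratio: float = 0.3
    mkt_dn_inflation: float = 3.0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "deletion_rate", "insertion_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_genes_per_group < 1 or self.n_expression_genes < 1 or self.n_mkt_genes < 1:
            raise ValueError("all gene counts must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per stream so call order cannot matter."""
        return np.random.default_rng([self.seed, stream])


GROUPS = ("fast_promoter", "background", "control")


def _evolve_species(
    ref: np.ndarray,
    sub_rate: np.ndarray,
    del_rate: np.ndarray,
    ins_rate: np.ndarray,
    mean_len: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[int, str]]:
    """One lineage: substituted/deleted reference chars + insertions per site."""
    n = len(ref)
    chars = ref.copy()
    sub = rng.random(n) < sub_rate
    if sub.any():
        # substitute to a uniformly chosen *different* base
        idx = np.searchsorted(_BASES, chars[sub])
        shift = rng.integers(1, 4, size=sub.sum())
        chars[sub] = _BASES[(idx + shift) % 4]
    del_start = np.flatnonzero(rng.random(n) < del_rate)
    p_geom = 1.0 / mean_len
    for i in del_start:
        chars[i : i + int(rng.geometric(p_geom))] = "-"
    ins_start = np.flatnonzero(rng.random(n) < ins_rate)
    insertions = {
        int(i): "".join(rng.choice(_BASES, size=int(rng.geometric(p_geom))))
        for i in ins_start
    }
    return chars, insertions


def simulate_alignment_set(
    cfg: SimulationConfig,
    groups: Sequence[str] = GROUPS,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, ReferenceAnchoredAlignment], pd.DataFrame]:
    """Aligned gene set per group; fast_promoter genes get boosted promoter rates.

    Returns gene_id -> anchored alignment plus a truth table; with *out_dir*
    each gene is additionally written as aligned FASTA (``<gene>.fa``).
    """
    rng = cfg.rng(1)
    window = cfg.window
    n = window.length
    promoter = window.promoter_mask()
    alignments: dict[str, ReferenceAnchoredAlignment] = {}
    truth_rows = []
    for group in groups:
        mult = cfg.promoter_rate_multiplier if group == "fast_promoter" else 1.0
        sub_rate = np.where(promoter, min(cfg.substitution_rate * mult, 0.95), cfg.substitution_rate)
        del_rate = np.where(promoter, min(cfg.deletion_rate * mult, 0.95), cfg.deletion_rate)
        ins_rate = np.where(promoter, min(cfg.insertion_rate * mult, 0.95), cfg.insertion_rate)
        for g in range(cfg.n_genes_per_group):
            gene_id = f"{group}_{g:03d}"
            ref = rng.choice(_BASES, size=n)
            per_species = [
                _evolve_species(ref, sub_rate, del_rate, ins_rate, cfg.indel_mean_length, rng)
                for _ in cfg.species[1:]
            ]
            # column layout: each site contributes 1 + max-insertion columns
            ins_len = np.zeros(n, dtype=np.int64)
            for _, ins in per_species:
                for i, s in ins.items():
                    ins_len[i] = max(ins_len[i], len(s))
            site_col = np.arange(n) + np.concatenate([[0], np.cumsum(ins_len[:-1])])
            total = n + int(ins_len.sum())
            cols = np.full((total, len(cfg.species)), "-", dtype="<U1")
            cols[site_col, 0] = ref
            for s_idx, (chars, ins) in enumerate(per_species, start=1):
                cols[site_col, s_idx] = chars
                for i, seq in ins.items():
                    start = site_col[i] + 1
                    cols[start : start + len(seq), s_idx] = list(seq)
            ref_offset = np.repeat(window.offsets(), 1 + ins_len)
            aln = ReferenceAnchoredAlignment(gene_id, tuple(cfg.species), cols, ref_offset)
            alignments[gene_id] = aln
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "group": group,
                    "promoter_substitution_rate": float(sub_rate[promoter][0]),
                    "promoter_deletion_rate": float(del_rate[promoter][0]),
                    "promoter_insertion_rate": float(ins_rate[promoter][0]),
                    "background_substitution_rate": cfg.substitution_rate,
                    "background_deletion_rate": cfg.deletion_rate,
                    "background_insertion_rate": cfg.insertion_rate,
                }
            )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gene_id in sorted(alignments):
            write_alignment_fasta(alignments[gene_id], out_dir / f"{gene_id}.fa")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return alignments, truth


def simulate_conservation(
    cfg: SimulationConfig,
    groups: Sequence[str] = GROUPS,
) -> tuple[dict[str, ConservationTrack], pd.DataFrame]:
    """Per-gene conservation tracks: iid N(mean, sd) scores, full coverage.

    ``fast_promoter`` genes have their promoter-window scores shifted down by
    ``conservation_effect`` (lower conservation = faster evolution).
    """
    rng = cfg.rng(2)
    window = cfg.window
    promoter = window.promoter_mask()
    tracks: dict[str, ConservationTrack] = {}
    rows = []
    for group in groups:
        shift = cfg.conservation_effect if group == "fast_promoter" else 0.0
        for g in range(cfg.n_genes_per_group):
            gene_id = f"{group}_{g:03d}"
            scores = rng.normal(cfg.conservation_mean, cfg.conservation_sd, size=window.length)
            scores[promoter] -= shift
            tracks[gene_id] = ConservationTrack(gene_id, scores)
            rows.append({"gene_id": gene_id, "group": group, "promoter_shift": -shift})
    return tracks, pd.DataFrame(rows)


def simulate_counts(cfg: SimulationConfig) -> dict:
    """Two-species NB count matrices with length divergence and known DE truth.

    Returns a dict with ``counts_a``/``counts_b`` (genes x samples),
    ``lengths_a``/``lengths_b``, the 1:1 ``orthologs`` map and a ``truth``
    table (``is_de``, ``log2fc`` = A-over-B expression effect).
    """
    rng = cfg.rng(3)
    n = cfg.n_expression_genes
    genes_a = [f"g{i:05d}" for i in range(n)]
    genes_b = [f"{g}_b" for g in genes_a]

    lengths_a = rng.integers(500, 5000, size=n).astype(float)
    lengths_b = np.round(lengths_a * rng.lognormal(0.0, cfg.length_divergence_sdlog, size=n))
    mean_expr = rng.lognormal(cfg.expression_meanlog, cfg.expression_sdlog, size=n)
    is_de = rng.random(n) < cfg.de_fraction
    lfc = np.where(is_de, rng.choice([-1.0, 1.0], size=n) * cfg.de_log2fc, 0.0)

    n_s = cfg.n_samples_per_species
    lib = rng.uniform(1 - cfg.library_size_spread, 1 + cfg.library_size_spread, size=2 * n_s)
    r = 1.0 / cfg.nb_dispersion

    def draw(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(r, r / (r + mu))

    # expected counts scale with expression, annotation length and library size
    mu_a = mean_expr[:, None] * (lengths_a[:, None] / 1000.0) * lib[None, :n_s]
    mu_b = (
        mean_expr[:, None]
        * 2.0 ** (-lfc[:, None])
        * (lengths_b[:, None] / 1000.0)
        * lib[None, n_s:]
    )
    counts_a = pd.DataFrame(draw(mu_a), index=genes_a, columns=[f"mel_{j}" for j in range(n_s)])
    counts_b = pd.DataFrame(draw(mu_b), index=genes_b, columns=[f"yak_{j}" for j in range(n_s)])
    truth = pd.DataFrame(
        {"gene_id": genes_a, "is_de": is_de, "log2fc": lfc, "mean_expression": mean_expr}
    )
    return {
        "counts_a": counts_a,
        "counts_b": counts_b,
        "lengths_a": dict(zip(genes_a, lengths_a)),
        "lengths_b": dict(zip(genes_b, lengths_b)),
        "orthologs": dict(zip(genes_a, genes_b)),
        "truth": truth,
    }


def simulate_mkt_tables(
    cfg: SimulationConfig,
    regime: str = "neutral",
    population: str = "Zambia",
) -> tuple[list[MKTable], pd.DataFrame]:
    """Poisson MKT count tables under a neutral or positive-selection regime.

    Neutral: Dn/Ds and Pn/Ps share the nonsynonymous-to-synonymous odds
    ``mkt_nonsyn_ratio`` (so NI is centred on 1, alpha on 0).  Positive: the
    Dn mean is additionally inflated by ``mkt_dn_inflation`` (expected pooled
    alpha ~ 1 - 1/inflation).
    """
    if regime not in {"neutral", "positive"}:
        raise ValueError(f"unknown regime {regime!r}")
    rng = cfg.rng(4 if regime == "neutral" else 5)
    inflation = cfg.mkt_dn_inflation if regime == "positive" else 1.0
    omega = cfg.mkt_nonsyn_ratio
    tables = []
    for i in range(cfg.n_mkt_genes):
        tables.append(
            MKTable(
                gene_id=f"mkt_{regime}_{i:05d}",
                population=population,
                Dn=int(rng.poisson(cfg.mkt_divergence_mean * omega * inflation)),
                Ds=int(rng.poisson(cfg.mkt_divergence_mean)),
                Pn=int(rng.poisson(cfg.mkt_polymorphism_mean * omega)),
                Ps=int(rng.poisson(cfg.mkt_polymorphism_mean)),
            )
        )
    truth = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tables],
            "regime": regime,
            "expected_alpha": 0.0 if regime == "neutral" else 1.0 - 1.0 / inflation,
        }
    )
    return tables, truth
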