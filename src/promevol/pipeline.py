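"""End-to-end analyses: promoter evolution, expression divergence and MKT.

Each ``run_*`` function orchestrates the lower-level modules over files,
writes TSV reports into an output directory and returns the key tables.  A
machine-readable exclusion log (gene, stage, reason) mirrors every removal
rule, so input genes = reported genes + excluded genes, always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coords import DEFAULT_WINDOW, AnalysisWindow
from .events import (
    DScore,
    call_events,
    concatenate_group,
    control_baseline,
    d_score,
    d_score_conservation,
    sliding_score,
    sum_events,
)
from .expression import bin_by_dP, classify_germ_soma, cross_species_de, volcano_classify
from .ingest import (
    ConservationTrack,
    CoverageError,
    GAP,
    InputError,
    ReferenceAnchoredAlignment,
    extract_window,
    filter_gene_set,
    read_alignment_fasta,
    read_group_lists,
)
from .mkt import MKTable, mkt_panel, pooled_group_mkt, standard_mkt
from .simulate import SPECIES
from .stats import build_heatmap, compare_panel, comparisons_to_frame, rank_panel

__all__ = [
    "RunConfig",
    "load_config",
    "run_promoter_analysis",
    "run_expression_analysis",
    "run_mkt",
    "read_conservation_tsv",
    "write_conservation_tsv",
]

CLASS_FILTERS = ("all", "base_change", "indel")


@dataclass
class RunConfig:
    """Key-value configuration driving every analysis mode."""

    mode: str = "alignment"  # alignment | conservation | expression | mkt | full
    control_group: str = "control"
    correction: str = "bonferroni"
    gene_correction: str = "bh_fdr"
    alpha: float = 0.05
    window: AnalysisWindow = field(default=DEFAULT_WINDOW)
    species: tuple[str, ...] = SPECIES
    sliding_window: int = 5
    fc_thresh: float = 0.5
    padj_thresh: float = 10 ** -0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        window_kwargs = raw.pop("window", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if window_kwargs:
            cfg.window = AnalysisWindow(**window_kwargs)
        if isinstance(cfg.species, list):
            cfg.species = tuple(cfg.species)
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    return RunConfig.from_yaml(path) if path else RunConfig()


# ---------------------------------------------------------------------------
# Conservation-track TSV interchange (gene-oriented, one row per offset)
# ---------------------------------------------------------------------------


def write_conservation_tsv(track: ConservationTrack, window: AnalysisWindow, path: str | Path) -> None:
    pd.DataFrame({"offset": window.offsets(), "score": track.scores}).to_csv(
        path, sep="\t", index=False
    )


def read_conservation_tsv(
    path: str | Path, window: AnalysisWindow = DEFAULT_WINDOW, gene_id: str | None = None
) -> ConservationTrack:
    df = pd.read_csv(path, sep="\t")
    scores = np.full(window.length, np.nan)
    for off, val in zip(df["offset"], df["score"]):
        scores[window.offset_to_index(int(off))] = val
    return ConservationTrack(gene_id or Path(path).stem, scores)


# ---------------------------------------------------------------------------
# Promoter evolution analysis
# ---------------------------------------------------------------------------


def _load_alignments(
    alignment_dir: str | Path,
    genes: Sequence[str],
    species: Sequence[str],
    window: AnalysisWindow,
) -> tuple[dict[str, ReferenceAnchoredAlignment], list[tuple[str, str, str]]]:
    """Read, trim and coverage-check per-gene FASTA files."""
    alignment_dir = Path(alignment_dir)
    out: dict[str, ReferenceAnchoredAlignment] = {}
    excluded: list[tuple[str, str, str]] = []
    for gene in genes:
        path = alignment_dir / f"{gene}.fa"
        if not path.exists():
            excluded.append((gene, "ingest", "missing_alignment_file"))
            continue
        try:
            aln = read_alignment_fasta(path, species, gene_id=gene, tss_index=window.upstream)
            aln = extract_window(aln, window)
        except CoverageError:
            excluded.append((gene, "ingest", "window_coverage"))
            continue
        # a species with no conserved genomic sequence contributes only gaps
        all_gap = [sp for j, sp in enumerate(aln.species) if (aln.columns[:, j] == GAP).all()]
        if all_gap:
            excluded.append((gene, "ingest", "species_coverage"))
            continue
        out[gene] = aln
    return out, excluded


def run_promoter_analysis(
    groups: Mapping[str, Sequence[str]] | str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    alignment_dir: str | Path | None = None,
    conservation: Mapping[str, ConservationTrack] | str | Path | None = None,
) -> dict:
    """Promoter hotspot analysis in alignment (d) or conservation (d_P) mode.

    ``groups`` maps group name -> gene ids (or is a TSV path); the control
    group named in the config must be present.  In alignment mode d scores
    are computed per class filter (all / base_change / indel) for every gene
    and group against the control baseline; in conservation mode d_P is
    computed against the pooled control (or genome-average) score.  Writes
    d-score, comparison, heatmap and exclusion-log TSVs and returns the
    tables.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(groups, Mapping):
        groups = read_group_lists(groups)
    if not groups or all(len(g) == 0 for g in groups.values()):
        raise InputError("empty gene group specification")
    if cfg.control_group not in groups:
        raise InputError(f"control group {cfg.control_group!r} not in group lists")

    memberships: dict[str, list[str]] = {}
    for grp, genes in groups.items():
        for g in genes:
            memberships.setdefault(g, []).append(grp)
    all_genes = sorted(memberships)
    unique_genes, dup_log = filter_gene_set(all_genes, group_memberships=memberships)
    exclusions = [(g, "group_filter", r) for g, r in dup_log.itertuples(index=False)]
    groups = {
        grp: [g for g in genes if g in set(unique_genes)] for grp, genes in groups.items()
    }

    if cfg.mode == "alignment":
        if alignment_dir is None:
            raise InputError("alignment mode needs an alignment directory")
        result = _promoter_alignment_mode(groups, alignment_dir, cfg, out_dir, exclusions)
    elif cfg.mode == "conservation":
        if conservation is None:
            raise InputError("conservation mode needs conservation tracks")
        if not isinstance(conservation, Mapping):
            cons_dir = Path(conservation)
            conservation = {
                p.stem: read_conservation_tsv(p, cfg.window) for p in sorted(cons_dir.glob("*.tsv"))
                if p.stem != "truth"
            }
        result = _promoter_conservation_mode(groups, conservation, cfg, out_dir, exclusions)
    else:
        raise InputError(f"unknown promoter mode {cfg.mode!r}")
    return result


def _promoter_alignment_mode(groups, alignment_dir, cfg, out_dir, exclusions):
    window = cfg.window
    genes_by_group: dict[str, list[str]] = {}
    alignments: dict[str, ReferenceAnchoredAlignment] = {}
    for grp, genes in groups.items():
        loaded, dropped = _load_alignments(alignment_dir, genes, cfg.species, window)
        exclusions.extend(dropped)
        alignments.update(loaded)
        genes_by_group[grp] = sorted(loaded)
    if not genes_by_group[cfg.control_group]:
        raise InputError("control group lost all genes during ingest")

    tracks = {g: call_events(a, window) for g, a in alignments.items()}
    gene_rows, comp_frames = [], []
    for class_filter in CLASS_FILTERS:
        sums = {g: sum_events(t, class_filter) for g, t in tracks.items()}
        se = {g: sliding_score(s, cfg.sliding_window) for g, s in sums.items()}
        baseline = control_baseline(
            [se[g] for g in genes_by_group[cfg.control_group]], window
        )
        # group-level: per-gene-average event track, same Se/baseline scale
        group_d: dict[str, DScore] = {}
        group_se = {}
        for grp, genes in genes_by_group.items():
            if not genes:
                continue
            track = concatenate_group([sums[g] for g in genes], grp, average=True)
            group_se[grp] = sliding_score(track, cfg.sliding_window)
            group_d[grp] = d_score(group_se[grp], baseline, window)
        test_groups = [g for g in group_d if g != cfg.control_group]
        comps = compare_panel(
            [group_d[g] for g in test_groups], group_d[cfg.control_group],
            cfg.correction, cfg.alpha,
        )
        df = comparisons_to_frame(comps)
        df.insert(0, "level", "group")
        df.insert(1, "class_filter", class_filter)
        comp_frames.append(df)
        # gene-level, FDR-corrected within each test group
        for grp in test_groups:
            gene_d = [d_score(se[g], baseline, window) for g in genes_by_group[grp]]
            comps = compare_panel(gene_d, group_d[cfg.control_group], cfg.gene_correction, cfg.alpha)
            df = comparisons_to_frame(comps)
            df.insert(0, "level", "gene")
            df.insert(1, "class_filter", class_filter)
            df["group"] = grp
            comp_frames.append(df)
            for d in gene_d:
                gene_rows.append(
                    {"gene_id": d.id, "group": grp, "class_filter": class_filter,
                     "d": d.value, "n_exceed": d.n_exceed, "N": d.N, "baseline": d.baseline}
                )
        if class_filter == "all":
            order = rank_panel(
                [d_score(se[g], baseline, window) for g in sorted(alignments)]
            )
            heatmap = build_heatmap([se[g] for g in sorted(alignments)], order=order)
            heatmap.to_csv(out_dir / "heatmap_se.tsv", sep="\t")

    comparisons = pd.concat(comp_frames, ignore_index=True)
    gene_scores = pd.DataFrame(gene_rows)
    exclusion_log = pd.DataFrame(exclusions, columns=["gene_id", "stage", "reason"])
    gene_scores.to_csv(out_dir / "gene_d_scores.tsv", sep="\t", index=False)
    comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    exclusion_log.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    return {
        "mode": "alignment",
        "gene_scores": gene_scores,
        "comparisons": comparisons,
        "exclusions": exclusion_log,
        "genes_by_group": genes_by_group,
    }


def _promoter_conservation_mode(groups, conservation, cfg, out_dir, exclusions):
    window = cfg.window
    genes_by_group: dict[str, list[str]] = {}
    for grp, genes in groups.items():
        kept, log = filter_gene_set(
            genes, conservation_tracks={g: conservation[g] for g in genes if g in conservation}
        )
        exclusions.extend((g, "conservation_filter", r) for g, r in log.itertuples(index=False))
        genes_by_group[grp] = kept
    control_genes = genes_by_group[cfg.control_group]
    if not control_genes:
        raise InputError("control group lost all genes during coverage filtering")

    baseline = control_baseline([conservation[g] for g in control_genes], window)
    gene_d = {
        grp: [d_score_conservation(conservation[g], baseline, window) for g in genes]
        for grp, genes in genes_by_group.items()
    }
    # group-level d_P pools promoter positions across the group's genes
    group_d = {}
    for grp, ds in gene_d.items():
        if not ds:
            continue
        n_exceed = sum(d.n_exceed for d in ds)
        N = sum(d.N for d in ds)
        group_d[grp] = DScore(grp, 100.0 * n_exceed / N, n_exceed, N, baseline, "conservation_dP")
    test_groups = [g for g in group_d if g != cfg.control_group]
    comp_frames = []
    comps = compare_panel(
        [group_d[g] for g in test_groups], group_d[cfg.control_group], cfg.correction, cfg.alpha
    )
    df = comparisons_to_frame(comps)
    df.insert(0, "level", "group")
    comp_frames.append(df)
    gene_rows = []
    for grp in test_groups:
        comps = compare_panel(gene_d[grp], group_d[cfg.control_group], cfg.gene_correction, cfg.alpha)
        df = comparisons_to_frame(comps)
        df.insert(0, "level", "gene")
        df["group"] = grp
        comp_frames.append(df)
        for d in gene_d[grp]:
            gene_rows.append(
                {"gene_id": d.id, "group": grp, "dP": d.value,
                 "n_exceed": d.n_exceed, "N": d.N, "baseline": d.baseline}
            )
    analysed = sorted(set().union(*(set(g) for g in genes_by_group.values())))
    order = rank_panel([d_score_conservation(conservation[g], baseline, window) for g in analysed])
    heatmap = build_heatmap([conservation[g] for g in analysed], order=order, window=window)
    heatmap.to_csv(out_dir / "heatmap_phylop.tsv", sep="\t")

    comparisons = pd.concat(comp_frames, ignore_index=True)
    gene_scores = pd.DataFrame(gene_rows)
    exclusion_log = pd.DataFrame(exclusions, columns=["gene_id", "stage", "reason"])
    gene_scores.to_csv(out_dir / "gene_dP_scores.tsv", sep="\t", index=False)
    comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    exclusion_log.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    return {
        "mode": "conservation",
        "gene_scores": gene_scores,
        "comparisons": comparisons,
        "exclusions": exclusion_log,
        "genes_by_group": genes_by_group,
    }


# ---------------------------------------------------------------------------
# Expression analysis
# ---------------------------------------------------------------------------


def run_expression_analysis(
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    profiles: pd.DataFrame | str | Path | None = None,
    counts_a: pd.DataFrame | str | Path | None = None,
    counts_b: pd.DataFrame | str | Path | None = None,
    orthologs: Mapping[str, str] | str | Path | None = None,
    lengths_a: Mapping[str, float] | str | Path | None = None,
    lengths_b: Mapping[str, float] | str | Path | None = None,
    dscores: Sequence[DScore] | None = None,
) -> dict:
    """Germline/soma classification, cross-species DE and d_P binning.

    Any input may be an in-memory object or a TSV path.  ``profiles`` feeds
    the classifier; the count matrices + ortholog map + lengths feed the DE
    stage; ``dscores`` (optional, e.g. from a conservation-mode promoter run)
    enable the promoter-score binning of expression divergence.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _frame(x, **kw):
        return pd.read_csv(x, sep="\t", **kw) if isinstance(x, (str, Path)) else x

    result: dict = {}
    labels = None
    if profiles is not None:
        labels = classify_germ_soma(_frame(profiles))
        labels.to_csv(out_dir / "gene_class_labels.tsv", sep="\t", index=False)
        result["labels"] = labels

    if counts_a is not None:
        if counts_b is None or orthologs is None or lengths_a is None or lengths_b is None:
            raise InputError("expression mode needs both count matrices, orthologs and lengths")
        counts_a = _frame(counts_a, index_col=0)
        counts_b = _frame(counts_b, index_col=0)
        if isinstance(orthologs, (str, Path)):
            df = pd.read_csv(orthologs, sep="\t")
            orthologs = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if isinstance(lengths_a, (str, Path)):
            df = pd.read_csv(lengths_a, sep="\t")
            lengths_a = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if isinstance(lengths_b, (str, Path)):
            df = pd.read_csv(lengths_b, sep="\t")
            lengths_b = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        de, de_exclusions = cross_species_de(counts_a, counts_b, orthologs, lengths_a, lengths_b)
        de = volcano_classify(de, cfg.fc_thresh, cfg.padj_thresh)
        de.to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
        de_exclusions.insert(1, "stage", "expression")
        de_exclusions.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
        result["de"] = de
        result["exclusions"] = de_exclusions

        if dscores is not None and labels is not None:
            bins = bin_by_dP(dscores, de, labels, cfg.fc_thresh, cfg.padj_thresh)
            bins.to_csv(out_dir / "dP_bin_summary.tsv", sep="\t", index=False)
            result["bins"] = bins
    return result


# ---------------------------------------------------------------------------
# MKT analysis
# ---------------------------------------------------------------------------


def run_mkt(
    tables: Sequence[MKTable] | str | Path,
    out_dir: str | Path,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict:
    """Per-gene Standard MKT panels (FDR per population) plus pooled groups."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, (str, Path)):
        df = pd.read_csv(tables, sep="\t")
        tables = [
            MKTable(r.gene_id, r.population, int(r.Dn), int(r.Ds), int(r.Pn), int(r.Ps))
            for r in df.itertuples(index=False)
        ]
    results = [standard_mkt(t) for t in tables]
    panel = mkt_panel(results)
    panel.to_csv(out_dir / "mkt_panel.tsv", sep="\t", index=False)

    pooled_rows = []
    by_pop: dict[str, list[MKTable]] = {}
    for t in tables:
        by_pop.setdefault(t.population, []).append(t)
    for pop, pop_tables in sorted(by_pop.items()):
        group_map = groups or {"all": [t.gene_id for t in pop_tables]}
        for grp, genes in group_map.items():
            sub = [t for t in pop_tables if t.gene_id in set(genes)]
            if not sub:
                continue
            res = pooled_group_mkt(sub, group_id=grp)
            pooled_rows.append(
                {"group": grp, "population": pop, "n_genes": len(sub),
                 "alpha": res.alpha, "NI": res.neutrality_index, "fisher_p": res.fisher_p}
            )
    pooled = pd.DataFrame(pooled_rows)
    pooled.to_csv(out_dir / "mkt_pooled.tsv", sep="\t", index=False)
    return {"panel": panel, "pooled": pooled}
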