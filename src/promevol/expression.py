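"""Germline/soma expression classification and cross-species DE.

Two concerns live here:

* **Gene classification** — the stringent germline / soma calls built from a
  germline-vs-soma (vasa-GFP sorted) differential expression contrast plus
  RPKM thresholds in whole ovary, early embryo (0-2 h) and ovarian somatic
  cell (OSC) datasets.

* **Cross-species differential expression** — a per-ortholog-pair negative
  binomial Wald test between two species' ovary count matrices with a
  species-specific gene-length normalization: each sample's median-of-ratios
  size factor is multiplied by a per-gene length factor
  ``L_{g,s} / sqrt(L_{g,A} * L_{g,B})`` so that annotation length divergence
  between the species does not masquerade as expression divergence.
  Dispersions are estimated per gene by the method of moments and shrunk
  toward a parametric mean-dispersion trend ``a0 + a1/mu``; the Wald test is
  on the species coefficient, with positive log2 fold change meaning higher
  expression in species A.  BH correction across genes.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .events import DScore
from .ingest import InputError
from .stats import adjust_pvalues

__all__ = [
    "compute_rpkm",
    "classify_germ_soma",
    "estimate_size_factors",
    "cross_species_de",
    "volcano_classify",
    "bin_by_dP",
    "GERMLINE_FILTERS",
    "SOMA_FILTERS",
]

#: Threshold filters defining the stringent germline list: germline-enriched
#: in the vasa-GFP contrast, expressed in whole ovary and in early embryos.
GERMLINE_FILTERS = {
    "vasa_log2fc": (">", 2.0),
    "vasa_padj": ("<", 0.01),
    "ovary_rpkm": (">", 10.0),
    "embryo_rpkm": (">", 9.0),
}

#: Threshold filters defining the stringent soma list: soma-enriched, ovary
#: expressed, highly expressed in OSCs and depleted from early embryos.
SOMA_FILTERS = {
    "vasa_log2fc": ("<", -1.0),
    "vasa_padj": ("<", 0.01),
    "ovary_rpkm": (">", 10.0),
    "osc_rpkm": (">", 20.0),
    "embryo_rpkm": ("<", 2.0),
}


def compute_rpkm(count: float, gene_length_nt: float, library_size: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_nt <= 0 or library_size <= 0:
        raise InputError("gene length and library size must be positive")
    return 1e9 * count / (gene_length_nt * library_size)


def _apply_filters(row: pd.Series, filters: Mapping[str, tuple[str, float]]) -> tuple[bool, list[str]]:
    reasons = []
    ok = True
    for col, (op, thr) in filters.items():
        val = row.get(col, np.nan)
        if pd.isna(val):
            reasons.append(f"{col}:missing")
            ok = False
            continue
        passed = val > thr if op == ">" else val < thr  # strict comparisons
        reasons.append(f"{col}{op}{thr}:{'pass' if passed else 'fail'}")
        ok = ok and passed
    return ok, reasons


def classify_germ_soma(profiles: pd.DataFrame) -> pd.DataFrame:
    """Label genes germline / soma / neither from strict threshold filters.

    Expects columns ``gene_id, vasa_log2fc, vasa_padj, ovary_rpkm,
    embryo_rpkm, osc_rpkm`` (missing values fail the filters that need them).
    The germline and soma filter sets are disjoint by construction (the vasa
    fold change cannot be both > 2 and < -1), so no gene gets both labels.
    """
    out = []
    for _, row in profiles.iterrows():
        germ, germ_reasons = _apply_filters(row, GERMLINE_FILTERS)
        soma, soma_reasons = _apply_filters(row, SOMA_FILTERS)
        if germ:
            label, reasons = "germline", germ_reasons
        elif soma:
            label, reasons = "soma", soma_reasons
        else:
            reasons = [r for r in germ_reasons + soma_reasons if not r.endswith("pass")]
            if all(r.endswith(":missing") for r in reasons):
                reasons = ["missing_data"]
            label = "neither"
        out.append({"gene_id": row["gene_id"], "label": label, "reasons": ";".join(reasons)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cross-species differential expression
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors (genes x samples input)."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    usable = np.isfinite(log_mat).all(axis=1)
    if usable.sum() == 0:
        raise InputError("no gene has positive counts in every sample")
    log_ref = log_mat[usable].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_mat[usable] - log_ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _resolve_orthologs(
    orthologs: Mapping[str, str],
    genes_a: Sequence[str],
    genes_b: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep 1:1 pairs present in both matrices; log everything dropped."""
    pairs = pd.DataFrame(
        {"gene_a": list(orthologs.keys()), "gene_b": list(orthologs.values())}
    )
    dropped = []
    dup_a = pairs["gene_a"].duplicated(keep=False)
    dup_b = pairs["gene_b"].duplicated(keep=False)
    for _, row in pairs[dup_a | dup_b].iterrows():
        dropped.append((row["gene_a"], "not_one_to_one"))
    pairs = pairs[~(dup_a | dup_b)]
    missing = ~(pairs["gene_a"].isin(genes_a) & pairs["gene_b"].isin(genes_b))
    for _, row in pairs[missing].iterrows():
        dropped.append((row["gene_a"], "missing_from_counts"))
    pairs = pairs[~missing].reset_index(drop=True)
    return pairs, pd.DataFrame(dropped, columns=["gene_id", "reason"])


def _dispersion_estimates(
    norm_counts: np.ndarray, species_b: np.ndarray, trend_weight: float
) -> np.ndarray:
    """Per-gene NB dispersions: within-group moments shrunk to an a0+a1/mu trend."""
    groups = [~species_b, species_b]
    mu = np.stack([norm_counts[:, g].mean(axis=1) for g in groups])
    var = np.stack([norm_counts[:, g].var(axis=1, ddof=1) for g in groups])
    w = np.array([[g.sum() - 1] for g in groups], dtype=float)
    pooled_var = (var * w).sum(axis=0) / w.sum()
    mean_mu = mu.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        genewise = (pooled_var - mean_mu) / mean_mu**2
    ok = np.isfinite(genewise) & (genewise > 0) & (mean_mu > 0)
    # parametric trend alpha(mu) = a0 + a1/mu, least squares on usable genes
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_mu[ok]])
        coef, *_ = np.linalg.lstsq(X, genewise[ok], rcond=None)
        a0, a1 = max(coef[0], 1e-6), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.nanmedian(genewise[ok]) if ok.any() else 0.01, 1e-6), 0.0
    trend = a0 + a1 / np.maximum(mean_mu, 1e-8)
    gw = np.where(ok, np.maximum(genewise, 1e-8), trend)
    log_final = trend_weight * np.log(trend) + (1 - trend_weight) * np.log(gw)
    return np.clip(np.exp(log_final), 1e-8, 10.0)


def cross_species_de(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    orthologs: Mapping[str, str],
    lengths_a: Mapping[str, float],
    lengths_b: Mapping[str, float],
    trend_weight: float = 0.7,
    dispersions: np.ndarray | float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length-normalized NB Wald test of species effect per ortholog pair.

    Parameters
    ----------
    counts_a, counts_b
        Integer count matrices (genes x samples), one per species, >= 2
        samples each.
    orthologs
        Mapping species-A gene id -> species-B gene id; only 1:1 pairs are
        tested, the rest are dropped and logged.
    lengths_a, lengths_b
        Per-gene annotated transcript lengths (nt) in each species.
    trend_weight
        Weight of the mean-dispersion trend when shrinking gene-wise
        dispersion estimates (0 = pure gene-wise, 1 = pure trend).
    dispersions
        Optional per-gene (or scalar) NB dispersion override, e.g. from an
        external estimator; skips the internal moment/trend estimate.

    Returns
    -------
    (results, exclusions)
        ``results`` has one row per tested pair: ``gene_id, ortholog_id,
        base_mean, log2fc, lfc_se, p, padj``; ``exclusions`` logs dropped
        genes with reasons.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise InputError("need at least two samples per species")
    pairs, exclusions = _resolve_orthologs(orthologs, counts_a.index, counts_b.index)
    if pairs.empty:
        raise InputError("ortholog map is empty after 1:1 filtering")

    mat = np.hstack(
        [
            counts_a.loc[pairs["gene_a"]].to_numpy(dtype=float),
            counts_b.loc[pairs["gene_b"]].to_numpy(dtype=float),
        ]
    )
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    species_b = np.array([False] * n_a + [True] * n_b)

    all_zero = mat.sum(axis=1) == 0
    if all_zero.any():
        exclusions = pd.concat(
            [
                exclusions,
                pd.DataFrame(
                    {"gene_id": pairs.loc[all_zero, "gene_a"], "reason": "all_zero"}
                ),
            ],
            ignore_index=True,
        )
    keep = ~all_zero
    pairs = pairs[keep].reset_index(drop=True)
    mat = mat[keep]

    combined = pd.DataFrame(mat, index=pairs["gene_a"])
    size_factors = estimate_size_factors(combined).to_numpy()

    la = np.array([lengths_a[g] for g in pairs["gene_a"]], dtype=float)
    lb = np.array([lengths_b[g] for g in pairs["gene_b"]], dtype=float)
    if (la <= 0).any() or (lb <= 0).any():
        raise InputError("gene lengths must be positive")
    geo = np.sqrt(la * lb)
    length_factors = np.where(species_b[None, :], (lb / geo)[:, None], (la / geo)[:, None])
    norm_factors = size_factors[None, :] * length_factors  # genes x samples

    norm_counts = mat / norm_factors
    if dispersions is None:
        # dispersion describes replicate variability within a species, so it is
        # estimated on size-factor-normalized counts only: the per-gene length
        # factor is constant within a species and must not leak length
        # divergence into the dispersion (this also makes the estimate exactly
        # invariant to rescaling one species' annotation lengths)
        dispersions = _dispersion_estimates(mat / size_factors[None, :], species_b, trend_weight)
    else:
        dispersions = np.broadcast_to(np.asarray(dispersions, dtype=float), (mat.shape[0],)).copy()

    design = sm.add_constant((~species_b).astype(float))  # effect = species A
    log_nf = np.log(norm_factors)
    rows = []
    for i in range(mat.shape[0]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    mat[i],
                    design,
                    family=sm.families.NegativeBinomial(alpha=float(dispersions[i])),
                    offset=log_nf[i],
                )
                res = model.fit()
            lfc = res.params[1] / np.log(2)
            se = res.bse[1] / np.log(2)
            z = res.params[1] / res.bse[1]
        except Exception:
            lfc = se = z = np.nan
        rows.append((lfc, se, z))
    lfc_arr, se_arr, z_arr = map(np.array, zip(*rows))
    p_arr = np.where(np.isfinite(z_arr), 2 * sps.norm.sf(np.abs(z_arr)), np.nan)

    results = pd.DataFrame(
        {
            "gene_id": pairs["gene_a"],
            "ortholog_id": pairs["gene_b"],
            "base_mean": norm_counts.mean(axis=1),
            "log2fc": lfc_arr,
            "lfc_se": se_arr,
            "p": p_arr,
            "dispersion": dispersions,
        }
    )
    tested = results["p"].notna()
    results["padj"] = np.nan
    if tested.any():
        results.loc[tested, "padj"] = adjust_pvalues(results.loc[tested, "p"].to_numpy(), "bh_fdr")
    return results.reset_index(drop=True), exclusions


def volcano_classify(
    de: pd.DataFrame,
    fc_thresh: float = 0.5,
    padj_thresh: float = 10 ** -0.5,
) -> pd.DataFrame:
    """Flag each DE result significant-toward-A / -toward-B / ns.

    Both criteria are strict: ``|log2fc| > fc_thresh`` and ``padj <
    padj_thresh``.  The default adjusted-p threshold mirrors a volcano-plot
    rule of thumb of log10(padj) < -0.5 and is deliberately configurable.
    """
    out = de.copy()
    sig = (out["padj"] < padj_thresh) & (out["log2fc"].abs() > fc_thresh)
    out["volcano"] = np.where(
        sig & (out["log2fc"] > 0), "toward_a", np.where(sig, "toward_b", "ns")
    )
    return out


DP_BINS = [(25.0, 50.0), (50.0, 75.0), (75.0, 100.0)]


def bin_by_dP(
    dscores: Sequence[DScore],
    de: pd.DataFrame,
    labels: pd.DataFrame,
    fc_thresh: float = 0.5,
    padj_thresh: float = 10 ** -0.5,
) -> pd.DataFrame:
    """Expression-divergence fractions in promoter-score bins, germ vs soma.

    Genes are binned by d_P into (25, 50], (50, 75], (75, 100] (left-open, so
    a gene at exactly 25 falls in no bin).  Per bin and fold-change direction
    the fraction of germline and soma genes passing the volcano criterion is
    reported, with a chi-squared germ-vs-soma comparison per (bin, direction)
    and BH-FDR correction across all such tests.
    """
    dp = {d.id: d.value for d in dscores}
    flagged = volcano_classify(de, fc_thresh, padj_thresh)
    merged = flagged.merge(labels[["gene_id", "label"]], on="gene_id")
    merged = merged[merged["gene_id"].isin(dp)]
    merged["dP"] = merged["gene_id"].map(dp)

    rows = []
    for lo, hi in DP_BINS:
        in_bin = merged[(merged["dP"] > lo) & (merged["dP"] <= hi)]
        for direction in ("toward_a", "toward_b"):
            counts = {}
            for grp in ("germline", "soma"):
                sub = in_bin[in_bin["label"] == grp]
                k = int((sub["volcano"] == direction).sum())
                counts[grp] = (k, len(sub))
            (kg, ng), (ks, ns_) = counts["germline"], counts["soma"]
            if ng > 0 and ns_ > 0 and (kg + ks) > 0 and (ng - kg + ns_ - ks) > 0:
                chi2, p, _, _ = sps.chi2_contingency(
                    [[kg, ng - kg], [ks, ns_ - ks]], correction=False
                )
            else:
                chi2, p = np.nan, np.nan
            rows.append(
                {
                    "bin": f">{lo:g}-{hi:g}",
                    "direction": direction,
                    "germ_n": ng,
                    "germ_sig": kg,
                    "germ_frac": kg / ng if ng else np.nan,
                    "soma_n": ns_,
                    "soma_sig": ks,
                    "soma_frac": ks / ns_ if ns_ else np.nan,
                    "chi2": chi2,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = adjust_pvalues(out.loc[tested, "p_raw"].to_numpy(), "bh_fdr")
    return out
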