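"""Significance testing of hotspot percentages against controls.

The comparison is a Pearson chi-squared test (df=1, no continuity
correction) on the 2x2 table of promoter exceedance counts::

            exceed      non-exceed
    test    n_exceed    N - n_exceed
    control n_exceed_C  N_C - n_exceed_C

followed by Bonferroni (small fixed group panels) or Benjamini-Hochberg
(gene-level panels) correction at alpha = 0.05.  The correction method is an
explicit parameter, never inferred.

Note the test treats per-position exceedance indicators as exchangeable
counts; for unsmoothed scores (conservation tracks, window size 1) this is a
standard two-proportion test, while sliding-window smoothing induces serial
correlation between neighbouring indicators that makes the test
anticonservative near the null (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coords import DEFAULT_WINDOW, AnalysisWindow
from .events import DScore, SlidingScore
from .ingest import ConservationTrack, InputError

__all__ = [
    "GroupComparison",
    "chi2_vs_control",
    "adjust_pvalues",
    "compare_panel",
    "comparisons_to_frame",
    "panel_summary",
    "rank_panel",
    "build_heatmap",
]

CorrectionMethod = Literal["bonferroni", "bh_fdr"]


@dataclass
class GroupComparison:
    """Chi-squared contingency result for one gene/group against the control."""

    id: str
    table: np.ndarray  # 2x2: rows test/control, cols exceed/non-exceed
    chi2: float
    p_raw: float
    d_test: float
    d_control: float
    undefined: bool = False  # a margin was zero; p forced to 1
    p_adj: float = np.nan
    method: str = ""
    significant: bool = False

    @property
    def direction(self) -> str:
        if self.d_test > self.d_control:
            return "increased"
        if self.d_test < self.d_control:
            return "decreased"
        return "equal"


def chi2_vs_control(test: DScore, control: DScore) -> GroupComparison:
    """Pearson chi-squared (df=1, uncorrected) of exceedance counts vs control.

    A table with a zero margin leaves the test undefined; it is flagged and
    reported with chi2=0, p=1 rather than raising.
    """
    if test.mode != control.mode:
        raise InputError(f"{test.id}: cannot compare {test.mode} against {control.mode}")
    table = np.array(
        [
            [test.n_exceed, test.N - test.n_exceed],
            [control.n_exceed, control.N - control.n_exceed],
        ],
        dtype=np.int64,
    )
    if (table < 0).any():
        raise InputError(f"{test.id}: negative counts in contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return GroupComparison(test.id, table, 0.0, 1.0, test.value, control.value, undefined=True)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return GroupComparison(test.id, table, float(chi2), float(p), test.value, control.value)


def adjust_pvalues(pvalues: Sequence[float], method: CorrectionMethod) -> np.ndarray:
    """Multiple-testing correction: Bonferroni (min(1, m*p)) or BH step-up."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    sm_method = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}.get(method)
    if sm_method is None:
        raise InputError(f"unknown correction method {method!r}")
    return multipletests(p, method=sm_method)[1]


def compare_panel(
    tests: Sequence[DScore],
    control: DScore,
    method: CorrectionMethod,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Test every DScore against the control and correct across the panel."""
    comps = [chi2_vs_control(t, control) for t in tests]
    adj = adjust_pvalues([c.p_raw for c in comps], method)
    for c, pa in zip(comps, adj):
        c.p_adj = float(pa)
        c.method = method
        c.significant = bool(pa <= alpha) and not c.undefined
    return comps


def panel_summary(comparisons: Sequence[GroupComparison]) -> pd.Series:
    """Counts of significantly increased / decreased / unchanged genes."""
    inc = sum(c.significant and c.d_test > c.d_control for c in comparisons)
    dec = sum(c.significant and c.d_test < c.d_control for c in comparisons)
    n = len(comparisons)
    return pd.Series(
        {
            "n": n,
            "increased": inc,
            "decreased": dec,
            "unchanged": n - inc - dec,
            "pct_increased": 100.0 * inc / n if n else np.nan,
            "pct_decreased": 100.0 * dec / n if n else np.nan,
        }
    )


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "id": c.id,
                "d": c.d_test,
                "n_exceed": int(c.table[0, 0]),
                "N": int(c.table[0].sum()),
                "d_control": c.d_control,
                "chi2": c.chi2,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "method": c.method,
                "significant": c.significant,
                "direction": c.direction,
                "undefined_test": c.undefined,
            }
        )
    return pd.DataFrame(rows)


def rank_panel(
    dscores: Sequence[DScore],
    key: Literal["dP_desc", "value_desc"] = "dP_desc",
) -> list[str]:
    """Order gene ids by d value, descending, gene id as the stable tie-break."""
    if key not in {"dP_desc", "value_desc"}:
        raise InputError(f"unknown ordering key {key!r}")
    return [d.id for d in sorted(dscores, key=lambda d: (-d.value, d.id))]


def build_heatmap(
    tracks: Sequence[SlidingScore | ConservationTrack],
    order: Sequence[str] | None = None,
    window: "AnalysisWindow | None" = None,
) -> pd.DataFrame:
    """Genes x positions matrix for heatmap rendering.

    Rows are Se tracks (alignment mode) or raw per-nucleotide conservation
    scores (conservation mode); columns are signed TSS offsets.  ``order``
    selects and orders rows by gene id (e.g. from :func:`rank_panel`).
    """
    if not tracks:
        raise InputError("no tracks to assemble")
    first = tracks[0]
    if isinstance(first, ConservationTrack):
        win = window or DEFAULT_WINDOW
        length = len(first.scores)
        if length != win.length:
            raise InputError("conservation tracks do not match the window length")
        data = {t.gene_id: t.scores for t in tracks}  # type: ignore[union-attr]
        offsets = win.offsets()
    else:
        length = first.window.length
        offsets = first.window.offsets()
        data = {t.gene_id: t.values for t in tracks}  # type: ignore[union-attr]
    if any(len(v) != length for v in data.values()):
        raise InputError("tracks must share one window")
    ids = list(data) if order is None else list(order)
    matrix = pd.DataFrame([data[g] for g in ids], index=ids, columns=offsets)
    matrix.index.name = "gene_id"
    return matrix
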