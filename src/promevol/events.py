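"""Per-nucleotide change events, sliding event scores and hotspot percentages.

This is the core statistic of the package.  A windowed multi-species
alignment is translated, per non-reference species and reference position,
into a binary *event* (0 = conserved, 1 = changed) classified as a base
change or an indel.  Event sums are smoothed with a 5-base sliding window
into the sliding event score ``Se``, and the hotspot percentage ``d`` is the
share of promoter-window positions whose ``Se`` strictly exceeds the control
group's average (``Se_C``).  The conservation-track analogue ``d_P`` counts
promoter positions whose per-base conservation score falls strictly below
the control average.

Event conventions (per species, per reference offset):

* a mismatched base is a ``base_change``;
* a species gap at a reference base is an ``indel`` (each deleted reference
  base is one event);
* an insertion run in the species (gap in the reference) is a single
  ``indel`` event at the offset of its 5'-anchoring reference base;
* comparisons are case-insensitive; an ambiguity/masked symbol (e.g. N)
  against a different symbol counts as a base change, against the same
  symbol as conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .coords import DEFAULT_WINDOW, AnalysisWindow
from .ingest import GAP, ConservationTrack, CoverageError, InputError, ReferenceAnchoredAlignment

__all__ = [
    "EVENT_NONE",
    "EVENT_BASE_CHANGE",
    "EVENT_INDEL",
    "EventTrack",
    "SummedEventTrack",
    "SlidingScore",
    "DScore",
    "call_events",
    "sum_events",
    "concatenate_group",
    "sliding_score",
    "control_baseline",
    "d_score",
    "d_score_conservation",
]

EVENT_NONE = 0
EVENT_BASE_CHANGE = 1
EVENT_INDEL = 2

ClassFilter = Literal["all", "base_change", "indel"]


@dataclass
class EventTrack:
    """Window-length x species matrix of event classes for one gene.

    ``classes[i, s]`` holds the event class of non-reference species ``s`` at
    window position ``i`` (codes: 0 none, 1 base change, 2 indel).
    """

    gene_id: str
    species: tuple[str, ...]  # non-reference species
    classes: np.ndarray
    window: AnalysisWindow

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.classes.shape != (self.window.length, len(self.species)):
            raise InputError("event matrix shape must be (window length, n species - 1)")

    @property
    def events(self) -> np.ndarray:
        """Binary event indicator (any class)."""
        return (self.classes != EVENT_NONE).astype(np.int8)


@dataclass
class SummedEventTrack:
    """Per-position event counts summed over species (and optionally genes)."""

    gene_id: str
    sums: np.ndarray
    window: AnalysisWindow
    class_filter: ClassFilter = "all"
    n_genes: int = 1

    def __post_init__(self) -> None:
        self.sums = np.asarray(self.sums, dtype=float)
        if self.sums.shape != (self.window.length,):
            raise InputError("sums length must equal window length")


@dataclass
class SlidingScore:
    """Sliding event score Se: smoothed event sums, defined at every position."""

    gene_id: str
    values: np.ndarray
    window: AnalysisWindow
    window_size: int = 5
    class_filter: ClassFilter = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.window.length,):
            raise InputError("Se length must equal window length")


@dataclass
class DScore:
    """Hotspot percentage for one gene or group.

    ``value = 100 * n_exceed / N`` where ``n_exceed`` counts promoter-window
    positions whose score passes the strict comparison against ``baseline``
    and ``N`` is the number of scored promoter positions.
    """

    id: str
    value: float
    n_exceed: int
    N: int
    baseline: float
    mode: Literal["alignment_d", "conservation_dP"]
    class_filter: ClassFilter = "all"


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------


def call_events(aln: ReferenceAnchoredAlignment, window: AnalysisWindow = DEFAULT_WINDOW) -> EventTrack:
    """Translate a windowed, anchored alignment into per-species event classes."""
    cols = np.char.upper(aln.columns)
    ref = cols[:, 0]
    ins = ref == GAP
    offs = aln.ref_offset

    idx = np.fromiter(
        (window.offset_to_index(int(o)) for o in offs), count=len(offs), dtype=np.int64
    )
    n_sp = len(aln.species) - 1
    classes = np.zeros((window.length, n_sp), dtype=np.int8)

    for s in range(n_sp):
        sp_col = cols[:, s + 1]
        # reference-base columns
        base_cols = ~ins
        bi = idx[base_cols]
        ref_b = ref[base_cols]
        sp_b = sp_col[base_cols]
        cls = np.zeros(len(bi), dtype=np.int8)
        cls[sp_b != ref_b] = EVENT_BASE_CHANGE
        cls[sp_b == GAP] = EVENT_INDEL
        classes[bi, s] = cls
        # insertion columns: one indel at the anchor, regardless of run length
        ins_here = ins & (sp_col != GAP)
        if ins_here.any():
            classes[idx[ins_here], s] = EVENT_INDEL
    return EventTrack(aln.gene_id, tuple(aln.species[1:]), classes, window)


def _class_mask(classes: np.ndarray, class_filter: ClassFilter) -> np.ndarray:
    if class_filter == "all":
        return classes != EVENT_NONE
    if class_filter == "base_change":
        return classes == EVENT_BASE_CHANGE
    if class_filter == "indel":
        return classes == EVENT_INDEL
    raise InputError(f"unknown class filter {class_filter!r}")


def sum_events(track: EventTrack, class_filter: ClassFilter = "all") -> SummedEventTrack:
    """Sum events matching *class_filter* over species at each position."""
    sums = _class_mask(track.classes, class_filter).sum(axis=1)
    return SummedEventTrack(track.gene_id, sums, track.window, class_filter)


def concatenate_group(
    tracks: Sequence[SummedEventTrack],
    group_id: str = "group",
    average: bool = False,
) -> SummedEventTrack:
    """Combine genes into a group-level per-position event track.

    By default positions are summed across genes (the concatenated-group
    convention); with ``average=True`` the sum is divided by the gene count,
    putting groups of different sizes on a common per-gene scale.
    """
    if len(tracks) == 0:
        raise InputError("cannot concatenate an empty gene group")
    window = tracks[0].window
    filt = tracks[0].class_filter
    if any(t.window != window or t.class_filter != filt for t in tracks):
        raise InputError("group tracks must share window and class filter")
    total = np.sum([t.sums for t in tracks], axis=0)
    if average:
        total = total / len(tracks)
    return SummedEventTrack(group_id, total, window, filt, n_genes=len(tracks))


def sliding_score(track: SummedEventTrack, window_size: int = 5) -> SlidingScore:
    """Smooth event sums with a centered mean of *window_size* positions.

    The window is truncated at the sequence ends (mean over the available
    positions), so Se is defined at every position of the analysis window.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise InputError("window_size must be odd and >= 1")
    kernel = np.ones(window_size)
    num = np.convolve(track.sums, kernel, mode="same")
    den = np.convolve(np.ones_like(track.sums), kernel, mode="same")
    return SlidingScore(track.gene_id, num / den, track.window, window_size, track.class_filter)


# ---------------------------------------------------------------------------
# Baselines and d scores
# ---------------------------------------------------------------------------


def control_baseline(
    control: Iterable[SlidingScore | ConservationTrack],
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> float:
    """Pooled mean of control values over all promoter-window positions.

    Accepts Se tracks (baseline ``Se_C``) or conservation tracks (baseline
    ``p_C``, e.g. the genome average over all gene promoters); all values from
    all control genes are pooled before averaging.
    """
    mask = window.promoter_mask()
    pooled: list[np.ndarray] = []
    for item in control:
        if isinstance(item, ConservationTrack):
            vals = item.scores[mask]
            vals = vals[~np.isnan(vals)]
        else:
            vals = item.values[mask]
        pooled.append(vals)
    if not pooled or sum(len(v) for v in pooled) == 0:
        raise InputError("control baseline needs at least one scored control gene")
    return float(np.concatenate(pooled).mean())


def d_score(
    score: SlidingScore,
    baseline: float,
    window: AnalysisWindow | None = None,
) -> DScore:
    """Hotspot percentage d: promoter positions with Se strictly > baseline."""
    window = window or score.window
    mask = window.promoter_mask()
    n = int(mask.sum())
    if n == 0:
        raise InputError("promoter window contains no positions")
    n_exceed = int((score.values[mask] > baseline).sum())
    return DScore(
        score.gene_id, 100.0 * n_exceed / n, n_exceed, n, baseline,
        "alignment_d", score.class_filter,
    )


def d_score_conservation(
    track: ConservationTrack,
    baseline: float,
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> DScore:
    """Conservation analogue d_P: promoter scores strictly < baseline.

    Requires full score coverage of the promoter window; genes with gaps in
    coverage are expected to have been removed upstream.
    """
    mask = window.promoter_mask()
    vals = track.scores[mask]
    if np.isnan(vals).any() or not track.coverage[mask].all():
        raise CoverageError(f"{track.gene_id}: promoter window not fully covered")
    n = len(vals)
    if n == 0:
        raise InputError("promoter window contains no positions")
    n_exceed = int((vals < baseline).sum())
    return DScore(track.gene_id, 100.0 * n_exceed / n, n_exceed, n, baseline, "conservation_dP")
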