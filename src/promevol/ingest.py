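"""Input parsing, reference anchoring, window trimming and gene-set filters.

Reads the interchange formats the pipeline consumes: per-gene aligned FASTA
(one record per species, reference species first), BED6/GTF gene annotations,
bedGraph or fixedStep-wiggle conservation tracks, and TSV group lists.  All
sequences and tracks are re-oriented to the gene's direction of transcription
here, so downstream modules are strand-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import DEFAULT_WINDOW, AnalysisWindow

__all__ = [
    "FormatError",
    "InputError",
    "CoverageError",
    "GeneAnnotation",
    "ReferenceAnchoredAlignment",
    "ConservationTrack",
    "alignment_from_strings",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "extract_window",
    "read_bed6",
    "read_gtf",
    "read_conservation_track",
    "read_group_lists",
    "filter_gene_set",
    "GAP",
]

GAP = "-"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class InputError(ValueError):
    """Inputs are structurally valid but violate a pipeline precondition."""


class CoverageError(InputError):
    """A gene lacks the sequence or score coverage the analysis requires."""


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS anchor: chromosome, 1-based TSS coordinate and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise InputError(f"{self.gene_id}: tss must be >= 1")
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")

    def genomic_position(self, offset: int) -> int:
        """1-based genomic coordinate of a signed TSS offset (gene oriented)."""
        if offset == 0:
            raise ValueError("offset 0 does not exist")
        if self.strand == "+":
            return self.tss + offset - (1 if offset > 0 else 0)
        return self.tss - offset + (1 if offset > 0 else 0)


def _check_unique(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"duplicate gene_id {g.gene_id!r} in annotation set")
        seen.add(g.gene_id)
    return list(genes)


def read_bed6(path: str | Path) -> list[GeneAnnotation]:
    """Read BED6 where each interval's 5' end (strand-aware) is the TSS."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise FormatError(f"{path}:{ln}: BED6 needs 6 columns")
        chrom, start, end, name, _score, strand = parts[:6]
        start_i, end_i = int(start), int(end)
        tss = start_i + 1 if strand == "+" else end_i  # BED is 0-based half-open
        out.append(GeneAnnotation(name, chrom, tss, strand))
    return _check_unique(out)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path, feature: str = "transcript") -> list[GeneAnnotation]:
    """Read GTF, one annotation per *feature* row (default: transcript)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}:{ln}: GTF needs 9 columns")
        chrom, _src, feat, start, end, _score, strand, _frame, attrs = parts
        if feat != feature:
            continue
        attr = dict(_GTF_ATTR.findall(attrs))
        gene_id = attr.get("gene_id")
        if gene_id is None:
            raise FormatError(f"{path}:{ln}: missing gene_id attribute")
        tss = int(start) if strand == "+" else int(end)
        out.append(GeneAnnotation(gene_id, chrom, tss, strand, attr.get("transcript_id", "")))
    return _check_unique(out)


# ---------------------------------------------------------------------------
# Reference-anchored alignments
# ---------------------------------------------------------------------------


@dataclass
class ReferenceAnchoredAlignment:
    """Multi-species alignment with each column mapped to a TSS offset.

    ``columns`` is a ``(n_columns, n_species)`` array of single characters
    (first species = reference); ``ref_offset[i]`` is the signed TSS offset of
    column ``i``'s reference base.  Columns where the reference has a gap are
    insertion columns and carry the offset of the nearest 5' reference base
    (leading insertions fall back to the first reference base's offset).
    """

    gene_id: str
    species: tuple[str, ...]
    columns: np.ndarray
    ref_offset: np.ndarray

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype="<U1")
        self.ref_offset = np.asarray(self.ref_offset, dtype=np.int64)
        if self.columns.ndim != 2 or self.columns.shape[0] != self.ref_offset.shape[0]:
            raise InputError("columns and ref_offset shapes disagree")
        if len(self.species) != self.columns.shape[1]:
            raise InputError("species count does not match columns")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[0]

    @property
    def reference(self) -> str:
        return self.species[0]

    @property
    def is_insertion(self) -> np.ndarray:
        """Boolean per column: reference has a gap (insertion column)."""
        return self.columns[:, 0] == GAP

    @property
    def reference_offsets(self) -> np.ndarray:
        """Offsets of the reference bases (non-insertion columns), 5'->3'."""
        return self.ref_offset[~self.is_insertion]

    def sequences(self) -> dict[str, str]:
        """Aligned sequences, species name -> gapped string."""
        return {sp: "".join(self.columns[:, j]) for j, sp in enumerate(self.species)}


def _anchor_offsets(ref_row: np.ndarray, tss_index: int) -> np.ndarray:
    """Assign signed TSS offsets to every alignment column.

    ``tss_index`` is the 0-based index of the TSS base within the *ungapped*
    reference; reference base r maps to offset r - tss_index (r < tss_index)
    or r - tss_index + 1 (r >= tss_index), so there is no offset 0.
    """
    is_base = ref_row != GAP
    n_ref = int(is_base.sum())
    if n_ref == 0:
        raise InputError("reference row is all gaps")
    rank = np.cumsum(is_base) - 1  # ungapped ref index of each base column
    # insertion columns inherit the rank of the nearest 5' base; leading
    # insertions (rank -1) are clamped to the first base
    anchor = np.where(is_base, rank, np.maximum(rank, 0))
    return np.where(anchor < tss_index, anchor - tss_index, anchor - tss_index + 1)


def alignment_from_strings(
    gene_id: str,
    species: Sequence[str],
    sequences: Mapping[str, str],
    tss_index: int = 1000,
) -> ReferenceAnchoredAlignment:
    """Build an anchored alignment from aligned strings (reference first)."""
    missing = [sp for sp in species if sp not in sequences]
    if missing:
        raise InputError(f"missing species {missing}")
    seqs = {sp: sequences[sp].upper().replace(".", GAP) for sp in species}
    if len({len(s) for s in seqs.values()}) != 1:
        raise FormatError("ragged alignment")
    cols = np.array([list(seqs[sp]) for sp in species], dtype="<U1").T
    return ReferenceAnchoredAlignment(
        gene_id, tuple(species), cols, _anchor_offsets(cols[:, 0], tss_index)
    )


def read_alignment_fasta(
    path: str | Path,
    species_order: Sequence[str],
    gene_id: str | None = None,
    tss_index: int = 1000,
) -> ReferenceAnchoredAlignment:
    """Read one gene's aligned FASTA (record id = species name).

    The input must already be TSS-oriented (5'->3' of the gene).  ``tss_index``
    locates the TSS base inside the ungapped reference sequence (0-based); the
    default matches alignments spanning -1000/+300.
    """
    path = Path(path)
    records = {rec.id: str(rec.seq).upper().replace(".", GAP) for rec in SeqIO.parse(str(path), "fasta")}
    missing = [sp for sp in species_order if sp not in records]
    if missing:
        raise InputError(f"{path}: missing species {missing}")
    lengths = {len(records[sp]) for sp in species_order}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    cols = np.array([list(records[sp]) for sp in species_order], dtype="<U1").T
    offsets = _anchor_offsets(cols[:, 0], tss_index)
    return ReferenceAnchoredAlignment(
        gene_id or path.stem, tuple(species_order), cols, offsets
    )


def write_alignment_fasta(aln: ReferenceAnchoredAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sp, description="")
        for sp, seq in aln.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def orient_sequences(seqs: Mapping[str, str], strand: str) -> dict[str, str]:
    """Reverse-complement genomic-orientation alignments of minus-strand genes."""
    if strand == "+":
        return dict(seqs)
    return {sp: str(Seq(s).reverse_complement()) for sp, s in seqs.items()}


def extract_window(
    aln: ReferenceAnchoredAlignment, window: AnalysisWindow = DEFAULT_WINDOW
) -> ReferenceAnchoredAlignment:
    """Trim an anchored alignment to the analysis window.

    Columns (insertions included, via their anchor offset) outside the window
    are dropped.  Raises :class:`CoverageError` if the reference does not
    cover every window offset — such genes are flagged for removal upstream.
    """
    keep = (aln.ref_offset >= -window.upstream) & (aln.ref_offset <= window.downstream)
    trimmed = ReferenceAnchoredAlignment(
        aln.gene_id, aln.species, aln.columns[keep], aln.ref_offset[keep]
    )
    covered = set(trimmed.reference_offsets.tolist())
    wanted = set(window.offsets().tolist())
    if not wanted <= covered:
        lo, hi = min(wanted - covered), max(wanted - covered)
        raise CoverageError(
            f"{aln.gene_id}: window not covered (missing offsets {lo}..{hi})"
        )
    return trimmed


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------


@dataclass
class ConservationTrack:
    """Per-offset conservation scores over the analysis window (gene oriented).

    ``scores`` has one value per window position (NaN where the track has no
    data); ``coverage`` marks positions with a defined score.
    """

    gene_id: str
    scores: np.ndarray
    coverage: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.coverage is None:
            self.coverage = ~np.isnan(self.scores)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.scores.shape != self.coverage.shape or self.scores.ndim != 1:
            raise InputError("scores and coverage must be 1-D and equal length")

    @property
    def full_coverage(self) -> bool:
        return bool(self.coverage.all())


def _parse_track_lines(lines: Iterable[str], path: str) -> dict[tuple[str, int], float]:
    """Parse bedGraph and/or fixedStep wiggle into {(chrom, 1-based pos): score}."""
    values: dict[tuple[str, int], float] = {}
    chrom = ""
    pos = step = 0
    mode = None  # None until first data line; 'fixed' inside a fixedStep block
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(f.split("=", 1) for f in line.split()[1:])
            try:
                chrom, pos, step = kv["chrom"], int(kv["start"]), int(kv.get("step", 1))
            except KeyError as exc:
                raise FormatError(f"{path}:{ln}: fixedStep missing {exc}") from exc
            mode = "fixed"
            continue
        if line.startswith("variableStep"):
            raise FormatError(f"{path}:{ln}: variableStep wiggle is not supported")
        fields = line.split()
        if mode == "fixed" and len(fields) == 1:
            values[(chrom, pos)] = float(fields[0])
            pos += step
        elif len(fields) == 4:
            c, start, end, val = fields  # bedGraph: 0-based half-open
            for p in range(int(start) + 1, int(end) + 1):
                values[(c, p)] = float(val)
            mode = None
        else:
            raise FormatError(f"{path}:{ln}: unrecognised track line {line!r}")
    return values


def read_conservation_track(
    path: str | Path,
    ann: GeneAnnotation,
    window: AnalysisWindow = DEFAULT_WINDOW,
) -> ConservationTrack:
    """Extract a gene's window from a bedGraph/fixedStep conservation track.

    Scores come out in gene orientation (reversed relative to genomic order
    for minus-strand genes); positions absent from the track get NaN with
    ``coverage`` False.
    """
    values = _parse_track_lines(Path(path).read_text().splitlines(), str(path))
    scores = np.full(window.length, np.nan)
    for i, off in enumerate(window.offsets()):
        scores[i] = values.get((ann.chrom, ann.genomic_position(int(off))), np.nan)
    return ConservationTrack(ann.gene_id, scores)


# ---------------------------------------------------------------------------
# Group lists and coverage filters
# ---------------------------------------------------------------------------


def read_group_lists(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV (gene_id, group) into group -> gene list."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need columns gene_id, group")
    gcol, grpcol = df.columns[:2]
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row[grpcol], []).append(row[gcol])
    return groups


def filter_gene_set(
    genes: Iterable[str],
    required_species: Sequence[str] | None = None,
    species_presence: Mapping[str, Iterable[str]] | None = None,
    conservation_tracks: Mapping[str, ConservationTrack] | None = None,
    group_memberships: Mapping[str, Iterable[str]] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the removal rules relevant to an analysis mode.

    Three independent filters, each active only when its inputs are given:
    species coverage (a gene is removed if any required species contributed no
    sequence), conservation coverage (removed if any window position has a
    score from the reference only, i.e. incomplete track coverage), and unique
    group membership (removed from a direct comparison when listed in more
    than one group).  Returns the retained genes (sorted, so the result does
    not depend on input order) and an exclusion log with one reason per drop.
    """
    exclusions: list[tuple[str, str]] = []
    retained = []
    for gene in sorted(set(genes)):
        reason = None
        if species_presence is not None and required_species is not None:
            present = set(species_presence.get(gene, ()))
            if not set(required_species) <= present:
                reason = "species_coverage"
        if reason is None and conservation_tracks is not None:
            track = conservation_tracks.get(gene)
            if track is None or not track.full_coverage:
                reason = "conservation_coverage"
        if reason is None and group_memberships is not None:
            if len(set(group_memberships.get(gene, ()))) > 1:
                reason = "multiple_group_membership"
        if reason is None:
            retained.append(gene)
        else:
            exclusions.append((gene, reason))
    log = pd.DataFrame(exclusions, columns=["gene_id", "reason"])
    return retained, log
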