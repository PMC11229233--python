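"""TSS-anchored coordinate conventions shared by every analysis stage.

All positions are signed offsets from the transcription start site in the
orientation of transcription: the TSS base itself is ``+1``, the base
immediately 5' of it is ``-1`` and there is **no offset 0**.  Internally the
window is a dense 0-based array of ``upstream + downstream`` positions; the
conversion between the two conventions lives here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnalysisWindow", "DEFAULT_WINDOW"]


@dataclass(frozen=True)
class AnalysisWindow:
    """Analysis window around a TSS, plus the promoter sub-interval.

    Parameters
    ----------
    upstream, downstream
        Number of bases kept 5' and 3' of the TSS (defaults 1000/300, i.e.
        offsets ``-1000 .. -1, +1 .. +300``).
    promoter_start, promoter_end
        Signed offsets bounding the promoter interval used for the hotspot
        percentage (inclusive; defaults ``-380 .. -31``, the 350-nt region
        upstream of the canonical TATA position at ``-30``).
    """

    upstream: int = 1000
    downstream: int = 300
    promoter_start: int = -380
    promoter_end: int = -31

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0 or self.upstream + self.downstream < 1:
            raise ValueError("window must contain at least one position")
        for name in ("promoter_start", "promoter_end"):
            if getattr(self, name) == 0:
                raise ValueError("offset 0 does not exist (TSS base is +1)")
        if self.promoter_start > self.promoter_end:
            raise ValueError("promoter_start must be 5' of promoter_end")
        if self.promoter_start < -self.upstream or self.promoter_end > self.downstream:
            raise ValueError("promoter interval must lie inside the analysis window")

    # -- conversions ---------------------------------------------------------

    @property
    def length(self) -> int:
        return self.upstream + self.downstream

    def offset_to_index(self, offset: int) -> int:
        """Signed TSS offset -> dense 0-based array index."""
        if offset == 0:
            raise ValueError("offset 0 does not exist")
        if offset < 0:
            idx = offset + self.upstream
        else:
            idx = self.upstream + offset - 1
        if not 0 <= idx < self.length:
            raise ValueError(f"offset {offset} outside window [-{self.upstream}, +{self.downstream}]")
        return idx

    def index_to_offset(self, index: int) -> int:
        if not 0 <= index < self.length:
            raise IndexError(index)
        return index - self.upstream if index < self.upstream else index - self.upstream + 1

    def offsets(self) -> np.ndarray:
        """All signed offsets of the window, 5' to 3'."""
        neg = np.arange(-self.upstream, 0)
        pos = np.arange(1, self.downstream + 1)
        return np.concatenate([neg, pos])

    def contains_offset(self, offset: int) -> bool:
        return offset != 0 and -self.upstream <= offset <= self.downstream

    # -- promoter sub-window -------------------------------------------------

    @property
    def promoter_size(self) -> int:
        return int(self.promoter_mask().sum())

    def promoter_mask(self) -> np.ndarray:
        """Boolean mask over the dense window marking promoter positions."""
        off = self.offsets()
        return (off >= self.promoter_start) & (off <= self.promoter_end)


#: The default window used throughout: 1000 nt upstream, 300 nt downstream,
#: promoter interval -380..-31 (350 positions).
DEFAULT_WINDOW = AnalysisWindow()
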