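"""Fixed-width genome binning.

All coordinates are 0-based, half-open. Each chromosome is tiled with
consecutive ``bin_width`` bins starting at 0; a trailing partial bin is
dropped, so the binned length of a chromosome is
``(length // bin_width) * bin_width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeBins"]


@dataclass(frozen=True)
class GenomeBins:
    """Immutable description of a fixed-width binning of a genome.

    Parameters
    ----------
    chrom_names
        Chromosome names, in the canonical order used for global indexing.
    chrom_lengths
        Chromosome lengths in bases, parallel to ``chrom_names``.
    bin_width
        Bin width in bases (200 by default, the resolution used for
        chromatin-state segmentation).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_width: int = 200
    _offsets: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length < self.bin_width:
                raise ValueError(
                    f"chromosome {name!r} shorter than one bin ({length} < {self.bin_width})"
                )
        counts = [length // self.bin_width for length in self.chrom_lengths]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        object.__setattr__(self, "_offsets", tuple(int(o) for o in offsets))

    @classmethod
    def from_dict(cls, chrom_sizes: dict[str, int], bin_width: int = 200) -> "GenomeBins":
        return cls(tuple(chrom_sizes), tuple(chrom_sizes.values()), bin_width)

    # ------------------------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_names)

    @property
    def total_bins(self) -> int:
        return self._offsets[-1]

    def n_bins(self, chrom: str) -> int:
        i = self._chrom_index(chrom)
        return self._offsets[i + 1] - self._offsets[i]

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self._chrom_index(chrom)]

    def binned_length(self, chrom: str) -> int:
        """Length in bases covered by complete bins on ``chrom``."""
        return self.n_bins(chrom) * self.bin_width

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin array belonging to ``chrom``."""
        i = self._chrom_index(chrom)
        return slice(self._offsets[i], self._offsets[i + 1])

    def _chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    # ------------------------------------------------------------------
    def global_index(self, chrom: str, start: int) -> int:
        """Global bin index of the bin whose start coordinate is ``start``."""
        if start % self.bin_width != 0:
            raise ValueError(f"{start} is not a bin start (bin_width={self.bin_width})")
        local = start // self.bin_width
        if not 0 <= local < self.n_bins(chrom):
            raise ValueError(f"bin start {start} out of range for {chrom}")
        return self._offsets[self._chrom_index(chrom)] + local

    def bin_location(self, index: int) -> tuple[str, int]:
        """Inverse of :meth:`global_index`: ``(chrom, start)`` of a global bin."""
        if not 0 <= index < self.total_bins:
            raise IndexError(f"global bin index {index} out of range")
        chrom_idx = int(np.searchsorted(self._offsets, index, side="right")) - 1
        local = index - self._offsets[chrom_idx]
        return self.chrom_names[chrom_idx], local * self.bin_width

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def overlapping_bins(self, chrom: str, start: float, end: float) -> tuple[int, int]:
        """Local ``[first, last)`` bin-index range overlapping ``[start, end)``.

        The range is clipped to the binned extent of the chromosome and may
        be empty (``first >= last``).
        """
        n = self.n_bins(chrom)
        first = max(0, int(np.floor(start / self.bin_width)))
        last = min(n, int(np.ceil(end / self.bin_width)))
        return first, max(first, last)
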