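"""Genome layouts and bin grids.

The package never needs real reference sequence: every operation works on
coordinates alone. A :class:`GenomeLayout` is an ordered mapping of
chromosome name to length in bp. Two miniature two-chromosome "toy" layouts
(30 Mb + 20 Mb) are the default coordinate systems for synthetic data, so
that binning and segmentation remain desk-scale while exercising exactly the
same code paths as full genomes would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError

__all__ = ["GenomeLayout", "HUMAN_TOY", "MOUSE_TOY"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length (bp) table."""

    name: str
    chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r} in layout {self.name}") from None

    def bins(self, width: int) -> pd.DataFrame:
        """Tile every chromosome with half-open bins of the given width.

        The trailing bin of each chromosome is truncated at the chromosome
        end. Returns columns ``chromosome, start, end``.
        """
        if width <= 0:
            raise ValueError("bin width must be positive")
        frames = []
        for chrom, length in self.chromosomes.items():
            starts = np.arange(0, length, width, dtype=np.int64)
            ends = np.minimum(starts + width, length)
            frames.append(pd.DataFrame({"chromosome": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)


#: Default synthetic coordinate system standing in for the human reference.
HUMAN_TOY = GenomeLayout("human_toy", {"hchr1": 30_000_000, "hchr2": 20_000_000})

#: Default synthetic coordinate system standing in for the mouse reference.
MOUSE_TOY = GenomeLayout("mouse_toy", {"mchr1": 30_000_000, "mchr2": 20_000_000})
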