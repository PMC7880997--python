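"""Genome binning model.

Coordinates are 0-based, half-open (BED convention) throughout the package.
Bin ``k`` of a chromosome covers ``[k*resolution, (k+1)*resolution)``; a
trailing partial bin is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names, lengths (bp) and a common bin resolution (bp).

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp.
    resolution
        Bin width in bp. The default of 2000 matches the working resolution
        of the contact-domain analysis this package implements.
    """

    chromosomes: dict[str, int] = field(default_factory=dict)
    resolution: int = 2000

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` (last partial bin counts)."""
        length = self.chromosomes[chrom]
        return -(-length // self.resolution)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index containing position ``pos`` (half-open bins)."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chromosomes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chromosomes[chrom]})")
        return pos // self.resolution

    def bin_start(self, k: int) -> int:
        return k * self.resolution

    def bin_center(self, k: int) -> float:
        return (k + 0.5) * self.resolution
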