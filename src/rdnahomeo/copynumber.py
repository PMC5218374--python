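"""rDNA genome proportion and 1C copy-number estimation.

Genome proportion (GP) is the fraction of sequencing reads mapping to the
rDNA reference, as a percentage.  The 1C copy number follows

    copies_1C = genome_size_bp * (GP / 100) / unit_length

with the genome sizes used in the source system supplied as defaults
(B. napus 1182 Mb, B. oleracea 630 Mb, B. rapa 530 Mb).  GP covers the
transcribed unit only; an optional multiplicative factor exposes the ~60%
uplift expected when intergenic spacers are counted as part of the repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GENOME_SIZES_MB",
    "CopyNumberEstimate",
    "genome_proportion",
    "copies_per_1C",
]

GENOME_SIZES_MB = {
    "B. napus": 1182.0,
    "B. oleracea": 630.0,
    "B. rapa": 530.0,
}


def genome_proportion(mapped_reads: int, total_reads: int) -> float:
    """Mapped/total read percentage, unrounded; present to 2 decimals."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= mapped_reads <= total_reads:
        raise ValueError("mapped_reads must lie in [0, total_reads]")
    return 100.0 * mapped_reads / total_reads


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def copies_per_1C(
    genome_size_mb: float,
    genome_proportion_pct: float,
    unit_length_bp: float,
    igs_factor: float = 1.0,
) -> tuple[float, int]:
    """(real, nearest-integer) rDNA copies per 1C genome."""
    if genome_size_mb <= 0 or unit_length_bp <= 0 or igs_factor <= 0:
        raise ValueError("genome size, unit length and igs_factor must be positive")
    if genome_proportion_pct < 0:
        raise ValueError("genome proportion must be non-negative")
    copies = (genome_size_mb * 1e6 * (genome_proportion_pct / 100.0) * igs_factor
              / unit_length_bp)
    return copies, _round_half_away(copies)


@dataclass
class CopyNumberEstimate:
    mapped_reads: int
    total_reads: int
    genome_size_mb: float
    unit_length_bp: float
    igs_factor: float = 1.0

    @property
    def genome_proportion_pct(self) -> float:
        return genome_proportion(self.mapped_reads, self.total_reads)

    @property
    def rdna_mass_mb(self) -> float:
        return self.genome_size_mb * self.genome_proportion_pct / 100.0 * self.igs_factor

    @property
    def copies_1c(self) -> float:
        return copies_per_1C(self.genome_size_mb, self.genome_proportion_pct,
                             self.unit_length_bp, self.igs_factor)[0]

    @property
    def copies_1c_int(self) -> int:
        return copies_per_1C(self.genome_size_mb, self.genome_proportion_pct,
                             self.unit_length_bp, self.igs_factor)[1]

    def as_dict(self) -> dict:
        return {
            "mapped_reads": self.mapped_reads,
            "total_reads": self.total_reads,
            "genome_proportion_pct": round(self.genome_proportion_pct, 2),
            "genome_size_mb": self.genome_size_mb,
            "unit_length_bp": self.unit_length_bp,
            "rdna_mass_mb": round(self.rdna_mass_mb, 2),
            "copies_1C": self.copies_1c,
            "copies_1C_int": self.copies_1c_int,
        }
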