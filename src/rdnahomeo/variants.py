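"""Intragenomic variant calling, frequency classes, window profiles,
consensus divergence and amplicon haplotype clustering.

The probabilistic component of the original workbench caller is replaced by
the explicit gates it reports: minimum coverage 100, minimum supporting
count 10, frequency >= 5%; variants at >= 20% frequency form the "high"
class, those in [5%, 20%) the "medium" class (the published "5-20%" range is
taken half-open so the classes are disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReadSet
from .mapping import AlignmentParams, Pileup, call_consensus, map_reads
from .simulate import UnitConsensus, encode

__all__ = [
    "Variant",
    "VariantSet",
    "WindowProfile",
    "HaplotypeTable",
    "call_variants",
    "window_profile",
    "consensus_divergence",
    "cluster_haplotypes",
]

BASES = "ACGT"
HIGH_FREQUENCY = 0.20


@dataclass(frozen=True)
class Variant:
    position: int
    ref_allele: str
    alt_allele: str
    count: int
    coverage: int

    @property
    def frequency(self) -> float:
        return self.count / self.coverage

    @property
    def freq_class(self) -> str:
        return "high" if self.frequency >= HIGH_FREQUENCY else "medium"

    @property
    def key(self) -> tuple[int, str]:
        # identity used for provenance set comparison
        return (self.position, self.alt_allele)


@dataclass
class VariantSet:
    reference_id: str
    reference_length: int
    variants: list[Variant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def high(self) -> "VariantSet":
        return VariantSet(self.reference_id, self.reference_length,
                          [v for v in self.variants if v.freq_class == "high"])

    def keys(self) -> set[tuple[int, str]]:
        return {v.key for v in self.variants}

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": [v.position for v in self.variants],
                "ref": [v.ref_allele for v in self.variants],
                "alt": [v.alt_allele for v in self.variants],
                "count": [v.count for v in self.variants],
                "coverage": [v.coverage for v in self.variants],
                "frequency": [v.frequency for v in self.variants],
                "class": [v.freq_class for v in self.variants],
            }
        )

    def to_vcf(self) -> str:
        """Minimal VCF v4.2 rendering (1-based positions)."""
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={self.reference_id},length={self.reference_length}>",
            '##INFO=<ID=COUNT,Number=1,Type=Integer,Description="Supporting reads">',
            '##INFO=<ID=COV,Number=1,Type=Integer,Description="Countable reads">',
            '##INFO=<ID=FREQ,Number=1,Type=Float,Description="Allele frequency">',
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="Frequency class">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for v in self.variants:
            info = (f"COUNT={v.count};COV={v.coverage};"
                    f"FREQ={v.frequency:.4f};CLASS={v.freq_class}")
            lines.append(
                f"{self.reference_id}\t{v.position + 1}\t.\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t{info}"
            )
        return "\n".join(lines) + "\n"


def call_variants(
    pileup: Pileup,
    reference: UnitConsensus | str,
    min_coverage: int = 100,
    min_count: int = 10,
    min_frequency: float = 0.05,
) -> VariantSet:
    """Emit every non-reference allele passing the coverage/count/frequency gates.

    ``reference`` supplies the per-position reference allele; it must match
    the pileup's coordinate frame in length.  Positions where the reference
    base is N are skipped.
    """
    ref_seq = reference.sequence if isinstance(reference, UnitConsensus) else str(reference)
    if len(ref_seq) != pileup.reference_length:
        raise ValueError("reference/pileup length mismatch")
    ref_codes = encode(ref_seq)
    cov = pileup.coverage
    variants = []
    covered = np.nonzero(cov >= min_coverage)[0]
    for pos in covered:
        rc = ref_codes[pos]
        if rc > 3:
            continue
        c = cov[pos]
        for b in range(4):
            if b == rc:
                continue
            n = int(pileup.counts[b, pos])
            if n >= min_count and n / c >= min_frequency:
                variants.append(Variant(int(pos), BASES[rc], BASES[b], n, int(c)))
    return VariantSet(pileup.reference_id, pileup.reference_length, variants)


@dataclass
class WindowProfile:
    window: int
    counts: np.ndarray  # high-frequency SNPs per non-overlapping window

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"window_start": np.arange(len(self.counts)) * self.window,
             "count": self.counts}
        )


def window_profile(variants: VariantSet, reference_length: int | None = None,
                   window: int = 10) -> WindowProfile:
    """High-frequency SNP counts per non-overlapping ``window``-bp bin."""
    if window < 1:
        raise ValueError("window must be >= 1")
    length = reference_length or variants.reference_length
    n_windows = -(-length // window)
    counts = np.zeros(n_windows, dtype=np.int64)
    seen = set()
    for v in variants:
        if v.freq_class == "high" and v.position not in seen:
            seen.add(v.position)
            counts[v.position // window] += 1
    return WindowProfile(window, counts)


def consensus_divergence(seq1: str, seq2: str) -> tuple[int, float]:
    """Polymorphic site count and percent divergence of two aligned sequences.

    Positions where either sequence is not a plain base (N, gap) are excluded
    from both numerator and denominator; percent is reported to 2 decimals.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    c1, c2 = encode(seq1), encode(seq2)
    comparable = (c1 <= 3) & (c2 <= 3)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return 0, 0.0
    sites = int(np.count_nonzero((c1 != c2) & comparable))
    return sites, round(100.0 * sites / n_comp, 2)


@dataclass
class HaplotypeTable:
    """Amplicon haplotypes above the reporting cutoff, sorted by fraction."""

    haplotypes: list[tuple[str, float]]
    variable_positions: list[int]
    n_reads_grouped: int
    cutoff: float = 0.10


def cluster_haplotypes(
    amplicons: ReadSet,
    region_reference: str,
    cutoff: float = 0.10,
    min_frequency: float = 0.05,
    params: AlignmentParams | None = None,
) -> HaplotypeTable:
    """Group amplicon reads into haplotypes over their variable positions.

    Reads are mapped to the region reference with the standard mapper; a
    position is variable when its minor allele frequency among mapped reads
    reaches ``min_frequency``.  Reads covering every variable position are
    grouped by their base calls there; groups with fraction >= ``cutoff``
    are reported (descending), as full-region sequences built on the mapped
    consensus.
    """
    if not region_reference:
        raise ValueError("empty region reference")
    pile, placements = map_reads(amplicons, region_reference, params,
                                 keep_alignments=True)
    if pile.mapped_read_count == 0:
        raise ValueError("no amplicon read maps to the region")

    cov = pile.coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = pile.counts / np.maximum(cov, 1)
    order = np.sort(freqs, axis=0)
    minor = order[-2]  # second-most-frequent allele share
    variable = [int(p) for p in np.nonzero((cov > 0) & (minor >= min_frequency))[0]]

    consensus = call_consensus(pile)
    groups: dict[tuple[int, ...], int] = {}
    n_grouped = 0
    for pl in placements:
        if pl is None:
            continue
        calls = {int(p): int(b) for p, b in zip(pl.ref_positions, pl.base_codes)}
        try:
            key = tuple(calls[p] for p in variable)
        except KeyError:
            continue  # read does not cover all variable positions
        groups[key] = groups.get(key, 0) + 1
        n_grouped += 1
    if n_grouped == 0:
        raise ValueError("no read covers all variable positions")

    out = []
    for key, n in groups.items():
        frac = n / n_grouped
        if frac >= cutoff:
            hap = list(consensus)
            for p, b in zip(variable, key):
                hap[p] = BASES[b]
            out.append(("".join(hap), frac))
    out.sort(key=lambda t: (-t[1], t[0]))
    return HaplotypeTable(out, variable, n_grouped, cutoff)
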