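"""Synthetic data generator for allopolyploid rDNA homogenization studies.

The generator emulates the sequencing regime of a recent Brassica-type
allotetraploid (AACC) and its two diploid progenitors:

* two progenitor 35S rDNA unit consensuses (default 5803 bp) diverged at a
  controlled fraction of fixed *diagnostic* sites (default 1.24%, i.e. 72
  sites over the full unit);
* intragenomic polymorphism within each progenitor unit pool (default ten
  polymorphic sites in the A-genome pool and seven in the C-genome pool,
  carried by a minor sub-haplotype);
* an allopolyploid unit pool combining ``n_A`` A-genome and ``n_C`` C-genome
  units, in which a configurable fraction of C units has been overwritten by
  the A-genome sequence (whole-unit gene conversion), plus an optionally
  amplified family of novel "mutated" units carrying unique variants;
* Illumina-like single-end reads over the pool diluted with random
  background reads so the rDNA genome proportion matches a target;
* amplicon read pools for a sub-region of the unit (ITS1-style).

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ReadSet

__all__ = [
    "UnitConsensus",
    "DiagnosticSite",
    "PoolEntry",
    "UnitPool",
    "SimConfig",
    "default_features",
    "make_progenitor_pair",
    "make_progenitor_pool",
    "make_allopolyploid_pool",
    "simulate_reads",
    "simulate_amplicons",
]

BASES = "ACGT"
_A_LABELS = frozenset({"A", "C_converted", "mutated"})

# numpy byte-code translation tables
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class DiagnosticSite:
    """A fixed inter-subgenome difference in the shared unit coordinates."""

    position: int
    allele_A: str
    allele_C: str

    def __post_init__(self):
        if self.allele_A == self.allele_C:
            raise ValueError("diagnostic alleles must differ")


@dataclass
class UnitConsensus:
    """Consensus sequence of one subgenome's rDNA unit.

    ``features`` maps region names (18S, ITS1, 5.8S, ITS2, 26S, promoter)
    to half-open ``(start, end)`` intervals; intervals are pairwise disjoint
    and lie within the unit.  ``polymorphic_sites`` lists intragenomic
    polymorphisms carried by a minor sub-haplotype of this subgenome's unit
    pool as ``(position, major_allele, minor_allele)``.
    """

    label: str
    sequence: str
    features: dict[str, tuple[int, int]] = field(default_factory=dict)
    polymorphic_sites: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self):
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty consensus sequence")
        ivals = sorted(self.features.values())
        for (s, e) in ivals:
            if not (0 <= s < e <= n):
                raise ValueError(f"feature interval ({s}, {e}) outside unit")
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("feature intervals overlap")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PoolEntry:
    sequence: str
    label: str  # A | C | C_converted | mutated
    count: int


@dataclass
class UnitPool:
    """Collection of rDNA unit sequences with provenance labels.

    Distinct sequences are stored once with a multiplicity; label counts are
    the simulator's ground truth for downstream recovery checks.
    """

    entries: list[PoolEntry]
    unit_length: int

    @property
    def size(self) -> int:
        return sum(e.count for e in self.entries)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.label] = out.get(e.label, 0) + e.count
        return out

    def fraction(self, label: str) -> float:
        return self.label_counts().get(label, 0) / self.size

    def c_unit_fraction(self) -> float:
        """Fraction of units still carrying the intact C-genome haplotype."""
        return self.fraction("C")


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the sequenced Brassica system: a 5803-bp 18S-5.8S-26S
    unit, 1.24% inter-progenitor divergence (72 diagnostic sites), ~1700
    A-genome vs ~1160 C-genome copies per 1C, 100-nt Illumina-like reads at
    0.5% substitution error, and a 1.39% rDNA genome proportion within a
    1182-Mb genome.
    """

    unit_length: int = 5803
    divergence: float = 0.0124
    n_A: int = 1700
    n_C: int = 1160
    conversion_fraction: float = 0.0
    unique_rate: float = 0.0
    n_unique_sites: int = 3
    n_intra_A: int = 10
    n_intra_C: int = 7
    intra_freq: float = 0.4
    coverage: float = 200.0
    read_length: int = 100
    error_rate: float = 0.005
    target_genome_proportion: float = 0.0139
    genome_size_mb: float = 1182.0
    seed: int = 0

    def __post_init__(self):
        for name in ("divergence", "conversion_fraction", "unique_rate",
                     "intra_freq", "target_genome_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if self.unit_length < self.read_length:
            raise ValueError("unit_length must be >= read_length")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def default_features(unit_length: int) -> dict[str, tuple[int, int]]:
    """Feature layout scaled from the 5803-bp reference unit.

    Boundaries at full length: promoter-proximal 0-150, 18S 150-1960,
    ITS1 1960-2216 (256 bp), 5.8S 2216-2380, ITS2 2380-2600, 26S 2600-5803.
    """
    anchors = [0, 150, 1960, 2216, 2380, 2600, 5803]
    names = ["promoter", "18S", "ITS1", "5.8S", "ITS2", "26S"]
    scaled = [int(round(a * unit_length / 5803)) for a in anchors]
    feats = {}
    for name, s, e in zip(names, scaled, scaled[1:]):
        if e > s:
            feats[name] = (s, e)
    return feats


def _other_base(rng: np.random.Generator, base_code: int) -> int:
    return (base_code + 1 + rng.integers(0, 3)) % 4


def make_progenitor_pair(
    config: SimConfig,
) -> tuple[UnitConsensus, UnitConsensus, list[DiagnosticSite]]:
    """Generate the two progenitor unit consensuses and their fixed differences.

    The two sequences differ at exactly ``round(divergence * unit_length)``
    positions, each reported as a :class:`DiagnosticSite`.  Intragenomic
    polymorphic sites for each progenitor pool are drawn at non-diagnostic
    positions and attached to the consensuses.
    """
    rng = np.random.default_rng(config.seed)
    n = config.unit_length
    n_sites = int(round(config.divergence * n))
    codes_a = rng.integers(0, 4, n, dtype=np.uint8)

    n_special = n_sites + config.n_intra_A + config.n_intra_C
    if n_special > n:
        raise ValueError("more variant sites requested than unit positions")
    special = rng.choice(n, size=n_special, replace=False)
    diag_pos = np.sort(special[:n_sites])
    intra_a_pos = np.sort(special[n_sites:n_sites + config.n_intra_A])
    intra_c_pos = np.sort(special[n_sites + config.n_intra_A:])

    codes_c = codes_a.copy()
    sites = []
    for p in diag_pos:
        codes_c[p] = _other_base(rng, codes_a[p])
        sites.append(DiagnosticSite(int(p), BASES[codes_a[p]], BASES[codes_c[p]]))

    def _intra(codes, positions):
        return tuple(
            (int(p), BASES[codes[p]], BASES[_other_base(rng, codes[p])])
            for p in positions
        )

    feats = default_features(n)
    cons_a = UnitConsensus("A", decode(codes_a), feats, _intra(codes_a, intra_a_pos))
    cons_c = UnitConsensus("C", decode(codes_c), feats, _intra(codes_c, intra_c_pos))
    return cons_a, cons_c, sites


def _apply_sites(sequence: str, sites) -> str:
    codes = encode(sequence).copy()
    for pos, _major, minor in sites:
        codes[pos] = BASES.index(minor)
    return decode(codes)


def make_progenitor_pool(consensus: UnitConsensus, n_units: int,
                         config: SimConfig) -> UnitPool:
    """Unit pool of a diploid progenitor with its intragenomic polymorphism.

    A fraction ``intra_freq`` of units carries the minor alleles at the
    consensus' polymorphic sites; the remainder matches the consensus.
    """
    if n_units <= 0:
        raise ValueError("progenitor pool must contain at least one unit")
    n_minor = int(round(config.intra_freq * n_units)) if consensus.polymorphic_sites else 0
    entries = []
    if n_units - n_minor > 0:
        entries.append(PoolEntry(consensus.sequence, consensus.label, n_units - n_minor))
    if n_minor > 0:
        entries.append(PoolEntry(_apply_sites(consensus.sequence,
                                              consensus.polymorphic_sites),
                                 consensus.label, n_minor))
    return UnitPool(entries, len(consensus))


def make_allopolyploid_pool(
    A: UnitConsensus,
    C: UnitConsensus,
    sites: list[DiagnosticSite],
    config: SimConfig,
) -> UnitPool:
    """Allopolyploid unit pool with whole-unit gene conversion.

    ``round(conversion_fraction * n_C)`` C units are replaced by the full
    A-genome sequence (label ``C_converted``); with per-unit probability
    ``unique_rate`` an A-derived unit instead joins an amplified family of
    ``mutated`` units sharing ``n_unique_sites`` novel substitutions at
    non-diagnostic, non-polymorphic positions.  Intragenomic polymorphism of
    each progenitor is propagated to its descendants.
    """
    if config.n_A == 0 and config.n_C == 0:
        raise ValueError("empty allopolyploid pool (n_A = n_C = 0)")
    if len(A) != len(C):
        raise ValueError("progenitor consensuses differ in length")
    rng = np.random.default_rng((config.seed, 1))
    n_conv = int(round(config.conversion_fraction * config.n_C))
    n_c_intact = config.n_C - n_conv

    # novel variant haplotype shared by the "mutated" family
    taken = {s.position for s in sites}
    taken.update(p for p, _, _ in A.polymorphic_sites + C.polymorphic_sites)
    free = np.setdiff1d(np.arange(config.unit_length), np.fromiter(taken, int, len(taken)))
    novel = []
    codes_a = encode(A.sequence)
    for p in rng.choice(free, size=min(config.n_unique_sites, free.size), replace=False):
        novel.append((int(p), BASES[codes_a[p]], BASES[_other_base(rng, codes_a[p])]))
    novel = tuple(sorted(novel))

    n_a_derived = config.n_A + n_conv
    n_mut = int(rng.binomial(n_a_derived, config.unique_rate)) if config.unique_rate else 0
    # mutated units are recruited from plain A units first, then converted ones
    mut_from_a = min(n_mut, config.n_A)
    mut_from_conv = n_mut - mut_from_a

    def _split_intra(seq, base_seq_minor, label, count):
        """Split `count` units into major/minor intragenomic haplotypes."""
        n_minor = int(round(config.intra_freq * count)) if base_seq_minor else 0
        out = []
        if count - n_minor > 0:
            out.append(PoolEntry(seq, label, count - n_minor))
        if n_minor > 0:
            out.append(PoolEntry(base_seq_minor, label, n_minor))
        return out

    a_minor = _apply_sites(A.sequence, A.polymorphic_sites) if A.polymorphic_sites else None
    c_minor = _apply_sites(C.sequence, C.polymorphic_sites) if C.polymorphic_sites else None

    entries: list[PoolEntry] = []
    entries += _split_intra(A.sequence, a_minor, "A", config.n_A - mut_from_a)
    entries += _split_intra(A.sequence, a_minor, "C_converted", n_conv - mut_from_conv)
    entries += _split_intra(C.sequence, c_minor, "C", n_c_intact)
    if n_mut > 0:
        entries.append(PoolEntry(_apply_sites(A.sequence, novel), "mutated", n_mut))
    entries = [e for e in entries if e.count > 0]
    return UnitPool(entries, config.unit_length)


def _sample_pool_reads(pool: UnitPool, n_reads: int, read_length: int,
                       rng: np.random.Generator, error_rate: float,
                       with_strand: bool):
    """Vectorised sampling of reads from pool units; returns a code matrix."""
    weights = np.array([e.count for e in pool.entries], dtype=float)
    weights /= weights.sum()
    entry_idx = rng.choice(len(pool.entries), size=n_reads, p=weights)
    starts = rng.integers(0, pool.unit_length - read_length + 1, size=n_reads)
    reverse = rng.random(n_reads) < 0.5 if with_strand else np.zeros(n_reads, bool)

    entry_codes = [encode(e.sequence) for e in pool.entries]
    mat = np.empty((n_reads, read_length), dtype=np.uint8)
    offs = np.arange(read_length)
    for k, codes in enumerate(entry_codes):
        sel = entry_idx == k
        if sel.any():
            mat[sel] = codes[starts[sel, None] + offs]
    if with_strand and reverse.any():
        mat[reverse] = (3 - mat[reverse])[:, ::-1]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        if err.any():
            mat[err] = (mat[err] + rng.integers(1, 4, int(err.sum()))) % 4
    return mat, entry_idx, starts, reverse


def simulate_reads(pool: UnitPool, config: SimConfig) -> ReadSet:
    """Illumina-like reads over the pool plus random background reads.

    rDNA read count is set by ``coverage`` over the unit; background reads
    of i.i.d. random DNA are appended so the rDNA-derived fraction of the
    read set equals ``target_genome_proportion``.  Substitution errors only;
    constant Phred-40 qualities; byte-identical output under a fixed seed.
    """
    if config.read_length > pool.unit_length:
        raise ValueError("read_length exceeds unit length")
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng((config.seed, 2))
    n_rdna = int(round(config.coverage * pool.unit_length / config.read_length))
    gp = config.target_genome_proportion
    n_bg = 0 if gp >= 1.0 else int(round(n_rdna * (1.0 - gp) / gp))

    mat, _, _, _ = _sample_pool_reads(pool, n_rdna, config.read_length, rng,
                                      config.error_rate, with_strand=True)
    qual = "I" * config.read_length
    ids, seqs = [], []
    for i in range(n_rdna):
        ids.append(f"sim_{i}")
        seqs.append(decode(mat[i]))
    if n_bg:
        bg = rng.integers(0, 4, size=(n_bg, config.read_length)).astype(np.uint8)
        for i in range(n_bg):
            ids.append(f"bg_{i}")
            seqs.append(decode(bg[i]))
    return ReadSet(ids, seqs, [qual] * (n_rdna + n_bg))


def simulate_amplicons(pool: UnitPool, region: tuple[int, int], n_reads: int,
                       config: SimConfig) -> ReadSet:
    """Amplicon reads covering ``region`` of the unit.

    Each read is the region extracted from a pool unit drawn proportionally
    to unit counts, with substitution errors at ``error_rate``; amplicons are
    reported on the forward strand.
    """
    start, end = region
    if not (0 <= start < end <= pool.unit_length):
        raise ValueError(f"region {region} outside unit bounds")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng((config.seed, 3))
    length = end - start
    weights = np.array([e.count for e in pool.entries], dtype=float)
    weights /= weights.sum()
    entry_idx = rng.choice(len(pool.entries), size=n_reads, p=weights)
    entry_codes = [encode(e.sequence)[start:end] for e in pool.entries]
    mat = np.empty((n_reads, length), dtype=np.uint8)
    for k, codes in enumerate(entry_codes):
        sel = entry_idx == k
        if sel.any():
            mat[sel] = codes
    if config.error_rate > 0:
        err = rng.random(mat.shape) < config.error_rate
        if err.any():
            mat[err] = (mat[err] + rng.integers(1, 4, int(err.sum()))) % 4
    qual = "I" * length
    return ReadSet([f"amp_{i}" for i in range(n_reads)],
                   [decode(mat[i]) for i in range(n_reads)],
                   [qual] * n_reads)


# ---------------------------------------------------------------------------
# ground-truth exports

def pool_to_records(pool: UnitPool) -> list[tuple[str, str, str]]:
    """(id, sequence, description) triples for FASTA export, one per entry."""
    out = []
    for i, e in enumerate(pool.entries):
        out.append((f"unit_{i}", e.sequence, f"origin={e.label} count={e.count}"))
    return out


def sites_to_table(sites: list[DiagnosticSite]):
    import pandas as pd

    return pd.DataFrame(
        {
            "position": [s.position for s in sites],
            "allele_A": [s.allele_A for s in sites],
            "allele_C": [s.allele_C for s in sites],
        }
    )


def pool_to_table(pool: UnitPool):
    import pandas as pd

    return pd.DataFrame(
        {
            "unit_id": [f"unit_{i}" for i in range(len(pool.entries))],
            "origin_label": [e.label for e in pool.entries],
            "count": [e.count for e in pool.entries],
        }
    )
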