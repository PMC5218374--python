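"""In-silico restriction assays: IUPAC-aware digestion, CAPS genotyping of
amplicons and Southern-like band quantification of labelled unit pools.

Band "intensity" defaults to molecule_count x fragment_length, i.e.
mass-proportional as on a hybridised blot; a count-proportional mode is
available.  Fragment lengths within +/-2 bp fall into one band (gel
resolution); partial digestion is not modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io import ReadSet
from .simulate import UnitPool

__all__ = [
    "Enzyme",
    "ENZYMES",
    "Band",
    "DigestProfile",
    "BandRatioReport",
    "digest",
    "digest_intervals",
    "cut_positions",
    "caps_assay",
    "southern_ratio",
    "load_enzyme_table",
]

A_TYPE_LABELS = frozenset({"A", "C_converted", "mutated"})


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str  # IUPAC DNA motif
    cut_offset: int   # cut position within the motif, 0..len(motif)

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition motif must be at least 4 bp")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside motif")
        for ch in self.recognition.upper():
            if ch not in "ACGTWSMKRYBDHVN":
                raise ValueError(f"invalid IUPAC code {ch!r} in motif")

    @property
    def regex(self) -> re.Pattern:
        cls = "".join(
            f"[{ambiguous_dna_values[ch]}]" if len(ambiguous_dna_values[ch]) > 1 else ch
            for ch in self.recognition.upper()
        )
        return re.compile(f"(?=({cls}))")  # lookahead: overlapping occurrences

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition).reverse_complement()) == self.recognition.upper()


ENZYMES = {
    "RsaI": Enzyme("RsaI", "GTAC", 2),
    "BstNI": Enzyme("BstNI", "CCWGG", 2),
}


def load_enzyme_table(path) -> dict[str, Enzyme]:
    """Extend the built-in table from a TSV (name, recognition, cut_offset)."""
    import pandas as pd

    table = dict(ENZYMES)
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        table[row.name] = Enzyme(row.name, row.recognition, int(row.cut_offset))
    return table


def cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Forward-strand cut coordinates from both strands' motif occurrences.

    A reverse-strand occurrence at position i (motif length m) cuts the
    forward strand at ``i + m - cut_offset``.  Cuts at position 0 or at the
    sequence end are dropped, so zero-length fragments cannot arise.
    """
    seq = sequence.upper()
    cuts = {m.start() + enzyme.cut_offset for m in enzyme.regex.finditer(seq)}
    if not enzyme.is_palindromic:
        rc = Enzyme(enzyme.name, str(Seq(enzyme.recognition).reverse_complement()),
                    enzyme.cut_offset)
        m_len = len(enzyme.recognition)
        cuts |= {
            m.start() + (m_len - enzyme.cut_offset)
            for m in rc.regex.finditer(seq)
        }
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(sequence: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths of a linear molecule, 5' to 3'."""
    if not sequence:
        raise ValueError("empty sequence")
    return [e - s for s, e in digest_intervals(sequence, enzyme)]


def digest_intervals(sequence: str, enzyme: Enzyme) -> list[tuple[int, int]]:
    if not sequence:
        raise ValueError("empty sequence")
    cuts = cut_positions(sequence, enzyme)
    bounds = [0] + cuts + [len(sequence)]
    return list(zip(bounds, bounds[1:]))


@dataclass
class Band:
    length: int                   # representative fragment length
    count: int                    # molecules contributing to the band
    label_counts: dict[str, int] = field(default_factory=dict)

    @property
    def subgenome(self) -> str:
        """'A', 'C', 'mixed' or 'unlabelled' attribution of the band."""
        if not self.label_counts:
            return "unlabelled"
        kinds = {"A" if lb in A_TYPE_LABELS else "C" for lb in self.label_counts}
        return kinds.pop() if len(kinds) == 1 else "mixed"


def _bin_fragments(frags: list[tuple[int, str | None, int]],
                   tolerance: int = 2) -> list[Band]:
    """Single-linkage binning of fragment lengths within the tolerance."""
    if not frags:
        return []
    frags = sorted(frags)
    bands: list[Band] = []
    cur: list[tuple[int, str | None, int]] = [frags[0]]
    for f in frags[1:]:
        if f[0] - cur[-1][0] <= tolerance:
            cur.append(f)
        else:
            bands.append(_make_band(cur))
            cur = [f]
    bands.append(_make_band(cur))
    return bands


def _make_band(frags) -> Band:
    total = sum(n for _, _, n in frags)
    mean_len = int(round(sum(l * n for l, _, n in frags) / total))
    labels: dict[str, int] = {}
    for _, lb, n in frags:
        if lb is not None:
            labels[lb] = labels.get(lb, 0) + n
    return Band(mean_len, total, labels)


@dataclass
class DigestProfile:
    bands: list[Band]
    codominant: bool | None  # None when molecules carry no labels

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "length": [b.length for b in self.bands],
                "count": [b.count for b in self.bands],
                "subgenome": [b.subgenome for b in self.bands],
            }
        )


def _region_molecules(source: UnitPool | ReadSet, region: tuple[int, int] | None):
    """(sequence, label, count) molecules; region extraction for unit pools."""
    if isinstance(source, UnitPool):
        if region is None:
            return [(e.sequence, e.label, e.count) for e in source.entries]
        s, e = region
        if not (0 <= s < e <= source.unit_length):
            raise ValueError(f"region {region} outside unit bounds")
        return [(en.sequence[s:e], en.label, en.count) for en in source.entries]
    return [(seq, None, 1) for _, seq, _ in source]


def caps_assay(
    source: UnitPool | ReadSet,
    region: tuple[int, int] | None,
    enzyme: Enzyme,
    tolerance: int = 2,
    detect_share: float = 0.05,
) -> DigestProfile:
    """Digest each molecule's amplicon and bin the fragments into bands.

    With a labelled unit pool, co-dominance is reported when subgenome-
    specific bands of both parents each exceed ``detect_share`` of the
    total molecule count.
    """
    molecules = _region_molecules(source, region)
    if not molecules:
        raise ValueError("no amplicon molecules to digest")
    frags: list[tuple[int, str | None, int]] = []
    for seq, label, count in molecules:
        for ln in digest(seq, enzyme):
            frags.append((ln, label, count))
    bands = _bin_fragments(frags, tolerance)
    labelled = any(b.label_counts for b in bands)
    codominant: bool | None = None
    if labelled:
        total = sum(b.count for b in bands)
        share_a = sum(b.count for b in bands if b.subgenome == "A") / total
        share_c = sum(b.count for b in bands if b.subgenome == "C") / total
        codominant = share_a >= detect_share and share_c >= detect_share
    return DigestProfile(bands, codominant)


@dataclass
class BandRatioReport:
    bands: list[Band]
    intensity_shares: list[float]
    c_fraction: float | None   # None when A and C co-migrate (unresolved)
    resolved: bool
    mass_weighted: bool


def southern_ratio(
    pool: UnitPool,
    enzyme: Enzyme,
    probe_interval: tuple[int, int],
    mass_weighted: bool = True,
    tolerance: int = 2,
) -> BandRatioReport:
    """Southern-style C/(C+A) quantification of probe-hybridising fragments.

    Each unit is digested; only fragments overlapping the probe interval
    contribute.  Band intensity is molecule_count x fragment_length by
    default (mass-proportional signal).  When A- and C-derived fragments
    co-migrate into one band the ratio is flagged unresolved.
    """
    ps, pe = probe_interval
    if pe <= ps:
        raise ValueError("probe interval is empty")
    if not (0 <= ps < pe <= pool.unit_length):
        raise ValueError("probe interval outside unit coordinates")
    frags: list[tuple[int, str, int]] = []
    for entry in pool.entries:
        for s, e in digest_intervals(entry.sequence, enzyme):
            if s < pe and e > ps:  # overlaps the probe
                frags.append((e - s, entry.label, entry.count))
    if not frags:
        raise ValueError("no fragment hybridises to the probe")
    bands = _bin_fragments(frags, tolerance)
    weights = [
        b.count * (b.length if mass_weighted else 1) for b in bands
    ]
    total = sum(weights)
    shares = [w / total for w in weights]
    resolved = all(b.subgenome != "mixed" for b in bands)
    c_fraction = None
    if resolved:
        c_fraction = sum(
            sh for b, sh in zip(bands, shares) if b.subgenome == "C"
        )
    return BandRatioReport(bands, shares, c_fraction, resolved, mass_weighted)
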