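"""Virtual-hybrid construction, variant provenance partitioning,
diagnostic-site homeologue readout, and C-copy elimination estimates.

The additive null for an allotetraploid is a "virtual hybrid": a 1:1
in-silico mixture of the two progenitors' read sets.  Calling every read set
against one shared coordinate frame lets each allopolyploid variant
(position, alt allele) be classified by provenance: present only in the
A-progenitor's variant set (A-inherited), only in the C-progenitor's
(C-inherited), in both (shared), or in neither (unique).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ReadSet
from .mapping import Pileup
from .simulate import DiagnosticSite
from .variants import VariantSet

__all__ = [
    "ProvenancePartition",
    "DiagnosticReadout",
    "EliminationEstimate",
    "make_virtual_hybrid",
    "partition_provenance",
    "diagnostic_frequencies",
    "estimate_elimination",
]

BASES = "ACGT"


@dataclass
class ProvenancePartition:
    n_a_inherited: int
    n_c_inherited: int
    n_shared: int
    n_unique: int

    @property
    def total(self) -> int:
        return self.n_a_inherited + self.n_c_inherited + self.n_shared + self.n_unique

    @property
    def pct_a_inherited(self) -> float:
        return 100.0 * self.n_a_inherited / self.total

    @property
    def pct_c_inherited(self) -> float:
        return 100.0 * self.n_c_inherited / self.total

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.n_shared / self.total

    @property
    def pct_unique(self) -> float:
        return 100.0 * self.n_unique / self.total

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_A_inherited": self.pct_a_inherited,
            "pct_C_inherited": self.pct_c_inherited,
            "pct_shared": self.pct_shared,
            "pct_unique": self.pct_unique,
        }


def make_virtual_hybrid(reads_A: ReadSet, reads_C: ReadSet, seed: int = 0) -> ReadSet:
    """1:1 in-silico mixture of two parental read sets.

    The larger set is down-sampled uniformly without replacement so each
    parent contributes ``min(|A|, |C|)`` reads; the merged order is shuffled
    deterministically under ``seed``.  Identifiers are prefixed by parent to
    stay unique.
    """
    if len(reads_A) == 0 or len(reads_C) == 0:
        raise ValueError("both parental read sets must be non-empty")
    rng = np.random.default_rng((seed, 17))
    n = min(len(reads_A), len(reads_C))

    def _sample(rs: ReadSet, prefix: str) -> ReadSet:
        idx = rng.choice(len(rs), size=n, replace=False) if len(rs) > n \
            else np.arange(len(rs))
        sub = rs.subset(idx)
        sub.ids = [f"{prefix}:{r}" for r in sub.ids]
        return sub

    a, c = _sample(reads_A, "A"), _sample(reads_C, "C")
    merged = ReadSet(a.ids + c.ids, a.sequences + c.sequences,
                     a.qualities + c.qualities)
    order = rng.permutation(len(merged))
    return merged.subset(order)


def partition_provenance(
    v_allo: VariantSet,
    v_a: VariantSet,
    v_c: VariantSet,
    use_medium: bool = False,
    merge_shared: bool = False,
) -> ProvenancePartition:
    """Classify each allopolyploid variant by progenitor provenance.

    By default only high-frequency variants of the allopolyploid enter the
    partition; ``use_medium`` admits the medium class as well.  Progenitor
    sets are matched at any frequency class by (position, alt allele).  With
    ``merge_shared`` the shared class is folded into the dominant inherited
    class, mirroring two-way Venn summaries.
    """
    ids = {v_allo.reference_id, v_a.reference_id, v_c.reference_id}
    if len(ids) != 1:
        raise ValueError(f"variant sets use different coordinate frames: {ids}")
    allo = v_allo if use_medium else v_allo.high()
    if len(allo) == 0:
        raise ValueError("no allopolyploid variants to partition")
    keys_a, keys_c = v_a.keys(), v_c.keys()
    n_a = n_c = n_sh = n_un = 0
    for v in allo:
        in_a, in_c = v.key in keys_a, v.key in keys_c
        if in_a and in_c:
            n_sh += 1
        elif in_a:
            n_a += 1
        elif in_c:
            n_c += 1
        else:
            n_un += 1
    if merge_shared and n_sh:
        if n_a >= n_c:
            n_a += n_sh
        else:
            n_c += n_sh
        n_sh = 0
    return ProvenancePartition(n_a, n_c, n_sh, n_un)


@dataclass
class DiagnosticReadout:
    """Per-site A/C allele fractions and the aggregate C-unit proportion."""

    positions: list[int]
    a_fractions: list[float]
    c_fractions: list[float]
    coverages: list[int]
    c_unit_proportion: float

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": self.positions,
                "A_fraction": self.a_fractions,
                "C_fraction": self.c_fractions,
                "coverage": self.coverages,
            }
        )


def diagnostic_frequencies(
    pileup: Pileup,
    sites: list[DiagnosticSite],
    min_coverage: int = 100,
    coverage_weighted: bool = False,
) -> DiagnosticReadout:
    """Read fractions of the two parental alleles at each diagnostic site.

    The aggregate C-unit proportion is the unweighted mean of per-site
    C-allele fractions over sites with coverage >= ``min_coverage`` (or the
    coverage-weighted mean with ``coverage_weighted``).
    """
    positions, fa, fc, covs = [], [], [], []
    for s in sites:
        if not 0 <= s.position < pileup.reference_length:
            raise ValueError(f"diagnostic site {s.position} outside reference")
        cov = int(pileup.coverage[s.position])
        if cov == 0:
            continue
        na = int(pileup.counts[BASES.index(s.allele_A), s.position])
        nc = int(pileup.counts[BASES.index(s.allele_C), s.position])
        positions.append(s.position)
        fa.append(na / cov)
        fc.append(nc / cov)
        covs.append(cov)
    if not positions:
        raise ValueError("no diagnostic site is covered")
    ok = [i for i, c in enumerate(covs) if c >= min_coverage]
    if not ok:
        raise ValueError(f"no diagnostic site reaches coverage {min_coverage}")
    if coverage_weighted:
        w = np.array([covs[i] for i in ok], dtype=float)
        agg = float(np.average([fc[i] for i in ok], weights=w))
    else:
        agg = float(np.mean([fc[i] for i in ok]))
    return DiagnosticReadout(positions, fa, fc, covs, agg)


@dataclass
class EliminationEstimate:
    expected_c_copies: float
    observed_c_copies: float
    eliminated_copies: float
    eliminated_fraction: float

    def rounded(self) -> dict[str, float]:
        return {
            "expected_C_copies": round(self.expected_c_copies),
            "observed_C_copies": round(self.observed_c_copies),
            "eliminated_copies": round(self.eliminated_copies),
            "eliminated_percent": round(100 * self.eliminated_fraction, 1),
        }


def estimate_elimination(
    c_unit_proportion: float,
    allo_copies_1c: float,
    progenitor_c_copies_1c: float,
) -> EliminationEstimate:
    """C-genome copies lost relative to additive inheritance.

    Observed C copies are the allopolyploid's 1C copy number scaled by the
    diagnostic C-unit proportion; the eliminated count is the shortfall from
    the progenitor's 1C copy number, floored at zero when the observed count
    exceeds expectation.
    """
    if progenitor_c_copies_1c <= 0:
        raise ValueError("progenitor copy number must be positive")
    if allo_copies_1c <= 0:
        raise ValueError("allopolyploid copy number must be positive")
    if not 0.0 <= c_unit_proportion <= 1.0:
        raise ValueError("c_unit_proportion must lie in [0, 1]")
    observed = c_unit_proportion * allo_copies_1c
    eliminated = max(0.0, progenitor_c_copies_1c - observed)
    return EliminationEstimate(
        expected_c_copies=float(progenitor_c_copies_1c),
        observed_c_copies=float(observed),
        eliminated_copies=float(eliminated),
        eliminated_fraction=float(eliminated / progenitor_c_copies_1c),
    )
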