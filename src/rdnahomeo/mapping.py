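"""Read filtering, seed-and-extend mapping to a single rDNA reference,
per-position base counts (pileup) and consensus calling.

The mapper reproduces the acceptance rules of the workbench pipeline the
analysis is modelled on: mismatch cost 2, insertion/deletion cost 3, and a
read is counted as mapped only if its aligned length fraction and identity
both reach 0.8.  Alignment is glocal ("fit"): the whole read is aligned,
reference flanks are free, so the length fraction of an accepted read is
1.0 and identity (matches over aligned columns, indel columns counting
against) is the binding criterion.  Candidate placements come from exact
15-mer seeds on both strands, each extended by a banded cost-minimising
dynamic programme; reads whose ungapped placement shows at most two
mismatches skip the band (no cheaper gapped path exists under these costs).
Ambiguous best placements resolve to the lowest reference coordinate,
forward strand first, so pileups are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReadSet
from .simulate import UnitConsensus, encode

__all__ = [
    "AlignmentParams",
    "Pileup",
    "ReadPlacement",
    "filter_reads",
    "map_reads",
    "call_consensus",
]

BASES = "ACGT"


@dataclass(frozen=True)
class AlignmentParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    min_length_fraction: float = 0.8
    min_similarity_fraction: float = 0.8
    seed_length: int = 15
    band_width: int = 10

    def __post_init__(self):
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("alignment costs must be positive")
        for f in (self.min_length_fraction, self.min_similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class Pileup:
    """Per-position A/C/G/T observation counts over one reference."""

    reference_id: str
    reference_length: int
    counts: np.ndarray  # shape (4, L)
    mapped_read_count: int = 0
    total_read_count: int = 0

    @classmethod
    def empty(cls, reference_id: str, length: int) -> "Pileup":
        return cls(reference_id, length, np.zeros((4, length), dtype=np.int64))

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_table(self, reference: str | None = None):
        import pandas as pd

        d = {"position": np.arange(self.reference_length)}
        if reference is not None:
            d["ref_base"] = list(reference)
        for i, b in enumerate(BASES):
            d[b] = self.counts[i]
        d["coverage"] = self.coverage
        return pd.DataFrame(d)


@dataclass
class ReadPlacement:
    """Accepted placement of one read on the forward reference strand."""

    read_index: int
    ref_start: int
    ref_end: int
    reverse: bool
    cost: int
    identity: float
    ref_positions: np.ndarray  # reference column of every placed read base
    base_codes: np.ndarray     # code of every placed read base

    @property
    def aligned_length(self) -> int:
        return len(self.ref_positions)


def filter_reads(reads: ReadSet, min_length: int = 90) -> ReadSet:
    """Drop reads shorter than ``min_length`` or containing any N; keep order."""
    keep = [
        i
        for i, s in enumerate(reads.sequences)
        if len(s) >= min_length and "N" not in s and "n" not in s
    ]
    return reads.subset(keep)


class _KmerIndex:
    """Exact k-mer index over the reference using base-4 rolling hashes.

    Hashes of all reference k-mers are kept sorted next to their positions,
    so a read's seed hits resolve through two vectorised searchsorted calls.
    """

    def __init__(self, ref_codes: np.ndarray, k: int):
        self.k = k
        self._powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        h, valid = self._hashes(ref_codes)
        pos = np.nonzero(valid)[0]
        h = h[pos]
        order = np.argsort(h, kind="stable")
        self.hashes = h[order]
        self.positions = pos[order]

    def _hashes(self, codes: np.ndarray):
        if len(codes) < self.k:
            return np.empty(0, np.int64), np.empty(0, bool)
        win = np.lib.stride_tricks.sliding_window_view(codes, self.k)
        valid = ~(win > 3).any(axis=1)
        h = (win.astype(np.int64) * self._powers).sum(axis=1)
        return h, valid

    def seed_diagonals_batch(self, code_matrix: np.ndarray) -> list[np.ndarray]:
        """Per-row unique candidate diagonals (ref_pos - read_offset).

        One vectorised hash/searchsorted pass over a whole (n_reads x L)
        code matrix; rows without any seed hit cost almost nothing.
        """
        n, m = code_matrix.shape
        if m < self.k:
            return [np.empty(0, np.int64)] * n
        win = np.lib.stride_tricks.sliding_window_view(code_matrix, self.k, axis=1)
        valid = ~(win > 3).any(axis=2)
        h = (win.astype(np.int64) * self._powers).sum(axis=2)
        lo = np.searchsorted(self.hashes, h, side="left")
        hi = np.searchsorted(self.hashes, h, side="right")
        hit = valid & (hi > lo)
        out: list[np.ndarray] = []
        rows_with_hits = hit.any(axis=1)
        counts = hi - lo
        for r in range(n):
            if not rows_with_hits[r]:
                out.append(np.empty(0, np.int64))
                continue
            offs = np.nonzero(hit[r])[0]
            if counts[r, offs].max() == 1:  # common case: unique k-mers
                diags = self.positions[lo[r, offs]] - offs
            else:
                diags = np.concatenate(
                    [self.positions[lo[r, o] : hi[r, o]] - o for o in offs]
                )
            out.append(np.unique(diags))
        return out


def _fit_align(read_codes: np.ndarray, ref_codes: np.ndarray,
               params: AlignmentParams):
    """Glocal DP: read global, reference flanks free; returns placement stats.

    Cost-minimising over ``mismatch/insertion/deletion`` costs; deletions are
    resolved with a prefix-minimum scan so each row is vectorised.  Traceback
    prefers diagonal, then insertion, then deletion, and ends at the lowest
    cost-minimal reference column.
    """
    m, w = len(read_codes), len(ref_codes)
    mis, ins, dele = params.mismatch_cost, params.insertion_cost, params.deletion_cost
    D = np.empty((m + 1, w + 1), dtype=np.int32)
    D[0] = 0
    jj = np.arange(w + 1, dtype=np.int32)
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + mis * (ref_codes != read_codes[i - 1])
        up = D[i - 1, 1:] + ins
        row = np.empty(w + 1, dtype=np.int32)
        row[0] = D[i - 1, 0] + ins
        np.minimum(sub, up, out=row[1:])
        # deletion scan: row[j] = min(row[j], min_{j'<j} row[j'] + (j-j')*del)
        g = np.minimum.accumulate(row - dele * jj)
        np.minimum(row, g + dele * jj, out=row)
        D[i] = row

    j = int(np.argmin(D[m]))
    cost = int(D[m, j])
    # traceback
    i = m
    matches = columns = 0
    ref_positions: list[int] = []
    base_codes: list[int] = []
    ref_end = j
    while i > 0:
        if j > 0:
            sub = D[i - 1, j - 1] + (0 if ref_codes[j - 1] == read_codes[i - 1] else mis)
            if D[i, j] == sub:
                matches += int(ref_codes[j - 1] == read_codes[i - 1])
                ref_positions.append(j - 1)
                base_codes.append(int(read_codes[i - 1]))
                columns += 1
                i -= 1
                j -= 1
                continue
        if D[i, j] == D[i - 1, j] + ins:  # read base inserted
            columns += 1
            i -= 1
            continue
        # deletion of reference base
        columns += 1
        j -= 1
    ref_start = j
    ref_positions.reverse()
    base_codes.reverse()
    return (cost, ref_start, ref_end, matches, columns,
            np.asarray(ref_positions, dtype=np.int64),
            np.asarray(base_codes, dtype=np.uint8))


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes <= 3, 3 - codes, codes)[::-1]
    return np.ascontiguousarray(out)


def _best_placement(fwd_codes: np.ndarray, rc_codes: np.ndarray,
                    fwd_diags: np.ndarray, rc_diags: np.ndarray,
                    ref_codes: np.ndarray, params: AlignmentParams):
    """Best-cost placement of a read (both strands) or None if unseeded."""
    n = len(ref_codes)
    candidates = []  # (cost, start, orient_rank, payload)
    for orient, codes, diags in ((0, fwd_codes, fwd_diags),
                                 (1, rc_codes, rc_diags)):
        m = len(codes)
        for d in diags:
            d = int(d)
            if 0 <= d and d + m <= n:
                mm = int(np.count_nonzero(ref_codes[d : d + m] != codes))
                # a gapped competitor needs an insertion/deletion pair plus
                # any residual mismatches, so up to this cost the ungapped
                # placement is optimal for non-self-similar references
                if mm * params.mismatch_cost <= (params.insertion_cost
                                                 + params.deletion_cost
                                                 + params.mismatch_cost):
                    candidates.append(
                        (mm * params.mismatch_cost, d, orient,
                         (d, d + m, m - mm, m,
                          np.arange(d, d + m, dtype=np.int64), codes))
                    )
                    continue
            ws = max(0, d - params.band_width)
            we = min(n, d + m + params.band_width)
            if we <= ws:
                continue
            cost, s, e, mat, cols, pos, bc = _fit_align(codes, ref_codes[ws:we], params)
            candidates.append(
                (cost, ws + s, orient, (ws + s, ws + e, mat, cols, pos + ws, bc))
            )
    if not candidates:
        return None
    cost, start, orient, (s, e, matches, columns, pos, bc) = min(
        candidates, key=lambda c: (c[0], c[1], c[2])
    )
    identity = matches / columns if columns else 0.0
    return cost, s, e, bool(orient), identity, pos, bc


def map_reads(
    reads: ReadSet,
    reference: UnitConsensus | str,
    params: AlignmentParams | None = None,
    keep_alignments: bool = False,
) -> Pileup | tuple[Pileup, list[ReadPlacement | None]]:
    """Map reads to a single reference and tally per-position base counts.

    A read is counted as mapped iff its aligned read fraction reaches
    ``min_length_fraction`` and its identity over aligned columns reaches
    ``min_similarity_fraction``; mapped reads contribute their placed bases
    to the pileup.  ``total_read_count`` is the (post-filter) input size.
    """
    params = params or AlignmentParams()
    if isinstance(reference, UnitConsensus):
        ref_seq, ref_id = reference.sequence, f"unit_{reference.label}"
    else:
        ref_seq, ref_id = str(reference), "reference"
    if len(ref_seq) == 0:
        raise ValueError("empty reference")
    ref_codes = encode(ref_seq)
    index = _KmerIndex(ref_codes, params.seed_length)

    pile = Pileup.empty(ref_id, len(ref_seq))
    pile.total_read_count = len(reads)
    placements: list[ReadPlacement | None] = [None] * len(reads)
    pos_buf: list[np.ndarray] = []
    code_buf: list[np.ndarray] = []

    # group reads by length so seed hashing runs on whole matrices
    by_length: dict[int, list[int]] = {}
    for i, seq in enumerate(reads.sequences):
        by_length.setdefault(len(seq), []).append(i)

    chunk = 4096
    for length, members in by_length.items():
        if length == 0:
            continue
        for c0 in range(0, len(members), chunk):
            idx = members[c0 : c0 + chunk]
            fwd = np.stack([encode(reads.sequences[i]) for i in idx])
            rc = np.stack([_rc_codes(row) for row in fwd])
            fwd_diags = index.seed_diagonals_batch(fwd)
            rc_diags = index.seed_diagonals_batch(rc)
            for row, i in enumerate(idx):
                if fwd_diags[row].size == 0 and rc_diags[row].size == 0:
                    continue
                hit = _best_placement(fwd[row], rc[row], fwd_diags[row],
                                      rc_diags[row], ref_codes, params)
                if hit is None:
                    continue
                cost, s, e, rev, identity, pos, bc = hit
                # glocal alignment consumes the whole read, so its aligned
                # fraction is 1; insertion columns degrade identity instead
                aligned_fraction = 1.0
                if (aligned_fraction >= params.min_length_fraction
                        and identity >= params.min_similarity_fraction):
                    placements[i] = ReadPlacement(i, s, e, rev, cost,
                                                  identity, pos, bc)
                    pile.mapped_read_count += 1
                    pos_buf.append(pos)
                    code_buf.append(bc)
    if pos_buf:
        np.add.at(pile.counts,
                  (np.concatenate(code_buf), np.concatenate(pos_buf)), 1)
    if keep_alignments:
        return pile, placements
    return pile


def call_consensus(pileup: Pileup) -> str:
    """Majority base per position; ties alphabetical; zero coverage emits N."""
    if pileup.reference_length == 0:
        raise ValueError("empty pileup")
    best = np.argmax(pileup.counts, axis=0)  # first (alphabetical) on ties
    cons = np.frombuffer(b"ACGT", dtype=np.uint8)[best].copy()
    cons[pileup.coverage == 0] = ord("N")
    return cons.tobytes().decode()
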