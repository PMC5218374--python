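"""Intergenic-spacer structure: tandem higher-order repeat (HOR) detection,
p-distances over aligned clone sets, and neighbour-joining trees with
bootstrap support.

HOR detection scores each candidate period p by the self-match fraction
(base(i) == base(i + p)) over the best contiguous run, found by a
maximum-sum scan with the acceptance threshold as offset.  The best-scoring
period defines the array; copies are consecutive p-length blocks (the last
may be partial, giving a fractional copy number), and consecutive copies are
compared by a unit-cost global alignment.

Neighbour joining is delegated to scikit-bio (Saitou-Nei agglomeration,
negative branch lengths clamped to zero with the deficit moved to the
sister edge); bootstrap resampling of alignment columns and bipartition
support counting are implemented here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .simulate import encode

__all__ = [
    "HorReport",
    "find_hor",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "to_newick",
]

GAP_CODE = 4  # anything outside ACGT is treated as a gap/missing state


@dataclass
class HorReport:
    period: int
    array_interval: tuple[int, int]
    copy_number: float
    copies: list[str]
    inter_copy_divergence: list[float]  # percent, consecutive copies
    self_match_fraction: float

    def as_dict(self) -> dict:
        return {
            "period": self.period,
            "array_start": self.array_interval[0],
            "array_end": self.array_interval[1],
            "copy_number": round(self.copy_number, 2),
            "inter_copy_divergence_pct": [round(d, 2) for d in
                                          self.inter_copy_divergence],
            "self_match_fraction": round(self.self_match_fraction, 3),
        }


def _best_run(match: np.ndarray, threshold: float):
    """Maximum-sum interval of (match - threshold); returns (start, end, sum)."""
    g = match - threshold
    s = np.concatenate([[0.0], np.cumsum(g)])
    prefix_min = np.minimum.accumulate(s[:-1])
    gains = s[1:] - prefix_min
    j = int(np.argmax(gains))  # first maximum: shortest right end
    # rightmost prefix minimum: zero-net flanking segments stay excluded
    head = s[: j + 1]
    i = j - int(np.argmin(head[::-1]))
    return i, j + 1, float(gains[j])


def _snap_boundaries(match: np.ndarray, i: int, j: int, w: int = 10):
    """Snap run ends to sustained matching.

    The maximum-sum scan can absorb short lucky match bursts from the
    flanks; trimming each end to the nearest run of ``w`` consecutive
    matches anchors the array boundary on genuine repeat structure.
    """
    if j - i <= w:
        return i, j
    window_all = np.lib.stride_tricks.sliding_window_view(match[i:j], w).all(axis=1)
    hits = np.nonzero(window_all)[0]
    if hits.size == 0:
        return i, j
    return i + int(hits[0]), i + int(hits[-1]) + w


def _unit_alignment_divergence(a: str, b: str) -> float:
    """Percent divergence from a unit-cost global alignment (match 0,
    mismatch 1, gap 1), over aligned columns."""
    res = edlib.align(a, b, task="path", mode="NW")
    dist = res["editDistance"]
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    return 100.0 * dist / columns if columns else 0.0


def find_hor(
    sequence: str,
    period_range: tuple[int, int] = (20, 1000),
    min_match_fraction: float = 0.7,
) -> HorReport | None:
    """Detect the dominant tandem higher-order repeat of a sequence.

    Returns ``None`` (distinct from an error) when no period in range
    achieves a self-match fraction of ``min_match_fraction`` over a run of
    at least half a period (i.e. an array of at least 1.5 periods).
    """
    n = len(sequence)
    p_min, p_max = period_range
    if p_min < 10:
        raise ValueError("minimum period must be >= 10")
    p_max = min(p_max, int(n / 1.5))
    if p_max < p_min:
        return None
    codes = encode(sequence)
    best = None  # (score, run_length, -period, p, start, end)
    for p in range(p_min, p_max + 1):
        match = (codes[p:] == codes[:-p]).astype(float)
        i, j, _gain = _best_run(match, min_match_fraction)
        run = j - i
        if run < 0.5 * p:
            continue
        score = float(match[i:j].mean())
        if score < min_match_fraction:
            continue
        key = (score, run, -p)
        if best is None or key > best[0]:
            best = (key, p, i, j)
    if best is None:
        return None
    _, p, i, j = best
    i, j = _snap_boundaries((codes[p:] == codes[:-p]), i, j)
    start, end = i, j + p  # positions i..j-1 pair with i+p..j+p-1
    array_len = end - start
    copy_number = array_len / p
    copies = []
    k = start
    while k < end:
        copies.append(sequence[k : min(k + p, end)])
        k += p
    divergences = [
        _unit_alignment_divergence(copies[t][: len(copies[t + 1])], copies[t + 1])
        for t in range(len(copies) - 1)
    ]
    score = float((codes[start + p : end] == codes[start : end - p]).mean())
    return HorReport(p, (start, end), copy_number, copies, divergences, score)


def p_distance_matrix(
    aligned_sequences: list[str], ids: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise p-distances over columns where both sequences carry a base.

    Gap characters ('-', '.') and N are excluded from both numerator and
    denominator of each pair.
    """
    if len(aligned_sequences) < 3:
        raise ValueError("need at least three aligned sequences")
    lengths = {len(s) for s in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    ids = ids or [f"seq{i}" for i in range(len(aligned_sequences))]
    mat = np.stack([encode(s) for s in aligned_sequences])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] <= 3) & (mat[j] <= 3)
            denom = int(ok.sum())
            if denom == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            d[i, j] = d[j, i] = np.count_nonzero((mat[i] != mat[j]) & ok) / denom
    return DistanceMatrix(d, ids)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised so the
    reported side excludes an arbitrary fixed anchor taxon."""
    anchor = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def nj_tree(
    matrix: DistanceMatrix,
    alignment: dict[str, str] | None = None,
    bootstrap_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Neighbour-joining tree, optionally with bootstrap supports.

    With an alignment, columns are resampled with replacement
    ``bootstrap_replicates`` times (after canonical taxon ordering, so
    supports are invariant to input order); internal nodes of the returned
    tree are labelled with the percentage of replicates containing the same
    bipartition.
    """
    data = np.asarray(matrix.data)
    if not np.all(np.isfinite(data)):
        raise ValueError("distance matrix contains non-finite entries")
    tree = nj(matrix, neg_as_zero=True)
    if alignment is None or bootstrap_replicates <= 0:
        return tree
    missing = set(matrix.ids) - set(alignment)
    if missing:
        raise ValueError(f"alignment lacks taxa: {sorted(missing)}")
    supports = bootstrap_supports(tree, alignment, bootstrap_replicates, seed)
    taxa = frozenset(matrix.ids)
    anchor = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if side in supports:
            node.name = str(int(round(supports[side])))
    return tree


def bootstrap_supports(
    tree: TreeNode,
    alignment: dict[str, str],
    replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Bipartition -> percent of column-resampled replicates containing it."""
    ids = sorted(alignment)
    taxa = frozenset(ids)
    seqs = [alignment[i] for i in ids]
    n_cols = len(seqs[0])
    if any(len(s) != n_cols for s in seqs):
        raise ValueError("alignment sequences differ in length")
    target = _bipartitions(tree, taxa)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng((seed, 29))
    mat = np.stack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, n_cols)
        res = ["".join(map(chr, row)) for row in mat[:, cols]]
        try:
            dm = p_distance_matrix(res, ids)
        except ValueError:
            continue  # a replicate with no comparable columns for some pair
        rep = nj(dm, neg_as_zero=True)
        rep_bps = _bipartitions(rep, taxa)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    return {bp: 100.0 * c / replicates for bp, c in counts.items()}


def to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
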