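"""Chromatin-interaction calling from inter-ligation PETs.

Each inter-ligation tag is extended 5'->3' by the tag extension length (the
modal self-ligation span, ~200 bp) to recover the ChIP fragment it came
from.  Piled-up extended tags define anchor regions (peaks split at
valleys); the number of PETs linking two anchors, I_AB, measures the
interaction frequency.  Under random ligation the chance of drawing I_AB
links between anchors holding c_A and c_B of the library's 2N PET ends is
hypergeometric, so the upper-tail hypergeometric probability scores each
anchor pair while correcting for ChIP enrichment of the anchors; an
empirical FDR comes from re-pairing the PET ends at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.special import gammaln, logsumexp

from .mapping import MappedPET

DEFAULT_EXTENSION_BP = 200
TAG_LENGTH_DEFAULT = 20


@dataclass(frozen=True)
class Anchor:
    chrom: str
    start: int
    end: int
    c: int  # extended PET ends overlapping the anchor
    peak_height: int

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class InteractionCluster:
    anchor_a: Anchor
    anchor_b: Anchor
    i_ab: int
    p_hyp: float
    fdr: float = float("nan")
    flags: set[str] = field(default_factory=set)

    @property
    def span(self) -> int | None:
        """Midpoint distance for intra-chromosomal pairs, None otherwise."""
        if self.anchor_a.chrom != self.anchor_b.chrom:
            return None
        mid_a = (self.anchor_a.start + self.anchor_a.end) // 2
        mid_b = (self.anchor_b.start + self.anchor_b.end) // 2
        return abs(mid_b - mid_a)


# ---------------------------------------------------------------------------
# Tag extension and anchors
# ---------------------------------------------------------------------------


def estimate_extension_length(
    self_spans: Sequence[int],
    bin_bp: int = 10,
    fallback: int = DEFAULT_EXTENSION_BP,
    min_spans: int = 100,
) -> int:
    """Mode of the binned self-ligation span histogram (bin centre of the
    maximal bin, smaller centre on ties); the fallback covers sparse data."""
    spans = np.asarray([s for s in self_spans if s is not None and s > 0])
    if len(spans) < min_spans:
        return fallback
    edges = np.arange(0, spans.max() + bin_bp, bin_bp)
    counts, _ = np.histogram(spans, bins=edges)
    i = int(np.argmax(counts))  # argmax takes the first = smaller centre on ties
    return int(edges[i] + bin_bp // 2)


def _extend_one(
    pos: int, strand: str, length: int, chrom_len: int, tag_length: int
) -> tuple[int, int]:
    if strand == "+":
        start, end = pos, pos + length
    else:
        start, end = pos + tag_length - length, pos + tag_length
    return max(0, start), min(chrom_len, end)


def extend_tags(
    inter_pets: Sequence[MappedPET],
    length: int,
    chrom_lengths: dict[str, int],
    tag_length: int = TAG_LENGTH_DEFAULT,
) -> list[tuple[tuple[str, int, int], tuple[str, int, int]]]:
    """Extend both tags of every PET 5'->3' to ``length`` bp (clipped to
    chromosome bounds); returns one (chrom,start,end) interval pair per PET."""
    if length < tag_length:
        raise ValueError("extension length must be at least the tag length")
    out = []
    for p in inter_pets:
        ia = _extend_one(
            p.head.pos, p.head.strand, length, chrom_lengths[p.head.chrom], tag_length
        )
        ib = _extend_one(
            p.tail.pos, p.tail.strand, length, chrom_lengths[p.tail.chrom], tag_length
        )
        out.append(((p.head.chrom, *ia), (p.tail.chrom, *ib)))
    return out


def _coverage_segments(
    intervals: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant coverage: breakpoints b[0..m] and heights h[0..m-1]
    for segment [b[i], b[i+1])."""
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    points = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(points), dtype=np.int64)
    np.add.at(delta, np.searchsorted(points, starts), 1)
    np.add.at(delta, np.searchsorted(points, ends), -1)
    return points, np.cumsum(delta)[:-1]


def _split_run(
    bounds: np.ndarray, heights: np.ndarray, valley_ratio: float
) -> list[tuple[int, int]]:
    """Split one coverage>=1 run at valleys: a local minimum whose height is
    below valley_ratio * min(flanking local maxima) separates two anchors.
    Recursive bisection at the deepest qualifying valley."""
    stack = [(0, len(heights))]
    out: list[tuple[int, int]] = []
    while stack:
        lo, hi = stack.pop()
        h = heights[lo:hi]
        if len(h) < 3:
            out.append((int(bounds[lo]), int(bounds[hi])))
            continue
        interior = np.arange(1, len(h) - 1)
        vi = interior[np.argmin(h[1:-1])]
        left_max = h[:vi].max()
        right_max = h[vi + 1 :].max()
        if h[vi] < valley_ratio * min(left_max, right_max):
            mid = lo + vi
            stack.append((lo, mid))
            stack.append((mid + 1, hi))
        else:
            out.append((int(bounds[lo]), int(bounds[hi])))
    return sorted(out)


def call_anchors(
    extended_intervals: Iterable[tuple[str, int, int]],
    valley_ratio: float = 0.5,
    min_c: int = 2,
) -> list[Anchor]:
    """Peaks-and-valleys anchor definition from the extended-tag coverage
    profile: maximal coverage>=1 runs, split at qualifying valleys; anchors
    supported by fewer than ``min_c`` extended tags are discarded."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in extended_intervals:
        if end > start:
            by_chrom.setdefault(chrom, []).append((start, end))
    anchors: list[Anchor] = []
    for chrom in sorted(by_chrom):
        ivals = by_chrom[chrom]
        bounds, heights = _coverage_segments(ivals)
        covered = heights > 0
        # maximal runs of covered segments
        edges = np.diff(np.concatenate([[0], covered.astype(int), [0]]))
        run_starts = np.nonzero(edges == 1)[0]
        run_ends = np.nonzero(edges == -1)[0]
        starts_arr = np.array([s for s, _ in ivals])
        ends_arr = np.array([e for _, e in ivals])
        for rs, re in zip(run_starts, run_ends):
            pieces = _split_run(bounds[rs : re + 1], heights[rs:re], valley_ratio)
            for a_start, a_end in pieces:
                mask = (starts_arr < a_end) & (ends_arr > a_start)
                c = int(mask.sum())
                if c < min_c:
                    continue
                seg = (bounds[rs:re] >= a_start) & (bounds[rs:re] < a_end)
                height = int(heights[rs:re][seg].max()) if seg.any() else 0
                anchors.append(Anchor(chrom, a_start, a_end, c, height))
    return anchors


# ---------------------------------------------------------------------------
# Pair counting
# ---------------------------------------------------------------------------


class _AnchorLookup:
    """Non-overlapping sorted anchors per chromosome -> overlap range query."""

    def __init__(self, anchors: Sequence[Anchor]):
        self.anchors = list(anchors)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per: dict[str, list[int]] = {}
        for i, a in enumerate(self.anchors):
            per.setdefault(a.chrom, []).append(i)
        for chrom, idxs in per.items():
            idxs.sort(key=lambda i: self.anchors[i].start)
            starts = np.array([self.anchors[i].start for i in idxs])
            ends = np.array([self.anchors[i].end for i in idxs])
            self._by_chrom[chrom] = (starts, ends, np.array(idxs))

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        if chrom not in self._by_chrom:
            return []
        starts, ends, idxs = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return [int(i) for i in idxs[lo:hi]]


def pair_counts(
    extended_pets: Sequence[tuple[tuple[str, int, int], tuple[str, int, int]]],
    anchors: Sequence[Anchor],
) -> dict[tuple[int, int], int]:
    """I_AB per anchor pair: a PET links (A, B) when one extended tag
    overlaps A and the other overlaps B.  Keys are canonically ordered
    anchor indices; both-tags-in-one-anchor PETs are self-loops and do not
    count."""
    lookup = _AnchorLookup(anchors)
    counts: dict[tuple[int, int], int] = {}
    for (ca, sa, ea), (cb, sb, eb) in extended_pets:
        hits_a = lookup.overlapping(ca, sa, ea)
        hits_b = lookup.overlapping(cb, sb, eb)
        seen = set()
        for i in hits_a:
            for j in hits_b:
                if i == j:
                    continue
                key = (i, j) if i < j else (j, i)
                seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Hypergeometric model
# ---------------------------------------------------------------------------


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(n_pets: int, c_a: int, c_b: int, i_ab: int) -> float:
    """Upper-tail probability that anchors holding c_A and c_B of the 2N
    PET ends share at least i_AB links when the c_B ends are drawn at
    random: P(X >= i_AB) with X ~ Hypergeom(2N, c_A, c_B), in log space.

    The model assumes c_A, c_B << N (documented, not enforced).
    """
    two_n = 2 * n_pets
    if c_a > two_n or c_b > two_n:
        raise ValueError("anchor end counts exceed the 2N end pool")
    upper = min(c_a, c_b)
    if i_ab > upper:
        raise ValueError("i_ab exceeds min(c_a, c_b)")
    lower_support = max(0, c_b - (two_n - c_a))
    if lower_support > upper:
        raise ValueError("impossible support: c_b - i > 2N - c_a for all i")
    i = np.arange(max(i_ab, lower_support), upper + 1, dtype=float)
    if len(i) == 0:
        return 0.0
    log_pmf = (
        _log_comb(c_a, i)
        + _log_comb(two_n - c_a, c_b - i)
        - _log_comb(two_n, np.float64(c_b))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def score_pairs(
    counts: dict[tuple[int, int], int],
    anchors: Sequence[Anchor],
    n_pets: int,
) -> list[InteractionCluster]:
    clusters = []
    for (i, j), i_ab in sorted(counts.items()):
        a, b = anchors[i], anchors[j]
        p = hypergeom_pvalue(n_pets, a.c, b.c, min(i_ab, min(a.c, b.c)))
        clusters.append(InteractionCluster(a, b, i_ab, p))
    return clusters


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------


def permutation_fdr(
    clusters: Sequence[InteractionCluster],
    extended_pets: Sequence[tuple[tuple[str, int, int], tuple[str, int, int]]],
    anchors: Sequence[Anchor],
    n_perm: int = 10,
    seed: int = 0,
) -> list[float]:
    """Empirical FDR per cluster: ends of the PETs are pooled and randomly
    re-paired (each end used exactly once), pair counting and hypergeometric
    scoring re-run against the same anchors; FDR at threshold T = (mean
    permuted count of p <= T) / (observed count of p <= T), evaluated at
    each observed cluster's p, capped at 1."""
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    obs_p = np.array([c.p_hyp for c in clusters])
    if len(obs_p) == 0:
        return []
    n = len(extended_pets)
    ends = [iv for pair in extended_pets for iv in pair]
    rng = np.random.default_rng(seed)
    perm_ps: list[np.ndarray] = []
    for _ in range(n_perm):
        order = rng.permutation(2 * n)
        permuted = [(ends[order[2 * i]], ends[order[2 * i + 1]]) for i in range(n)]
        counts = pair_counts(permuted, anchors)
        ps = [
            hypergeom_pvalue(
                n, anchors[i].c, anchors[j].c, min(v, anchors[i].c, anchors[j].c)
            )
            for (i, j), v in counts.items()
        ]
        perm_ps.append(np.array(ps))
    all_perm = np.sort(np.concatenate(perm_ps)) if perm_ps else np.empty(0)
    obs_sorted = np.sort(obs_p)
    fdrs = []
    for p in obs_p:
        n_obs = int(np.searchsorted(obs_sorted, p, side="right"))
        n_perm_le = int(np.searchsorted(all_perm, p, side="right")) / n_perm
        fdrs.append(min(1.0, n_perm_le / n_obs))
    return fdrs


def call_interactions(
    clusters: Sequence[InteractionCluster],
    min_pets: int = 3,
    fdr_max: float = 0.05,
) -> tuple[list[InteractionCluster], list[InteractionCluster]]:
    """Keep clusters with I_AB >= min_pets and FDR below the threshold;
    returns (intra-chromosomal, inter-chromosomal) lists."""
    intra, inter = [], []
    for c in clusters:
        if c.i_ab < min_pets or not (c.fdr < fdr_max):
            continue
        (intra if c.span is not None else inter).append(c)
    return intra, inter


def filter_interactions(
    interactions: Sequence[InteractionCluster],
    drop_chroms: set[str] = frozenset({"chrY", "chrM"}),
    blacklist: Iterable[tuple[str, int, int]] | None = None,
    sv_breakpoints: Iterable[tuple[str, int, int]] | None = None,
    sv_window_bp: int = 10_000,
) -> list[InteractionCluster]:
    """Remove interactions whose anchors sit on dropped chromosomes,
    overlap the blacklist, or fall within ``sv_window_bp`` of a structural
    variation breakpoint (rearrangements masquerade as interactions)."""
    bl: dict[str, IntervalTree] = {}
    for chrom, s, e in blacklist or []:
        bl.setdefault(chrom, IntervalTree()).addi(s, e)
    sv: dict[str, IntervalTree] = {}
    for chrom, s, e in sv_breakpoints or []:
        sv.setdefault(chrom, IntervalTree()).addi(s - sv_window_bp, e + sv_window_bp)

    def bad(a: Anchor) -> bool:
        if a.chrom in drop_chroms:
            return True
        if a.chrom in bl and bl[a.chrom].overlap(a.start, a.end):
            return True
        if a.chrom in sv and sv[a.chrom].overlap(a.start, a.end):
            return True
        return False

    return [c for c in interactions if not (bad(c.anchor_a) or bad(c.anchor_b))]
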