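"""Binding-site calling from self-ligation PETs.

Each self-ligation PET delimits the sonicated ChIP fragment that produced
it.  ChIP-enriched loci accumulate overlapping fragments, while background
fragments scatter; connected components of overlapping fragments are the
candidate sites, scored by their fragment count k.  The null (how often a
random genome-wide placement of the same number and lengths of fragments
produces a cluster of size >= k) is estimated by Monte-Carlo simulation and
summarised as an expected-over-observed FDR per k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .classify import genomic_span
from .mapping import MappedPET


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int  # 0-based half-open

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Cluster:
    chrom: str
    start: int  # hull
    end: int
    k: int
    summit_start: int
    summit_end: int
    depth: int  # max stacking depth


@dataclass
class BindingSite:
    chrom: str
    start: int
    end: int
    summit_start: int
    summit_end: int
    k: int
    fdr: float
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class MonteCarloNull:
    """Null model: fragments placed uniformly on the mappable genome
    (chromosome lengths minus excluded regions), lengths resampled with
    replacement from the observed pool."""

    chrom_lengths: dict[str, int]
    iterations: int = 10
    seed: int = 0
    excluded: tuple[tuple[str, int, int], ...] = ()

    def mappable_segments(self) -> list[tuple[str, int, int]]:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.excluded:
            by_chrom.setdefault(c, []).append((s, e))
        segments: list[tuple[str, int, int]] = []
        for chrom, length in self.chrom_lengths.items():
            cursor = 0
            for s, e in sorted(by_chrom.get(chrom, [])):
                if s > cursor:
                    segments.append((chrom, cursor, min(s, length)))
                cursor = max(cursor, e)
            if cursor < length:
                segments.append((chrom, cursor, length))
        return segments


def self_pets_to_fragments(self_pets: Iterable[MappedPET]) -> list[Fragment]:
    """One fragment per self-ligation PET, spanning the outermost tag
    coordinates."""
    frags = []
    for p in self_pets:
        span = genomic_span(p)
        if span is None:
            raise ValueError(f"self-ligation PET {p.id} spans two chromosomes")
        start = min(p.head.pos, p.tail.pos)
        frags.append(Fragment(p.head.chrom, start, start + span))
    return frags


def _summit(starts: np.ndarray, ends: np.ndarray) -> tuple[int, int, int]:
    """Max-depth subinterval of a stack of intervals (leftmost on ties)."""
    events = np.concatenate(
        [np.stack([starts, np.ones_like(starts)], 1), np.stack([ends, -np.ones_like(ends)], 1)]
    )
    order = np.lexsort((-events[:, 1], events[:, 0]))  # starts before ends at ties
    events = events[order]
    depth = np.cumsum(events[:, 1])
    best = depth.max()
    i = int(np.argmax(depth))
    return int(events[i, 0]), int(events[i + 1, 0]), int(best)


def cluster_fragments(fragments: Sequence[Fragment]) -> list[Cluster]:
    """Connected components under >=1 bp interval overlap (half-open; no
    bookended merging), per chromosome."""
    clusters: list[Cluster] = []
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom in sorted(by_chrom):
        frs = sorted(by_chrom[chrom], key=lambda f: (f.start, f.end))
        group: list[Fragment] = []
        reach = -1
        for f in frs + [None]:  # type: ignore[list-item]
            if f is not None and (not group or f.start < reach):
                group.append(f)
                reach = max(reach, f.end)
            else:
                if group:
                    starts = np.array([g.start for g in group])
                    ends = np.array([g.end for g in group])
                    ss, se, d = _summit(starts, ends)
                    clusters.append(
                        Cluster(chrom, int(starts.min()), int(ends.max()), len(group), ss, se, d)
                    )
                if f is not None:
                    group = [f]
                    reach = f.end
    return clusters


def cluster_sizes_from_arrays(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Cluster sizes only, vectorised (for the Monte-Carlo null); intervals
    must all lie on one coordinate axis."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    reach = np.maximum.accumulate(e)
    breaks = np.nonzero(s[1:] >= reach[:-1])[0] + 1
    bounds = np.concatenate([[0], breaks, [len(s)]])
    return np.diff(bounds)


def place_random_fragments(
    rng: np.random.Generator,
    n: int,
    length_pool: np.ndarray,
    segments: list[tuple[str, int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniformly place ``n`` fragments (lengths resampled from the pool)
    on the mappable segments; returns (segment index, start, end) arrays
    on a per-segment coordinate axis."""
    seg_lens = np.array([e - s for _, s, e in segments], dtype=float)
    lengths = rng.choice(length_pool, size=n, replace=True)
    seg_idx = rng.choice(len(segments), size=n, p=seg_lens / seg_lens.sum())
    room = np.maximum(seg_lens[seg_idx] - lengths, 1)
    starts = (rng.random(n) * room).astype(np.int64)
    ends = starts + np.minimum(lengths, seg_lens[seg_idx]).astype(np.int64)
    return seg_idx, starts, ends


def simulate_null_cluster_sizes(
    rng: np.random.Generator,
    n_fragments: int,
    length_pool: np.ndarray,
    segments: list[tuple[str, int, int]],
) -> np.ndarray:
    """One Monte-Carlo iteration: place fragments and return cluster sizes."""
    seg_idx, starts, ends = place_random_fragments(rng, n_fragments, length_pool, segments)
    sizes = []
    for i in np.unique(seg_idx):
        mask = seg_idx == i
        sizes.append(cluster_sizes_from_arrays(starts[mask], ends[mask]))
    return np.concatenate(sizes) if sizes else np.empty(0, dtype=np.int64)


def mc_fdr(
    observed_clusters: Sequence[Cluster],
    n_fragments: int,
    fragment_length_pool: Sequence[int],
    null: MonteCarloNull,
) -> dict[int, float]:
    """FDR(k) = mean simulated count of clusters of size >= k over the
    observed count, capped at 1 and made non-increasing in k (cumulative
    max from high k).  k values with no observed cluster are omitted (NA)."""
    if null.iterations < 1:
        raise ValueError("need at least one Monte-Carlo iteration")
    pool = np.asarray(fragment_length_pool, dtype=np.int64)
    if len(pool) == 0:
        raise ValueError("empty fragment length pool")
    segments = null.mappable_segments()
    seg_chroms = {c for c, _, _ in segments}
    for cl in observed_clusters:
        if cl.chrom not in seg_chroms:
            raise ValueError(f"cluster chromosome {cl.chrom} outside the mappable model")

    obs_k = np.array([c.k for c in observed_clusters], dtype=np.int64)
    if len(obs_k) == 0:
        return {}
    kmax = int(obs_k.max())
    obs_ge = np.array([(obs_k >= k).sum() for k in range(1, kmax + 1)], dtype=float)

    rng = np.random.default_rng(null.seed)
    sim_ge = np.zeros(kmax, dtype=float)
    for _ in range(null.iterations):
        sizes = simulate_null_cluster_sizes(rng, n_fragments, pool, segments)
        for k in range(1, kmax + 1):
            sim_ge[k - 1] += (sizes >= k).sum()
    sim_ge /= null.iterations

    fdr = np.minimum(sim_ge / obs_ge, 1.0)
    fdr[obs_ge == 0] = np.nan
    # enforce FDR(k) >= FDR(k+1): sweep from high k down, carrying the max
    for k in range(kmax - 2, -1, -1):
        if not isnan(fdr[k]) and not isnan(fdr[k + 1]):
            fdr[k] = max(fdr[k], fdr[k + 1])
    return {k + 1: float(fdr[k]) for k in range(kmax) if obs_ge[k] > 0}


def call_sites(
    clusters: Sequence[Cluster],
    fdr_by_k: dict[int, float],
    fdr_threshold: float = 0.01,
) -> list[BindingSite]:
    """Clusters with FDR(k) below the threshold become binding sites; the
    enrichment score of a site is its fragment count k."""
    sites = []
    for c in clusters:
        fdr = fdr_by_k.get(c.k, float("nan"))
        if not isnan(fdr) and fdr < fdr_threshold:
            sites.append(
                BindingSite(c.chrom, c.start, c.end, c.summit_start, c.summit_end, c.k, fdr)
            )
    return sites


def _bed_tree(intervals: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def read_bed3(path: str) -> list[tuple[str, int, int]]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: int, 2: int},
    )
    return list(df.itertuples(index=False, name=None))


def filter_sites(
    sites: Sequence[BindingSite],
    drop_chroms: set[str] = frozenset({"chrY"}),
    blacklist: Iterable[tuple[str, int, int]] | None = None,
    amplification: Iterable[tuple[str, int, int]] | None = None,
) -> tuple[list[BindingSite], dict[str, int]]:
    """Drop sites on excluded chromosomes or overlapping the blacklist
    (satellite repeats); sites overlapping known amplification regions are
    kept but flagged ``amplification_suspect``."""
    bl = _bed_tree(blacklist) if blacklist else {}
    amp = _bed_tree(amplification) if amplification else {}
    kept: list[BindingSite] = []
    removed = {"drop_chrom": 0, "blacklist": 0}
    for s in sites:
        if s.chrom in drop_chroms:
            removed["drop_chrom"] += 1
            continue
        if s.chrom in bl and bl[s.chrom].overlap(s.start, s.end):
            removed["blacklist"] += 1
            continue
        if s.chrom in amp and amp[s.chrom].overlap(s.start, s.end):
            s.flags.add("amplification_suspect")
        kept.append(s)
    return kept, removed


def site_pet_coverage(
    sites: Sequence[BindingSite], self_pets: Sequence[MappedPET]
) -> tuple[int, float]:
    """How many self-ligation PETs have their fragment overlap any called
    site; returns (count, fraction of all self-ligation PETs)."""
    if not self_pets:
        return 0, 0.0
    trees = _bed_tree((s.chrom, s.start, s.end) for s in sites)
    covered = 0
    for f in self_pets_to_fragments(self_pets):
        if f.chrom in trees and trees[f.chrom].overlap(f.start, f.end):
            covered += 1
    return covered, covered / len(self_pets)
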