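"""Synthetic ChIA-PET library generator with known ground truth.

Emulates the data model of a ChIA-PET experiment end to end: a random
reference genome; planted protein binding sites that shed overlapping
self-ligation fragments; planted loops that shed inter-ligation PETs
connecting two anchor points; background self-ligation, long-span
intra-chromosomal, inter-chromosomal and fully random PETs; chimeric (AB)
PETs built by randomly re-pairing ends across complexes (so they carry no
loop signal by construction); ambiguous pairs with unreadable linkers.
Reads follow the tag + half-linker layout (20 nt genomic tag, 16 nt
half-linker with the CG/AT barcode) with configurable substitution errors.
Every emitted pair carries exactly one truth record.

Fragment spans follow truncated discrete power laws: a steep law for
sonicated fragments (self-ligation population) and a shallow law for
intra-chromosomal interaction distances, which is what makes the two-line
log-log span histogram — and its fitted intersection — reproducible from
synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .linker import (
    Composition,
    LinkerSpec,
    ReadPair,
)
from .mapping import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the desk-scale synthetic library.

    Defaults: a 20 Mb genome over 4 chromosomes, 50,000 PETs, 30 planted
    sites (depth ~ Poisson(30)), 15 planted loops (10 PETs each), 30%
    chimeric and 5% ambiguous pairs, 0.5% substitution error.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 5_000_000 for i in range(1, 5)}
    )
    n_pets: int = 50_000
    n_sites: int = 30
    site_depth_mean: float = 30.0
    n_loops: int = 15
    loop_depth: int = 10
    # background mixture: self-ligation / intra-chromosomal inter-ligation /
    # inter-chromosomal / fully random noise
    mixture: tuple[float, float, float, float] = (0.45, 0.15, 0.35, 0.05)
    self_exponent: float = 2.5
    self_span_range: tuple[int, int] = (200, 3000)
    inter_exponent: float = 1.2
    inter_span_range: tuple[int, int] = (3000, 2_000_000)
    chimeric_fraction: float = 0.30
    ambiguous_fraction: float = 0.05
    error_rate: float = 0.005
    linker: LinkerSpec = field(default_factory=LinkerSpec)
    seed: int = 7
    min_feature_separation: int = 20_000
    edge_margin: int = 10_000

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        for frac in (self.chimeric_fraction, self.ambiguous_fraction):
            if not 0 <= frac < 1:
                raise ValueError("fractions must lie in [0, 1)")
        if any(l < 1000 for l in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be >= 1 kb")


@dataclass
class TruthSet:
    sites: list[tuple[str, int, int]]  # planted site intervals
    loops: list[tuple[str, int, str, int]]  # (chromA, posA, chromB, posB)
    reads: pd.DataFrame  # one row per emitted read pair


@dataclass
class SimLibrary:
    genome: dict[str, str]
    pairs: list[ReadPair]
    truth: TruthSet
    config: SimConfig


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def simulate_genome(
    chrom_sizes: dict[str, int], seed: int | np.random.Generator = 0
) -> dict[str, str]:
    """Uniform random ACGT genome, deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome = {}
    for name, size in chrom_sizes.items():
        if size < 1000:
            raise ValueError(f"chromosome {name} shorter than 1 kb")
        codes = rng.integers(0, 4, size=size, dtype=np.uint8)
        genome[name] = _BASES[codes].tobytes().decode()
    return genome


class PowerLawSampler:
    """Discrete truncated power law P(k) ~ k^-exponent on [lo, hi] with a
    precomputed inverse-CDF table."""

    def __init__(self, exponent: float, span_range: tuple[int, int]):
        if exponent <= 1:
            raise ValueError("exponent must exceed 1")
        lo, hi = span_range
        if not 0 < lo <= hi:
            raise ValueError("invalid span range")
        self.lo = lo
        support = np.arange(lo, hi + 1, dtype=np.float64)
        cdf = np.cumsum(support**-exponent)
        self._cdf = cdf / cdf[-1]

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0, dtype=np.int64)
        u = rng.random(n)
        return (self.lo + np.searchsorted(self._cdf, u, side="left")).astype(np.int64)


def sample_spans(
    exponent: float,
    span_range: tuple[int, int],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Discrete truncated power-law samples via inverse CDF."""
    return PowerLawSampler(exponent, span_range).draw(rng, n)


def _place_features(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n: int,
    taken: list[tuple[str, int]],
    min_sep: int,
    margin: int,
    max_tries: int = 1000,
) -> list[tuple[str, int]]:
    """Random feature points with a minimum separation from each other and
    from already-taken points; bounded retries, then error."""
    chroms = list(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: list[tuple[str, int]] = []
    for _ in range(n):
        for _try in range(max_tries):
            ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
            chrom = chroms[ci]
            pos = int(rng.integers(margin, chrom_sizes[chrom] - margin))
            if all(
                c != chrom or abs(p - pos) >= min_sep for c, p in taken + placed
            ):
                placed.append((chrom, pos))
                break
        else:
            raise RuntimeError("could not place features without collision")
    return placed


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

_END = tuple[str, int, str]  # (chrom, tag start, strand)


def _self_pet(
    rng: np.random.Generator, chrom: str, point: int, span: int, chrom_len: int, tag: int
) -> tuple[_END, _END]:
    """Head-to-tail tag pair of a fragment of the given span covering
    ``point`` (the ChIP pull-down geometry)."""
    span = max(span, 2 * tag)
    lo = max(0, point - span + 1)
    hi = min(point, chrom_len - span)
    start = int(rng.integers(lo, max(lo, hi) + 1))
    return (chrom, start, "+"), (chrom, start + span - tag, "-")


def _loop_end(
    rng: np.random.Generator, chrom: str, point: int, chrom_len: int, tag: int, ext: int = 200
) -> _END:
    u = int(rng.integers(0, ext - tag))
    if rng.random() < 0.5:
        start = point - u
    else:
        start = point + u - tag
    start = min(max(0, start), chrom_len - tag)
    return (chrom, start, "+" if rng.random() < 0.5 else "-")


def _uniform_end(rng: np.random.Generator, chrom: str, chrom_len: int, tag: int) -> _END:
    start = int(rng.integers(0, chrom_len - tag + 1))
    return (chrom, start, "+" if rng.random() < 0.5 else "-")


class _PetFactory:
    """Draws labelled (end1, end2) pairs from the study's generative mix."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator,
                 sites: list[tuple[str, int]], loops: list[tuple[str, int, str, int]]):
        self.cfg = cfg
        self.rng = rng
        self.sites = sites
        self.loops = loops
        self.chroms = list(cfg.chrom_sizes)
        self.lens = np.array([cfg.chrom_sizes[c] for c in self.chroms], dtype=float)
        self.tag = cfg.linker.tag_length
        self._probs = self.lens / self.lens.sum()
        self._self_sampler = PowerLawSampler(cfg.self_exponent, cfg.self_span_range)
        self._intra_samplers: dict[tuple[int, int], PowerLawSampler] = {}

    def _intra_sampler(self, span_range: tuple[int, int]) -> PowerLawSampler:
        if span_range not in self._intra_samplers:
            self._intra_samplers[span_range] = PowerLawSampler(
                self.cfg.inter_exponent, span_range
            )
        return self._intra_samplers[span_range]

    def _rand_chrom(self) -> str:
        return self.chroms[int(self.rng.choice(len(self.chroms), p=self._probs))]

    def site_self(self, site_idx: int) -> tuple[_END, _END, str, str]:
        chrom, point = self.sites[site_idx]
        span = int(self._self_sampler.draw(self.rng, 1)[0])
        e1, e2 = _self_pet(self.rng, chrom, point, span, self.cfg.chrom_sizes[chrom], self.tag)
        return e1, e2, "self_ligation", f"site:{site_idx}"

    def loop_pet(self, loop_idx: int) -> tuple[_END, _END, str, str]:
        ca, pa, cb, pb = self.loops[loop_idx]
        e1 = _loop_end(self.rng, ca, pa, self.cfg.chrom_sizes[ca], self.tag)
        e2 = _loop_end(self.rng, cb, pb, self.cfg.chrom_sizes[cb], self.tag)
        cat = "intra_inter" if ca == cb else "inter_chrom"
        return e1, e2, cat, f"loop:{loop_idx}"

    def background(self) -> tuple[_END, _END, str, str]:
        r = self.rng.random()
        p_self, p_intra, p_inter, _ = self.cfg.mixture
        if r < p_self:
            chrom = self._rand_chrom()
            clen = self.cfg.chrom_sizes[chrom]
            span = int(self._self_sampler.draw(self.rng, 1)[0])
            point = int(self.rng.integers(span, clen - span))
            e1, e2 = _self_pet(self.rng, chrom, point, span, clen, self.tag)
            return e1, e2, "self_ligation", "background_self"
        if r < p_self + p_intra:
            chrom = self._rand_chrom()
            clen = self.cfg.chrom_sizes[chrom]
            lo, hi = self.cfg.inter_span_range
            hi = min(hi, clen - 2 * self.tag - 1)
            span = int(self._intra_sampler((lo, hi)).draw(self.rng, 1)[0])
            s1 = int(self.rng.integers(0, clen - span - self.tag))
            e1 = (chrom, s1, "+" if self.rng.random() < 0.5 else "-")
            e2 = (chrom, s1 + span, "+" if self.rng.random() < 0.5 else "-")
            return e1, e2, "intra_inter", "background_intra"
        if r < p_self + p_intra + p_inter:
            c1 = self._rand_chrom()
            c2 = self._rand_chrom()
            while c2 == c1:
                c2 = self._rand_chrom()
            e1 = _uniform_end(self.rng, c1, self.cfg.chrom_sizes[c1], self.tag)
            e2 = _uniform_end(self.rng, c2, self.cfg.chrom_sizes[c2], self.tag)
            return e1, e2, "inter_chrom", "background_inter"
        c1 = self._rand_chrom()
        c2 = self._rand_chrom()
        e1 = _uniform_end(self.rng, c1, self.cfg.chrom_sizes[c1], self.tag)
        e2 = _uniform_end(self.rng, c2, self.cfg.chrom_sizes[c2], self.tag)
        return e1, e2, "noise", "background_noise"


def _tag_seq(genome: dict[str, str], end: _END, tag_length: int) -> str:
    chrom, start, strand = end
    seq = genome[chrom][start : start + tag_length]
    return revcomp(seq) if strand == "-" else seq


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def _random_linker(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length, dtype=np.uint8)].tobytes().decode()


def generate_library(config: SimConfig | None = None) -> SimLibrary:
    """Build the full synthetic library: genome, planted features, reads
    and the per-read truth table.  Deterministic per ``config.seed``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome = simulate_genome(cfg.chrom_sizes, rng)

    site_points = _place_features(
        rng, cfg.chrom_sizes, cfg.n_sites, [], cfg.min_feature_separation, cfg.edge_margin
    )
    loop_anchor_points = _place_features(
        rng, cfg.chrom_sizes, 2 * cfg.n_loops, site_points,
        cfg.min_feature_separation, cfg.edge_margin,
    )
    loops: list[tuple[str, int, str, int]] = []
    for i in range(cfg.n_loops):
        (ca, pa), (cb, pb) = loop_anchor_points[2 * i], loop_anchor_points[2 * i + 1]
        loops.append((ca, pa, cb, pb))

    site_depths = rng.poisson(cfg.site_depth_mean, size=cfg.n_sites)
    site_depths = np.maximum(site_depths, 5)
    n_signal = int(site_depths.sum()) + cfg.n_loops * cfg.loop_depth
    n_ambig = int(round(cfg.ambiguous_fraction * cfg.n_pets))
    n_chim = int(round(cfg.chimeric_fraction * cfg.n_pets))
    n_background = cfg.n_pets - n_ambig - n_chim - n_signal
    if n_background < 0:
        raise ValueError("n_pets too small for the configured signal")

    factory = _PetFactory(cfg, rng, site_points, loops)
    drawn: list[tuple[_END, _END, str, str]] = []
    for i in range(cfg.n_sites):
        drawn += [factory.site_self(i) for _ in range(int(site_depths[i]))]
    for i in range(cfg.n_loops):
        drawn += [factory.loop_pet(i) for _ in range(cfg.loop_depth)]
    drawn += [factory.background() for _ in range(n_background)]

    # chimeric pool: draw source PETs from the same mix, then re-pair the
    # ends at random across complexes (destroys any loop pairing)
    w_sig = n_signal / max(1, n_signal + n_background)
    chim_source: list[tuple[_END, _END, str, str]] = []
    for _ in range(n_chim):
        if cfg.n_sites and rng.random() < w_sig:
            chim_source.append(factory.site_self(int(rng.integers(0, cfg.n_sites))))
        else:
            chim_source.append(factory.background())
    chim_ends: list[_END] = [e for rec in chim_source for e in rec[:2]]
    order = rng.permutation(len(chim_ends))
    chimeric: list[tuple[_END, _END, str, str]] = []
    for i in range(n_chim):
        e1 = chim_ends[order[2 * i]]
        e2 = chim_ends[order[2 * i + 1]]
        chimeric.append((e1, e2, "chimeric", "chimeric"))

    ambiguous = [factory.background()[:2] + ("ambiguous", "ambiguous") for _ in range(n_ambig)]

    records = (
        [(rec, "non_chimeric") for rec in drawn]
        + [(rec, "chimeric") for rec in chimeric]
        + [(rec, "ambiguous") for rec in ambiguous]
    )
    perm = rng.permutation(len(records))

    spec = cfg.linker
    pairs: list[ReadPair] = []
    rows = []
    for out_i, rec_i in enumerate(perm):
        (e1, e2, category, origin), kind = records[rec_i]
        pid = f"pet{out_i:06d}"
        if rng.random() < 0.5:  # randomise which end is read 1
            e1, e2 = e2, e1
        t1 = _tag_seq(genome, e1, spec.tag_length)
        t2 = _tag_seq(genome, e2, spec.tag_length)
        if kind == "non_chimeric":
            half = spec.half_linker_a if rng.random() < 0.5 else spec.half_linker_b
            l1 = l2 = half
            comp = "AA" if half == spec.half_linker_a else "BB"
        elif kind == "chimeric":
            if rng.random() < 0.5:
                l1, l2 = spec.half_linker_a, spec.half_linker_b
            else:
                l1, l2 = spec.half_linker_b, spec.half_linker_a
            comp = "AB"
        else:
            l1 = _random_linker(rng, spec.linker_length)
            l2 = _random_linker(rng, spec.linker_length)
            comp = "ambiguous"
        seq1 = _mutate(t1 + l1, rng, cfg.error_rate)
        seq2 = _mutate(t2 + l2, rng, cfg.error_rate)
        pairs.append(ReadPair(pid, seq1, seq2, "I" * len(seq1), "I" * len(seq2)))
        rows.append(
            {
                "id": pid,
                "composition": comp,
                "category": category,
                "origin": origin,
                "chrom1": e1[0], "pos1": e1[1], "strand1": e1[2],
                "chrom2": e2[0], "pos2": e2[1], "strand2": e2[2],
            }
        )

    truth = TruthSet(
        sites=[(c, max(0, p - 250), p + 250) for c, p in site_points],
        loops=loops,
        reads=pd.DataFrame(rows),
    )
    return SimLibrary(genome=genome, pairs=pairs, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------


def write_library(lib: SimLibrary, outdir: str) -> dict[str, str]:
    """Write ref.fa, reads_{1,2}.fastq.gz and the truth tables; returns the
    path map."""
    import gzip
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": str(out / "ref.fa"),
        "fq1": str(out / "reads_1.fastq.gz"),
        "fq2": str(out / "reads_2.fastq.gz"),
        "sites": str(out / "truth_sites.bed"),
        "loops": str(out / "truth_loops.tsv"),
        "reads": str(out / "truth_reads.tsv"),
    }
    with open(paths["ref"], "w") as fa:
        for name, seq in lib.genome.items():
            fa.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")
    for key, idx in (("fq1", 0), ("fq2", 1)):
        with gzip.open(paths[key], "wt") as fq:
            for p in lib.pairs:
                seq = (p.seq1, p.seq2)[idx]
                qual = (p.qual1, p.qual2)[idx] or "I" * len(seq)
                fq.write(f"@{p.id}/{idx + 1}\n{seq}\n+\n{qual}\n")
    with open(paths["sites"], "w") as bed:
        for i, (c, s, e) in enumerate(lib.truth.sites):
            bed.write(f"{c}\t{s}\t{e}\tsite:{i}\n")
    with open(paths["loops"], "w") as tsv:
        tsv.write("chromA\tposA\tchromB\tposB\n")
        for ca, pa, cb, pb in lib.truth.loops:
            tsv.write(f"{ca}\t{pa}\t{cb}\t{pb}\n")
    lib.truth.reads.to_csv(paths["reads"], sep="\t", index=False)
    return paths
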