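"""Short-tag mapping with at most one mismatch.

The 20 nt tags coming out of linker filtering are placed on the reference
genome in two tiers: exact matches first; only if a tag has no exact match
anywhere is a single mismatch allowed.  A tag with one hit in its tier is
"unique", with several "multiple", with none "non-mappable"; PETs are kept
only when both tags map uniquely.  The index is a sorted-code k-mer table
over both strands; the one-mismatch tier uses the pigeonhole rule that any
<=1-mismatch hit matches at least one half of the tag exactly.  For genomes
too large for in-memory indexing, pre-computed alignments can be imported
from SAM or BED instead.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .linker import Composition

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MapStatus(Enum):
    UNIQUE = "unique"
    MULTIPLE = "multiple"
    NON_MAPPABLE = "non_mappable"


@dataclass(frozen=True)
class TagAlignment:
    status: MapStatus
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost
    strand: str | None = None  # '+'/'-'
    mismatches: int | None = None  # 0 or 1


@dataclass(frozen=True)
class MappedPET:
    """A PET with both tags uniquely mapped; head has the lexicographically
    smaller (chrom, pos)."""

    id: str
    head: TagAlignment
    tail: TagAlignment
    composition: Composition = Composition.AA


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_genome(path: str) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered name -> uppercase sequence map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes for every k-mer window; windows containing N get -1."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = code * 4 + enc[j : j + n]
    # invalidate windows containing an N (code 4)
    bad = enc >= 4
    if bad.any():
        bad_any = np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32))[
            k - 1 : k - 1 + n
        ]
        code[bad_any > 0] = -1
    return code


class TagIndex:
    """Exact + one-mismatch lookup over both strands of a genome.

    Stores sorted full-tag codes and sorted half-tag codes with companion
    position arrays; a reverse-strand query is made by looking up the
    reverse complement of the tag in the same forward-strand tables.
    """

    def __init__(self, genome: dict[str, str], tag_length: int = 20):
        if not genome:
            raise ValueError("genome is empty")
        if tag_length % 2 != 0:
            raise ValueError("tag_length must be even (two equal half-seeds)")
        self.tag_length = tag_length
        self.half = tag_length // 2
        self.chrom_names: list[str] = []
        self.chrom_lengths: dict[str, int] = {}
        encs: list[np.ndarray] = []
        offsets: list[int] = []
        off = 0
        for name, seq in genome.items():
            if len(seq) < tag_length:
                logger.warning(
                    "chromosome %s shorter than tag length %d: skipped",
                    name,
                    tag_length,
                )
                continue
            self.chrom_names.append(name)
            self.chrom_lengths[name] = len(seq)
            encs.append(_encode(seq))
            offsets.append(off)
            off += len(seq) + tag_length  # spacer keeps windows within one chrom
        if not self.chrom_names:
            raise ValueError("no chromosome is long enough to index")
        self._offsets = np.array(offsets, dtype=np.int64)
        self._enc = np.full(off, 4, dtype=np.uint8)
        for o, e in zip(offsets, encs):
            self._enc[o : o + len(e)] = e

        full = _window_codes(self._enc, tag_length)
        halfc = _window_codes(self._enc, self.half)
        self._full_order = np.argsort(full, kind="stable")
        self._full_sorted = full[self._full_order]
        self._half_order = np.argsort(halfc, kind="stable")
        self._half_sorted = halfc[self._half_order]

    # -- coordinate translation ------------------------------------------
    def _to_chrom(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        return self.chrom_names[i], int(gpos - self._offsets[i])

    # -- lookups ----------------------------------------------------------
    def _exact_positions(self, code: int) -> np.ndarray:
        if code < 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._full_sorted, code, side="left")
        hi = np.searchsorted(self._full_sorted, code, side="right")
        return self._full_order[lo:hi]

    def _half_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._half_sorted, code, side="left")
        hi = np.searchsorted(self._half_sorted, code, side="right")
        return self._half_order[lo:hi]

    def _mismatch_counts(self, starts: np.ndarray, tag_enc: np.ndarray) -> np.ndarray:
        k = self.tag_length
        idx = starts[:, None] + np.arange(k)[None, :]
        window = self._enc[idx]
        # N on either side counts as mismatch (genome N never equals tag N)
        return np.sum(
            (window != tag_enc[None, :]) | (window >= 4) | (tag_enc[None, :] >= 4),
            axis=1,
        )


def _tag_code(enc: np.ndarray) -> int:
    if (enc >= 4).any():
        return -1
    code = 0
    for v in enc:
        code = code * 4 + int(v)
    return code


def map_tag(index: TagIndex, tag: str) -> TagAlignment:
    """Map one tag: exact tier first, then <=1 mismatch; hits on either
    strand count, a forward hit and its reverse-strand shadow at the same
    locus count once."""
    if len(tag) != index.tag_length:
        raise ValueError(f"tag length {len(tag)} != index tag length {index.tag_length}")
    fwd = _encode(tag)
    rev = _encode(revcomp(tag))

    # exact tier
    hits: dict[int, str] = {}
    for enc, strand in ((fwd, "+"), (rev, "-")):
        for g in index._exact_positions(_tag_code(enc)):
            hits.setdefault(int(g), strand)
    if len(hits) == 1:
        g, strand = next(iter(hits.items()))
        chrom, pos = index._to_chrom(g)
        return TagAlignment(MapStatus.UNIQUE, chrom, pos, strand, 0)
    if len(hits) > 1:
        return TagAlignment(MapStatus.MULTIPLE)

    # one-mismatch tier via half seeds
    h = index.half
    hits1: dict[int, tuple[str, int]] = {}
    for enc, strand in ((fwd, "+"), (rev, "-")):
        cand: list[np.ndarray] = []
        c1 = _tag_code(enc[:h])
        c2 = _tag_code(enc[h:])
        if c1 >= 0:
            cand.append(index._half_positions(c1))
        if c2 >= 0:
            cand.append(index._half_positions(c2) - h)
        if not cand:
            continue
        starts = np.unique(np.concatenate(cand))
        starts = starts[(starts >= 0) & (starts + index.tag_length <= len(index._enc))]
        if len(starts) == 0:
            continue
        mm = index._mismatch_counts(starts, enc)
        for g in starts[mm <= 1]:
            chrom, pos = index._to_chrom(int(g))
            if pos + index.tag_length > index.chrom_lengths[chrom]:
                continue  # window leaks into the inter-chromosome spacer
            hits1.setdefault(int(g), (strand, 1))
    if len(hits1) == 1:
        g, (strand, mm1) = next(iter(hits1.items()))
        chrom, pos = index._to_chrom(g)
        return TagAlignment(MapStatus.UNIQUE, chrom, pos, strand, 1)
    if len(hits1) > 1:
        return TagAlignment(MapStatus.MULTIPLE)
    return TagAlignment(MapStatus.NON_MAPPABLE)


def map_tags(index: TagIndex, tags: Sequence[str]) -> list[TagAlignment]:
    """Vectorised batch mapping: the exact tier is resolved for all tags at
    once; only tags without an exact hit fall through to the per-tag
    one-mismatch path."""
    n = len(tags)
    out: list[TagAlignment | None] = [None] * n
    codes_f = np.empty(n, dtype=np.int64)
    codes_r = np.empty(n, dtype=np.int64)
    for i, t in enumerate(tags):
        if len(t) != index.tag_length:
            raise ValueError(f"tag {i} has length {len(t)}")
        codes_f[i] = _tag_code(_encode(t))
        codes_r[i] = _tag_code(_encode(revcomp(t)))

    def counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(index._full_sorted, codes, side="left")
        hi = np.searchsorted(index._full_sorted, codes, side="right")
        c = hi - lo
        c[codes < 0] = 0
        return c, lo

    cf, lof = counts(codes_f)
    cr, lor = counts(codes_r)
    palindrome = codes_f == codes_r
    total = np.where(palindrome, cf, cf + cr)
    for i in range(n):
        if total[i] == 1:
            if cf[i] == 1:
                g, strand = int(index._full_order[lof[i]]), "+"
            else:
                g, strand = int(index._full_order[lor[i]]), "-"
            chrom, pos = index._to_chrom(g)
            out[i] = TagAlignment(MapStatus.UNIQUE, chrom, pos, strand, 0)
        elif total[i] > 1:
            out[i] = TagAlignment(MapStatus.MULTIPLE)
    for i in range(n):
        if out[i] is None:
            out[i] = map_tag(index, tags[i])
    return out  # type: ignore[return-value]


def assemble_pets(
    tag1_alignments: Iterable[tuple[str, TagAlignment]],
    tag2_alignments: Iterable[tuple[str, TagAlignment]],
    compositions: dict[str, Composition] | None = None,
) -> tuple[list[MappedPET], Counter]:
    """Join two (pet_id, alignment) streams; keep PETs with both tags unique.

    Rejections are tallied by reason; an id present in only one stream
    counts as an orphan.
    """
    a1 = dict(tag1_alignments)
    a2 = dict(tag2_alignments)
    pets: list[MappedPET] = []
    rejects: Counter = Counter()
    for pid, al1 in a1.items():
        al2 = a2.get(pid)
        if al2 is None:
            rejects["orphan"] += 1
            continue
        bad = False
        for role, al in (("head", al1), ("tail", al2)):
            if al.status is not MapStatus.UNIQUE:
                rejects[f"{role}_{al.status.value}"] += 1
                bad = True
        if bad:
            continue
        comp = (compositions or {}).get(pid, Composition.AA)
        pets.append(make_mapped_pet(pid, al1, al2, comp))
    for pid in a2:
        if pid not in a1:
            rejects["orphan"] += 1
    return pets, rejects


def make_mapped_pet(
    pid: str, al1: TagAlignment, al2: TagAlignment, comp: Composition = Composition.AA
) -> MappedPET:
    """Canonical head/tail ordering by (chrom, pos)."""
    if (al1.chrom, al1.pos) <= (al2.chrom, al2.pos):
        head, tail = al1, al2
    else:
        head, tail = al2, al1
    return MappedPET(pid, head, tail, comp)


# ---------------------------------------------------------------------------
# Alignment import/export (large-genome path)
# ---------------------------------------------------------------------------


def _split_read_name(name: str) -> tuple[str, int]:
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    raise ValueError(f"read name {name!r} lacks /1 or /2 tag-role suffix")


def import_alignments(path: str, format: str = "SAM") -> Iterator[tuple[str, int, TagAlignment]]:
    """Yield (pet_id, tag_role, TagAlignment) from SAM or BED6.

    SAM: the unmapped flag -> non_mappable; secondary/supplementary records
    or MAPQ 0 -> multiple; otherwise unique with strand from the flag and
    mismatches from the NM tag.  BED6 rows are taken as unique.  Malformed
    rows are logged and skipped.
    """
    fmt = format.upper()
    if fmt == "SAM":
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for rec in sam:
                try:
                    pid, role = _split_read_name(rec.query_name)
                except ValueError as exc:
                    logger.warning("skipping SAM row: %s", exc)
                    continue
                if rec.is_unmapped:
                    yield pid, role, TagAlignment(MapStatus.NON_MAPPABLE)
                elif rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0:
                    yield pid, role, TagAlignment(MapStatus.MULTIPLE)
                else:
                    nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                    yield pid, role, TagAlignment(
                        MapStatus.UNIQUE,
                        rec.reference_name,
                        rec.reference_start,
                        "-" if rec.is_reverse else "+",
                        int(nm),
                    )
    elif fmt == "BED":
        with open(path) as handle:
            for ln, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    logger.warning("skipping BED line %d: fewer than 6 columns", ln)
                    continue
                try:
                    chrom, start, _end, name, _score, strand = fields[:6]
                    pid, role = _split_read_name(name)
                    yield pid, role, TagAlignment(
                        MapStatus.UNIQUE, chrom, int(start), strand, 0
                    )
                except (ValueError, IndexError) as exc:
                    logger.warning("skipping BED line %d: %s", ln, exc)
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def export_alignments_sam(
    alignments: Iterable[tuple[str, int, TagAlignment]],
    chrom_lengths: dict[str, int],
    path: str,
    tag_length: int = 20,
) -> None:
    """Write (pet_id, role, alignment) triples as text SAM (round-trippable
    through :func:`import_alignments`)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
    }
    names = list(chrom_lengths)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for pid, role, al in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"{pid}/{role}"
            rec.query_sequence = "N" * tag_length
            if al.status is MapStatus.NON_MAPPABLE:
                rec.flag = 4
            elif al.status is MapStatus.MULTIPLE:
                # MAPQ 0 marks a multiply-mapping tag; position is a
                # placeholder when no location is stored
                rec.flag = 16 if al.strand == "-" else 0
                rec.reference_id = names.index(al.chrom) if al.chrom else 0
                rec.reference_start = al.pos or 0
                rec.cigarstring = f"{tag_length}M"
                rec.mapping_quality = 0
            else:
                rec.flag = 16 if al.strand == "-" else 0
                rec.reference_id = names.index(al.chrom)
                rec.reference_start = al.pos
                rec.cigarstring = f"{tag_length}M"
                rec.mapping_quality = 60
                rec.set_tag("NM", int(al.mismatches or 0))
            out.write(rec)


def naive_scan(
    genome: dict[str, str], tag: str, max_mismatch: int = 1
) -> list[tuple[str, int, str, int]]:
    """Brute-force all-position, both-strand scan; the mapping oracle.

    Returns (chrom, pos, strand, mismatches) for every locus within
    ``max_mismatch``; a forward hit shadowed on the reverse strand at the
    same locus is reported once (forward preferred, smaller mm kept).
    """
    k = len(tag)
    fwd = _encode(tag)
    rev = _encode(revcomp(tag))
    found: dict[tuple[str, int], tuple[str, int]] = {}
    for chrom, seq in genome.items():
        enc = _encode(seq)
        n = len(enc) - k + 1
        if n <= 0:
            continue
        for enc_tag, strand in ((fwd, "+"), (rev, "-")):
            mm = np.zeros(n, dtype=np.int32)
            for j in range(k):
                g = enc[j : j + n]
                t = enc_tag[j]
                mm += (g != t) | (g >= 4) | (t >= 4)
            for pos in np.nonzero(mm <= max_mismatch)[0]:
                key = (chrom, int(pos))
                val = (strand, int(mm[pos]))
                if key not in found or val[1] < found[key][1]:
                    if key in found and found[key][0] == "+":
                        val = ("+", min(val[1], found[key][1]))
                    found[key] = val
    return [(c, p, s, m) for (c, p), (s, m) in sorted(found.items())]
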