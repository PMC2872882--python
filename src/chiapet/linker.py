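"""Linker barcode demultiplexing and trimming for ChIA-PET read pairs.

A ChIA-PET sequencing read is 36 nt: a 20 nt genomic tag followed by the
16 nt proximal part of one half-linker.  Each half-linker carries a
dinucleotide barcode (CG for half-linker A, AT for half-linker B) at fixed
positions.  The barcode composition of the full linker separates
intra-complex ligation products (AA/BB, "non-chimeric") from random
ligations between two different ChIP complexes (AB, "chimeric"); pairs
whose linkers cannot be read are discarded as ambiguous.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

# Placeholder half-linker sequences: 16 nt, barcode at (1-based) 9-10.
# These are configuration, not biology; real libraries supply their own.
DEFAULT_HALF_LINKER_A = "GTTGGATACGGCTATC"
DEFAULT_HALF_LINKER_B = "GTAGGATTATGCAATG"

_VALID_BASES = frozenset("ACGTN")


class HalfLinker(Enum):
    A = "A"
    B = "B"
    AMBIGUOUS = "ambiguous"


class Composition(Enum):
    AA = "AA"
    BB = "BB"
    AB = "AB"  # chimeric; BA collapses to AB
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LinkerSpec:
    """Configuration of the half-linker layout inside a read.

    ``barcode_positions`` are 1-based offsets within the 16 nt linker part;
    the barcode must match exactly, while up to ``max_linker_mismatch``
    mismatches are tolerated over the full 16 nt (sequencing error).
    """

    half_linker_a: str = DEFAULT_HALF_LINKER_A
    half_linker_b: str = DEFAULT_HALF_LINKER_B
    barcode_positions: tuple[int, int] = (9, 10)
    barcode_a: str = "CG"
    barcode_b: str = "AT"
    max_linker_mismatch: int = 2
    tag_length: int = 20
    read_length: int = 36

    def __post_init__(self) -> None:
        ll = len(self.half_linker_a)
        if len(self.half_linker_b) != ll:
            raise ValueError("half-linkers must have equal length")
        if self.read_length != self.tag_length + ll:
            raise ValueError("read_length must equal tag_length + linker length")
        if self.barcode_a == self.barcode_b:
            raise ValueError("barcodes A and B must differ")
        for p in self.barcode_positions:
            if not 1 <= p <= ll:
                raise ValueError("barcode positions must lie within the linker")

    @property
    def linker_length(self) -> int:
        return len(self.half_linker_a)


@dataclass(frozen=True)
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None


@dataclass(frozen=True)
class LinkerCall:
    composition: Composition
    mm1: int
    mm2: int


@dataclass(frozen=True)
class TrimmedPET:
    """A tag pair leaving linker filtering; composition is never ambiguous."""

    id: str
    tag1: str
    tag2: str
    linker: LinkerCall


@dataclass
class LinkerStats:
    total: int = 0
    non_chimeric: int = 0  # AA + BB
    aa: int = 0
    bb: int = 0
    chimeric: int = 0  # AB
    ambiguous: int = 0
    malformed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_half_linker(linker_seq: str, spec: LinkerSpec) -> tuple[HalfLinker, int]:
    """Call A/B/ambiguous for one 16 nt linker segment.

    A call requires Hamming distance <= max_linker_mismatch to the
    half-linker AND an exact barcode match; N at a barcode position makes
    the call ambiguous (a signal, not an error).  Returns the call and the
    mismatch count to the called half-linker (the smaller distance when
    ambiguous).
    """
    if len(linker_seq) != spec.linker_length:
        raise ValueError(
            f"linker segment must be {spec.linker_length} nt, got {len(linker_seq)}"
        )
    seq = linker_seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-ACGTN characters in linker segment: {sorted(bad)}")

    d_a = _hamming(seq, spec.half_linker_a)
    d_b = _hamming(seq, spec.half_linker_b)
    barcode = "".join(seq[p - 1] for p in spec.barcode_positions)
    if "N" in barcode:
        return HalfLinker.AMBIGUOUS, min(d_a, d_b)
    is_a = d_a <= spec.max_linker_mismatch and barcode == spec.barcode_a
    is_b = d_b <= spec.max_linker_mismatch and barcode == spec.barcode_b
    if is_a and is_b:
        if d_a < d_b:
            return HalfLinker.A, d_a
        if d_b < d_a:
            return HalfLinker.B, d_b
        return HalfLinker.AMBIGUOUS, d_a
    if is_a:
        return HalfLinker.A, d_a
    if is_b:
        return HalfLinker.B, d_b
    return HalfLinker.AMBIGUOUS, min(d_a, d_b)


def classify_pet(pair: ReadPair, spec: LinkerSpec) -> TrimmedPET | LinkerCall:
    """Classify a read pair by full-linker composition and trim the linkers.

    Returns a :class:`TrimmedPET` for AA/BB/AB pairs; an ambiguous
    :class:`LinkerCall` (the discard record) otherwise.
    """
    for seq in (pair.seq1, pair.seq2):
        if len(seq) != spec.read_length:
            raise ValueError(
                f"read pair {pair.id!r}: read length {len(seq)} != {spec.read_length}"
            )
    t = spec.tag_length
    call1, mm1 = classify_half_linker(pair.seq1[t:], spec)
    call2, mm2 = classify_half_linker(pair.seq2[t:], spec)
    calls = {call1, call2}
    if HalfLinker.AMBIGUOUS in calls:
        comp = Composition.AMBIGUOUS
    elif calls == {HalfLinker.A}:
        comp = Composition.AA
    elif calls == {HalfLinker.B}:
        comp = Composition.BB
    else:
        comp = Composition.AB
    link = LinkerCall(comp, mm1, mm2)
    if comp is Composition.AMBIGUOUS:
        return link
    return TrimmedPET(pair.id, pair.seq1[:t].upper(), pair.seq2[:t].upper(), link)


def filter_library(
    pairs: Iterable[ReadPair], spec: LinkerSpec
) -> tuple[list[TrimmedPET], list[TrimmedPET], list[ReadPair], LinkerStats]:
    """Split a library into non-chimeric (AA+BB), chimeric (AB) and
    ambiguous streams.  Every readable input pair lands in exactly one
    stream; unreadable records are tallied as malformed."""
    non_chimeric: list[TrimmedPET] = []
    chimeric: list[TrimmedPET] = []
    ambiguous: list[ReadPair] = []
    stats = LinkerStats()
    for pair in pairs:
        stats.total += 1
        try:
            result = classify_pet(pair, spec)
        except ValueError:
            stats.malformed += 1
            continue
        if isinstance(result, LinkerCall):
            stats.ambiguous += 1
            ambiguous.append(pair)
        elif result.linker.composition is Composition.AB:
            stats.chimeric += 1
            chimeric.append(result)
        else:
            stats.non_chimeric += 1
            if result.linker.composition is Composition.AA:
                stats.aa += 1
            else:
                stats.bb += 1
            non_chimeric.append(result)
    return non_chimeric, chimeric, ambiguous, stats


# ---------------------------------------------------------------------------
# FASTQ boundary
# ---------------------------------------------------------------------------


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _strip_mate_suffix(name: str) -> str:
    name = name.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def read_paired_fastq(fq1: str, fq2: str) -> Iterator[ReadPair]:
    """Iterate matched read pairs from two FASTQ files (gzip transparent).

    Records are matched by order; ids may differ by /1,/2 or space suffixes
    but must otherwise agree.
    """
    with _open_text(fq1) as h1, _open_text(fq2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2):
            n1, n2 = _strip_mate_suffix(id1), _strip_mate_suffix(id2)
            if n1 != n2:
                raise ValueError(f"read id mismatch at record: {id1!r} vs {id2!r}")
            yield ReadPair(n1, s1.upper(), s2.upper(), q1, q2)


def write_tag_fastq(pets: Iterable[TrimmedPET], fq1: str, fq2: str) -> None:
    """Write trimmed tag pairs as FASTQ, composition appended to the id."""
    op = gzip.open if fq1.endswith(".gz") else open
    with op(fq1, "wt") as h1, (gzip.open if fq2.endswith(".gz") else open)(
        fq2, "wt"
    ) as h2:
        for p in pets:
            comp = p.linker.composition.value
            h1.write(f"@{p.id}_{comp}/1\n{p.tag1}\n+\n{'I' * len(p.tag1)}\n")
            h2.write(f"@{p.id}_{comp}/2\n{p.tag2}\n+\n{'I' * len(p.tag2)}\n")


def load_linker_config(path: str) -> LinkerSpec:
    """Read a LinkerSpec from a YAML mapping (missing keys -> defaults)."""
    import yaml

    with _open_text(path) as handle:
        data = yaml.safe_load(handle) or {}
    if "barcode_positions" in data:
        data["barcode_positions"] = tuple(data["barcode_positions"])
    return LinkerSpec(**data)
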