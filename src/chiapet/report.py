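"""Library summary statistics and browser-track export.

All printed percentages and ratios are pure functions of the stored
integer counts, rounded half-up to one decimal place.  Tracks go out as
BED (0-based half-open) and GFF3 (1-based inclusive); an interaction is
exported as two anchor features sharing an ID attribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .binding import BindingSite
from .interactions import InteractionCluster


def round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10**decimals
    return math.floor(x * factor + 0.5) / factor


def percent(x: int, total: int) -> float | None:
    """Percentage rounded half-up to 1 dp; None (NA) when the total is 0."""
    if total == 0:
        return None
    return round_half_up(100.0 * x / total)


def self_ligation_ratio(count_non_chimeric_self: int, count_chimeric_self: int) -> float | None:
    """Ratio of self-ligation PET counts between the non-chimeric and
    chimeric pools (1 dp); the paired-library enrichment diagnostic."""
    if count_chimeric_self == 0:
        import warnings

        warnings.warn("chimeric self-ligation count is zero; ratio is NA")
        return None
    return round_half_up(count_non_chimeric_self / count_chimeric_self)


@dataclass
class LibrarySummary:
    total_pets: int
    non_chimeric: int
    chimeric: int
    ambiguous: int
    unique_mapped_pets: int = 0
    self_ligation: int = 0
    different_orientation: int = 0
    intra_inter: int = 0
    inter_chrom: int = 0
    binding_sites: int = 0
    intra_interactions: int = 0
    inter_interactions: int = 0
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def non_chimeric_percent(self) -> float | None:
        return percent(self.non_chimeric, self.total_pets)

    @property
    def chimeric_percent(self) -> float | None:
        return percent(self.chimeric, self.total_pets)

    def to_frame(self) -> pd.DataFrame:
        def fmt(count: int, pct: float | None) -> str:
            return f"{count:,}" if pct is None else f"{count:,} ({pct}%)"

        rows = [
            ("Total PETs", f"{self.total_pets:,}"),
            ("Non-chimeric PETs", fmt(self.non_chimeric, self.non_chimeric_percent)),
            ("Chimeric PETs", fmt(self.chimeric, self.chimeric_percent)),
            ("Ambiguous PETs", fmt(self.ambiguous, percent(self.ambiguous, self.total_pets))),
            ("Unique PETs with unique mapping", f"{self.unique_mapped_pets:,}"),
            ("Self-ligation PETs", f"{self.self_ligation:,}"),
            ("Different orientation PETs", f"{self.different_orientation:,}"),
            ("Intra-chromosomal inter-ligation PETs", f"{self.intra_inter:,}"),
            ("Inter-chromosomal inter-ligation PETs", f"{self.inter_chrom:,}"),
            ("Binding sites", f"{self.binding_sites:,}"),
            ("Intra-chromosomal interactions", f"{self.intra_interactions:,}"),
            ("Inter-chromosomal interactions", f"{self.inter_interactions:,}"),
        ]
        rows += [(k, str(v)) for k, v in self.extras.items()]
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def summarize(
    total_pets: int,
    non_chimeric: int,
    chimeric: int,
    ambiguous: int,
    **counts: int,
) -> LibrarySummary:
    known = {
        f.name for f in LibrarySummary.__dataclass_fields__.values()  # type: ignore[attr-defined]
    }
    extras = {k: v for k, v in counts.items() if k not in known}
    kwargs = {k: v for k, v in counts.items() if k in known and k != "extras"}
    return LibrarySummary(
        total_pets, non_chimeric, chimeric, ambiguous, extras=extras, **kwargs
    )


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------


def sites_to_bed(sites: Sequence[BindingSite], path: str) -> None:
    """BED6+: chrom, start, end, name, k, strand '.', fdr, flags."""
    with open(path, "w") as out:
        for i, s in enumerate(sites):
            flags = ",".join(sorted(s.flags)) or "."
            out.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tsite_{i}\t{s.k}\t.\t{s.fdr:.6g}\t{flags}\n"
            )


def read_sites_bed(path: str) -> list[BindingSite]:
    sites = []
    with open(path) as handle:
        for line in handle:
            f = line.rstrip("\n").split("\t")
            flags = set() if f[7] == "." else set(f[7].split(","))
            sites.append(
                BindingSite(f[0], int(f[1]), int(f[2]), int(f[1]), int(f[2]),
                            int(f[4]), float(f[6]), flags)
            )
    return sites


def sites_to_gff3(sites: Sequence[BindingSite], path: str, source: str = "chiapet") -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, s in enumerate(sites):
            attrs = f"ID=site_{i};k={s.k};fdr={s.fdr:.6g}"
            if s.flags:
                attrs += ";flags=" + ",".join(sorted(s.flags))
            out.write(
                f"{s.chrom}\t{source}\tbinding_site\t{s.start + 1}\t{s.end}\t"
                f"{s.k}\t.\t.\t{attrs}\n"
            )


def interactions_to_tsv(interactions: Sequence[InteractionCluster], path: str) -> None:
    """14-column interaction table (two anchors, counts, statistics)."""
    cols = [
        "chromA", "startA", "endA", "chromB", "startB", "endB",
        "I_AB", "c_A", "c_B", "p_hyp", "fdr", "span", "flags", "site_overlap",
    ]
    rows = []
    for c in interactions:
        rows.append(
            [
                c.anchor_a.chrom, c.anchor_a.start, c.anchor_a.end,
                c.anchor_b.chrom, c.anchor_b.start, c.anchor_b.end,
                c.i_ab, c.anchor_a.c, c.anchor_b.c,
                f"{c.p_hyp:.6g}", f"{c.fdr:.6g}",
                c.span if c.span is not None else "interchrom",
                ",".join(sorted(c.flags)) or ".",
                "site_overlap" in c.flags,
            ]
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def interactions_to_gff3(
    interactions: Sequence[InteractionCluster], path: str, source: str = "chiapet"
) -> None:
    """Two GFF3 anchor records per interaction, sharing an ID attribute."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, c in enumerate(interactions):
            for which, a in (("A", c.anchor_a), ("B", c.anchor_b)):
                out.write(
                    f"{a.chrom}\t{source}\tinteraction_anchor\t{a.start + 1}\t{a.end}\t"
                    f"{c.i_ab}\t.\t.\tID=interaction_{i};anchor={which};"
                    f"p={c.p_hyp:.6g};fdr={c.fdr:.6g}\n"
                )


def read_gff3_intervals(path: str) -> list[tuple[str, int, int, str]]:
    """(chrom, start0, end, id) per record, converting back to 0-based
    half-open; the BED<->GFF3 coordinate maps are mutual inverses."""
    out = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append((f[0], int(f[3]) - 1, int(f[4]), attrs.get("ID", ".")))
    return out


def pets_to_bedpe(pets, path: str, tag_length: int = 20) -> None:
    """Unique PETs as 10-column paired BED (both tag intervals, id,
    category, strands)."""
    with open(path, "w") as out:
        for p, category in pets:
            out.write(
                f"{p.head.chrom}\t{p.head.pos}\t{p.head.pos + tag_length}\t"
                f"{p.tail.chrom}\t{p.tail.pos}\t{p.tail.pos + tag_length}\t"
                f"{p.id}\t{category}\t{p.head.strand}\t{p.tail.strand}\n"
            )
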