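# Methods

This note records the models implemented, the parameters that matter, the
numerical choices made where the procedure was genuinely open, and what the
synthetic-data checks do and do not demonstrate.

## Linker model

A read is `tag (20 nt) + half-linker (16 nt)`; the half-linker carries a
dinucleotide barcode at 1-based positions 9–10 (CG for A, AT for B). A
half-linker call requires Hamming distance ≤ `max_linker_mismatch`
(default 2) to the configured sequence **and** an exact barcode match. The
strict barcode rule is what makes AB (chimeric) pairs detectable at all: a
distance-only rule would happily absorb a barcode flip as two tolerated
mismatches. When both half-linkers qualify, the smaller distance wins and a
tie is ambiguous. `N` outside the barcode counts as a mismatch; `N` at a
barcode position makes the call ambiguous (unreadable barcode is a signal
about the read, not a program error). Reverse-complement linker orientation
is not searched: the construct fixes the linker's orientation within the
read.

The shipped half-linker sequences are placeholders with the documented
barcode layout (real libraries configure their own); the A and B backbones
deliberately differ at four positions outside the barcode so that a
barcode-flipped A read is distance 4 from B and lands in the ambiguous
stream instead of being miscalled.

## Tag mapping

Tags map in two tiers: exact first; one mismatch is considered only when a
tag has no exact match anywhere. Within the deciding tier one hit is
`unique`, several are `multiple`, none is `non_mappable`; only PETs with
both tags unique proceed. The index stores sorted base-4 codes of every
20-mer and every 10-mer on the forward strand; a reverse-strand query looks
up the reverse complement of the tag. One-mismatch candidates come from the
pigeonhole rule (a ≤ 1-mismatch hit matches at least one half exactly) and
are verified against the encoded genome, with `N` on either side counting
as a mismatch. A hit and its own reverse-strand shadow at the same locus
(palindromic tags) count once. Coordinates are 0-based half-open
everywhere except GFF3 output.

For genomes too large to index in memory the same alignment contract is
filled by SAM/BED import: SAM unmapped flag → non-mappable,
secondary/supplementary or MAPQ 0 → multiple, otherwise unique.

PCR duplicates are removed by merging PETs whose chromosomes and strands
agree exactly and whose coordinates agree within ± 1 bp on both tags
(single linkage over the sorted stream; the smallest-coordinate member
represents the group). Dedup runs before classification, so category
counts refer to unique PETs.

## Span model and PET categories

Same-chromosome spans mix two truncated power laws — sonicated fragment
sizes (self-ligation population) and intra-chromosomal interaction
distances — each a straight line in a log-log histogram. The cutoff
between them is the abscissa where two fitted lines intersect.

Fitting choices, each guarding a specific failure mode:

* **Log-spaced bins (50), geometric bin centres, density = count/width.**
  Equal-width bins would starve the upper decades.
* **Bins with < 5 counts are excluded.** Sparse tail bins sit on the
  single-count floor of a histogram; on log axes that floor is itself a
  line of slope ≈ −1 and would fake a second population.
* **Count-weighted least squares.** The variance of a bin's log density
  scales roughly as 1/count; unweighted fits let a handful of noisy tail
  bins steer the breakpoint.
* **Breakpoint grid with ≥ 3 bins and ≥ 0.5 decades per segment.** A real
  population spans a range of scales; without the decade floor the best
  "segment" is whatever noise pocket the grid can carve off.
* **Acceptance margin: the two-segment weighted SSE must be < 50% of the
  one-line SSE.** Measured on pure single power laws, the extra
  parameters plus the adaptive breakpoint already buy a 10–25% spurious
  reduction, while genuine two-law mixtures exceed 95%; 50% sits between
  the regimes with a wide margin on both sides. A 5% margin — the obvious
  first guess — accepts a split on every pure power law tried.
* **Validity: both slopes negative, left steeper, intersection inside the
  fitted range;** otherwise the fit is rejected and the caller falls back
  to a configurable default cutoff of 5,000 bp (sonication rarely leaves
  fragments above that size).

Categories for a unique PET given cutoff `s*`: different chromosomes →
inter-chromosomal inter-ligation; span > `s*` → intra-chromosomal
inter-ligation; span ≤ `s*` and head-to-tail (lower-coordinate tag `+`,
higher `−`, the geometry self-circularisation forces) → self-ligation;
otherwise different-orientation. Every PET gets exactly one category.

## Random-ligation diagnostics

If ligation were random, an inter-ligation PET lands on one chromosome
with probability `Σ_c n_c² / N²` (`n_c` = fragments on chromosome c). The
with-replacement form is the default; the without-replacement variant
`Σ n(n−1)/(N(N−1))` differs by O(1/N) and is available as an option. The
observed rate counts intra-chromosomal inter-ligation PETs over
intra + inter-chromosomal, excluding different-orientation PETs from both
numerator and denominator. The comparison is a two-sided binomial test —
exact via `scipy.stats.binomtest` up to 5×10⁷ trials, beyond that a normal
approximation with continuity correction; the result records which method
ran. The chromosome-pair density map divides pair counts by the product of
chromosome lengths before max-normalising to [0, 1] (a flag disables the
length correction for a raw-count map).

## Binding sites

Each self-ligation PET delimits its source fragment (outermost tag
coordinates). Sites are connected components of fragments sharing ≥ 1 bp
(half-open arithmetic; book-ended intervals do not merge), scored by
fragment count k, with a summit at the deepest stacking interval (leftmost
on ties — the summit is an addition; the underlying method reports only
clusters). The Monte-Carlo null places the same number of fragments
uniformly on the mappable genome (chromosome lengths minus excluded
regions), lengths resampled with replacement from the observed pool;
placement does not preserve chromosome of origin (the null is genome-wide
randomness). FDR(k) = mean simulated count of clusters of size ≥ k over
the observed count, capped at 1 and made non-increasing in k by a
cumulative max from high k. Default 10 iterations: one genome-wide
placement already yields thousands of null clusters, so the k-profile is
stable (seeded, hence reproducible). Post-filters drop sites on excluded
chromosomes (default chrY, for female-derived samples) or overlapping a
satellite-repeat blacklist, and flag — but keep — sites in known
amplification regions.

## Interactions

Inter-ligation tags are extended 5'→3' to the modal self-ligation span
(mode of a 10 bp-binned histogram; ties take the smaller bin; fallback
200 bp when fewer than 100 spans are available). Anchors are maximal
covered runs of the extension pile-up, split wherever an internal valley
drops below `valley_ratio` (default 0.5) × the smaller flanking maximum
(recursively, at the deepest valley first); anchors need ≥ 2 supporting
extensions. `c` counts extensions overlapping the anchor; a PET links
anchors (A, B) when one extension overlaps A and the other B — a PET whose
two extensions fall in one anchor is a self-loop, not a duplex
interaction, and is not counted.

With `N` inter-ligation PETs (2N ends), link counts under random ligation
are hypergeometric: `P(X = i) = C(c_A, i)·C(2N−c_A, c_B−i) / C(2N, c_B)`.
The reported p-value is the upper tail `P(X ≥ I_AB)`, computed in log
space (`gammaln` + `logsumexp`) for stability; since `c_A·c_B / 2N` is the
null expectation, enriched anchors are automatically penalised. The model
assumes `c_A, c_B ≪ N` (documented, not enforced). Intra- and
inter-chromosomal pairs are scored against the same `N` and reported
separately.

The empirical FDR re-pairs the pooled 2N ends at random (each end used
exactly once; a permutation cannot pair an end with itself), re-runs pair
counting and scoring against the *same* anchors, and evaluates
FDR(T) = mean permuted count of p ≤ T over observed count of p ≤ T at each
observed p, capped at 1. The comparisons are inclusive on both sides: a
strict `<` would make the best observed cluster's own threshold exclude
it, leaving a 0/0 ratio. Ten permutations by default. Called interactions
need `I_AB ≥ 3` and FDR < 0.05; filters then remove interactions whose
anchors sit on chrY/chrM, overlap the blacklist, or fall within 10 kb
(configurable) of a supplied structural-variation breakpoint —
rearrangements turn self-ligations into apparent long-range interactions.
Anchors are not required to coincide with called binding sites.

## Synthetic library

The generator emulates the construct end to end on a desk-scale genome:
4 × 5 Mb of uniform random sequence, 50,000 PETs. Planted features: 30
binding sites (self-ligation PETs whose fragments cover the site point;
per-site depth ~ Poisson(30), floored at 5) and 15 loops (10 PETs each,
tags scattered within ~200 bp of either anchor point), all features ≥ 20 kb
apart. Background PETs (the library minus signal, chimeric and ambiguous
parts) mix self-ligation / intra-chromosomal / inter-chromosomal / fully
random at 0.45 / 0.15 / 0.35 / 0.05 — intra-heavy relative to random
ligation, as a real ChIP-enriched library is. Spans draw from discrete
truncated power laws: exponent 2.5 on [200, 3000] bp for fragments,
exponent 1.2 on [3000, 2×10⁶] bp for interaction distances, so the span
histogram reproduces the two-line log-log shape with a fitted intersection
near the analytic crossing of the generating lines. 30% of pairs are
chimeric: their ends are drawn from the same generative mix and then
re-paired at random across complexes, so they inherit realistic end
positions (including ChIP-site bias) but carry no loop pairing — the AB
pool is a faithful negative control. 5% of pairs get unreadable random
linkers. Substitution errors at 0.5% per base over the full read.
Everything derives from one seeded generator; each emitted pair has
exactly one truth row.

What passing on this data does **not** show: robustness to real base-quality
profiles, PCR-duplicate structure beyond ± 1 bp jitter, repeat-driven
multi-mapping (the genome is i.i.d. random, so 20-mers are almost surely
unique), restriction-site sequence context, or chromatin-domain background
structure in interaction distances. Thresholds transfer to real data only
with those caveats.

## Problem sizes of the standard checks

The mapper oracle compares against a brute-force all-position scan for
1,000 tags on a 200 kb genome; span-model recovery uses 50,000 sampled
spans; Monte-Carlo FDR calibration pools clusters from 10 seeded runs of
400 null fragments on 10 Mb; the end-to-end recovery run is the default
50,000-PET library above. These sizes give the property checks stable
statistics while keeping a full run of everything within a few minutes on
one core.

## Known limitations

* The internal index targets desk-scale genomes (≤ a few hundred Mb);
  larger genomes go through SAM/BED import.
* Gapped alignment and > 1 mismatch are out of scope, as is
  mapping-quality modelling.
* The segmented span fit assumes both populations are present in force;
  libraries overwhelmingly dominated by one population fall back to the
  default cutoff.
* Anchors are 1-D coverage objects; no 2-D (Hi-C-style) binning or
  distance-dependent background model is applied to interaction scoring
  beyond the hypergeometric/permutation machinery described above.
* The permutation FDR's resolution is limited by the number of permuted
  pair p-values; with 10 permutations the smallest resolvable non-zero
  FDR scales accordingly.
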