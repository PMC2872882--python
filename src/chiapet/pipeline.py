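"""End-to-end wiring of the processing stages.

Runs linker filtering -> tag mapping -> deduplication -> span-model
classification -> binding-site calling -> interaction calling for one pool
of reads, collecting the per-stage counts a library summary needs.  This is
the path the command line drives and the one the synthetic-library recovery
checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import binding, classify, interactions, linker, mapping


@dataclass
class PipelineParams:
    cutoff_bp: int | None = None  # None -> fit from the span histogram
    default_cutoff_bp: int = classify.DEFAULT_CUTOFF_BP
    dedupe_tolerance_bp: int = 1
    site_fdr: float = 0.01
    mc_iterations: int = 10
    interaction_min_pets: int = 3
    interaction_fdr: float = 0.05
    n_permutations: int = 10
    valley_ratio: float = 0.5
    min_anchor_support: int = 2
    seed: int = 0
    drop_chroms_sites: frozenset[str] = frozenset({"chrY"})
    drop_chroms_interactions: frozenset[str] = frozenset({"chrY", "chrM"})


@dataclass
class PoolResult:
    trimmed: list[linker.TrimmedPET]
    mapped: list[mapping.MappedPET]
    unique: list[mapping.MappedPET]
    duplicates: int
    cutoff_bp: int
    span_model: classify.SpanModel | None
    categories: dict[classify.PETCategory, list[mapping.MappedPET]]
    clusters: list[binding.Cluster]
    fdr_by_k: dict[int, float]
    sites: list[binding.BindingSite]
    anchors: list[interactions.Anchor]
    scored: list[interactions.InteractionCluster]
    intra_interactions: list[interactions.InteractionCluster]
    inter_interactions: list[interactions.InteractionCluster]
    extension_bp: int = interactions.DEFAULT_EXTENSION_BP
    reject_counts: dict[str, int] = field(default_factory=dict)


def map_trimmed(
    trimmed: list[linker.TrimmedPET], index: mapping.TagIndex
) -> tuple[list[mapping.MappedPET], dict[str, int]]:
    tags1 = [t.tag1 for t in trimmed]
    tags2 = [t.tag2 for t in trimmed]
    al1 = mapping.map_tags(index, tags1)
    al2 = mapping.map_tags(index, tags2)
    comps = {t.id: t.linker.composition for t in trimmed}
    pets, rejects = mapping.assemble_pets(
        [(t.id, a) for t, a in zip(trimmed, al1)],
        [(t.id, a) for t, a in zip(trimmed, al2)],
        comps,
    )
    return pets, dict(rejects)


def run_pool(
    trimmed: list[linker.TrimmedPET],
    index: mapping.TagIndex,
    params: PipelineParams | None = None,
) -> PoolResult:
    """Process one pool (non-chimeric or chimeric) of trimmed tag pairs."""
    params = params or PipelineParams()
    mapped, rejects = map_trimmed(trimmed, index)
    unique, duplicates = classify.dedupe_pets(mapped, params.dedupe_tolerance_bp)

    spans = [s for s in (classify.genomic_span(p) for p in unique) if s is not None]
    if params.cutoff_bp is not None:
        cutoff, model = params.cutoff_bp, None
    else:
        cutoff, model = classify.fit_or_default_cutoff(
            spans, default_cutoff=params.default_cutoff_bp
        )
    cats = classify.categorize(unique, cutoff)

    self_pets = cats[classify.PETCategory.SELF_LIGATION]
    fragments = binding.self_pets_to_fragments(self_pets)
    clusters = binding.cluster_fragments(fragments)
    fdr_by_k: dict[int, float] = {}
    sites: list[binding.BindingSite] = []
    if clusters:
        null = binding.MonteCarloNull(
            chrom_lengths=index.chrom_lengths,
            iterations=params.mc_iterations,
            seed=params.seed,
        )
        fdr_by_k = binding.mc_fdr(
            clusters, len(fragments), [f.length for f in fragments], null
        )
        sites = binding.call_sites(clusters, fdr_by_k, params.site_fdr)
        sites, _ = binding.filter_sites(sites, set(params.drop_chroms_sites))

    self_spans = [classify.genomic_span(p) for p in self_pets]
    ext = interactions.estimate_extension_length([s for s in self_spans if s])
    inter_pets = (
        cats[classify.PETCategory.INTRA_INTER] + cats[classify.PETCategory.INTER_CHROM]
    )
    anchors: list[interactions.Anchor] = []
    scored: list[interactions.InteractionCluster] = []
    intra: list[interactions.InteractionCluster] = []
    inter: list[interactions.InteractionCluster] = []
    if inter_pets:
        extended = interactions.extend_tags(inter_pets, ext, index.chrom_lengths)
        flat = [iv for pair in extended for iv in pair]
        anchors = interactions.call_anchors(
            flat, params.valley_ratio, params.min_anchor_support
        )
        counts = interactions.pair_counts(extended, anchors)
        scored = interactions.score_pairs(counts, anchors, len(inter_pets))
        fdrs = interactions.permutation_fdr(
            scored, extended, anchors, params.n_permutations, params.seed
        )
        for c, f in zip(scored, fdrs):
            c.fdr = f
        intra, inter = interactions.call_interactions(
            scored, params.interaction_min_pets, params.interaction_fdr
        )
        intra = interactions.filter_interactions(
            intra, set(params.drop_chroms_interactions)
        )
        inter = interactions.filter_interactions(
            inter, set(params.drop_chroms_interactions)
        )
    return PoolResult(
        trimmed=trimmed,
        mapped=mapped,
        unique=unique,
        duplicates=duplicates,
        cutoff_bp=cutoff,
        span_model=model,
        categories=cats,
        clusters=clusters,
        fdr_by_k=fdr_by_k,
        sites=sites,
        anchors=anchors,
        scored=scored,
        intra_interactions=intra,
        inter_interactions=inter,
        extension_bp=ext,
        reject_counts=rejects,
    )
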