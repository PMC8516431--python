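"""End-to-end orchestration over synthetic or ingested multi-species data.

Glue between the stage modules: build per-species datasets (simulate or
load, collapse, filter, map), call and rank clusters, trace loci across
species, and run the breakpoint-enrichment analysis that compares the
between-flanks breakpoint frequency with the flank-window background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustercall, rearrange, synteny, synthio
from .smallrna import collapse_reads, filter_reads, map_reads

__all__ = [
    "build_species_dataset",
    "call_and_rank",
    "trace_breakpoints",
    "simulate_world",
]


def simulate_world(config: synthio.WorldConfig
                   ) -> tuple[list[synthio.SpeciesTruth], pd.DataFrame]:
    """Ancestor + evolved leaves + ortholog map for a world config."""
    ancestor = synthio.generate_ancestor(config)
    leaves, ortholog_map = synthio.evolve_species(ancestor, config)
    return leaves, ortholog_map


def build_species_dataset(
    truth: synthio.SpeciesTruth,
    read_params: dict | None = None,
    seed: int = 0,
    min_contig: int = 0,
    mode: str = "unique",
) -> tuple[synteny.SpeciesDataset, pd.DataFrame]:
    """Simulate a small-RNA library from the truth, map it, and package the
    species for downstream stages.  Returns (dataset, read truth table).

    With no miRNA annotation in the synthetic world the normalization
    ledger falls back to the genome-mapped read count (an identity rpm
    scale), which keeps expression thresholds meaningful.
    """
    read_params = dict(read_params or {})
    read_params.setdefault("seed", seed)
    reads, table = synthio.simulate_small_rna(truth, **read_params)
    collapsed = collapse_reads(reads)
    filtered, mirna_count = filter_reads(collapsed)
    aln = map_reads(filtered, truth.genome, mode=mode, min_contig=min_contig)
    aln.mirna_count = mirna_count if mirna_count else aln.total_mapped
    dataset = synteny.SpeciesDataset(
        name=truth.name,
        contig_lengths=truth.contig_lengths(),
        genes=truth.genes,
        te_annotation=truth.te_insertions,
        alignments=aln,
        clusters=pd.DataFrame(),
    )
    return dataset, table


def call_and_rank(
    dataset: synteny.SpeciesDataset,
    params: clustercall.ClusterCallParams | None = None,
    top_n: int = 20,
) -> list[clustercall.PiRNACluster]:
    """Call clusters on a species dataset, fill metrics, rank the top n and
    store the ranked frame on the dataset."""
    clusters = clustercall.call_clusters(dataset.alignments, params)
    for c in clusters:
        clustercall.cluster_metrics(
            c, dataset.alignments,
            te_annotation=dataset.te_annotation,
            gene_annotation=dataset.genes,
        )
    top = clustercall.rank_top(clusters, n=top_n)
    for c in top:
        c.cluster_id = f"{dataset.name}.pic{c.rank}"
    dataset.clusters = clustercall.clusters_to_frame(top) if top else (
        pd.DataFrame(columns=["contig", "start", "end", "cluster_id"])
    )
    return top


@dataclass
class BreakpointTraceResult:
    """Aggregated breakpoint profile around traced loci."""

    x0: float
    flank_frequencies: list[float]
    offsets: list[float]
    enrichment: rearrange.EnrichmentResult
    n_traces: int
    positions: list[tuple[str, str, float]] = field(default_factory=list)


def trace_breakpoints(
    species_genes: dict[str, pd.DataFrame],
    loci: dict[str, pd.DataFrame],
    contig_lengths: dict[str, dict[str, int]],
    span: int = 200_000,
    window: int = 15_000,
    extent: int = 150_000,
    inversion_only: bool = True,
) -> BreakpointTraceResult | None:
    """Signed-permutation breakpoint enrichment around traced loci.

    For every ordered species pair and every query locus, the flank gene
    arrays are located in the subject, the subject order is expressed as a
    signed permutation in the query frame, breakpoints are detected and
    positioned at the midpoint of the anchoring subject gene pair, and
    events are binned by distance to the traced subject locus border
    (between-flanks events feed the central x0 bin).  Frequencies are
    averaged over traces and the between-flanks frequency is tested against
    the flank-window background with Z0 = (x0 - mu) / sigma.

    ``inversion_only`` restricts the profile to inversion-flagged
    breakpoints (sign reversals at disordered adjacencies).  A breakpoint
    is an event in the subject genome: detections of the same junction from
    different query species are deduplicated (within 2 kb) before binning,
    and each genome's events are profiled against that genome's own loci.
    """
    n_side = max(1, extent // window)
    counts = np.zeros(2 * n_side)
    valid = np.zeros(2 * n_side)
    x0_total = 0.0
    n_traces = 0
    all_positions: list[tuple[str, str, float]] = []
    names = sorted(species_genes)
    for q in names:
        q_loci = loci.get(q)
        if q_loci is None or q_loci.empty:
            continue
        for s in names:
            if s == q:
                continue
            s_genes = species_genes[s]
            for _, row in q_loci.iterrows():
                left, right = synteny.extract_flanks(
                    (row.contig, int(row.start), int(row.end)),
                    species_genes[q], span=span,
                    contig_length=contig_lengths[q].get(row.contig),
                )
                cand = synteny.locate_homolog(left, right, s_genes)
                if not cand.get("resolved"):
                    continue
                contig = cand["contig"]
                lo, hi = cand["start"], cand["end"]
                sub = s_genes[s_genes.contig == contig].sort_values("start")
                query_order = list(zip(
                    list(reversed(list(left.entries.ortholog_group)))
                    + list(right.entries.ortholog_group),
                    list(reversed(list(left.entries.strand)))
                    + list(right.entries.strand),
                ))
                q_ogs = {og for og, _ in query_order}
                sub = sub[sub.ortholog_group.isin(q_ogs)]
                if len(sub) < 2:
                    continue
                subject_order = list(zip(sub.ortholog_group, sub.strand))
                try:
                    perm = rearrange.build_signed_permutation(
                        subject_order, query_order)
                except ValueError:
                    continue
                bps = rearrange.find_breakpoints(perm)
                mids = ((sub.start + sub.end) / 2).tolist()
                clen = contig_lengths[s].get(contig, int(sub.end.max()))
                positions = rearrange.breakpoint_positions(bps, mids, clen)
                if inversion_only:
                    positions = [
                        p for p, f in zip(positions, bps.inversion_flags) if f
                    ]
                n_traces += 1
                for p in positions:
                    all_positions.append((s, contig, p))
    if n_traces == 0:
        return None
    # one event per junction per subject genome: merge detections of the
    # same breakpoint from different query species (within 2 kb)
    events: dict[str, dict[str, list[float]]] = {}
    for s, contig, p in sorted(all_positions):
        merged = events.setdefault(s, {}).setdefault(contig, [])
        if merged and abs(p - merged[-1]) <= 2000:
            continue
        merged.append(p)
    n_loci = 0
    for s in names:
        s_loci = loci.get(s)
        if s_loci is None or s_loci.empty:
            continue
        for _, row in s_loci.iterrows():
            contig = row.contig
            lo, hi = int(row.start), int(row.end)
            clen = contig_lengths[s].get(contig, hi)
            positions = events.get(s, {}).get(contig, [])
            n_loci += 1
            x0_total += sum(1 for p in positions if lo <= p < hi)
            for i in range(n_side):
                w_lo, w_hi = lo - (i + 1) * window, lo - i * window
                j = n_side - 1 - i
                if w_lo >= 0:
                    valid[j] += 1
                    counts[j] += sum(
                        1 for p in positions if w_lo <= p < w_hi)
                w_lo, w_hi = hi + i * window, hi + (i + 1) * window
                j = n_side + i
                if w_hi <= clen:
                    valid[j] += 1
                    counts[j] += sum(
                        1 for p in positions if w_lo <= p < w_hi)
    if n_loci == 0:
        return None
    freqs = np.divide(counts, valid, out=np.zeros_like(counts),
                      where=valid > 0)
    x0 = x0_total / n_loci
    offsets = [-(i + 0.5) * window for i in reversed(range(n_side))] + [
        (i + 0.5) * window for i in range(n_side)
    ]
    enr = rearrange.enrichment_zscore(x0, freqs.tolist())
    return BreakpointTraceResult(
        x0=x0, flank_frequencies=freqs.tolist(), offsets=offsets,
        enrichment=enr, n_traces=n_traces, positions=all_positions,
    )
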