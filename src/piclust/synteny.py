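"""Cross-species tracing of piRNA cluster loci via flanking-gene synteny.

Repeat-rich cluster bodies cannot be aligned directly, so each cluster is
anchored by the ortholog-tagged genes within 200 kb of its borders.  In a
subject species the homologous locus is the interval between the innermost
matched flank genes, preferring placements with both flanks on one contig,
anchors nearest the query cluster, and the longest contiguous collinear
flank runs.  The locus is then classified: an active piRNA cluster (piRNA
expression and content thresholds met), conserved synteny without cluster
activity, an inversion break exactly between the two flank arrays, or
unresolved.  Pairwise calls are linked into cross-species homology groups by
overlap, and each group is aged by the divergence time of the most recent
common ancestor of the species where the locus is an active cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .rearrange import build_signed_permutation
from .smallrna import AlignmentSet

__all__ = [
    "FlankGeneArray",
    "SyntenyCall",
    "SyntenyThresholds",
    "HomologyGroup",
    "SpeciesDataset",
    "extract_flanks",
    "locate_homolog",
    "classify_locus",
    "pairwise_table",
    "link_groups",
    "assign_age",
]


@dataclass
class FlankGeneArray:
    """Ortholog-tagged genes flanking one cluster border.

    ``entries`` columns: ortholog_group, strand, distance (bp from the
    cluster border to the gene's nearest edge), ordered outward from the
    border.  Only genes wholly within the span are kept.  ``truncated``
    marks flanks clipped by a contig end.
    """

    cluster_id: str
    side: str  # {"left", "right"}
    entries: pd.DataFrame
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SyntenyThresholds:
    """Requirements for calling a traced locus an active piRNA cluster."""

    min_rpm: float = 100.0
    min_rpkm: float = 10.0
    min_size_bp: int = 5000
    min_te_fraction: float = 0.25
    max_gene_fraction: float = 0.25


@dataclass
class SyntenyCall:
    """One pairwise homology decision for a query cluster."""

    query_species: str
    subject_species: str
    cluster_id: str
    status: str  # {"active_piC", "synteny", "inversion_break", "unresolved"}
    subject_contig: str | None = None
    subject_start: int | None = None
    subject_end: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status in ("active_piC", "synteny") and (
            self.subject_contig is None
        ):
            raise ValueError(f"status {self.status} requires a subject locus")


@dataclass
class HomologyGroup:
    """Cross-species set of homologous loci linked by overlap.

    ``members`` columns: species, contig, start, end, status, locus_id.
    """

    members: pd.DataFrame
    age_my: float | None = None
    category: str | None = None

    @property
    def conserved(self) -> bool:
        active = self.members[self.members.status == "active_piC"]
        return active.species.nunique() >= 2


@dataclass
class SpeciesDataset:
    """Everything synteny tracing needs to know about one species."""

    name: str
    contig_lengths: dict[str, int]
    genes: pd.DataFrame
    te_annotation: pd.DataFrame
    alignments: AlignmentSet
    clusters: pd.DataFrame  # called clusters with contig/start/end/cluster_id


def extract_flanks(
    cluster: tuple[str, int, int],
    gene_annotation: pd.DataFrame,
    span: int = 200_000,
    contig_length: int | None = None,
    cluster_id: str = "",
) -> tuple[FlankGeneArray, FlankGeneArray]:
    """Genes wholly within ``span`` bp of each cluster border.

    Left flank covers [start - span, start), right flank [end, end + span);
    both are ordered outward from the border (innermost gene first).
    """
    contig, start, end = cluster
    genes = gene_annotation[gene_annotation.contig == contig]
    left_sel = genes[(genes.start >= max(0, start - span))
                     & (genes.end <= start)].copy()
    left_sel["distance"] = start - left_sel["end"]
    left = FlankGeneArray(
        cluster_id, "left",
        left_sel.sort_values("distance")[
            ["ortholog_group", "strand", "distance"]
        ].reset_index(drop=True),
        truncated=start - span < 0,
    )
    right_hi = end + span
    right_sel = genes[(genes.start >= end) & (genes.end <= right_hi)].copy()
    right_sel["distance"] = right_sel["start"] - end
    truncated_r = contig_length is not None and right_hi > contig_length
    right = FlankGeneArray(
        cluster_id, "right",
        right_sel.sort_values("distance")[
            ["ortholog_group", "strand", "distance"]
        ].reset_index(drop=True),
        truncated=bool(truncated_r),
    )
    return left, right


def _collinear_run(query_ogs: list[str], subject_genes: pd.DataFrame) -> int:
    """Length of the longest run of consecutive query flank genes placed
    consecutively (in either direction) in the subject gene order."""
    order = {og: i for i, og in
             enumerate(subject_genes.sort_values("start").ortholog_group)}
    best = run = 0
    prev = None
    for og in query_ogs:
        pos = order.get(og)
        if pos is None:
            prev, run = None, 0
            continue
        if prev is not None and abs(pos - prev) == 1:
            run += 1
        else:
            run = 1
        best = max(best, run)
        prev = pos
    return best


def locate_homolog(
    left: FlankGeneArray,
    right: FlankGeneArray,
    subject_genes: pd.DataFrame,
) -> dict:
    """Find the candidate subject locus between matched flank genes.

    Candidates are ranked by, in order: (1) both flanks on the same contig,
    (2) innermost anchors closest to the query cluster (smallest summed
    query distance), (3) longest contiguous collinear flank runs.  Returns a
    diagnostics dict with keys ``resolved``, ``contig``, ``start``, ``end``,
    ``left_anchor``, ``right_anchor``, ``same_contig``, ``collinear_run``.
    """
    subject_loc = {
        og: (contig, int(s), int(e))
        for og, contig, s, e in zip(
            subject_genes.ortholog_group, subject_genes.contig,
            subject_genes.start, subject_genes.end,
        )
    }

    def anchors_by_contig(flank: FlankGeneArray) -> dict[str, tuple]:
        # innermost (smallest query distance) anchor per subject contig
        out: dict[str, tuple] = {}
        for og, dist in zip(flank.entries.ortholog_group,
                            flank.entries.distance):
            hit = subject_loc.get(og)
            if hit is not None and hit[0] not in out:
                out[hit[0]] = (dist, og, hit)
        return out

    lefts = anchors_by_contig(left)
    rights = anchors_by_contig(right)
    if not lefts or not rights:
        return {"resolved": False, "reason": "no resolvable flank ortholog"}
    shared_contigs = sorted(set(lefts) & set(rights))
    if not shared_contigs:
        # both flanks resolvable but never on one contig
        dl, og_l, _ = min(lefts.values())
        dr, og_r, _ = min(rights.values())
        return {
            "resolved": False, "same_contig": False,
            "reason": "flanks on different contigs",
            "left_anchor": og_l, "right_anchor": og_r,
        }
    query_ogs = (
        list(reversed(list(left.entries.ortholog_group)))
        + list(right.entries.ortholog_group)
    )
    best = None
    for contig in shared_contigs:
        dl, og_l, (_, ls, le) = lefts[contig]
        dr, og_r, (_, rs, re) = rights[contig]
        lo, hi = min(le, re), max(ls, rs)
        if hi <= lo:  # anchors overlap or touch; degenerate interval
            lo, hi = min(ls, rs), max(le, re)
        run = _collinear_run(
            query_ogs, subject_genes[subject_genes.contig == contig])
        key = (dl + dr, -run)
        if best is None or key < best[0]:
            best = (key, contig, lo, hi, og_l, og_r, run)
    _, contig, lo, hi, og_l, og_r, run = best
    return {
        "resolved": True, "same_contig": True, "contig": contig,
        "start": lo, "end": hi, "left_anchor": og_l, "right_anchor": og_r,
        "collinear_run": run,
    }


def _junction_intact(
    left: FlankGeneArray,
    right: FlankGeneArray,
    subject_genes: pd.DataFrame,
    contig: str,
) -> bool | None:
    """Whether the adjacency between the two flank arrays survives in the
    subject: the innermost left and innermost right flank genes must be
    consecutive and consistently oriented in the subject gene order.

    Returns None when the check is undecidable (fewer than one shared gene
    per flank on the subject contig).
    """
    # query chromosome order: left flank outermost->innermost, then right
    query_order = [
        (og, s) for og, s in zip(
            reversed(list(left.entries.ortholog_group)),
            reversed(list(left.entries.strand)),
        )
    ] + list(zip(right.entries.ortholog_group, right.entries.strand))
    sub = subject_genes[subject_genes.contig == contig].sort_values("start")
    subject_order = [
        (og, s) for og, s in zip(sub.ortholog_group, sub.strand)
        if og in {q[0] for q in query_order}
    ]
    shared = {og for og, _ in subject_order}
    left_shared = [og for og, _ in query_order
                   if og in shared and og in set(left.entries.ortholog_group)]
    right_shared = [og for og, _ in query_order
                    if og in shared and og in set(right.entries.ortholog_group)]
    if not left_shared or not right_shared:
        return None
    perm = build_signed_permutation(subject_order, query_order)
    k = len(left_shared)  # query rank of the innermost left gene
    seq = perm.elements
    for i in range(len(seq) - 1):
        if (seq[i], seq[i + 1]) == (k, k + 1):
            return True
        if (seq[i], seq[i + 1]) == (-(k + 1), -k):
            return True
    return False


def classify_locus(
    candidate: dict,
    left: FlankGeneArray,
    right: FlankGeneArray,
    subject: SpeciesDataset,
    query_species: str,
    cluster_id: str,
    thresholds: SyntenyThresholds | None = None,
) -> SyntenyCall:
    """Turn a located (or unlocatable) subject locus into a synteny call.

    active_piC: the junction between the flanks is intact and a
    piRNA-expressing region within the locus passes all five thresholds
    (rpm, rpkm, size, minimum TE content, maximum gene content).
    synteny: junction intact but thresholds unmet.  inversion_break: the
    flank gene order/orientation is interrupted exactly between the two
    flank arrays.  unresolved: anything else.
    """
    thresholds = thresholds or SyntenyThresholds()
    sp = subject.name
    if not candidate.get("resolved"):
        return SyntenyCall(query_species, sp, cluster_id, "unresolved",
                           diagnostics=candidate)
    contig = candidate["contig"]
    start, end = candidate["start"], candidate["end"]
    intact = _junction_intact(left, right, subject.genes, contig)
    if intact is None:
        return SyntenyCall(query_species, sp, cluster_id, "unresolved",
                           diagnostics={**candidate, "junction": "undecided"})
    if not intact:
        return SyntenyCall(
            query_species, sp, cluster_id, "inversion_break",
            subject_contig=contig, subject_start=start, subject_end=end,
            diagnostics={**candidate, "junction": "broken"},
        )
    active = _active_region(subject, contig, start, end, thresholds)
    status = "active_piC" if active else "synteny"
    return SyntenyCall(
        query_species, sp, cluster_id, status,
        subject_contig=contig, subject_start=start, subject_end=end,
        diagnostics={**candidate, "junction": "intact"},
    )


def _interval_metrics(subject: SpeciesDataset, contig: str,
                      start: int, end: int) -> dict:
    rec = subject.alignments.records
    sel = rec[(rec.contig == contig) & (rec.start >= start)
              & (rec.start < end)]
    count = float(sel["copies"].sum())
    total = subject.alignments.total_mapped or 1
    rpm = count * 1e6 / total
    length = max(1, end - start)
    rpkm = rpm * 1000 / length
    te = subject.te_annotation
    te_sel = te[(te.contig == contig) & (te.end > start) & (te.start < end)]
    te_bp = float((te_sel["end"].clip(upper=end)
                   - te_sel["start"].clip(lower=start)).sum())
    g = subject.genes
    g_sel = g[(g.contig == contig) & (g.end > start) & (g.start < end)]
    g_bp = float((g_sel["end"].clip(upper=end)
                  - g_sel["start"].clip(lower=start)).sum())
    return {"rpm": rpm, "rpkm": rpkm, "length": end - start,
            "te_fraction": te_bp / length, "gene_fraction": g_bp / length}


def _passes(m: dict, t: SyntenyThresholds) -> bool:
    return (m["rpm"] >= t.min_rpm and m["rpkm"] >= t.min_rpkm
            and m["length"] >= t.min_size_bp
            and m["te_fraction"] >= t.min_te_fraction
            and m["gene_fraction"] <= t.max_gene_fraction)


def _active_region(subject: SpeciesDataset, contig: str, start: int,
                   end: int, thresholds: SyntenyThresholds) -> bool:
    """A piRNA-expressing region within the locus passing all thresholds:
    preferably one of the subject's own called clusters overlapping the
    interval, otherwise the interval itself."""
    cl = subject.clusters
    if cl is not None and len(cl):
        overlapping = cl[(cl.contig == contig) & (cl.end > start)
                         & (cl.start < end)]
        return any(
            _passes(_interval_metrics(subject, contig, int(row.start),
                                      int(row.end)), thresholds)
            for _, row in overlapping.iterrows()
        )
    return _passes(_interval_metrics(subject, contig, start, end),
                   thresholds)


def pairwise_table(
    species: dict[str, SpeciesDataset],
    top_clusters: dict[str, pd.DataFrame],
    span: int = 200_000,
    thresholds: SyntenyThresholds | None = None,
) -> list[SyntenyCall]:
    """All ordered species-pair homology calls, one per query top cluster.

    For S species with data this produces S*(S-1) ordered pairs (90 for 10
    species); a pair is skipped with a warning if either side's data is
    missing.
    """
    calls: list[SyntenyCall] = []
    names = sorted(species)
    for q in names:
        clusters = top_clusters.get(q)
        if clusters is None:
            continue
        for s in names:
            if s == q:
                continue
            subject = species[s]
            for _, row in clusters.iterrows():
                cid = str(row.get("cluster_id") or
                          f"{row.contig}:{row.start}-{row.end}")
                left, right = extract_flanks(
                    (row.contig, int(row.start), int(row.end)),
                    species[q].genes, span=span,
                    contig_length=species[q].contig_lengths.get(row.contig),
                    cluster_id=cid,
                )
                cand = locate_homolog(left, right, subject.genes)
                calls.append(classify_locus(
                    cand, left, right, subject, q, cid, thresholds
                ))
    return calls


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_groups(
    calls: list[SyntenyCall],
    top_clusters: dict[str, pd.DataFrame],
) -> list[HomologyGroup]:
    """Link pairwise calls into cross-species homology groups.

    Loci are the query clusters themselves (active in their own species)
    plus every resolvable subject locus; a call links its query cluster to
    its subject locus, and loci of the same species overlapping by > 0 bp
    are merged transitively.
    """
    loci: list[tuple] = []  # (species, contig, start, end, status, locus_id)
    index: dict[str, int] = {}

    def add(species, contig, start, end, status, locus_id):
        if locus_id in index:
            return index[locus_id]
        index[locus_id] = len(loci)
        loci.append((species, contig, int(start), int(end), status, locus_id))
        return index[locus_id]

    uf = _UnionFind()
    for sp, clusters in top_clusters.items():
        for _, row in clusters.iterrows():
            cid = str(row.get("cluster_id") or
                      f"{row.contig}:{row.start}-{row.end}")
            add(sp, row.contig, row.start, row.end, "active_piC",
                f"{sp}:{cid}")
    for call in calls:
        q_id = f"{call.query_species}:{call.cluster_id}"
        if q_id not in index:
            continue
        if call.subject_contig is None:
            continue
        s_id = (f"{call.subject_species}:{call.subject_contig}"
                f":{call.subject_start}-{call.subject_end}"
                f"<{q_id}")
        j = add(call.subject_species, call.subject_contig,
                call.subject_start, call.subject_end, call.status, s_id)
        uf.union(index[q_id], j)
    # merge same-species overlapping loci
    by_species: dict[str, list[int]] = {}
    for i, (sp, *_rest) in enumerate(loci):
        by_species.setdefault(sp, []).append(i)
    for sp, idxs in by_species.items():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ia, ib = idxs[a], idxs[b]
                _, ca, sa, ea, *_ = loci[ia]
                _, cb, sb, eb, *_ = loci[ib]
                if ca == cb and sa < eb and sb < ea:
                    uf.union(ia, ib)
    groups: dict = {}
    for i in range(len(loci)):
        groups.setdefault(uf.find(i), []).append(loci[i])
    out = []
    for members in groups.values():
        df = pd.DataFrame(
            members,
            columns=["species", "contig", "start", "end", "status",
                     "locus_id"],
        )
        out.append(HomologyGroup(df))
    return out


def assign_age(
    group: HomologyGroup, tree: dendropy.Tree
) -> HomologyGroup:
    """Age a homology group from the species tree.

    The age is the divergence time (My, from branch lengths of an
    ultrametric tree) of the most recent common ancestor of all species
    where the locus is an active piRNA cluster; groups active in a single
    species are species-specific with age 0.
    """
    tree.is_rooted = True
    active = sorted(
        group.members[group.members.status == "active_piC"].species.unique()
    )
    labels = {t.label for t in tree.taxon_namespace}
    missing = [sp for sp in active if sp not in labels]
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    if len(active) <= 1:
        group.age_my = 0.0
        group.category = "species-specific"
        return group
    mrca = tree.mrca(taxon_labels=active)
    group.age_my = float(mrca.distance_from_tip())
    group.category = "conserved"
    return group
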