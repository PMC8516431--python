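"""piRNA cluster identification from unique-mapper alignments.

Clusters are called from the density of uniquely mapping 23-29 nt reads:
sliding windows whose read count is improbable under a genome-wide Poisson
null are chained into candidates, which must then exceed a minimum size
(5 kb) and a minimum 1U-or-10A composition (30%, strand-agnostic).  Closely
adjacent clusters are merged when the gap between two loci is smaller than
their combined length.  Per-cluster metrics cover expression (rpm against
the miRNA ledger, rpkm against genome-mapped reads), strand composition
(uni-strand when >95% of unique reads come from one strand), the ping-pong
signature z-score, and TE/CDS base-pair content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .smallrna import AlignmentSet, normalize_rpm

__all__ = [
    "ClusterCallParams",
    "PiRNACluster",
    "call_clusters",
    "merge_clusters",
    "classify_strand",
    "pingpong_z",
    "cluster_metrics",
    "rank_top",
    "clusters_to_frame",
]


@dataclass(frozen=True)
class ClusterCallParams:
    """Thresholds and window geometry for cluster identification."""

    min_size_bp: int = 5000
    min_1u_or_10a: float = 0.30
    density_p: float = 0.05
    window_bp: int = 1000
    step_bp: int = 500
    uni_strand_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.min_1u_or_10a <= 1 and 0 < self.density_p <= 1
                and 0 < self.uni_strand_threshold <= 1):
            raise ValueError("fractional parameters must lie in (0, 1]")
        if self.min_size_bp < self.window_bp:
            raise ValueError("min_size_bp must be >= window_bp")


@dataclass
class PiRNACluster:
    """A called piRNA cluster and its summary metrics."""

    contig: str
    start: int
    end: int
    unique_read_count: float = 0.0
    rpm: float | None = None
    rpkm: float | None = None
    plus_strand_read_fraction: float | None = None
    type: str | None = None  # {"uni", "dual"}
    pingpong_z_unique: float | None = None
    pingpong_z_all: float | None = None
    te_bp_fraction: float | None = None
    cds_bp_fraction: float | None = None
    rank: int | None = None
    cluster_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def clusters_to_frame(clusters: list[PiRNACluster]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in clusters])


def _composition(records: pd.DataFrame, weights: pd.Series) -> float:
    """Strand-agnostic max of the 1U and 10A read fractions (reads are
    stored 5'->3', so 1U means first_nt == T in DNA)."""
    total = weights.sum()
    if total == 0:
        return 0.0
    u1 = weights[records["first_nt"] == "T"].sum() / total
    a10 = weights[records["tenth_nt"] == "A"].sum() / total
    return float(max(u1, a10))


def call_clusters(
    alignments: AlignmentSet, params: ClusterCallParams | None = None
) -> list[PiRNACluster]:
    """Identify clusters from unique-mapper read density.

    Windows of ``window_bp`` advanced by ``step_bp`` are tested against a
    Poisson null with lambda = N * window / G (N = total mapped read copies,
    G = summed contig length); windows with tail probability
    P(X >= k) < ``density_p`` are chained (overlapping or adjacent
    significant windows form one candidate), candidate bounds are tightened
    to the extent of the reads they contain, and candidates below
    ``min_size_bp`` or below the 1U-or-10A floor are discarded.  The merge
    rule for closely adjacent clusters is then applied to fixed point.
    """
    params = params or ClusterCallParams()
    if alignments.mode != "unique":
        raise ValueError("cluster calling requires unique-mode alignments")
    rec = alignments.records
    if rec.empty:
        return []
    if not alignments.contig_lengths:
        raise ValueError("alignment set lacks contig lengths")
    genome_bp = sum(alignments.contig_lengths.values())
    n_total = float(rec["copies"].sum())
    lam = n_total * params.window_bp / genome_bp
    clusters: list[PiRNACluster] = []
    for contig, sub in rec.groupby("contig"):
        clen = alignments.contig_lengths[contig]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        copies = sub["copies"].to_numpy(dtype=float)
        sig_spans: list[tuple[int, int]] = []
        for w_start in range(0, max(1, clen - params.window_bp + 1),
                             params.step_bp):
            w_end = w_start + params.window_bp
            k = copies[(starts >= w_start) & (starts < w_end)].sum()
            if k > 0 and stats.poisson.sf(k - 1, lam) < params.density_p:
                if sig_spans and w_start <= sig_spans[-1][1]:
                    sig_spans[-1] = (sig_spans[-1][0], w_end)
                else:
                    sig_spans.append((w_start, w_end))
        for span_start, span_end in sig_spans:
            inside = (starts >= span_start) & (starts < span_end)
            if not inside.any():
                continue
            c_start = int(starts[inside].min())
            c_end = int(ends[inside].max())
            if c_end - c_start < params.min_size_bp:
                continue
            sub_in = sub[(sub["start"] >= c_start) & (sub["start"] < c_end)]
            w = sub_in["copies"].astype(float)
            if _composition(sub_in, w) < params.min_1u_or_10a:
                continue
            clusters.append(PiRNACluster(
                contig, c_start, c_end, unique_read_count=float(w.sum())
            ))
    return merge_clusters(clusters)


def merge_clusters(clusters: list[PiRNACluster]) -> list[PiRNACluster]:
    """Merge closely adjacent clusters to fixed point.

    An adjacent pair (A, B) on one contig with gap(A, B) < len(A) + len(B)
    is replaced by its span with summed counts; overlapping inputs count as
    gap 0 and always merge.
    """
    by_contig: dict[str, list[PiRNACluster]] = {}
    for c in clusters:
        by_contig.setdefault(c.contig, []).append(c)
    out: list[PiRNACluster] = []
    for contig in sorted(by_contig):
        cs = sorted(by_contig[contig], key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[PiRNACluster] = []
            for c in cs:
                if merged:
                    prev = merged[-1]
                    gap = max(0, c.start - prev.end)
                    if gap < prev.length + c.length:
                        merged[-1] = PiRNACluster(
                            contig, prev.start, max(prev.end, c.end),
                            unique_read_count=prev.unique_read_count
                            + c.unique_read_count,
                        )
                        changed = True
                        continue
                merged.append(c)
            cs = merged
        out.extend(cs)
    return out


def _region_records(alignments: AlignmentSet, cluster: PiRNACluster
                    ) -> pd.DataFrame:
    rec = alignments.records
    m = ((rec["contig"] == cluster.contig) & (rec["start"] >= cluster.start)
         & (rec["start"] < cluster.end))
    return rec[m]


def classify_strand(
    cluster: PiRNACluster, alignments: AlignmentSet,
    threshold: float = 0.95,
) -> str:
    """uni when strictly more than ``threshold`` of unique reads come from
    one strand, else dual; exactly at the threshold is dual."""
    sub = _region_records(alignments, cluster)
    total = sub["copies"].sum()
    if total == 0:
        raise ValueError("cluster has no reads; strandedness undefined")
    plus = sub.loc[sub["strand"] == "+", "copies"].sum()
    frac = plus / total
    return "uni" if max(frac, 1 - frac) > threshold else "dual"


def pingpong_z(alignments: AlignmentSet,
               contig: str | None = None,
               start: int | None = None,
               end: int | None = None) -> float | None:
    """Ping-pong signature z-score over a region (or the whole set).

    For every opposite-strand read pair the 5'-5' overlap o = (minus-read 5'
    position) - (plus-read 5' position) + 1 is accumulated with weight
    copies (split by 1/n_genomic_hits in all_best mode) for o in 1..20; the
    score is z = (c(10) - mean(c)) / sd(c) with mean and population sd taken
    over all 20 overlap bins.  With all pairs at o = 10 this gives
    z = sqrt(19).  Returns None when there are no opposite-strand pairs in
    range or the bin counts are flat (sd = 0).
    """
    rec = alignments.records
    w = alignments.weights
    if contig is not None:
        m = rec["contig"] == contig
        if start is not None:
            m &= (rec["start"] >= start) & (rec["start"] < end)
        rec = rec[m]
        w = w[m]
    plus = rec[rec["strand"] == "+"]
    minus = rec[rec["strand"] == "-"]
    if plus.empty or minus.empty:
        return None
    c = np.zeros(21)  # index = overlap, 1..20 used
    for contig_name, p_sub in plus.groupby("contig"):
        m_sub = minus[minus["contig"] == contig_name]
        if m_sub.empty:
            continue
        p5 = p_sub["start"].to_numpy()
        pw = w.loc[p_sub.index].to_numpy()
        # minus-strand 5' end is the last genomic base of the placement
        m5 = (m_sub["end"] - 1).to_numpy()
        mw = w.loc[m_sub.index].to_numpy()
        m_weight: dict[int, float] = {}
        for pos, wt in zip(m5, mw):
            m_weight[pos] = m_weight.get(pos, 0.0) + wt
        for pos, wt in zip(p5, pw):
            for o in range(1, 21):
                partner = pos + o - 1
                if partner in m_weight:
                    c[o] += wt * m_weight[partner]
    bins = c[1:21]
    if bins.sum() == 0:
        return None
    sd = bins.std(ddof=0)
    if sd == 0:
        # flat signature: every overlap equally common, no ping-pong signal
        return 0.0
    return float((bins[10 - 1] - bins.mean()) / sd)


def _overlap_bp(start: int, end: int, annotation: pd.DataFrame,
                contig: str) -> int:
    sel = annotation[(annotation["contig"] == contig)
                     & (annotation["end"] > start)
                     & (annotation["start"] < end)]
    if sel.empty:
        return 0
    # merge to avoid double counting overlapping annotation entries
    ivs = sorted(zip(sel["start"].clip(lower=start),
                     sel["end"].clip(upper=end)))
    total, cur_s, cur_e = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return total + (cur_e - cur_s)


def cluster_metrics(
    cluster: PiRNACluster,
    alignments: AlignmentSet,
    te_annotation: pd.DataFrame | None = None,
    gene_annotation: pd.DataFrame | None = None,
    mirna_count: int | None = None,
    total_mapped: int | None = None,
    all_mapper_alignments: AlignmentSet | None = None,
) -> PiRNACluster:
    """Fill expression, strandedness, ping-pong and content metrics.

    rpm is miRNA-normalized (count x 1e6 / miRNA-matching reads); rpkm uses
    per-million genome-mapped 23-29 nt reads as denominator, per kilobase of
    cluster.  TE and CDS fractions are annotated bp overlap / length.
    """
    sub = _region_records(alignments, cluster)
    count = float(sub["copies"].sum())
    cluster.unique_read_count = count
    mirna_count = mirna_count if mirna_count is not None else alignments.mirna_count
    total_mapped = (total_mapped if total_mapped is not None
                    else alignments.total_mapped)
    if mirna_count:
        cluster.rpm = normalize_rpm(count, mirna_count)
    if total_mapped:
        cluster.rpkm = (count * 1e6 / total_mapped) * 1000 / cluster.length
    total = sub["copies"].sum()
    if total > 0:
        cluster.plus_strand_read_fraction = float(
            sub.loc[sub["strand"] == "+", "copies"].sum() / total
        )
        cluster.type = classify_strand(cluster, alignments)
    cluster.pingpong_z_unique = pingpong_z(
        alignments, cluster.contig, cluster.start, cluster.end
    )
    if all_mapper_alignments is not None:
        cluster.pingpong_z_all = pingpong_z(
            all_mapper_alignments, cluster.contig, cluster.start, cluster.end
        )
    if te_annotation is not None:
        cluster.te_bp_fraction = _overlap_bp(
            cluster.start, cluster.end, te_annotation, cluster.contig
        ) / cluster.length
    if gene_annotation is not None:
        cluster.cds_bp_fraction = _overlap_bp(
            cluster.start, cluster.end, gene_annotation, cluster.contig
        ) / cluster.length
    return cluster


def rank_top(clusters: list[PiRNACluster], n: int = 20
             ) -> list[PiRNACluster]:
    """Top-n clusters by accumulated unique reads, ties broken by
    (contig, start); assigns 1-based ranks."""
    ranked = sorted(
        clusters,
        key=lambda c: (-c.unique_read_count, c.contig, c.start),
    )[:n]
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked
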