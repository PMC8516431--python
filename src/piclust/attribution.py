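"""Attribution of TE-family piRNAs to clusters and in-silico deletions.

Each TE family's piRNA reads are apportioned among named clusters, the
remaining clusters, and dispersed copies outside clusters, identifying the
principal source loci per family.  Mutant-vs-control comparisons quantify
the cis effect of cluster deletions (log2 fold changes of miRNA-normalized
counts, families losing most of their piRNAs, total TE-piRNA loss), genomic
TE copy numbers are recovered from DNA-seq counts, and chromosomal cluster
deletions can be applied in silico to a full annotated dataset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .smallrna import AlignmentSet, normalize_rpm

__all__ = [
    "DeletionSpec",
    "TELOMERIC_FAMILIES",
    "family_source_matrix",
    "log2_fold_change",
    "families_over_threshold",
    "total_te_loss",
    "te_copy_number",
    "apply_deletion",
]

#: telomere-associated families excluded from attribution by default; their
#: copy number varies strongly between strains
TELOMERIC_FAMILIES = frozenset({"Het-A", "HeT-A", "TAHRE", "TART"})

_COORD_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


@dataclass(frozen=True)
class DeletionSpec:
    """A chromosomal deletion given in printed browser coordinates.

    ``start``/``end`` are stored 0-based half-open; ``length_bp`` is
    end - start.  Printed ranges like ``chr2L:20104769-20243057`` parse via
    :meth:`from_string`.
    """

    label: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("deletion end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return round(self.length_bp / 1000, 1)

    @classmethod
    def from_string(cls, label: str, coords: str) -> "DeletionSpec":
        m = _COORD_RE.match(coords.replace(",", ""))
        if not m:
            raise ValueError(f"cannot parse coordinates {coords!r}")
        contig, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        return cls(label, contig, start, end)


def _assign_families(
    alignments: AlignmentSet,
    te_annotation: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
    exclude_families: frozenset = TELOMERIC_FAMILIES,
) -> pd.DataFrame:
    """Records annotated with the TE family whose insertion covers at least
    ``min_overlap_fraction`` of the read; unassigned reads are dropped."""
    rec = alignments.records
    out_rows = []
    te_by_contig = {c: sub.sort_values("start")
                    for c, sub in te_annotation.groupby("contig")}
    for idx, row in rec.iterrows():
        tes = te_by_contig.get(row.contig)
        if tes is None:
            continue
        sel = tes[(tes.end > row.start) & (tes.start < row.end)]
        best_fam, best_ov = None, 0
        for _, te in sel.iterrows():
            if te.family in exclude_families:
                continue
            ov = min(te.end, row.end) - max(te.start, row.start)
            if ov > best_ov:
                best_fam, best_ov = te.family, ov
        if best_fam is not None and best_ov >= min_overlap_fraction * row.length:
            out_rows.append((idx, best_fam))
    fam = pd.Series(dict(out_rows), name="family")
    annotated = rec.join(fam, how="inner")
    annotated["weight"] = alignments.weights.loc[annotated.index]
    return annotated


def family_source_matrix(
    alignments: AlignmentSet,
    te_annotation: pd.DataFrame,
    clusters: pd.DataFrame,
    named_clusters: list[str] | None = None,
    mode: str | None = None,
) -> pd.DataFrame:
    """Percentage of each family's piRNA reads per source locus.

    Sources are the ``named_clusters`` (by cluster_id), ``other_clusters``
    and ``outside``.  Reads are assigned to the family of the insertion
    covering >= 50% of the read; in all_best mode each placement contributes
    1/n_genomic_hits.  Rows are percentages summing to 100; families with no
    matching reads are omitted.
    """
    mode = mode or alignments.mode
    annotated = _assign_families(alignments, te_annotation)
    if annotated.empty:
        return pd.DataFrame()
    named = list(named_clusters or [])

    def source_of(row) -> str:
        sel = clusters[(clusters.contig == row.contig)
                       & (clusters.start <= row.start)
                       & (clusters.end > row.start)]
        if sel.empty:
            return "outside"
        cid = str(sel.iloc[0].get("cluster_id"))
        return cid if cid in named else "other_clusters"

    annotated["source"] = [source_of(r) for _, r in annotated.iterrows()]
    table = annotated.pivot_table(
        index="family", columns="source", values="weight", aggfunc="sum",
        fill_value=0.0,
    )
    for col in named + ["other_clusters", "outside"]:
        if col not in table.columns:
            table[col] = 0.0
    table = table[named + ["other_clusters", "outside"]]
    return table.div(table.sum(axis=1), axis=0) * 100


def log2_fold_change(
    mutant_counts: pd.Series,
    control_counts: pd.Series,
    mutant_mirna: float,
    control_mirna: float,
    pseudo_rpm: float = 1.0,
) -> pd.Series:
    """Per-item log2 fold change of miRNA-normalized counts.

    Both samples are scaled to reads per million miRNA-matching reads and a
    pseudo-count of ``pseudo_rpm`` bounds the ratio; items at zero in both
    samples are NaN (no evidence either way).
    """
    idx = mutant_counts.index.union(control_counts.index)
    m = mutant_counts.reindex(idx, fill_value=0.0).astype(float)
    c = control_counts.reindex(idx, fill_value=0.0).astype(float)
    m_rpm = m.map(lambda v: normalize_rpm(v, mutant_mirna))
    c_rpm = c.map(lambda v: normalize_rpm(v, control_mirna))
    out = np.log2((m_rpm + pseudo_rpm) / (c_rpm + pseudo_rpm))
    out[(m == 0) & (c == 0)] = np.nan
    return out


def families_over_threshold(
    values: pd.Series, threshold: float
) -> list[str]:
    """Families whose value strictly exceeds ``threshold`` (e.g. loss
    fraction > 0.75, or source share > 0.50); exactly at the threshold is
    excluded."""
    return sorted(values.index[values > threshold])


def total_te_loss(
    mutant_total: float, control_total: float
) -> float:
    """Percentage of TE-matching piRNAs lost in the mutant.

    Inputs are miRNA-normalized all-mapper totals; the result is
    100 * (1 - mutant/control), floored at 0 (a gain reports as 0 loss).
    """
    if control_total == 0:
        raise ZeroDivisionError("control TE-matching total is zero")
    return max(0.0, 100.0 * (1.0 - mutant_total / control_total))


def te_copy_number(
    read_count: float, consensus_length_bp: float, coverage_depth: float
) -> float:
    """Genomic copies of a TE family from DNA-seq counts.

    copies = read_count * 300 / consensus_length / coverage_depth, where 300
    is the sequenced base pairs contributed by one 150 nt paired-end read
    pair.
    """
    if consensus_length_bp <= 0 or coverage_depth <= 0:
        raise ValueError("consensus length and coverage must be positive")
    return read_count * 300.0 / consensus_length_bp / coverage_depth


@dataclass
class DeletionReport:
    spec: DeletionSpec
    length_bp: int
    cluster_overlap_bp: dict[str, int] = field(default_factory=dict)
    reads_removed: float = 0.0


def _shift_intervals(df: pd.DataFrame, contig: str, start: int, end: int
                     ) -> pd.DataFrame:
    """Excise [start, end) from interval annotations on ``contig``:
    contained entries are dropped, straddling ones clipped, downstream ones
    shifted left; ordering is preserved."""
    length = end - start
    df = df.copy()
    on = df["contig"] == contig
    contained = on & (df["start"] >= start) & (df["end"] <= end)
    df = df[~contained].copy()
    on = df["contig"] == contig
    # clip partial overlaps
    left_clip = on & (df["start"] < start) & (df["end"] > start) & (df["end"] <= end)
    df.loc[left_clip, "end"] = start
    right_clip = on & (df["start"] >= start) & (df["start"] < end) & (df["end"] > end)
    df.loc[right_clip, "start"] = end
    spanning = on & (df["start"] < start) & (df["end"] > end)
    df.loc[spanning, "end"] -= length
    downstream_start = on & (df["start"] >= end)
    df.loc[downstream_start, "start"] -= length
    downstream_end = on & (df["end"] > end)
    df.loc[downstream_end & ~spanning, "end"] -= length
    return df.reset_index(drop=True)


def apply_deletion(
    genome: dict[str, str],
    genes: pd.DataFrame,
    te_annotation: pd.DataFrame,
    clusters: pd.DataFrame,
    alignments: AlignmentSet,
    spec: DeletionSpec,
) -> tuple[dict, DeletionReport]:
    """Apply a chromosomal deletion in silico.

    The interval is excised from the genome sequence and from every
    annotation table (contained entries dropped, partial overlaps clipped,
    downstream coordinates shifted left by the deletion length); alignment
    records overlapping the interval are dropped.  Returns the modified
    dataset and a report with the deletion length and its bp overlap with
    each cluster.
    """
    if spec.contig not in genome:
        raise ValueError(f"contig {spec.contig} not in genome")
    clen = len(genome[spec.contig])
    if spec.start < 0 or spec.end > clen:
        raise ValueError("deletion overlaps a contig boundary")
    seq = genome[spec.contig]
    new_genome = dict(genome)
    new_genome[spec.contig] = seq[:spec.start] + seq[spec.end:]
    overlap = {}
    for _, row in clusters.iterrows():
        ov = min(spec.end, int(row.end)) - max(spec.start, int(row.start))
        if ov > 0:
            overlap[str(row.get("cluster_id", f"{row.contig}:{row.start}"))] = ov
    rec = alignments.records
    on = rec["contig"] == spec.contig
    inside = on & (rec["start"] < spec.end) & (rec["end"] > spec.start)
    removed = float(rec.loc[inside, "copies"].sum())
    kept = rec[~inside].copy()
    shift = kept["contig"].eq(spec.contig) & (kept["start"] >= spec.end)
    kept.loc[shift, ["start", "end"]] -= spec.length_bp
    new_alignments = AlignmentSet(
        kept.reset_index(drop=True), alignments.mode,
        mirna_count=alignments.mirna_count,
        total_mapped=alignments.total_mapped,
        contig_lengths={
            n: (len(s) if n != spec.contig else clen - spec.length_bp)
            for n, s in genome.items()
        },
    )
    out = {
        "genome": new_genome,
        "genes": _shift_intervals(genes, spec.contig, spec.start, spec.end),
        "te_annotation": _shift_intervals(
            te_annotation, spec.contig, spec.start, spec.end),
        "clusters": _shift_intervals(
            clusters, spec.contig, spec.start, spec.end),
        "alignments": new_alignments,
    }
    report = DeletionReport(spec, spec.length_bp, overlap, removed)
    return out, report
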