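"""Repeat-landscape analytics.

Kimura two-parameter divergence from transition/transversion proportions,
TE/CDS content and divergence profiles around cluster borders, a
deterministic heterochromatin designation (contiguous two-fold TE-density
runs reaching a contig end), strand-bias correlation between TE insertions
and piRNA reads, and per-compartment divergence summaries.

Insertion divergence is normally ingested from a RepeatMasker-style
annotation; :func:`kimura2p` recomputes it from pairwise substitution
proportions where alignments (or simulations) are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kimura2p",
    "ChromatinPartition",
    "border_content_profile",
    "divergence_border_profile",
    "call_heterochromatin",
    "strand_bias_correlation",
    "divergence_class_summary",
]


def kimura2p(P: float, Q: float) -> float:
    """Kimura two-parameter divergence from transition (P) and transversion
    (Q) proportions: K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).

    Returned as a proportion (multiply by 100 for percent).  Raises
    ValueError when the substitution proportions saturate the model
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        raise ValueError(
            f"Kimura divergence saturated for P={P}, Q={Q}"
        )
    return -0.5 * math.log(a * math.sqrt(b))


@dataclass
class ChromatinPartition:
    """Heterochromatin/euchromatin intervals tiling each contig.

    ``intervals`` columns: contig, start, end, label in {"HC", "EC"}.
    """

    intervals: pd.DataFrame

    def label_at(self, contig: str, position: float) -> str:
        sel = self.intervals[
            (self.intervals.contig == contig)
            & (self.intervals.start <= position)
            & (self.intervals.end > position)
        ]
        return sel.iloc[0]["label"] if len(sel) else "EC"


def _interval_cover(annotation: pd.DataFrame, contig: str,
                    lo: int, hi: int) -> int:
    """Total annotated bp within [lo, hi), overlaps merged."""
    sel = annotation[(annotation["contig"] == contig)
                     & (annotation["end"] > lo) & (annotation["start"] < hi)]
    if sel.empty:
        return 0
    ivs = sorted(zip(sel["start"].clip(lower=lo), sel["end"].clip(upper=hi)))
    total, cs, ce = 0, *ivs[0]
    for s, e in ivs[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def border_content_profile(
    clusters: pd.DataFrame,
    te_annotation: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 500,
    flank: int = 10_000,
    internal: int = 5_000,
) -> pd.DataFrame:
    """Mean TE and CDS bp fractions in fixed windows around cluster borders.

    For each border, ``flank // window`` flanking and ``internal // window``
    internal windows (20 + 10 at the defaults); fractions are averaged across
    clusters per window index.  Window index 0 is the window immediately
    inside the border, negative indices lie in the flank.  Clusters whose
    profile would extend beyond the contig are dropped from that border's
    average; internal windows beyond a short cluster's midpoint are skipped.

    ``clusters`` needs columns contig/start/end.  Returns a tidy frame with
    columns border, window_index, te_fraction, cds_fraction, n_clusters.
    """
    n_flank = flank // window
    n_internal = internal // window
    acc: dict[tuple[str, int], list[tuple[float, float]]] = {}
    for _, row in clusters.iterrows():
        contig, start, end = row["contig"], int(row["start"]), int(row["end"])
        clen = contig_lengths.get(contig)
        length = end - start
        for border, sign in (("left", +1), ("right", -1)):
            origin = start if border == "left" else end
            if border == "left" and origin - flank < 0:
                continue
            if border == "right" and clen is not None and origin + flank > clen:
                continue
            for idx in range(-n_flank, n_internal):
                # idx >= 0: internal window idx; idx < 0: flank window
                off_lo = idx * window
                off_hi = off_lo + window
                if sign > 0:
                    lo, hi = origin + off_lo, origin + off_hi
                else:
                    lo, hi = origin - off_hi, origin - off_lo
                if idx >= 0 and (idx + 1) * window > length:
                    continue  # internal window past the far border
                te = _interval_cover(te_annotation, contig, lo, hi) / window
                cds = _interval_cover(gene_annotation, contig, lo, hi) / window
                acc.setdefault((border, idx), []).append((te, cds))
    rows = []
    for (border, idx), vals in sorted(acc.items()):
        te = float(np.mean([v[0] for v in vals]))
        cds = float(np.mean([v[1] for v in vals]))
        rows.append((border, idx, te, cds, len(vals)))
    return pd.DataFrame(
        rows, columns=["border", "window_index", "te_fraction",
                       "cds_fraction", "n_clusters"]
    )


def _window_divergence(te_annotation: pd.DataFrame, contig: str,
                       lo: int, hi: int) -> float | None:
    """Length-weighted mean divergence of insertions overlapping [lo, hi);
    None when no TE bp falls in the window."""
    sel = te_annotation[(te_annotation["contig"] == contig)
                        & (te_annotation["end"] > lo)
                        & (te_annotation["start"] < hi)]
    if sel.empty:
        return None
    bp = (sel["end"].clip(upper=hi) - sel["start"].clip(lower=lo)).to_numpy()
    div = sel["divergence_pct"].to_numpy()
    return float(np.average(div, weights=bp))


def divergence_border_profile(
    clusters: pd.DataFrame,
    te_annotation: pd.DataFrame,
    mode: str = "absolute_500bp",
    window: int = 500,
    flank: int = 10_000,
    internal: int = 5_000,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Windowed mean TE divergence around cluster borders.

    ``absolute_500bp``: fixed ``window``-bp windows spanning ``flank`` bp
    outside and ``internal`` bp inside each border.  ``percent_halves``:
    each cluster is rescaled to its own length — the inner half of the
    cluster (+50% of length) and a flank of the same physical length
    (-50%) are each split into ``n_bins`` bins.  Per cluster the mean
    divergence of each window is taken first (length-weighted over
    insertions); windows with no TE bp are skipped in the cross-cluster
    average.  Window/bin index < 0 is flanking, >= 0 internal.
    """
    if mode not in ("absolute_500bp", "percent_halves"):
        raise ValueError(f"unknown mode {mode!r}")
    acc: dict[tuple[str, int], list[float]] = {}
    for _, row in clusters.iterrows():
        contig, start, end = row["contig"], int(row["start"]), int(row["end"])
        length = end - start
        for border, sign in (("left", +1), ("right", -1)):
            origin = start if border == "left" else end
            if mode == "absolute_500bp":
                span_out, span_in, step = flank, internal, window
                n_out, n_in = flank // window, internal // window
            else:
                half = length // 2
                span_out, span_in = half, half
                step = max(1, half // n_bins)
                n_out = n_in = n_bins
            for idx in range(-n_out, n_in):
                off_lo, off_hi = idx * step, (idx + 1) * step
                if sign > 0:
                    lo, hi = origin + off_lo, origin + off_hi
                else:
                    lo, hi = origin - off_hi, origin - off_lo
                val = _window_divergence(te_annotation, contig, lo, hi)
                if val is not None:
                    acc.setdefault((border, idx), []).append(val)
    rows = [
        (border, idx, float(np.mean(vals)), len(vals))
        for (border, idx), vals in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["border", "window_index", "mean_divergence",
                       "n_clusters"]
    )


def call_heterochromatin(
    te_annotation: pd.DataFrame,
    contig_lengths: dict[str, int],
    density_window: int = 50_000,
) -> ChromatinPartition:
    """Designate heterochromatin deterministically.

    Contigs are tiled with ``density_window`` windows (last window partial);
    maximal runs of windows with TE bp density at least twice the genomic
    average are labeled heterochromatin when the run includes a contig end,
    all other sequence euchromatin.  A contig shorter than one window is
    handled as a single window.
    """
    total_te = 0
    total_bp = sum(contig_lengths.values())
    for contig, clen in contig_lengths.items():
        total_te += _interval_cover(te_annotation, contig, 0, clen)
    genomic_avg = total_te / total_bp if total_bp else 0.0
    rows = []
    for contig in sorted(contig_lengths):
        clen = contig_lengths[contig]
        bounds = list(range(0, clen, density_window)) + [clen]
        windows = [(bounds[i], bounds[i + 1])
                   for i in range(len(bounds) - 1) if bounds[i + 1] > bounds[i]]
        dense = [
            genomic_avg > 0
            and _interval_cover(te_annotation, contig, lo, hi) / (hi - lo)
            >= 2 * genomic_avg
            for lo, hi in windows
        ]
        n = len(windows)
        hc = [False] * n
        # maximal dense runs touching either contig end
        i = 0
        while i < n:
            if dense[i]:
                j = i
                while j + 1 < n and dense[j + 1]:
                    j += 1
                if i == 0 or j == n - 1:
                    for k in range(i, j + 1):
                        hc[k] = True
                i = j + 1
            else:
                i += 1
        # collapse consecutive same-label windows into intervals
        i = 0
        while i < n:
            j = i
            while j + 1 < n and hc[j + 1] == hc[i]:
                j += 1
            rows.append((contig, windows[i][0], windows[j][1],
                         "HC" if hc[i] else "EC"))
            i = j + 1
    return ChromatinPartition(
        pd.DataFrame(rows, columns=["contig", "start", "end", "label"])
    )


def strand_bias_correlation(
    clusters: pd.DataFrame,
    alignments,
    te_annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, float | None]:
    """Per-cluster plus-strand fractions of TE insertions and of unique
    reads, plus their Pearson correlation across clusters.

    Returns ``(frame, r)``; r is None with fewer than 3 clusters or with
    zero variance on either axis.
    """
    rec = alignments.records
    rows = []
    for _, row in clusters.iterrows():
        contig, start, end = row["contig"], int(row["start"]), int(row["end"])
        tes = te_annotation[
            (te_annotation.contig == contig)
            & (te_annotation.end > start) & (te_annotation.start < end)
        ]
        te_bp = (tes["end"].clip(upper=end) - tes["start"].clip(lower=start))
        te_plus = (
            float(te_bp[tes["strand"] == "+"].sum() / te_bp.sum())
            if te_bp.sum() else np.nan
        )
        reads = rec[(rec.contig == contig) & (rec.start >= start)
                    & (rec.start < end)]
        total = reads["copies"].sum()
        read_plus = (
            float(reads.loc[reads.strand == "+", "copies"].sum() / total)
            if total else np.nan
        )
        rows.append((row.get("cluster_id", f"{contig}:{start}-{end}"),
                     te_plus, read_plus))
    frame = pd.DataFrame(
        rows, columns=["cluster_id", "te_plus_fraction", "read_plus_fraction"]
    ).dropna()
    r = None
    if len(frame) >= 3:
        x = frame["te_plus_fraction"].to_numpy()
        y = frame["read_plus_fraction"].to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(stats.pearsonr(x, y).statistic)
    return frame, r


def divergence_class_summary(
    te_annotation: pd.DataFrame,
    clusters: pd.DataFrame,
    partition: ChromatinPartition,
) -> pd.DataFrame:
    """Divergence distribution per compartment {cluster, HC, EC}.

    Each insertion is assigned by its midpoint: to a cluster if the midpoint
    falls inside one, otherwise to the chromatin partition's label there.
    Returns per-class mean divergence and a histogram in 1% bins (columns
    class, mean_divergence, n, hist with bin counts 0-100%).
    """
    assignments = []
    for _, te in te_annotation.iterrows():
        mid = (te["start"] + te["end"]) / 2
        in_cluster = (
            (clusters["contig"] == te["contig"])
            & (clusters["start"] <= mid) & (clusters["end"] > mid)
        ).any()
        if in_cluster:
            cls = "cluster"
        else:
            cls = partition.label_at(te["contig"], mid)
        assignments.append(cls)
    df = te_annotation.assign(cls=assignments)
    rows = []
    for cls in ("cluster", "EC", "HC"):
        sel = df[df.cls == cls]
        hist = np.histogram(
            sel["divergence_pct"], bins=np.arange(0, 101)
        )[0].tolist() if len(sel) else [0] * 100
        rows.append((
            cls,
            float(sel["divergence_pct"].mean()) if len(sel) else np.nan,
            len(sel),
            hist,
        ))
    return pd.DataFrame(
        rows, columns=["cls", "mean_divergence", "n", "hist"]
    )
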