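"""Signed-permutation breakpoint analysis around genomic loci.

Gene order of one species expressed in the coordinate and orientation frame
of another forms a signed permutation; adjacencies that deviate from the
identity mark rearrangement breakpoints, and sign reversals at those
adjacencies mark inversion breakpoints.  Breakpoint frequencies in the window
between a locus' flanking gene arrays are compared against the flank-window
background with the z-statistic Z0 = (x0 - mu) / sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SignedPermutation",
    "BreakpointSet",
    "EnrichmentResult",
    "build_signed_permutation",
    "find_breakpoints",
    "profile_breakpoints",
    "sample_background",
    "enrichment_zscore",
    "normal_upper_p",
]


@dataclass(frozen=True)
class SignedPermutation:
    """Signed integers whose absolute values form a permutation of 1..n.

    ``elements`` excludes the boundary padding; analyses implicitly pad with
    0 on the left and n+1 on the right so terminal rearrangements count.
    """

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        absvals = sorted(abs(e) for e in self.elements)
        n = len(self.elements)
        if absvals != list(range(1, n + 1)):
            raise ValueError(
                "absolute values must be a permutation of 1..n, got "
                f"{self.elements}"
            )

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def padded(self) -> tuple[int, ...]:
        n = len(self.elements)
        return (0, *self.elements, n + 1)


@dataclass(frozen=True)
class BreakpointSet:
    """Disordered adjacencies of a padded signed permutation.

    ``adjacencies`` holds indices i (into the padded sequence) such that
    p[i+1] - p[i] != 1; ``inversion_flags`` marks, for each, whether the two
    elements differ in sign (padding counts as +).
    """

    perm: SignedPermutation
    adjacencies: tuple[int, ...]
    inversion_flags: tuple[bool, ...]

    @property
    def n_breakpoints(self) -> int:
        return len(self.adjacencies)

    @property
    def n_inversion_breakpoints(self) -> int:
        return sum(self.inversion_flags)

    @property
    def inversion_adjacencies(self) -> tuple[int, ...]:
        return tuple(
            a for a, f in zip(self.adjacencies, self.inversion_flags) if f
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Breakpoint enrichment between flanks relative to flank windows."""

    x0: float
    mu: float
    sigma: float
    z0: float | None
    p: float | None
    n_flank_windows: int = 0


def _sign(x: int) -> int:
    # padding elements (0 and n+1) are treated as forward-oriented
    return -1 if x < 0 else 1


def build_signed_permutation(
    subject_order: list[tuple[str, str]],
    query_order: list[tuple[str, str]],
) -> SignedPermutation:
    """Express subject gene order in the query's coordinate frame.

    Parameters
    ----------
    subject_order, query_order:
        Ordered lists of ``(ortholog_group, strand)`` with strand ``+``/``-``,
        listed along the chromosome.  Genes present in only one species are
        dropped; each ortholog group must appear at most once per species.

    Returns
    -------
    SignedPermutation where the query positions are renumbered 1..n and the
    sign is positive when subject and query strands agree.
    """
    q_ids = [g for g, _ in query_order]
    s_ids = [g for g, _ in subject_order]
    if len(set(q_ids)) != len(q_ids) or len(set(s_ids)) != len(s_ids):
        raise ValueError("duplicated ortholog group violates one-to-one mapping")
    shared = set(q_ids) & set(s_ids)
    if not shared:
        raise ValueError("no shared ortholog groups between query and subject")
    q_rank = {g: i + 1 for i, (g, _) in
              enumerate((g, s) for g, s in query_order if g in shared)}
    q_strand = {g: s for g, s in query_order if g in shared}
    elements = []
    for g, s_strand in subject_order:
        if g not in shared:
            continue
        sign = 1 if s_strand == q_strand[g] else -1
        elements.append(sign * q_rank[g])
    return SignedPermutation(tuple(elements))


def find_breakpoints(perm: SignedPermutation) -> BreakpointSet:
    """Report adjacencies of the padded permutation with p[i+1] - p[i] != 1.

    An adjacency is inversion-flagged when its two elements carry opposite
    signs, padding treated as positive.
    """
    padded = perm.padded
    adjacencies: list[int] = []
    flags: list[bool] = []
    for i in range(len(padded) - 1):
        if padded[i + 1] - padded[i] != 1:
            adjacencies.append(i)
            flags.append(_sign(padded[i]) != _sign(padded[i + 1]))
    return BreakpointSet(perm, tuple(adjacencies), tuple(flags))


def breakpoint_positions(
    bps: BreakpointSet, gene_midpoints: list[float], contig_length: float
) -> list[float]:
    """Genomic positions of breakpoints: midpoint of the intergenic span
    between the two genes anchoring each disordered adjacency.

    ``gene_midpoints`` are subject-genome midpoints in subject order (same
    order as the permutation elements); padded boundaries anchor at 0 and
    ``contig_length``.
    """
    anchors = [0.0, *gene_midpoints, float(contig_length)]
    return [
        0.5 * (anchors[i] + anchors[i + 1]) for i in bps.adjacencies
    ]


def profile_breakpoints(
    positions: list[tuple[str, float]],
    loci: list[tuple[str, int, int]],
    window: int = 15_000,
    extent: int = 150_000,
    contig_lengths: dict[str, int] | None = None,
) -> dict:
    """Bin breakpoint events by signed distance to the nearest locus border.

    Events falling inside a locus (between its flanks) accumulate in the
    central ``x0`` bin; flanking events fall in ``extent // window`` windows
    per side, negative indices left of the locus.  Frequencies are events per
    window averaged over loci; a flank window that runs off the contig end is
    excluded from averaging for that locus.

    Parameters
    ----------
    positions: ``(contig, position)`` breakpoint events.
    loci: ``(contig, start, end)`` half-open locus intervals.

    Returns dict with ``x0`` (mean events inside loci), ``offsets`` (window
    center offsets in bp, signed), ``frequencies`` (per-window mean events)
    and ``n_loci``.
    """
    n_side = max(1, extent // window)
    offsets = [
        -(i + 0.5) * window for i in reversed(range(n_side))
    ] + [(i + 0.5) * window for i in range(n_side)]
    counts = np.zeros(2 * n_side)
    valid = np.zeros(2 * n_side)
    x0_total = 0.0
    n_loci = 0
    by_contig: dict[str, list[float]] = {}
    for contig, pos in positions:
        by_contig.setdefault(contig, []).append(pos)
    for contig, start, end in loci:
        n_loci += 1
        events = by_contig.get(contig, [])
        clen = None if contig_lengths is None else contig_lengths.get(contig)
        # left flank windows end at `start`, right flank windows start at `end`
        for i in range(n_side):
            # left side, window i counts outward: [-(i+1)w, -iw) rel. to start
            lo, hi = start - (i + 1) * window, start - i * window
            j = n_side - 1 - i
            if lo >= 0:
                valid[j] += 1
                counts[j] += sum(1 for p in events if lo <= p < hi)
            # right side: [end + iw, end + (i+1)w)
            lo, hi = end + i * window, end + (i + 1) * window
            j = n_side + i
            if clen is None or hi <= clen:
                valid[j] += 1
                counts[j] += sum(1 for p in events if lo <= p < hi)
        x0_total += sum(1 for p in events if start <= p < end)
    freqs = np.divide(counts, valid, out=np.zeros_like(counts), where=valid > 0)
    return {
        "x0": x0_total / n_loci if n_loci else 0.0,
        "offsets": offsets,
        "frequencies": freqs.tolist(),
        "n_loci": n_loci,
    }


def sample_background(
    contig_lengths: dict[str, int],
    locus_lengths: list[int],
    n_sets: int = 10,
    seed: int | None = None,
) -> list[list[tuple[str, int, int]]]:
    """Draw random genomic locus sets length-matched to the observed loci.

    Each of ``n_sets`` sets contains one interval per observed locus, with the
    same length multiset, placed uniformly on contigs that can hold it.
    """
    rng = np.random.default_rng(seed)
    contigs = list(contig_lengths.items())
    sets = []
    for _ in range(n_sets):
        out = []
        for length in locus_lengths:
            fitting = [(c, ln) for c, ln in contigs if ln >= length]
            if not fitting:
                raise ValueError(
                    f"locus length {length} exceeds every contig length"
                )
            # weight by available placements for uniformity over positions
            weights = np.array([ln - length + 1 for _, ln in fitting], float)
            idx = rng.choice(len(fitting), p=weights / weights.sum())
            contig, clen = fitting[idx]
            start = int(rng.integers(0, clen - length + 1))
            out.append((contig, start, start + length))
        sets.append(out)
    return sets


def enrichment_zscore(
    x0: float, flank_frequencies: list[float]
) -> EnrichmentResult:
    """Z0 = (x0 - mu) / sigma against the flank-window frequency background.

    mu and sigma are the mean and population standard deviation of the flank
    window frequencies; p is the one-sided upper-tail normal probability.
    With sigma = 0 the z-score is undefined and reported as None.
    """
    flank = np.asarray(flank_frequencies, dtype=float)
    if flank.size < 2:
        raise ValueError("need at least 2 flank windows")
    mu = float(flank.mean())
    sigma = float(flank.std(ddof=0))
    if sigma == 0.0:
        return EnrichmentResult(x0, mu, sigma, None, None, flank.size)
    z0 = (x0 - mu) / sigma
    return EnrichmentResult(x0, mu, sigma, z0, normal_upper_p(z0), flank.size)


def normal_upper_p(z: float) -> float:
    """One-sided upper-tail standard normal probability, 1 - Phi(z)."""
    return float(stats.norm.sf(z))
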