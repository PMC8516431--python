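"""Canonical validation studies on synthetic worlds.

Each study fixes one experimental design — world geometry, planted effect
sizes, read budgets — and measures how well the corresponding analysis stage
recovers the planted truth.  The designs are deliberately scaled-down
genomes (hundreds of kb rather than hundreds of Mb) with read budgets in the
thousands; the methods note discusses what that does and does not show.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import attribution, pipeline, rearrange, repeatscape, synthio

__all__ = [
    "enrichment_study",
    "recovery_study",
    "deletion_study",
    "kimura_oracle_study",
    "reversal_oracle_study",
]


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def enrichment_study(seed: int, hotspot_bias: float) -> float | None:
    """Breakpoint enrichment Z0 on a 4-species world.

    Four 300 kb contigs carry two planted clusters each (8 loci, 40 locus
    profiles over 5 genomes); each branch draws ~2 inversions whose
    breakpoints either concentrate in the hotspot windows at cluster
    borders (``hotspot_bias=1``) or fall in random intergenic space
    (``hotspot_bias=0``).  Returns Z0 (None if undefined).
    """
    config = synthio.WorldConfig(
        n_species=5, seed=seed, inversion_rate=2.0,
        hotspot_bias=hotspot_bias,
        # star tree: every branch is private to one leaf, so each inversion
        # differentiates that species from all others (maximal power per
        # event for a fixed event budget)
        tree="(sp1:20,sp2:20,sp3:20,sp4:20,sp5:20);",
        contig_lengths=[300_000] * 4, n_genes=240,
        euchrom_te_coverage=0.25,
        cluster_specs=[synthio.ClusterSpec(6000, "dual", 800)
                       for _ in range(8)],
    )
    leaves, _ = pipeline.simulate_world(config)
    genes = {t.name: t.genes for t in leaves}
    loci = {t.name: t.true_clusters for t in leaves}
    clens = {t.name: t.contig_lengths() for t in leaves}
    res = pipeline.trace_breakpoints(genes, loci, clens)
    if res is None:
        return None
    return res.enrichment.z0


def recovery_study(seed: int, pingpong_fraction: float = 0.5) -> dict:
    """Cluster-caller truth recovery on a single-species world.

    Five planted clusters (two uni-strand) on a 500 kb contig emit 23-29 nt
    reads with a 75% 1U bias and the requested ping-pong pairing; the study
    maps the library, calls clusters with default parameters and scores
    recovery (Jaccard >= 0.5 against planted intervals), uni-strand
    classification and the ping-pong z-score of recovered clusters.
    """
    specs = [
        synthio.ClusterSpec(8000, "dual", 1500),
        synthio.ClusterSpec(7000, "uni", 1200),
        synthio.ClusterSpec(6000, "dual", 1000),
        synthio.ClusterSpec(9000, "uni", 1400),
        synthio.ClusterSpec(6000, "dual", 900),
    ]
    config = synthio.WorldConfig(
        n_species=1, seed=seed, inversion_rate=0.0,
        contig_lengths=[500_000], n_genes=70, cluster_specs=specs,
    )
    leaves, _ = pipeline.simulate_world(config)
    truth = leaves[0]
    ds, _ = pipeline.build_species_dataset(
        truth, read_params={"pingpong_fraction": pingpong_fraction},
        seed=seed + 1,
    )
    called = pipeline.call_and_rank(ds, top_n=20)
    recovered = 0
    uni_total = uni_correct = 0
    zs = []
    for _, planted in truth.true_clusters.iterrows():
        best = None
        for c in called:
            if c.contig != planted.contig:
                continue
            j = _jaccard((planted.start, planted.end), (c.start, c.end))
            if best is None or j > best[0]:
                best = (j, c)
        if best and best[0] >= 0.5:
            recovered += 1
            c = best[1]
            if c.pingpong_z_unique is not None:
                zs.append(c.pingpong_z_unique)
            if planted.strand_mode == "uni":
                uni_total += 1
                uni_correct += c.type == "uni"
    n = len(truth.true_clusters)
    return {
        "n_planted": n,
        "recovery_rate": recovered / n,
        "uni_total": uni_total,
        "uni_correct": uni_correct,
        "min_pingpong_z": min(zs) if zs else None,
        "median_pingpong_z": float(np.median(zs)) if zs else None,
    }


def deletion_study(seed: int) -> dict:
    """End-to-end in-silico deletion of the top planted cluster.

    A three-cluster single-species world is simulated and mapped; the top
    called cluster is deleted in silico; log2 fold changes of per-cluster
    unique read counts (mutant vs control, shared miRNA ledger) and the
    total TE-matching piRNA loss are compared with the planted share of the
    deleted cluster among TE-matching reads.
    """
    config = synthio.WorldConfig(
        n_species=1, seed=seed, inversion_rate=0.0,
        contig_lengths=[400_000], n_genes=60,
        cluster_specs=[
            synthio.ClusterSpec(8000, "dual", 2000),
            synthio.ClusterSpec(7000, "dual", 1200),
            synthio.ClusterSpec(6000, "uni", 800),
        ],
    )
    leaves, _ = pipeline.simulate_world(config)
    truth = leaves[0]
    ds, table = pipeline.build_species_dataset(truth, seed=seed + 1)
    pipeline.call_and_rank(ds)
    clusters = ds.clusters
    top = clusters.iloc[0]
    spec = attribution.DeletionSpec(
        "topdel", top.contig, int(top.start), int(top.end))
    out, report = attribution.apply_deletion(
        truth.genome, truth.genes, truth.te_insertions, clusters,
        ds.alignments, spec,
    )

    def per_cluster_counts(aln, cl):
        rec = aln.records
        vals = {}
        for _, r in cl.iterrows():
            sel = rec[(rec.contig == r.contig) & (rec.start >= r.start)
                      & (rec.start < r.end)]
            vals[r.cluster_id] = float(sel.copies.sum())
        return pd.Series(vals)

    ctl = per_cluster_counts(ds.alignments, clusters)
    mut = per_cluster_counts(out["alignments"], out["clusters"])
    fc = attribution.log2_fold_change(
        mut, ctl, ds.alignments.mirna_count, ds.alignments.mirna_count)
    cis_fc = float(fc[top.cluster_id])
    trans_fc = fc.drop(top.cluster_id).abs()

    ctl_fam = attribution._assign_families(ds.alignments,
                                           truth.te_insertions)
    mut_fam = attribution._assign_families(out["alignments"],
                                           out["te_annotation"])
    loss = attribution.total_te_loss(
        float(mut_fam.weight.sum()), float(ctl_fam.weight.sum()))

    # planted share: TE-matching truth reads (>= 50% covered by an
    # insertion) originating from the planted cluster under the deletion
    tes = truth.te_insertions
    tc = truth.true_clusters
    planted = tc[(tc.contig == top.contig) & (tc.end > top.start)
                 & (tc.start < top.end)].iloc[0]

    def te_match(row):
        sel = tes[(tes.contig == row.contig) & (tes.end > row.start)
                  & (tes.start < row.end)]
        if sel.empty:
            return False
        ov = (sel.end.clip(upper=row.end)
              - sel.start.clip(lower=row.start)).max()
        return ov >= 0.5 * (row.end - row.start)

    te_reads = table[table.apply(te_match, axis=1)]
    planted_share = 100.0 * float(
        (te_reads.origin == planted.cluster_id).mean())
    return {
        "cis_log2fc": cis_fc,
        "max_trans_abs_log2fc": float(trans_fc.max()),
        "te_loss_pct": loss,
        "planted_share_pct": planted_share,
        "deletion_length_bp": report.length_bp,
    }


_K2P_STEP = {
    # single-substitution step: transition with prob pt, each transversion
    # with prob (1-pt)/2; bases indexed A,G,C,T so transitions are 0<->1
    # and 2<->3
    "A": "GCT", "G": "ACT", "C": "TAG", "T": "CAG",
}


def kimura_oracle_study(seed: int, length: int = 10_000,
                        kappa: float = 2.0) -> dict:
    """Validate the Kimura estimator against a substitution-counting oracle.

    Pairs of 10 kb sequences are diverged by an explicit per-site Poisson
    substitution process at several expected divergences (transitions
    ``kappa`` times as likely as each transversion type per event); the
    realized number of substitution events per site is the oracle, and the
    two-parameter estimate from the observed transition/transversion
    proportions must agree within 5% for K <= 0.3.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("AGCT"))
    transition = {0: 1, 1: 0, 2: 3, 3: 2}
    transversions = {0: (2, 3), 1: (2, 3), 2: (0, 1), 3: (0, 1)}
    p_ts = kappa / (kappa + 2.0)
    results = []
    for target_k in (0.05, 0.1, 0.2, 0.3):
        anc = rng.integers(0, 4, size=length)
        der = anc.copy()
        n_events = rng.poisson(target_k, size=length)
        for site in np.flatnonzero(n_events):
            for _ in range(n_events[site]):
                if rng.random() < p_ts:
                    der[site] = transition[der[site]]
                else:
                    der[site] = transversions[der[site]][rng.integers(0, 2)]
        realized = float(n_events.mean())  # oracle: events per site
        diff = der != anc
        is_ts = np.array([transition[a] == d
                          for a, d in zip(anc[diff], der[diff])])
        P = float(is_ts.sum()) / length
        Q = float((~is_ts).sum()) / length
        est = repeatscape.kimura2p(P, Q)
        results.append((realized, est))
    rel_errors = [abs(est - truth) / truth for truth, est in results]
    return {
        "pairs": results,
        "max_rel_error": max(rel_errors),
    }


def _reverse(perm: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Apply a segment reversal (inclusive 0-based indices) to a signed
    permutation: order flips and signs negate."""
    return perm[:i] + tuple(-x for x in reversed(perm[i:j + 1])) + perm[j + 1:]


def _one_reversal_from_identity(perm: tuple[int, ...]) -> tuple | None:
    """Brute force: the (i, j) reversal turning the identity into ``perm``,
    or None if no single reversal does."""
    n = len(perm)
    identity = tuple(range(1, n + 1))
    for i in range(n):
        for j in range(i, n):
            if _reverse(identity, i, j) == perm:
                return (i, j)
    return None


def _all_signed_permutations(n: int):
    from itertools import permutations, product
    for p in permutations(range(1, n + 1)):
        for signs in product((1, -1), repeat=n):
            yield tuple(s * v for s, v in zip(signs, p))


def reversal_oracle_study(max_n_reversals: int = 8,
                          max_n_exhaustive: int = 4) -> dict:
    """Breakpoint detector vs a brute-force single-reversal oracle.

    Every single segment reversal of the identity for n <= ``max_n_reversals``
    must be flagged with exactly two inversion breakpoints at the reversal
    endpoints; exhaustively for n <= ``max_n_exhaustive``, a signed
    permutation is one reversal away from the identity (by brute-force
    search) if and only if the detector reports exactly two breakpoints,
    both inversion-flagged, and the identity has zero breakpoints.
    """
    checked = agreed = 0
    for n in range(1, max_n_reversals + 1):
        identity = tuple(range(1, n + 1))
        for i in range(n):
            for j in range(i, n):
                perm = rearrange.SignedPermutation(_reverse(identity, i, j))
                bps = rearrange.find_breakpoints(perm)
                ok = (
                    bps.n_breakpoints == 2
                    and bps.n_inversion_breakpoints == 2
                    and bps.adjacencies == (i, j + 1)
                )
                checked += 1
                agreed += ok
    for n in range(1, max_n_exhaustive + 1):
        for elements in _all_signed_permutations(n):
            perm = rearrange.SignedPermutation(elements)
            bps = rearrange.find_breakpoints(perm)
            reachable = _one_reversal_from_identity(elements) is not None
            detected = (bps.n_breakpoints == 2
                        and bps.n_inversion_breakpoints == 2)
            identity_ok = (elements == tuple(range(1, n + 1))) == (
                bps.n_breakpoints == 0)
            checked += 1
            agreed += (reachable == detected) and identity_ok
    return {"checked": checked, "agreement": agreed / checked}
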