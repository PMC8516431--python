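"""Multi-species synthetic worlds with known truth.

Emulates a clade of species related by chromosomal inversions: an ancestral
genome carries ordered, ortholog-tagged genes, transposon insertions with
per-insertion divergence, and planted TE-dense piRNA clusters; each lineage
then accumulates Poisson-distributed segment inversions whose breakpoints are
recorded.  Small-RNA libraries with 1U/10A composition and ping-pong pairing,
and DNA-seq per-family read counts, are simulated from the truth, so every
downstream stage (mapping, cluster calling, landscape, synteny, breakpoint
enrichment, attribution) can be validated against planted ground truth.

Design constraints baked into the generator:

* inversion breakpoints are sampled in annotation-free intergenic space, so
  genes, TE insertions and clusters are never split and move as whole units
  (gene-anchored synteny stays well defined);
* per-insertion divergence is an annotation (age proxy + noise), not realized
  in sequence: there is no substitution model, and planted clusters receive
  lower divergence than heterochromatin;
* sequences are plain ACGT with no Ns, so exact-substring mapping is exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .smallrna import revcomp

__all__ = [
    "ClusterSpec",
    "WorldConfig",
    "SpeciesTruth",
    "generate_ancestor",
    "evolve_species",
    "simulate_small_rna",
    "simulate_te_dnaseq",
    "default_tree",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

GENE_COLUMNS = ["contig", "start", "end", "strand", "gene_id", "ortholog_group"]
TE_COLUMNS = ["contig", "start", "end", "strand", "family",
              "divergence_pct", "full_length"]
CLUSTER_COLUMNS = ["cluster_id", "contig", "start", "end", "strand_mode",
                   "read_budget", "active"]


@dataclass(frozen=True)
class ClusterSpec:
    """A planted piRNA cluster: span, strand composition and read budget."""

    length: int
    strand_mode: str = "dual"  # {"uni", "dual"}
    read_budget: int = 1000

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cluster length must be > 0")
        if self.strand_mode not in ("uni", "dual"):
            raise ValueError(f"strand_mode must be uni or dual")
        if self.read_budget < 0:
            raise ValueError("read_budget must be >= 0")


def default_tree(n_species: int, depth_my: float = 20.0) -> str:
    """Ultrametric caterpillar tree over sp1..spN, newick branch lengths in
    My; successive species split at evenly spaced depths."""
    if n_species == 1:
        return f"(sp1:{depth_my});"
    step = depth_my / (n_species - 1)
    ages = [step * k for k in range(1, n_species)]
    tree = f"(sp1:{ages[0]},sp2:{ages[0]})"
    for k in range(1, n_species - 1):
        stem = ages[k] - ages[k - 1]
        tree = f"({tree}:{stem},sp{k + 2}:{ages[k]})"
    return tree + ";"


@dataclass
class WorldConfig:
    """Parameters of a synthetic multi-species world.

    ``inversion_rate`` is the expected number of inversions per tree branch;
    ``hotspot_bias`` is the fraction of inversions whose breakpoints are drawn
    from the designated hotspot windows flanking planted cluster borders.
    ``cluster_losses`` optionally lists cluster ids silenced (no piRNA
    output) in given leaf species, modelling lineage-specific cluster death.
    """

    n_species: int = 3
    tree: str | None = None
    contig_lengths: list[int] = field(default_factory=lambda: [300_000])
    n_genes: int = 60
    n_te_families: int = 8
    cluster_specs: list[ClusterSpec] = field(
        default_factory=lambda: [ClusterSpec(8000, "dual", 1500),
                                 ClusterSpec(8000, "uni", 1500)]
    )
    inversion_rate: float = 1.0
    hotspot_bias: float = 0.0
    seed: int = 0
    # layout knobs (fractions of contig length / coverage levels)
    gene_length: int = 1500
    hetero_frac: float = 0.15
    cluster_te_coverage: float = 0.7
    hetero_te_coverage: float = 0.6
    euchrom_te_coverage: float = 0.05
    cluster_divergence: float = 3.0
    hetero_divergence: float = 8.0
    euchrom_divergence: float = 15.0
    hotspot_width: int = 1000
    cluster_losses: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be > 0")
        if not 0.0 <= self.hotspot_bias <= 1.0:
            raise ValueError("hotspot_bias must be within [0, 1]")
        if self.tree is None:
            self.tree = default_tree(self.n_species)
        taxa = dendropy.TaxonNamespace()
        t = dendropy.Tree.get(data=self.tree, schema="newick",
                              taxon_namespace=taxa)
        leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
        if len(leaves) != self.n_species:
            raise ValueError(
                f"tree has {len(leaves)} leaves, expected {self.n_species}"
            )
        self.leaf_names = leaves

    def parsed_tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.tree, schema="newick")


@dataclass
class SpeciesTruth:
    """Full ground truth for one species."""

    name: str
    genome: dict[str, str]
    genes: pd.DataFrame
    te_insertions: pd.DataFrame
    true_clusters: pd.DataFrame
    hotspots: pd.DataFrame = field(default_factory=pd.DataFrame)
    inversion_events: list[dict] = field(default_factory=list)
    te_families: pd.DataFrame = field(default_factory=pd.DataFrame)

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def clone(self, name: str) -> "SpeciesTruth":
        return SpeciesTruth(
            name=name,
            genome=dict(self.genome),
            genes=self.genes.copy(),
            te_insertions=self.te_insertions.copy(),
            true_clusters=self.true_clusters.copy(),
            hotspots=self.hotspots.copy(),
            inversion_events=copy.deepcopy(self.inversion_events),
            te_families=self.te_families,
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _place_tes(rng, contig, lo, hi, coverage, mean_div, families,
               family_lengths, rows, avoid=()):
    """Tile [lo, hi) with TE insertions to roughly `coverage`, skipping
    `avoid` intervals."""
    target_bp = int((hi - lo) * coverage)
    placed_bp = 0
    occupied = sorted(avoid)
    attempts = 0
    while placed_bp < target_bp and attempts < 50 * max(1, len(families)):
        attempts += 1
        fam = families[rng.integers(0, len(families))]
        full = rng.random() < 0.5
        flen = family_lengths[fam]
        length = flen if full else max(150, int(flen * rng.uniform(0.2, 0.8)))
        if length >= hi - lo:
            length = max(150, (hi - lo) // 2)
            full = False
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        if any(start < oe and end > os for os, oe in occupied):
            continue
        occupied.append((start, end))
        div = max(0.1, rng.normal(mean_div, mean_div * 0.15))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((contig, start, end, strand, fam, round(div, 2), full))
        placed_bp += length
    return rows


def generate_ancestor(config: WorldConfig) -> SpeciesTruth:
    """Build the ancestral genome: contigs, ordered ortholog-tagged genes,
    planted clusters with hotspot margins, and a structured TE landscape
    (dense low-divergence TEs in clusters, dense mid-divergence TEs in the
    terminal heterochromatic zone, sparse high-divergence TEs elsewhere).

    Genes are numbered 1..n_genes in chromosomal order; the gene number is
    the ortholog identity.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    max_contig = max(config.contig_lengths)
    for spec in config.cluster_specs:
        if spec.length + 2 * config.hotspot_width >= max_contig:
            raise ValueError(
                f"cluster of {spec.length} bp cannot be placed on any contig"
            )
    contigs = {
        f"contig{i + 1}": _random_seq(rng, length)
        for i, length in enumerate(config.contig_lengths)
    }
    names = list(contigs)
    lengths = {n: len(contigs[n]) for n in names}
    total = sum(lengths.values())

    # --- clusters: round-robin over contigs, spread across the euchromatic
    # core with a hotspot margin at each border
    cluster_rows = []
    hotspot_rows = []
    assigned: dict[str, list[tuple[int, ClusterSpec]]] = {n: [] for n in names}
    for ci, spec in enumerate(config.cluster_specs):
        contig = names[ci % len(names)]
        assigned[contig].append((ci, spec))
    margin = config.hotspot_width + config.gene_length + 200
    for contig, specs in assigned.items():
        if not specs:
            continue
        clen = lengths[contig]
        ec_end = int(clen * (1 - config.hetero_frac))
        core_lo, core_hi = int(ec_end * 0.10), int(ec_end * 0.92)
        total_len = sum(s.length for _, s in specs)
        free = core_hi - core_lo - total_len - 2 * margin * len(specs)
        if free < 0:
            raise ValueError(
                f"clusters totalling {total_len} bp do not fit on {contig}"
            )
        # spread clusters evenly so the merge rule (gap < combined length)
        # never joins distinct planted loci when gaps allow
        gap = free // (len(specs) + 1)
        cursor = core_lo + gap
        for ci, spec in specs:
            start = cursor + margin
            end = start + spec.length
            cursor = end + margin + gap
            cid = f"piC{ci + 1}"
            cluster_rows.append(
                (cid, contig, start, end, spec.strand_mode, spec.read_budget,
                 True)
            )
            hotspot_rows.append((cid, contig, start - config.hotspot_width,
                                 start, "left"))
            hotspot_rows.append((cid, contig, end, end + config.hotspot_width,
                                 "right"))
    clusters = pd.DataFrame(cluster_rows, columns=CLUSTER_COLUMNS)
    hotspots = pd.DataFrame(
        hotspot_rows, columns=["cluster_id", "contig", "start", "end", "side"]
    )

    # --- genes in euchromatic space outside clusters and hotspot margins
    gene_rows = []
    weights = np.array([lengths[n] for n in names], float)
    counts = np.floor(weights / weights.sum() * config.n_genes).astype(int)
    while counts.sum() < config.n_genes:
        counts[int(np.argmax(weights))] += 1
        weights[int(np.argmax(weights))] -= 1e9
    gene_no = 0
    for contig, n_c in zip(names, counts):
        clen = lengths[contig]
        ec_end = int(clen * (1 - config.hetero_frac))
        blocked = [
            (r[2] - config.hotspot_width, r[3] + config.hotspot_width)
            for r in cluster_rows if r[1] == contig
        ]
        free: list[tuple[int, int]] = []
        cursor = 200
        for bs, be in sorted(blocked):
            if bs - cursor > config.gene_length + 400:
                free.append((cursor, bs))
            cursor = be
        if ec_end - cursor > config.gene_length + 400:
            free.append((cursor, ec_end))
        free_bp = sum(e - s for s, e in free)
        placed = 0
        for s, e in free:
            n_here = round(n_c * (e - s) / free_bp) if free_bp else 0
            if s is free[-1][0] and e is free[-1][1]:
                n_here = n_c - placed  # remainder into last gap
            n_here = min(n_here,
                         (e - s) // (config.gene_length + 200))
            if n_here <= 0:
                continue
            pitch = (e - s) / n_here
            for j in range(n_here):
                g_start = int(s + j * pitch + 100)
                g_end = g_start + config.gene_length
                gene_no += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append(
                    (contig, g_start, g_end, strand, f"g{gene_no}",
                     f"og{gene_no}")
                )
                placed += 1
    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)

    # --- TE landscape
    families = [f"TE{i + 1}" for i in range(config.n_te_families)]
    family_lengths = {
        fam: int(rng.integers(1000, 4001)) for fam in families
    }
    te_rows: list[tuple] = []
    for contig in names:
        clen = lengths[contig]
        ec_end = int(clen * (1 - config.hetero_frac))
        for _, row in clusters[clusters.contig == contig].iterrows():
            _place_tes(rng, contig, row.start, row.end,
                       config.cluster_te_coverage, config.cluster_divergence,
                       families, family_lengths, te_rows)
        if clen - ec_end > 1000:
            _place_tes(rng, contig, ec_end, clen,
                       config.hetero_te_coverage, config.hetero_divergence,
                       families, family_lengths, te_rows)
        avoid = [(r[1], r[2]) for r in gene_rows if r[0] == contig]
        avoid += [(r[2] - config.hotspot_width, r[3] + config.hotspot_width)
                  for r in cluster_rows if r[1] == contig]
        _place_tes(rng, contig, 200, ec_end, config.euchrom_te_coverage,
                   config.euchrom_divergence, families, family_lengths,
                   te_rows, avoid=avoid)
    tes = pd.DataFrame(te_rows, columns=TE_COLUMNS).sort_values(
        ["contig", "start"]).reset_index(drop=True)
    fam_df = pd.DataFrame(
        {"family": families,
         "consensus_length": [family_lengths[f] for f in families]}
    )
    return SpeciesTruth(
        name="ancestor", genome=contigs, genes=genes, te_insertions=tes,
        true_clusters=clusters, hotspots=hotspots, te_families=fam_df,
    )


# ---------------------------------------------------------------------------
# inversion machinery


def _transform_interval(start, end, strand, b1, b2):
    """Map an interval wholly inside the reversed segment [b1, b2)."""
    return b1 + b2 - end, b1 + b2 - start, ("-" if strand == "+" else "+")


def _transform_point(x, b1, b2):
    """Junction-coordinate transform under reversal of [b1, b2)."""
    return b1 + b2 - x if b1 < x < b2 else x


def _hotspot_windows(truth: SpeciesTruth, width: int) -> pd.DataFrame:
    """Annotation-free windows of up to ``width`` bp just outside each
    cluster border — the designated inversion-breakpoint hotspots."""
    rows = []
    for _, cl in truth.true_clusters.iterrows():
        contig = cl.contig
        clen = len(truth.genome[contig])
        blockers = []
        for df in (truth.genes, truth.te_insertions, truth.true_clusters):
            sel = df[df.contig == contig]
            blockers += list(zip(sel.start, sel.end))
        blockers = [
            (s, e) for s, e in blockers if not (s == cl.start and e == cl.end)
        ]
        lo = max([e for s, e in blockers if e <= cl.start] or [0])
        w_lo = max(lo, cl.start - width)
        if cl.start - w_lo >= 50:
            rows.append((cl.cluster_id, contig, w_lo, cl.start, "left"))
        hi = min([s for s, e in blockers if s >= cl.end] or [clen])
        w_hi = min(hi, cl.end + width)
        if w_hi - cl.end >= 50:
            rows.append((cl.cluster_id, contig, cl.end, w_hi, "right"))
    return pd.DataFrame(
        rows, columns=["cluster_id", "contig", "start", "end", "side"]
    )


def _apply_inversion(truth: SpeciesTruth, contig: str, b1: int, b2: int,
                     branch: str, hotspot: bool = False) -> None:
    """Reverse [b1, b2) on ``contig`` in place: revcomp the sequence, flip
    contained annotations, record the event with its broken gene adjacencies
    and keep earlier breakpoints' coordinates current."""
    seq = truth.genome[contig]
    assert 0 <= b1 < b2 <= len(seq)
    truth.genome[contig] = seq[:b1] + revcomp(seq[b1:b2]) + seq[b2:]

    def flanking_genes(x):
        g = truth.genes[truth.genes.contig == contig]
        left = g[g.end <= x]
        right = g[g.start >= x]
        og_l = left.loc[left.end.idxmax(), "ortholog_group"] if len(left) else None
        og_r = right.loc[right.start.idxmin(), "ortholog_group"] if len(right) else None
        return og_l, og_r

    broken = [flanking_genes(b1), flanking_genes(b2)]

    for attr in ("genes", "te_insertions"):
        df = getattr(truth, attr)
        inside = (df.contig == contig) & (df.start >= b1) & (df.end <= b2)
        strad = (df.contig == contig) & ~inside & (df.start < b2) & (df.end > b1)
        if strad.any():
            raise RuntimeError("inversion breakpoint splits an annotation")
        if inside.any():
            ns = b1 + b2 - df.loc[inside, "end"]
            ne = b1 + b2 - df.loc[inside, "start"]
            df.loc[inside, "start"] = ns
            df.loc[inside, "end"] = ne
            df.loc[inside, "strand"] = df.loc[inside, "strand"].map(
                {"+": "-", "-": "+"}
            )
    df = truth.true_clusters
    inside = (df.contig == contig) & (df.start >= b1) & (df.end <= b2)
    strad = (df.contig == contig) & ~inside & (df.start < b2) & (df.end > b1)
    if strad.any():
        raise RuntimeError("inversion breakpoint splits an annotation")
    if inside.any():
        ns = b1 + b2 - df.loc[inside, "end"]
        ne = b1 + b2 - df.loc[inside, "start"]
        df.loc[inside, "start"] = ns
        df.loc[inside, "end"] = ne
    for ev in truth.inversion_events:
        if ev["contig"] == contig:
            ev["positions"] = [
                _transform_point(p, b1, b2) for p in ev["positions"]
            ]
    truth.inversion_events.append({
        "contig": contig,
        "branch": branch,
        "positions": [b1, b2],
        "positions_at_event": (b1, b2),
        "hotspot": hotspot,
        "broken_adjacencies": broken,
    })
    # hotspot windows are derived from cluster borders; refresh them so the
    # next inversion samples from windows valid for the current layout
    width = None
    if len(truth.hotspots):
        width = int((truth.hotspots.end - truth.hotspots.start).max())
    if width:
        truth.hotspots = _hotspot_windows(truth, width)


def _free_gaps(truth: SpeciesTruth, contig: str, margin: int = 200
               ) -> list[tuple[int, int]]:
    """Annotation-free intergenic gaps on a contig, the candidate space for
    random inversion breakpoints (hotspot windows are ordinary intergenic
    space and stay eligible)."""
    clen = len(truth.genome[contig])
    occupied = []
    for df in (truth.genes, truth.te_insertions, truth.true_clusters):
        sel = df[df.contig == contig]
        occupied += list(zip(sel.start, sel.end))
    occupied.sort()
    gaps = []
    cursor = margin
    for s, e in occupied:
        if s - cursor >= 100:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if clen - margin - cursor >= 100:
        gaps.append((cursor, clen - margin))
    return gaps


def _sample_free_position(rng, gaps) -> int:
    weights = np.array([e - s for s, e in gaps], float)
    idx = rng.choice(len(gaps), p=weights / weights.sum())
    s, e = gaps[idx]
    return int(rng.integers(s, e))


def _sample_breakpoints(rng, truth: SpeciesTruth, hotspot: bool
                        ) -> tuple[str, int, int] | None:
    if hotspot:
        hs = truth.hotspots
        # two windows on one contig flanking *different* clusters, so the
        # reversed segment carries genes and the gene order is disrupted
        eligible = [
            contig for contig in sorted(hs.contig.unique())
            if hs[hs.contig == contig].cluster_id.nunique() >= 2
        ]
        if eligible:
            contig = eligible[rng.integers(0, len(eligible))]
            sel = hs[hs.contig == contig]
            if True:
                cids = sorted(sel.cluster_id.unique())
                pick = rng.choice(len(cids), size=2, replace=False)
                w1 = sel[sel.cluster_id == cids[pick[0]]].sample(
                    1, random_state=int(rng.integers(2**31)))
                w2 = sel[sel.cluster_id == cids[pick[1]]].sample(
                    1, random_state=int(rng.integers(2**31)))
                p1 = int(rng.integers(w1.start.iloc[0], w1.end.iloc[0]))
                p2 = int(rng.integers(w2.start.iloc[0], w2.end.iloc[0]))
                return contig, min(p1, p2), max(p1, p2)
        return None
    names = sorted(truth.genome)
    for _ in range(20):
        contig = names[rng.integers(0, len(names))]
        gaps = _free_gaps(truth, contig)
        if len(gaps) < 2:
            continue
        p1 = _sample_free_position(rng, gaps)
        p2 = _sample_free_position(rng, gaps)
        if abs(p2 - p1) < 2000:
            continue
        return contig, min(p1, p2), max(p1, p2)
    return None


def evolve_species(
    ancestor: SpeciesTruth, config: WorldConfig
) -> tuple[list[SpeciesTruth], pd.DataFrame]:
    """Evolve the ancestor along the configured tree.

    Each branch applies Poisson(``inversion_rate``) segment inversions; a
    ``hotspot_bias`` fraction of them draw both breakpoints from hotspot
    windows at planted cluster borders, the rest from annotation-free
    intergenic space.  Returns one SpeciesTruth per leaf plus the full
    ortholog table (species, gene_id, ortholog_group).
    """
    tree = config.parsed_tree()
    rng = np.random.default_rng(config.seed + 1)
    leaves: list[SpeciesTruth] = []

    def descend(node, state: SpeciesTruth, label: str):
        for child in node.child_nodes():
            child_label = (child.taxon.label if child.is_leaf()
                           else f"{label}/{id(child) % 997}")
            branch_state = state.clone(child_label)
            n_inv = int(rng.poisson(config.inversion_rate))
            for _ in range(n_inv):
                hotspot = bool(rng.random() < config.hotspot_bias)
                bp = _sample_breakpoints(rng, branch_state, hotspot)
                if bp is None and hotspot:
                    bp = _sample_breakpoints(rng, branch_state, False)
                if bp is None:
                    continue
                contig, b1, b2 = bp
                _apply_inversion(branch_state, contig, b1, b2, child_label,
                                 hotspot=hotspot)
            if child.is_leaf():
                for sp, lost in config.cluster_losses.items():
                    if sp == child_label:
                        m = branch_state.true_clusters.cluster_id.isin(lost)
                        branch_state.true_clusters.loc[m, "active"] = False
                leaves.append(branch_state)
            else:
                descend(child, branch_state, child_label)

    root = tree.seed_node
    if root.is_leaf():
        leaves.append(ancestor.clone(root.taxon.label))
    else:
        descend(root, ancestor, "root")
    order = {name: i for i, name in enumerate(config.leaf_names)}
    leaves.sort(key=lambda t: order.get(t.name, 99))
    rows = []
    for sp in leaves:
        for _, g in sp.genes.iterrows():
            rows.append((sp.name, g.gene_id, g.ortholog_group))
    ortholog_map = pd.DataFrame(
        rows, columns=["species", "gene_id", "ortholog_group"]
    )
    return leaves, ortholog_map


# ---------------------------------------------------------------------------
# read simulation


def _draw_cluster_read(rng, seq, c_start, c_end, strand, u1_bias, tries=40):
    """One read from [c_start, c_end) on the given strand; with probability
    ``u1_bias`` the 5' nucleotide is forced to U (T in DNA) by rejection."""
    length = int(rng.integers(23, 30))
    want_u1 = rng.random() < u1_bias
    for _ in range(tries):
        start = int(rng.integers(c_start, c_end - length + 1))
        first = seq[start] if strand == "+" else revcomp(seq[start + length - 1])
        if not want_u1 or first == "T":
            return start, length
    return start, length  # bias unmet after `tries` draws; keep last


def simulate_small_rna(
    truth: SpeciesTruth,
    read_budget: int | None = None,
    pingpong_fraction: float = 0.3,
    u1_bias: float = 0.75,
    noise_fraction: float = 0.1,
    uni_share: float = 0.98,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw 23-29 nt reads from the planted clusters plus genomic noise.

    Cluster reads carry a 1U bias of ``u1_bias``; a ``pingpong_fraction`` of
    each cluster's reads is emitted as opposite-strand pairs whose 5' ends
    overlap by exactly 10 nt (giving responder reads a 10A by pairing
    complementarity); uni-mode clusters emit ``uni_share`` of their reads
    from the cluster's major (plus) strand.  ``noise_fraction`` of the total
    cluster budget is added as uniform genomic background.  Returns
    ``(reads, truth_table)`` with reads as (id, sequence) and the table
    recording the intended placement of every read.

    The total read count equals the summed active-cluster budgets (or the
    ``read_budget`` override split evenly) plus the noise budget.
    """
    if not 0.0 <= pingpong_fraction <= 1.0:
        raise ValueError("pingpong_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    active = truth.true_clusters[truth.true_clusters.active]
    budgets = {}
    for _, row in active.iterrows():
        budgets[row.cluster_id] = (
            int(round(read_budget / len(active))) if read_budget
            else int(row.read_budget)
        )
    reads: list[tuple[str, str]] = []
    rows: list[tuple] = []
    counter = 0

    def emit(contig, start, length, strand, origin):
        nonlocal counter
        seq = truth.genome[contig][start:start + length]
        if strand == "-":
            seq = revcomp(seq)
        rid = f"{truth.name}_r{counter}"
        counter += 1
        reads.append((rid, seq))
        rows.append((rid, truth.name, contig, start, start + length, strand,
                     length, origin))

    for _, row in active.iterrows():
        n = budgets[row.cluster_id]
        seq = truth.genome[row.contig]
        minor_frac = (1 - uni_share) if row.strand_mode == "uni" else 0.5
        n_pairs = int(round(pingpong_fraction * n / 2))
        n_pairs = min(n_pairs, int(n * minor_frac))
        n_rest = n - 2 * n_pairs
        for _ in range(n_pairs):
            # initiator on plus strand with 1U; responder 5' end 10 nt in
            # (responders reach up to 19 bp left of the initiator 5' end,
            # so initiators start at least that far inside the cluster)
            start, length = _draw_cluster_read(
                rng, seq, min(row.start + 19, row.end - 30),
                min(row.end, len(seq)), "+", u1_bias)
            m5 = start + 9
            l2 = int(rng.integers(23, 30))
            emit(row.contig, start, length, "+", row.cluster_id)
            emit(row.contig, m5 - l2 + 1, l2, "-", row.cluster_id)
        n_minor_rest = max(0, int(round(n * minor_frac)) - n_pairs)
        for i in range(n_rest):
            strand = "-" if i < n_minor_rest else "+"
            start, length = _draw_cluster_read(
                rng, seq, row.start, min(row.end, len(seq)), strand, u1_bias)
            emit(row.contig, start, length, strand, row.cluster_id)

    n_noise = int(round(noise_fraction * sum(budgets.values())))
    names = sorted(truth.genome)
    lens = np.array([len(truth.genome[n]) for n in names], float)
    for _ in range(n_noise):
        contig = names[rng.choice(len(names), p=lens / lens.sum())]
        length = int(rng.integers(23, 30))
        start = int(rng.integers(0, len(truth.genome[contig]) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        emit(contig, start, length, strand, "noise")
    table = pd.DataFrame(
        rows, columns=["read_id", "species", "contig", "start", "end",
                       "strand", "length", "origin"]
    )
    return reads, table


def simulate_te_dnaseq(
    truth: SpeciesTruth, coverage_depth: float = 30.0, seed: int = 0
) -> pd.DataFrame:
    """Per-family paired-end DNA-seq read counts.

    Expected count = family genomic bp x coverage / 300 (one 150 nt read
    pair contributes 300 sequenced bases), Poisson-dispersed.  Returns a
    table with read_count, consensus_length, coverage_depth and the planted
    copy number (family bp / consensus length).
    """
    if coverage_depth <= 0:
        raise ValueError("coverage_depth must be > 0")
    rng = np.random.default_rng(seed)
    fam_bp = truth.te_insertions.assign(
        bp=lambda d: d.end - d.start
    ).groupby("family")["bp"].sum()
    rows = []
    for _, fam in truth.te_families.iterrows():
        bp = int(fam_bp.get(fam.family, 0))
        expected = bp * coverage_depth / 300.0
        count = int(rng.poisson(expected))
        rows.append((fam.family, count, fam.consensus_length, coverage_depth,
                     bp / fam.consensus_length))
    return pd.DataFrame(
        rows, columns=["family", "read_count", "consensus_length",
                       "coverage_depth", "true_copies"]
    )
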