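"""Flank extraction, homolog location, locus classification, homology
groups and ages."""

import dendropy
import pandas as pd
import pytest

from conftest import make_alignment_set
from piclust import pipeline, synteny, synthio
from piclust.synteny import (
    SpeciesDataset,
    SyntenyCall,
    assign_age,
    classify_locus,
    extract_flanks,
    link_groups,
    locate_homolog,
    pairwise_table,
)


def gene_frame(rows):
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "gene_id",
                       "ortholog_group"])


def linear_genes(contig, n, start=0, pitch=10_000, length=2000, prefix="og"):
    return gene_frame([
        (contig, start + i * pitch, start + i * pitch + length, "+",
         f"g{i + 1}", f"{prefix}{i + 1}") for i in range(n)
    ])


class TestExtractFlanks:
    def test_five_genes_each_side(self):
        genes = linear_genes("c1", 12)
        # cluster between genes 6 and 7
        left, right = extract_flanks(("c1", 55_000, 58_000), genes,
                                     span=200_000, contig_length=200_000)
        assert len(left) == 6 and len(right) == 6
        assert left.entries.iloc[0].ortholog_group == "og6"  # innermost first
        assert right.entries.iloc[0].ortholog_group == "og7"

    def test_cluster_at_contig_start_truncated_left(self):
        genes = linear_genes("c1", 5, start=10_000)
        left, right = extract_flanks(("c1", 0, 5000), genes, span=200_000,
                                     contig_length=100_000)
        assert len(left) == 0 and left.truncated
        assert len(right) == 5 and right.truncated

    def test_gene_straddling_span_excluded(self):
        genes = gene_frame([
            ("c1", 199_000, 201_500, "+", "g1", "og1"),  # straddles limit
            ("c1", 210_000, 212_000, "+", "g2", "og2"),
        ])
        left, right = extract_flanks(("c1", 400_000, 405_000), genes,
                                     span=200_000, contig_length=600_000)
        assert list(left.entries.ortholog_group) == ["og2"]


class TestLocateHomolog:
    def test_identity_recovery(self):
        genes = linear_genes("c1", 10)
        left, right = extract_flanks(("c1", 45_000, 48_000), genes,
                                     span=200_000)
        cand = locate_homolog(left, right, genes)
        assert cand["resolved"]
        assert cand["left_anchor"] == "og5" and cand["right_anchor"] == "og6"
        assert cand["start"] == 42_000 and cand["end"] == 50_000

    def test_single_contig_placement_preferred(self):
        query_genes = linear_genes("c1", 6)
        left, right = extract_flanks(("c1", 25_000, 28_000), query_genes,
                                     span=200_000)
        # innermost anchors og3/og4 split over two contigs; outer anchors
        # og2/og5 colocalize on cA
        subject = gene_frame([
            ("cB", 1000, 3000, "+", "s3", "og3"),
            ("cC", 1000, 3000, "+", "s4", "og4"),
            ("cA", 10_000, 12_000, "+", "s2", "og2"),
            ("cA", 30_000, 32_000, "+", "s5", "og5"),
        ])
        cand = locate_homolog(left, right, subject)
        assert cand["resolved"] and cand["contig"] == "cA"

    def test_nearer_anchor_pair_preferred(self):
        query_genes = linear_genes("c1", 6)
        left, right = extract_flanks(("c1", 25_000, 28_000), query_genes,
                                     span=200_000)
        # both og3 (innermost left) and og2 available on one contig: the
        # innermost anchor wins
        subject = gene_frame([
            ("cA", 10_000, 12_000, "+", "s2", "og2"),
            ("cA", 20_000, 22_000, "+", "s3", "og3"),
            ("cA", 30_000, 32_000, "+", "s4", "og4"),
        ])
        cand = locate_homolog(left, right, subject)
        assert cand["left_anchor"] == "og3"
        assert cand["start"] == 22_000 and cand["end"] == 30_000

    def test_unresolvable_flanks(self):
        genes = linear_genes("c1", 6)
        left, right = extract_flanks(("c1", 25_000, 28_000), genes,
                                     span=200_000)
        stranger = linear_genes("c9", 4, prefix="zz")
        cand = locate_homolog(left, right, stranger)
        assert not cand["resolved"]


def make_subject(genes, contig_lengths, aln_rows=(), clusters=None,
                 tes=None, name="subj"):
    aln = make_alignment_set(list(aln_rows), contig_lengths)
    return SpeciesDataset(
        name=name, contig_lengths=contig_lengths, genes=genes,
        te_annotation=tes if tes is not None else pd.DataFrame(
            columns=["contig", "start", "end", "strand", "family",
                     "divergence_pct", "full_length"]),
        alignments=aln,
        clusters=clusters if clusters is not None else pd.DataFrame(),
    )


class TestClassifyLocus:
    def _query_flanks(self):
        genes = linear_genes("c1", 10)
        return extract_flanks(("c1", 45_000, 48_000), genes, span=200_000)

    def test_threshold_passing_locus_is_active(self):
        left, right = self._query_flanks()
        subject_genes = linear_genes("c1", 10)
        # piRNA-dense TE-rich 6 kb region between og5 and og6
        aln_rows = [("c1", 42_500 + i * 50, 26, "+", "T", "A", 1, 1)
                    for i in range(100)]
        tes = pd.DataFrame(
            [("c1", 42_200, 49_000, "+", "TE1", 5.0, True)],
            columns=["contig", "start", "end", "strand", "family",
                     "divergence_pct", "full_length"])
        subject = make_subject(subject_genes, {"c1": 200_000}, aln_rows,
                               tes=tes)
        cand = locate_homolog(left, right, subject_genes)
        call = classify_locus(cand, left, right, subject, "query", "picX")
        assert call.status == "active_piC"

    def test_collinear_flanks_without_reads_is_synteny(self):
        left, right = self._query_flanks()
        subject_genes = linear_genes("c1", 10)
        subject = make_subject(subject_genes, {"c1": 200_000})
        cand = locate_homolog(left, right, subject_genes)
        call = classify_locus(cand, left, right, subject, "query", "picX")
        assert call.status == "synteny"

    def test_planted_inversion_between_flanks_breaks_synteny(self):
        left, right = self._query_flanks()
        # subject carries an inversion spanning genes 6..8: the adjacency
        # between og5 and og6 is disrupted with a sign reversal
        rows = []
        for i in range(10):
            rows.append(["c1", i * 10_000, i * 10_000 + 2000, "+",
                         f"s{i + 1}", f"og{i + 1}"])
        inverted = rows[5:8][::-1]
        for j, r in enumerate(inverted):
            r = list(r)
            r[1], r[2] = 50_000 + j * 10_000, 50_000 + j * 10_000 + 2000
            r[3] = "-"
            rows[5 + j] = r
        subject_genes = gene_frame([tuple(r) for r in rows])
        subject = make_subject(subject_genes, {"c1": 200_000})
        cand = locate_homolog(left, right, subject_genes)
        call = classify_locus(cand, left, right, subject, "query", "picX")
        assert call.status == "inversion_break"

    def test_unresolved_when_no_anchor(self):
        left, right = self._query_flanks()
        stranger = linear_genes("c9", 4, prefix="zz")
        subject = make_subject(stranger, {"c9": 100_000})
        cand = locate_homolog(left, right, stranger)
        call = classify_locus(cand, left, right, subject, "query", "picX")
        assert call.status == "unresolved"


class TestPairwiseTable:
    def _species(self, n):
        out = {}
        top = {}
        for i in range(n):
            name = f"sp{i + 1}"
            genes = linear_genes("c1", 10)
            out[name] = make_subject(genes, {"c1": 200_000}, name=name)
            top[name] = pd.DataFrame({
                "contig": ["c1"], "start": [45_000], "end": [48_000],
                "cluster_id": [f"{name}.pic1"]})
        return out, top

    @pytest.mark.parametrize("n, expected", [(10, 90), (2, 2), (1, 0)])
    def test_ordered_pair_counts(self, n, expected):
        species, top = self._species(n)
        calls = pairwise_table(species, top)
        assert len(calls) == expected
        pairs = {(c.query_species, c.subject_species) for c in calls}
        assert len(pairs) == expected


class TestLinkGroups:
    def _call(self, q, s, cid, status="active_piC", locus=("c1", 100, 200)):
        return SyntenyCall(q, s, cid, status, subject_contig=locus[0],
                           subject_start=locus[1], subject_end=locus[2])

    def _top(self, species_loci):
        return {
            sp: pd.DataFrame({
                "contig": [c for c, _, _ in loci],
                "start": [s for _, s, _ in loci],
                "end": [e for _, _, e in loci],
                "cluster_id": [f"{sp}.pic{i}" for i in range(len(loci))],
            })
            for sp, loci in species_loci.items()
        }

    def test_reciprocal_calls_form_one_group(self):
        top = self._top({"A": [("c1", 0, 5000)], "B": [("c1", 100, 5100)]})
        calls = [self._call("A", "B", "A.pic0", locus=("c1", 100, 5100)),
                 self._call("B", "A", "B.pic0", locus=("c1", 0, 5000))]
        groups = link_groups(calls, top)
        assert len(groups) == 1
        assert set(groups[0].members.species) == {"A", "B"}

    def test_transitive_chain_links_three_species(self):
        top = self._top({"A": [("c1", 0, 5000)], "B": [("c1", 0, 5000)],
                         "C": [("c1", 0, 5000)]})
        calls = [self._call("A", "B", "A.pic0", locus=("c1", 0, 5000)),
                 self._call("B", "C", "B.pic0", locus=("c1", 0, 5000))]
        groups = link_groups(calls, top)
        assert len(groups) == 1
        assert set(groups[0].members.species) == {"A", "B", "C"}

    def test_disjoint_loci_stay_separate(self):
        top = self._top({"A": [("c1", 0, 5000)], "B": [("c1", 50_000, 56_000)]})
        groups = link_groups([], top)
        assert len(groups) == 2


class TestAssignAge:
    def _tree(self):
        return dendropy.Tree.get(
            data="((sp1:1.9,sp2:1.9):5.4,sp3:7.3);", schema="newick")

    def _group(self, statuses):
        members = pd.DataFrame({
            "species": list(statuses),
            "contig": ["c1"] * len(statuses),
            "start": [0] * len(statuses),
            "end": [100] * len(statuses),
            "status": [statuses[sp] for sp in statuses],
            "locus_id": list(statuses),
        })
        return synteny.HomologyGroup(members)

    def test_single_active_species_is_species_specific(self):
        g = assign_age(self._group({"sp1": "active_piC", "sp2": "synteny"}),
                       self._tree())
        assert g.category == "species-specific"
        assert g.age_my == 0.0
        assert not g.conserved

    def test_two_species_age_from_split(self):
        g = assign_age(
            self._group({"sp1": "active_piC", "sp2": "active_piC"}),
            self._tree())
        assert g.age_my == pytest.approx(1.9)
        assert g.conserved

    def test_all_leaves_root_age(self):
        g = assign_age(
            self._group({s: "active_piC" for s in ("sp1", "sp2", "sp3")}),
            self._tree())
        assert g.age_my == pytest.approx(7.3)

    def test_species_missing_from_tree_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            assign_age(self._group({"spX": "active_piC",
                                    "sp1": "active_piC"}), self._tree())


class TestSyntenyOnSimulatedWorlds:
    def test_identity_world_full_recovery(self):
        """Without rearrangements every top cluster maps to itself in every
        species (identity recovery)."""
        config = synthio.WorldConfig(
            n_species=3, seed=31, inversion_rate=0.0,
            contig_lengths=[350_000], n_genes=60,
            cluster_specs=[synthio.ClusterSpec(8000, "dual", 1500)],
        )
        leaves, _ = pipeline.simulate_world(config)
        species, top = {}, {}
        for i, truth in enumerate(leaves):
            ds, _ = pipeline.build_species_dataset(truth, seed=50 + i)
            pipeline.call_and_rank(ds)
            species[truth.name] = ds
            top[truth.name] = ds.clusters
        calls = pairwise_table(species, top)
        assert len(calls) == 6
        assert all(c.status == "active_piC" for c in calls)
        planted = leaves[0].true_clusters.iloc[0]
        for c in calls:
            assert c.subject_start < planted.end
            assert c.subject_end > planted.start

    def test_cluster_death_reports_synteny_not_break(self):
        """A cluster silenced on one branch is found as conserved synteny
        (flanks intact, no expression), not as an inversion break."""
        config = synthio.WorldConfig(
            n_species=3, seed=21, inversion_rate=0.0,
            contig_lengths=[350_000], n_genes=60,
            cluster_specs=[synthio.ClusterSpec(8000, "dual", 1500),
                           synthio.ClusterSpec(7000, "dual", 1200)],
            cluster_losses={"sp3": ["piC2"]},
        )
        leaves, _ = pipeline.simulate_world(config)
        species, top = {}, {}
        for i, truth in enumerate(leaves):
            ds, _ = pipeline.build_species_dataset(truth, seed=80 + i)
            pipeline.call_and_rank(ds)
            species[truth.name] = ds
            top[truth.name] = ds.clusters
        calls = pairwise_table(species, top)
        into_sp3 = [c for c in calls if c.subject_species == "sp3"]
        statuses = sorted(c.status for c in into_sp3)
        assert statuses.count("synteny") == 2  # dead piC2 from sp1 and sp2
        assert "inversion_break" not in statuses
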