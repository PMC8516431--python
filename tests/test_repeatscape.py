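"""Kimura divergence, border profiles, heterochromatin, strand bias."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_alignment_set
from piclust import studies
from piclust.repeatscape import (
    border_content_profile,
    call_heterochromatin,
    divergence_border_profile,
    divergence_class_summary,
    kimura2p,
    strand_bias_correlation,
)


def te_frame(rows):
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "family",
                       "divergence_pct", "full_length"])


class TestKimura:
    def test_identical_sequences(self):
        assert kimura2p(0.0, 0.0) == 0.0

    def test_formula_value(self):
        assert kimura2p(0.1, 0.05) == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            kimura2p(0.5, 0.0)

    def test_against_substitution_counting_oracle(self):
        """The estimator recovers the realized substitutions per site of an
        explicit per-site Poisson substitution process within 5% for
        divergences up to 0.3."""
        result = studies.kimura_oracle_study(seed=11)
        assert result["max_rel_error"] < 0.05


class TestBorderContentProfile:
    def test_te_tiled_cluster_with_clean_flanks(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        tes = te_frame([("c1", 50_000, 60_000, "+", "TE1", 5.0, True)])
        genes = pd.DataFrame(columns=["contig", "start", "end"])
        prof = border_content_profile(
            clusters, tes, genes, {"c1": 200_000})
        for border in ("left", "right"):
            sub = prof[prof.border == border]
            assert len(sub) == 30  # (10000 + 5000) / 500 windows
            internal = sub[sub.window_index >= 0]
            flank = sub[sub.window_index < 0]
            assert (internal.te_fraction == 1.0).all()
            assert (flank.te_fraction == 0.0).all()
            assert (sub.cds_fraction == 0.0).all()

    def test_empty_annotation_gives_zero_profile(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        empty = pd.DataFrame(columns=["contig", "start", "end"])
        prof = border_content_profile(clusters, empty, empty,
                                      {"c1": 200_000})
        assert (prof.te_fraction == 0.0).all()

    def test_truncated_border_dropped(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [2000], "end": [12_000]})
        empty = pd.DataFrame(columns=["contig", "start", "end"])
        prof = border_content_profile(clusters, empty, empty,
                                      {"c1": 200_000})
        assert "left" not in set(prof.border)

    def test_profile_invariant_to_cluster_order(self):
        clusters = pd.DataFrame({
            "contig": ["c1", "c1"], "start": [50_000, 120_000],
            "end": [60_000, 130_000]})
        tes = te_frame([("c1", 50_000, 60_000, "+", "TE1", 5.0, True),
                        ("c1", 118_000, 125_000, "-", "TE2", 9.0, False)])
        genes = pd.DataFrame(columns=["contig", "start", "end"])
        a = border_content_profile(clusters, tes, genes, {"c1": 300_000})
        b = border_content_profile(clusters.iloc[::-1], tes, genes,
                                   {"c1": 300_000})
        pd.testing.assert_frame_equal(a, b)


class TestDivergenceProfile:
    def test_uniform_divergence_is_flat(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        tes = te_frame([("c1", 30_000, 80_000, "+", "TE1", 5.0, True)])
        prof = divergence_border_profile(clusters, tes)
        assert np.allclose(prof.mean_divergence, 5.0)

    def test_low_divergence_cluster_in_high_background(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        tes = te_frame(
            [("c1", 50_000, 60_000, "+", "TE1", 3.0, True),
             ("c1", 20_000, 50_000, "+", "TE2", 10.0, False),
             ("c1", 60_000, 90_000, "-", "TE3", 10.0, False)])
        prof = divergence_border_profile(clusters, tes)
        internal = prof[prof.window_index >= 0].mean_divergence
        flank = prof[prof.window_index < 0].mean_divergence
        assert internal.max() == pytest.approx(3.0)
        assert flank.min() == pytest.approx(10.0)

    def test_percent_halves_mode(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        tes = te_frame([("c1", 50_000, 60_000, "+", "TE1", 4.0, True)])
        prof = divergence_border_profile(clusters, tes,
                                         mode="percent_halves")
        assert np.allclose(prof[prof.window_index >= 0].mean_divergence, 4.0)

    def test_cluster_without_tes_contributes_nothing(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        empty = te_frame([])
        assert divergence_border_profile(clusters, empty).empty


class TestHeterochromatin:
    def test_uniform_density_no_heterochromatin(self):
        tes = te_frame([("c1", i * 10_000, i * 10_000 + 1000, "+", "TE1",
                         5.0, False) for i in range(30)])
        part = call_heterochromatin(tes, {"c1": 300_000})
        assert set(part.intervals.label) == {"EC"}

    def test_terminal_dense_run_is_heterochromatin(self):
        # terminal 20%: densely tiled; elsewhere sparse
        rows = [("c1", 250_000 + i * 1000, 250_000 + i * 1000 + 800, "+",
                 "TE1", 5.0, False) for i in range(50)]
        rows += [("c1", i * 20_000, i * 20_000 + 500, "+", "TE1", 5.0, False)
                 for i in range(12)]
        part = call_heterochromatin(te_frame(rows), {"c1": 300_000})
        assert part.label_at("c1", 290_000) == "HC"
        assert part.label_at("c1", 100_000) == "EC"

    def test_interior_dense_run_stays_euchromatin(self):
        rows = [("c1", 100_000 + i * 1000, 100_000 + i * 1000 + 800, "+",
                 "TE1", 5.0, False) for i in range(50)]
        rows += [("c1", i * 30_000, i * 30_000 + 500, "+", "TE1", 5.0, False)
                 for i in range(3)]
        part = call_heterochromatin(te_frame(rows), {"c1": 300_000})
        assert part.label_at("c1", 120_000) == "EC"

    def test_partition_tiles_contigs(self):
        rows = [("c1", 250_000 + i * 1000, 250_000 + i * 1000 + 800, "+",
                 "TE1", 5.0, False) for i in range(40)]
        part = call_heterochromatin(te_frame(rows),
                                    {"c1": 300_000, "c2": 70_000})
        for contig, clen in (("c1", 300_000), ("c2", 70_000)):
            iv = part.intervals[part.intervals.contig == contig].sort_values(
                "start")
            assert iv.start.iloc[0] == 0 and iv.end.iloc[-1] == clen
            assert (iv.start.values[1:] == iv.end.values[:-1]).all()


class TestStrandBias:
    def _clusters(self, n):
        return pd.DataFrame({
            "contig": ["c1"] * n,
            "start": [i * 20_000 for i in range(n)],
            "end": [i * 20_000 + 10_000 for i in range(n)],
            "cluster_id": [f"pc{i}" for i in range(n)],
        })

    def test_antisense_design_strong_anticorrelation(self):
        """Uni-strand clusters whose TEs all point opposite to the reads
        give |r| ~ 1."""
        n = 6
        clusters = self._clusters(n)
        rng = np.random.default_rng(2)
        te_rows, aln_rows = [], []
        for i in range(n):
            lo = i * 20_000
            te_plus = i / (n - 1)  # spread TE strand fractions 0..1
            for j in range(10):
                strand = "+" if j < te_plus * 10 else "-"
                te_rows.append(("c1", lo + j * 900, lo + j * 900 + 700,
                                strand, "TE1", 5.0, False))
            read_strand_plus = 1.0 - te_plus  # reads antisense to TEs
            for j in range(50):
                strand = "+" if j < read_strand_plus * 50 else "-"
                aln_rows.append(("c1", lo + 100 + j * 150, 26, strand, "T",
                                 "A", 1, 1))
        aln = make_alignment_set(aln_rows, {"c1": 200_000})
        frame, r = strand_bias_correlation(clusters, aln, te_frame(te_rows))
        assert r is not None and abs(r) >= 0.99 and r < 0

    def test_zero_variance_not_available(self):
        clusters = self._clusters(3)
        te_rows, aln_rows = [], []
        for i in range(3):
            lo = i * 20_000
            te_rows.append(("c1", lo, lo + 5000, "+", "TE1", 5.0, False))
            aln_rows.append(("c1", lo + 100, 26, "+", "T", "A", 1, 1))
        aln = make_alignment_set(aln_rows, {"c1": 100_000})
        _, r = strand_bias_correlation(clusters, aln, te_frame(te_rows))
        assert r is None

    def test_fewer_than_three_clusters_no_r(self):
        clusters = self._clusters(2)
        aln = make_alignment_set(
            [("c1", 100, 26, "+", "T", "A", 1, 1),
             ("c1", 20_100, 26, "-", "T", "A", 1, 1)], {"c1": 100_000})
        tes = te_frame([("c1", 0, 5000, "+", "TE1", 5.0, False),
                        ("c1", 20_000, 25_000, "-", "TE1", 5.0, False)])
        frame, r = strand_bias_correlation(clusters, aln, tes)
        assert len(frame) == 2 and r is None

    def test_independent_fractions_weak_correlation(self):
        rng = np.random.default_rng(8)
        n = 100
        clusters = pd.DataFrame({
            "contig": ["c1"] * n,
            "start": [i * 2000 for i in range(n)],
            "end": [i * 2000 + 1500 for i in range(n)],
            "cluster_id": [f"p{i}" for i in range(n)],
        })
        te_rows, aln_rows = [], []
        for i in range(n):
            lo = i * 2000
            te_rows.append(("c1", lo, lo + 1000, rng.choice(["+", "-"]),
                            "TE1", 5.0, False))
            for j in range(10):
                aln_rows.append(("c1", lo + j * 100, 26,
                                 rng.choice(["+", "-"]), "T", "A", 1, 1))
        aln = make_alignment_set(aln_rows, {"c1": 300_000})
        _, r = strand_bias_correlation(clusters, aln, te_frame(te_rows))
        assert r is not None and abs(r) < 0.3


class TestDivergenceClassSummary:
    def test_planted_ordering_cluster_below_hc_below_ec(self):
        clusters = pd.DataFrame(
            {"contig": ["c1"], "start": [50_000], "end": [60_000]})
        rows = [("c1", 50_000 + i * 1000, 50_000 + i * 1000 + 800, "+",
                 "TE1", 3.0, True) for i in range(10)]
        rows += [("c1", 250_000 + i * 1000, 250_000 + i * 1000 + 800, "+",
                  "TE1", 8.0, False) for i in range(50)]
        rows += [("c1", 100_000 + i * 10_000, 100_000 + i * 10_000 + 500,
                  "+", "TE1", 15.0, False) for i in range(10)]
        tes = te_frame(rows)
        part = call_heterochromatin(tes, {"c1": 300_000})
        summary = divergence_class_summary(tes, clusters, part).set_index(
            "cls")
        assert (summary.loc["cluster", "mean_divergence"]
                < summary.loc["HC", "mean_divergence"]
                < summary.loc["EC", "mean_divergence"])

    def test_empty_class_empty_distribution(self):
        clusters = pd.DataFrame(columns=["contig", "start", "end"])
        tes = te_frame([("c1", 0, 5000, "+", "TE1", 5.0, False)])
        part = call_heterochromatin(tes, {"c1": 300_000})
        summary = divergence_class_summary(tes, clusters, part).set_index(
            "cls")
        assert summary.loc["cluster", "n"] == 0
        assert np.isnan(summary.loc["cluster", "mean_divergence"])
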