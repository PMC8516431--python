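import pandas as pd
import pytest

from piclust import pipeline, synthio


@pytest.fixture(scope="session")
def identity_world():
    """One species, no inversions, three planted clusters, mapped reads and
    called clusters; shared by cluster-level tests."""
    config = synthio.WorldConfig(
        n_species=1, seed=42, inversion_rate=0.0,
        contig_lengths=[400_000], n_genes=60,
        cluster_specs=[
            synthio.ClusterSpec(8000, "dual", 1800),
            synthio.ClusterSpec(7000, "uni", 1200),
            synthio.ClusterSpec(6000, "dual", 900),
        ],
    )
    leaves, ortholog_map = pipeline.simulate_world(config)
    truth = leaves[0]
    dataset, read_table = pipeline.build_species_dataset(truth, seed=7)
    called = pipeline.call_and_rank(dataset)
    return {
        "config": config,
        "truth": truth,
        "dataset": dataset,
        "read_table": read_table,
        "called": called,
        "ortholog_map": ortholog_map,
    }


def make_alignment_set(rows, contig_lengths, mode="unique"):
    """AlignmentSet from (contig, start, length, strand, first, tenth,
    copies, hits) tuples."""
    from piclust.smallrna import ALN_COLUMNS, AlignmentSet

    records = pd.DataFrame(
        [
            (c, s, s + ln, f"r{i}", cp, st, ln, f1, t10, h)
            for i, (c, s, ln, st, f1, t10, cp, h) in enumerate(rows)
        ],
        columns=ALN_COLUMNS,
    )
    total = int(records["copies"].sum()) if len(records) else 0
    return AlignmentSet(records, mode, mirna_count=total or 1,
                        total_mapped=total, contig_lengths=contig_lengths)
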