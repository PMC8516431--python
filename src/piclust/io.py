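"""Readers and writers for the standard formats the pipeline exchanges.

FASTA via Biopython, gene annotations as GFF3 with an ``ortholog_group=``
attribute, TE insertions as BED6 plus a TSV sidecar carrying family and
divergence, species trees as newick (branch lengths in My), and plain TSV
truth/metric tables.  All coordinates on disk follow each format's own
convention (GFF3 1-based inclusive, BED 0-based half-open); in memory
everything is 0-based half-open.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthio import GENE_COLUMNS, TE_COLUMNS

__all__ = [
    "write_fasta", "read_fasta",
    "write_genes_gff3", "read_genes_gff3",
    "write_te_table", "read_te_table",
]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_genes_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};ortholog_group={g.ortholog_group}"
            fh.write(
                f"{g.contig}\tpiclust\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append((
                f[0], int(f[3]) - 1, int(f[4]), f[6],
                attrs.get("ID", ""), attrs.get("ortholog_group", ""),
            ))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_te_table(tes: pd.DataFrame, bed_path, tsv_path) -> None:
    """BED6 (name = family) plus a TSV with family, divergence and the
    full-length flag, keyed by row order."""
    bed = tes[["contig", "start", "end", "family"]].copy()
    bed["score"] = 0
    bed["strand"] = tes["strand"]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    tes[TE_COLUMNS].to_csv(tsv_path, sep="\t", index=False)


def read_te_table(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t")
    missing = set(TE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TE table missing columns: {sorted(missing)}")
    return df[TE_COLUMNS]


def write_reads_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def read_reads_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
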