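"""Small-RNA read filtering, exact-match genome mapping and normalization.

Reads are collapsed to unique sequences with a ``copies`` count, screened
against annotation sequence sets (ncRNA, miRNA, coding, pseudogene), size
selected to the piRNA range (23-29 nt by default) and placed on the genome by
exact substring match on both strands.  No-mismatch mapping is exactly
substring search, so the mapper is a 2-bit-encoded k-mer index rather than an
external aligner; pre-computed alignments can be ingested as BED instead.

The count of miRNA-matching reads is kept as the normalization denominator:
downstream expression values are reads per million miRNA-matching reads.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SmallRead",
    "AlignmentSet",
    "collapse_reads",
    "filter_reads",
    "map_reads",
    "normalize_rpm",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: alignment record columns, BED6-compatible prefix plus extras
ALN_COLUMNS = [
    "contig", "start", "end", "read_id", "copies", "strand",
    "length", "first_nt", "tenth_nt", "n_genomic_hits",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRead:
    """A collapsed small-RNA read: unique sequence plus its multiplicity."""

    id: str
    sequence: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        object.__setattr__(
            self, "sequence", self.sequence.upper().replace("U", "T")
        )


@dataclass
class AlignmentSet:
    """Genome placements of small-RNA reads plus the normalization ledger.

    ``records`` columns follow :data:`ALN_COLUMNS`; coordinates are 0-based
    half-open.  ``mode`` is ``unique`` (reads with exactly one genomic hit) or
    ``all_best`` (every exact hit, with ``n_genomic_hits`` recorded).
    ``mirna_count`` is the number of miRNA-matching reads discerned during
    filtering; ``total_mapped`` the number of genome-mapped reads (copies,
    counting each read once regardless of its number of placements).
    """

    records: pd.DataFrame
    mode: str
    mirna_count: int = 0
    total_mapped: int = 0
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("unique", "all_best"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "unique" and len(self.records):
            if (self.records["n_genomic_hits"] != 1).any():
                raise ValueError("unique mode requires n_genomic_hits == 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def weights(self) -> pd.Series:
        """Per-record read weight: copies, split across placements in
        all_best mode (1/n_genomic_hits per placement)."""
        w = self.records["copies"].astype(float)
        if self.mode == "all_best":
            w = w / self.records["n_genomic_hits"]
        return w

    def to_bed(self, path) -> None:
        self.records[ALN_COLUMNS].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path, mode: str, mirna_count: int = 0,
                 total_mapped: int = 0,
                 contig_lengths: dict[str, int] | None = None
                 ) -> "AlignmentSet":
        df = pd.read_csv(path, sep="\t", header=None, names=ALN_COLUMNS)
        return cls(df, mode, mirna_count, total_mapped, contig_lengths or {})


def collapse_reads(sequences) -> list[SmallRead]:
    """Collapse an iterable of (id, sequence) or plain sequences to unique
    sequences with summed copies.  U is converted to T at ingest."""
    counts: Counter[str] = Counter()
    for item in sequences:
        seq = item[1] if isinstance(item, tuple) else item
        counts[seq.upper().replace("U", "T")] += 1
    return [
        SmallRead(f"r{i}", seq, n)
        for i, (seq, n) in enumerate(sorted(counts.items()))
    ]


def _encode(seq: str) -> np.ndarray:
    """2-bit encode ACGT; other symbols map to 255."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _match_positions(read: np.ndarray, target: np.ndarray,
                     max_mismatches: int) -> bool:
    """True if ``read`` occurs in ``target`` with <= max_mismatches
    substitutions (no indels)."""
    L, n = read.size, target.size
    if L > n:
        return False
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    mism = (windows != read).sum(axis=1)
    return bool((mism <= max_mismatches).any())


def filter_reads(
    reads: list[SmallRead],
    annotation_sequences: dict[str, list[str]] | None = None,
    size_range: tuple[int, int] = (23, 29),
    max_mismatches: int = 2,
) -> tuple[list[SmallRead], int]:
    """Screen reads against annotation sets and size-select survivors.

    A read matching any annotation sequence (either orientation, up to
    ``max_mismatches`` substitutions) is removed.  Reads matching a mature
    miRNA exactly are additionally tallied into the miRNA ledger that serves
    as the cross-sample normalization denominator.  Surviving reads are
    restricted to ``size_range`` (inclusive).

    Returns (surviving reads, miRNA-matching read count).
    """
    annotation_sequences = annotation_sequences or {}
    lo, hi = size_range
    # miRNA first so the ledger sees every miRNA read before removal
    categories = sorted(
        annotation_sequences, key=lambda k: (k != "miRNA", k)
    )
    encoded: dict[str, list[np.ndarray]] = {}
    for cat in categories:
        encoded[cat] = []
        for seq in annotation_sequences[cat]:
            seq = seq.upper().replace("U", "T")
            encoded[cat].append(_encode(seq))
            encoded[cat].append(_encode(revcomp(seq)))
    survivors: list[SmallRead] = []
    mirna_count = 0
    for read in reads:
        arr = _encode(read.sequence)
        removed = False
        for cat in categories:
            mm = 0 if cat == "miRNA" else max_mismatches
            if any(_match_positions(arr, t, mm) for t in encoded[cat]):
                if cat == "miRNA":
                    mirna_count += read.copies
                removed = True
                break
        if removed:
            continue
        # a read within 2 mismatches of a miRNA (but not exact) is still
        # annotation-matched; re-scan miRNA at the relaxed tolerance
        if "miRNA" in encoded and any(
            _match_positions(arr, t, max_mismatches) for t in encoded["miRNA"]
        ):
            continue
        if lo <= len(read.sequence) <= hi:
            survivors.append(read)
    return survivors, mirna_count


class GenomeIndex:
    """Sorted 2-bit k-mer prefix index over the plus strand of a genome.

    Supports exact-occurrence lookup for query sequences of length >= k.
    Minus-strand placements are found by searching the reverse complement of
    the query.
    """

    def __init__(self, contigs: dict[str, str], k: int = 23,
                 min_contig: int = 0):
        self.k = k
        self.contigs = {
            name: seq.upper() for name, seq in contigs.items()
            if len(seq) >= min_contig
        }
        self._names: list[str] = []
        self._enc: dict[str, np.ndarray] = {}
        codes_all, pos_all, cid_all = [], [], []
        for cid, (name, seq) in enumerate(sorted(self.contigs.items())):
            self._names.append(name)
            enc = _encode(seq)
            self._enc[name] = enc
            if enc.size < k:
                continue
            valid = np.lib.stride_tricks.sliding_window_view(enc, k)
            ok = (valid != 255).all(axis=1)
            code = np.zeros(enc.size - k + 1, dtype=np.uint64)
            for j in range(k):
                code = (code << np.uint64(2)) | enc[j:enc.size - k + 1 + j].astype(np.uint64)
            codes_all.append(code[ok])
            pos_all.append(np.flatnonzero(ok).astype(np.int64))
            cid_all.append(np.full(int(ok.sum()), cid, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_all)[order]
            self._cid = np.concatenate(cid_all)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
            self._cid = np.empty(0, dtype=np.int32)

    def occurrences(self, seq: str) -> list[tuple[str, int]]:
        """All (contig, start) exact occurrences of ``seq`` on the plus
        strand of the indexed contigs."""
        if len(seq) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        arr = _encode(seq)
        if (arr == 255).any():
            return []
        code = np.uint64(0)
        for j in range(self.k):
            code = (code << np.uint64(2)) | np.uint64(arr[j])
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        out = []
        for idx in range(lo, hi):
            name = self._names[self._cid[idx]]
            pos = int(self._pos[idx])
            enc = self._enc[name]
            if pos + arr.size <= enc.size and np.array_equal(
                enc[pos:pos + arr.size], arr
            ):
                out.append((name, pos))
        return out


def map_reads(
    reads: list[SmallRead],
    genome: dict[str, str],
    mode: str = "unique",
    min_contig: int = 50_000,
    exclusion_bed: list[tuple[str, int, int]] | None = None,
) -> AlignmentSet:
    """Place reads on the genome by exact match on both strands.

    Contigs shorter than ``min_contig`` are dropped before matching (poorly
    assembled fragments inflate multi-mapping).  ``mode='unique'`` keeps only
    reads with exactly one genomic hit; ``mode='all_best'`` keeps every hit
    and records the hit count.  Reads containing non-ACGT symbols are skipped
    with a warning.  ``exclusion_bed`` intervals (e.g. user-supplied highly
    structured loci) mask placements overlapping them.
    """
    if mode not in ("unique", "all_best"):
        raise ValueError(f"unknown mode {mode!r}")
    index = GenomeIndex(genome, k=23, min_contig=min_contig)
    contig_lengths = {n: len(s) for n, s in index.contigs.items()}
    rows = []
    total_mapped = 0
    for read in reads:
        seq = read.sequence
        if any(c not in "ACGT" for c in seq):
            warnings.warn(f"read {read.id} contains non-ACGT symbols; skipped")
            continue
        hits = [(c, p, "+") for c, p in index.occurrences(seq)]
        hits += [(c, p, "-") for c, p in index.occurrences(revcomp(seq))]
        if exclusion_bed:
            hits = [
                (c, p, s) for c, p, s in hits
                if not any(
                    c == xc and p < xe and p + len(seq) > xs
                    for xc, xs, xe in exclusion_bed
                )
            ]
        n_hits = len(hits)
        if n_hits == 0:
            continue
        total_mapped += read.copies
        if mode == "unique" and n_hits != 1:
            continue
        for contig, pos, strand in hits:
            rows.append((
                contig, pos, pos + len(seq), read.id, read.copies, strand,
                len(seq), seq[0], seq[9] if len(seq) >= 10 else "N", n_hits,
            ))
    records = pd.DataFrame(rows, columns=ALN_COLUMNS)
    return AlignmentSet(records, mode, mirna_count=0,
                        total_mapped=total_mapped,
                        contig_lengths=contig_lengths)


def normalize_rpm(count: float, mirna_count: float) -> float:
    """Reads per million miRNA-matching reads: count * 1e6 / mirna_count."""
    if mirna_count == 0:
        raise ZeroDivisionError(
            "miRNA-matching read count is zero; cannot normalize"
        )
    return count * 1e6 / mirna_count
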