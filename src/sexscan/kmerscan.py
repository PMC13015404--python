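"""Reference-free sex-specific k-mer discovery.

Canonical 31-mers are counted per individual from reads, merged per sex,
filtered at a minimum merged count (20 or 40 by default usage), and the
per-sex sets compared to yield male-specific, female-specific and common
k-mers.  Sex-specific sets are then localized on a reference by exact
canonical matching, binned, and smoothed — clusters of one sex's specific
k-mers mark sex-limited sequence such as Y-linked insertions.

k-mers are stored packed as uint64 (see :mod:`sexscan._dna`); tables are
(codes, counts) sorted by code, which makes merging and set algebra plain
sorted-array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _dna
from .covscan import rolling_mean


@dataclass
class KmerCountTable:
    """Canonical k-mer counts: sorted packed codes with parallel counts."""

    k: int
    codes: np.ndarray  # uint64, strictly increasing
    counts: np.ndarray  # int64, >= 1
    label: str = ""

    def __post_init__(self):
        if self.codes.size != self.counts.size:
            raise ValueError("codes and counts lengths differ")

    def __len__(self) -> int:
        return int(self.codes.size)

    def as_dict(self) -> dict[str, int]:
        return {
            _dna.unpack_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{_dna.unpack_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def read_tsv(cls, path, label: str = "") -> "KmerCountTable":
        kmers, counts = [], []
        with open(path) as fh:
            for line in fh:
                km, n = line.split("\t")
                kmers.append(_dna.pack_kmer(km))
                counts.append(int(n))
        k = 0
        with open(path) as fh:
            first = fh.readline()
            if first:
                k = len(first.split("\t")[0])
        codes = np.asarray(kmers, dtype=np.uint64)
        cnts = np.asarray(counts, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        return cls(k=k, codes=codes[order], counts=cnts[order], label=label)


def _aggregate(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if codes.size == 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq, counts.astype(np.int64)


def count_kmers_in_seqs(seqs, k: int = 31, label: str = "") -> KmerCountTable:
    """Canonical k-mer counts over an iterable of sequences.

    Windows containing non-ACGT characters are skipped.  Sequences shorter
    than k contribute nothing.
    """
    chunks = []
    buf = []
    buf_len = 0
    for seq in seqs:
        buf.append(seq)
        buf_len += len(seq)
        if buf_len >= 8_000_000:
            chunks.append(_chunk_codes(buf, k))
            buf, buf_len = [], 0
    if buf:
        chunks.append(_chunk_codes(buf, k))
    allc = np.concatenate(chunks) if chunks else np.empty(0, np.uint64)
    codes, counts = _aggregate(allc)
    return KmerCountTable(k=k, codes=codes, counts=counts, label=label)


def _chunk_codes(seqs: list[str], k: int) -> np.ndarray:
    # join with 'N' so windows never span sequence boundaries
    joined = "N".join(seqs)
    return _dna.kmer_codes(_dna.encode(joined), k)


def count_kmers(fastx_path, k: int = 31, label: str = "") -> KmerCountTable:
    """Canonical k-mer counts from a FASTQ/FASTA file (gzip accepted)."""
    import warnings

    import pysam

    def _reads():
        with pysam.FastxFile(str(fastx_path)) as fh:
            for entry in fh:
                if len(entry.sequence) >= k:
                    yield entry.sequence

    table = count_kmers_in_seqs(_reads(), k=k, label=label or str(fastx_path))
    if len(table) == 0:
        warnings.warn(f"no k-mers of length {k} in {fastx_path}")
    return table


def merge_counts(tables: list[KmerCountTable], label: str = "") -> KmerCountTable:
    """Sum counts across tables (e.g. individuals of one sex)."""
    if not tables:
        raise ValueError("no tables to merge")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("k mismatch between tables")
    codes = np.concatenate([t.codes for t in tables])
    counts = np.concatenate([t.counts for t in tables])
    order = np.argsort(codes, kind="stable")
    codes, counts = codes[order], counts[order]
    if codes.size == 0:
        return KmerCountTable(k=k, codes=codes, counts=counts, label=label)
    uniq_mask = np.r_[True, codes[1:] != codes[:-1]]
    uniq = codes[uniq_mask]
    group = np.cumsum(uniq_mask) - 1
    sums = np.bincount(group, weights=counts).astype(np.int64)
    return KmerCountTable(k=k, codes=uniq, counts=sums, label=label)


def filter_counts(table: KmerCountTable, min_count: int) -> KmerCountTable:
    """Keep k-mers with count >= min_count (inclusive boundary)."""
    keep = table.counts >= min_count
    return KmerCountTable(
        k=table.k,
        codes=table.codes[keep],
        counts=table.counts[keep],
        label=f"{table.label}|min{min_count}",
    )


@dataclass
class SexKmerSets:
    """Male-specific / female-specific / common k-mers after filtering."""

    k: int
    min_count: int
    male_specific: np.ndarray
    female_specific: np.ndarray
    common: np.ndarray
    male_counts: dict = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        return {
            "male_specific": int(self.male_specific.size),
            "female_specific": int(self.female_specific.size),
            "common": int(self.common.size),
        }


def compare_sex_sets(
    male: KmerCountTable,
    female: KmerCountTable,
    min_count: int,
    male_raw: KmerCountTable | None = None,
    female_raw: KmerCountTable | None = None,
    strict: bool = False,
) -> SexKmerSets:
    """Compare filtered per-sex tables into specific and common sets.

    ``male`` / ``female`` are the merged, already-filtered tables (or raw
    tables, which are filtered here at ``min_count``).  In strict mode a
    sex-specific k-mer must additionally be absent from the other sex's
    *raw* (unfiltered) table.
    """
    if male.k != female.k:
        raise ValueError("k mismatch")
    mf = filter_counts(male, min_count)
    ff = filter_counts(female, min_count)
    male_specific = np.setdiff1d(mf.codes, ff.codes, assume_unique=True)
    female_specific = np.setdiff1d(ff.codes, mf.codes, assume_unique=True)
    common = np.intersect1d(mf.codes, ff.codes, assume_unique=True)
    if strict:
        if female_raw is not None:
            male_specific = np.setdiff1d(
                male_specific, female_raw.codes, assume_unique=True
            )
        if male_raw is not None:
            female_specific = np.setdiff1d(
                female_specific, male_raw.codes, assume_unique=True
            )
    return SexKmerSets(
        k=male.k,
        min_count=min_count,
        male_specific=male_specific,
        female_specific=female_specific,
        common=common,
    )


# ---------------------------------------------------------------------------
# localization


def localize_kmers(
    kmer_set: np.ndarray | set,
    reference: dict[str, str],
    k: int = 31,
    bin_size: int = 5000,
    smooth_spans: tuple[int, ...] = (500_000, 20_000),
) -> dict:
    """Exact canonical localization of a k-mer set on a reference.

    Returns {'positions': {chrom: array of 0-based hit starts},
    'track': binned hit-count frame, 'smoothed': {span: frame}}.
    A hit is a reference position whose canonical k-mer is in the set
    (this covers forward and reverse-strand matches at once).
    """
    if isinstance(kmer_set, set):
        arr = np.asarray(
            sorted(
                _dna.pack_kmer(_dna.canonical(s)) if isinstance(s, str) else int(s)
                for s in kmer_set
            ),
            dtype=np.uint64,
        )
    else:
        arr = np.asarray(kmer_set, dtype=np.uint64)
        arr = np.sort(arr)
    positions = {}
    frames = []
    for chrom, seq in reference.items():
        canon, pos = _dna.kmer_positions(_dna.encode(seq), k)
        hit = np.isin(canon, arr, assume_unique=False)
        hit_pos = pos[hit]
        positions[chrom] = hit_pos
        n_bins = int(np.ceil(len(seq) / bin_size))
        counts = np.bincount(
            (hit_pos // bin_size).astype(np.int64), minlength=n_bins
        ).astype(float)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, len(seq)),
                    "depth": counts,
                }
            )
        )
    track = pd.concat(frames, ignore_index=True)
    smoothed = {span: rolling_mean(track, span) for span in smooth_spans}
    return {"positions": positions, "track": track, "smoothed": smoothed}


def sex_kmer_pipeline(
    fastq_by_sample: dict[str, Path],
    sexes: dict[str, str],
    k: int = 31,
    min_count: int = 40,
    strict: bool = False,
) -> SexKmerSets:
    """Count per individual, merge per sex, filter, compare."""
    male_tables, female_tables = [], []
    for sample, path in fastq_by_sample.items():
        t = count_kmers(path, k=k, label=sample)
        (male_tables if sexes[sample] == "M" else female_tables).append(t)
    male = merge_counts(male_tables, label="male_merged")
    female = merge_counts(female_tables, label="female_merged")
    return compare_sex_sets(
        male,
        female,
        min_count=min_count,
        male_raw=male if strict else None,
        female_raw=female if strict else None,
        strict=strict,
    )
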