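"""Synthetic sexed populations, genomes, reads, paralog pairs, RNA-seq.

Every generator takes an explicit seed and records complete ground truth
(:class:`TruthSet`), so all downstream detection stages can be validated
against known answers.  Defaults mirror a resequencing study of ~20 males
and ~20 females at ~10x depth; synthetic genomes are Mb-scale stand-ins
for Gb-scale genomes, while window and bin sizes keep their full-scale
defaults so detection thresholds transfer.

Sex-determination architectures:

* ``NULL`` — no sex-linked variation anywhere.
* ``XY`` — male-heterogametic; SNPs inside the declared regions are
  heterozygous in all males and homozygous in all females.
* ``ZW`` / ``POLYGENIC_ZW`` — female-heterogametic; polygenic requires at
  least two regions on at least two chromosomes.

A male-limited insertion (``y_insertion``) models Y-specific sequence: the
reference genome (male-derived) carries it, females lack it entirely, and
males carry it on one haplotype — producing reduced female coverage and
male-specific k-mers over the interval.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from . import _dna
from .covscan import write_bedgraph
from .vcfio import MISSING, SITE_COLUMNS, SampleSheet, SexedGenotypeMatrix

PHRED_HIGH = "I"  # Q40, used for all simulated bases

_FASTQ_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _write_fastq_records(fh, prefix: str, start_no: int, mat: np.ndarray, suffix: str = ""):
    """Append reads (2-bit code matrix, one row per read) as FASTQ bytes.

    Names are ``@{prefix}{zero-padded running number}{suffix}`` with a fixed
    9-digit pad so every record has identical width, which allows the whole
    block to be assembled as one byte matrix.
    """
    n, L = mat.shape
    if n == 0:
        return
    name_body = f"@{prefix}".encode()
    suffix_b = suffix.encode()
    digits = 9
    rec_len = len(name_body) + digits + len(suffix_b) + 1 + L + 3 + L + 1
    rec = np.empty((n, rec_len), dtype=np.uint8)
    col = 0
    rec[:, col : col + len(name_body)] = np.frombuffer(name_body, np.uint8)
    col += len(name_body)
    nums = np.arange(start_no, start_no + n, dtype=np.int64)
    for d in range(digits):
        rec[:, col + d] = (nums // 10 ** (digits - 1 - d)) % 10 + ord("0")
    col += digits
    if suffix_b:
        rec[:, col : col + len(suffix_b)] = np.frombuffer(suffix_b, np.uint8)
        col += len(suffix_b)
    rec[:, col] = ord("\n")
    col += 1
    rec[:, col : col + L] = _FASTQ_BASES[mat]
    col += L
    rec[:, col : col + 3] = np.frombuffer(b"\n+\n", np.uint8)
    col += 3
    rec[:, col : col + L] = ord(PHRED_HIGH)
    col += L
    rec[:, col] = ord("\n")
    fh.write(rec.tobytes())


class SDArchitecture(str, Enum):
    NULL = "NULL"
    XY = "XY"
    ZW = "ZW"
    POLYGENIC_ZW = "POLYGENIC_ZW"

    @property
    def snp_type(self) -> str | None:
        if self is SDArchitecture.NULL:
            return None
        return "XY" if self is SDArchitecture.XY else "ZW"


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class RepeatSpike:
    """Repeat-collapse coverage spike: both sexes elevated, males slightly more."""

    chrom: str
    start: int
    end: int
    multiplier: float = 5.0
    male_extra: float = 1.2


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the sex-determination architecture.

    ``sd_regions`` and ``y_insertion`` are 0-based half-open intervals
    (chrom, start, end).
    """

    chromosomes: tuple[tuple[str, int], ...]
    sd_architecture: SDArchitecture = SDArchitecture.NULL
    sd_regions: tuple[tuple[str, int, int], ...] = ()
    y_insertion: tuple[str, int, int] | None = None

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        if any(n <= 0 for n in lengths.values()):
            raise ValueError("zero- or negative-length chromosome")
        for chrom, s, e in self.sd_regions:
            if chrom not in lengths:
                raise ValueError(f"sd_region on unknown chromosome {chrom!r}")
            if not 0 <= s < e <= lengths[chrom]:
                raise ValueError(f"sd_region ({chrom},{s},{e}) outside chromosome")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.sd_regions:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping sd_regions on {chrom}")
        if self.sd_architecture is SDArchitecture.NULL and self.sd_regions:
            raise ValueError("NULL architecture cannot carry sd_regions")
        if self.sd_architecture is SDArchitecture.POLYGENIC_ZW:
            chroms = {c for c, _, _ in self.sd_regions}
            if len(self.sd_regions) < 2 or len(chroms) < 2:
                raise ValueError("POLYGENIC_ZW needs >=2 regions on >=2 chromosomes")
        if self.y_insertion is not None:
            chrom, s, e = self.y_insertion
            if chrom not in lengths or not 0 <= s < e <= lengths[chrom]:
                raise ValueError("y_insertion outside chromosome")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


def _default_maf_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    # autosomal alt-allele frequencies; MAF >= 0.05 so sites survive filtering
    return rng.uniform(0.05, 0.95, size=size)


@dataclass(frozen=True)
class PopulationSpec:
    """Sexed diploid population and sequencing characteristics."""

    seed: int
    n_males: int = 20
    n_females: int = 20
    snp_density: float = 0.01
    maf_sampler: object = None  # callable (rng, size) -> alt frequencies
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.02
    depth_mean: float = 10.0
    depth_sd: float = 2.0
    excess_missing_samples: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one individual of each sex")
        for name, rate in [
            ("snp_density", self.snp_density),
            ("genotype_error_rate", self.genotype_error_rate),
            ("missing_rate", self.missing_rate),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def sample_names(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_males)] + [
            f"F{i + 1:02d}" for i in range(self.n_females)
        ]

    @property
    def sexes(self) -> list[str]:
        return ["M"] * self.n_males + ["F"] * self.n_females


@dataclass(frozen=True)
class ParalogSpec:
    """Blueprint for a canonical gene and its structurally divergent paralog.

    The derived copy differs from the canonical copy by an in-frame
    deletion in exon 1 (default 18 bp, i.e. six codons), a frameshifting
    deletion in exon 2 (default 2 bp), a premature stop codon inside a
    designated protein-domain interval, a large simple-repeat insertion in
    intron 1, and background SNVs.  Offsets are 0-based within each piece.
    """

    seed: int
    exon_lengths: tuple[int, ...] = (600, 450)
    intron_lengths: tuple[int, ...] = (800,)
    exon1_deletion_len: int = 18
    exon1_deletion_offset: int = 24
    exon2_deletion_len: int = 2
    exon2_deletion_offset: int = 60
    domain_codon_interval: tuple[int, int] = (60, 160)
    premature_stop_offset: int | None = 15  # codon index within the domain
    intron1_repeat_insertion_len: int = 1200
    repeat_unit: str = "ACAT"
    background_snv_rate: float = 0.01

    def __post_init__(self):
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly one intron between consecutive exons")
        if sum(self.exon_lengths) % 3 != 0:
            raise ValueError("total CDS length must be a codon multiple")
        if self.exon1_deletion_len:
            if self.exon1_deletion_offset + self.exon1_deletion_len > self.exon_lengths[0]:
                raise ValueError("exon-1 deletion exceeds exon length")
        if self.exon2_deletion_len:
            if len(self.exon_lengths) < 2:
                raise ValueError("exon-2 deletion requires a second exon")
            if self.exon2_deletion_offset + self.exon2_deletion_len > self.exon_lengths[1]:
                raise ValueError("exon-2 deletion exceeds exon length")
        if self.premature_stop_offset is not None:
            lo, hi = self.domain_codon_interval
            codon = lo + self.premature_stop_offset
            if not lo <= codon < hi:
                raise ValueError("premature stop outside the domain interval")
            if (codon + 1) * 3 > sum(self.exon_lengths) - 3:
                raise ValueError("premature stop not upstream of the canonical stop")


# ---------------------------------------------------------------------------
# truth


@dataclass
class TruthSet:
    """Recorded ground truth of a simulation."""

    sample_sexes: dict[str, str] = field(default_factory=dict)
    true_sexlinked_snps: list[tuple[str, int, str]] = field(default_factory=list)
    true_regions: list[tuple[str, int, int, str]] = field(default_factory=list)
    true_y_kmers: set[str] = field(default_factory=set)
    paralog_variant_table: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, pos, _ in self.true_sexlinked_snps:
            if not any(
                c == chrom and s < pos <= e for c, s, e, _ in self.true_regions
            ):
                raise ValueError(f"truth SNP {chrom}:{pos} outside all true regions")

    def write(self, path) -> None:
        payload = {
            "sample_sexes": self.sample_sexes,
            "true_sexlinked_snps": [list(t) for t in self.true_sexlinked_snps],
            "true_regions": [list(t) for t in self.true_regions],
            "true_y_kmers": sorted(self.true_y_kmers),
            "paralog_variant_table": self.paralog_variant_table,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            sample_sexes=d["sample_sexes"],
            true_sexlinked_snps=[tuple(t) for t in d["true_sexlinked_snps"]],
            true_regions=[tuple(t) for t in d["true_regions"]],
            true_y_kmers=set(d["true_y_kmers"]),
            paralog_variant_table=d["paralog_variant_table"],
        )

    def write_regions_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e, kind in self.true_regions:
                fh.write(f"{chrom}\t{s}\t{e}\t{kind}\n")


# ---------------------------------------------------------------------------
# genotype simulation


def simulate_genotypes(
    layout: GenomeLayout, pop: PopulationSpec
) -> tuple[SexedGenotypeMatrix, SampleSheet, TruthSet]:
    """Simulate a sexed genotype matrix with recorded truth.

    Autosomal SNPs are drawn at ``snp_density`` with Hardy-Weinberg
    genotypes at a sampled alt frequency, identically in both sexes.
    Inside declared sd_regions every SNP is fully sex-linked: heterozygous
    in the heterogametic sex and homozygous reference in the other, before
    genotyping error and missingness are applied.  Genotyping errors
    replace the called genotype by one of the two other states with equal
    probability.
    """
    rng = np.random.default_rng(pop.seed)
    sampler = pop.maf_sampler or _default_maf_sampler
    samples = pop.sample_names
    sexes = pop.sexes
    n = len(samples)
    male_mask = np.array([x == "M" for x in sexes])
    het_sex_mask = male_mask if layout.sd_architecture is SDArchitecture.XY else ~male_mask

    truth = TruthSet(sample_sexes=dict(zip(samples, sexes)))
    snp_type = layout.sd_architecture.snp_type

    site_rows = []
    dosage_blocks = []
    bases = np.array(list("ACGT"))
    for chrom, length in layout.chromosomes:
        n_snps = int(rng.binomial(length, pop.snp_density))
        if n_snps == 0:
            continue
        pos0 = np.sort(rng.choice(length, size=n_snps, replace=False))
        pos1 = pos0 + 1
        regions = [(s, e) for c, s, e in layout.sd_regions if c == chrom]
        linked = np.zeros(n_snps, dtype=bool)
        for s, e in regions:
            linked |= (pos0 >= s) & (pos0 < e)

        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
        quals = np.round(rng.uniform(30, 100, size=n_snps), 1)

        freqs = np.asarray(sampler(rng, n_snps))
        dosage = rng.binomial(2, freqs[:, None], size=(n_snps, n)).astype(np.int8)
        if linked.any():
            dosage[np.ix_(linked, het_sex_mask)] = 1
            dosage[np.ix_(linked, ~het_sex_mask)] = 0
            for p in pos1[linked]:
                truth.true_sexlinked_snps.append((chrom, int(p), snp_type))

        if pop.genotype_error_rate > 0:
            err = rng.random((n_snps, n)) < pop.genotype_error_rate
            shift = rng.integers(1, 3, size=(n_snps, n), dtype=np.int8)
            dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)
        if pop.missing_rate > 0:
            miss = rng.random((n_snps, n)) < pop.missing_rate
            dosage[miss] = MISSING
        for sample, extra in pop.excess_missing_samples:
            if sample in samples:
                j = samples.index(sample)
                extra_miss = rng.random(n_snps) < extra
                dosage[extra_miss, j] = MISSING

        for i in range(n_snps):
            site_rows.append(
                (
                    chrom,
                    int(pos1[i]),
                    bases[ref_idx[i]],
                    bases[alt_idx[i]],
                    float(quals[i]),
                    True,
                    2,
                )
            )
        dosage_blocks.append(dosage)

    mu = np.clip(rng.normal(pop.depth_mean, pop.depth_sd, size=n), 1.0, None)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    dosage = (
        np.vstack(dosage_blocks) if dosage_blocks else np.empty((0, n), np.int8)
    )
    depth = rng.poisson(mu[None, :], size=dosage.shape).astype(np.int32)

    matrix = SexedGenotypeMatrix(
        sites=sites,
        dosage=dosage,
        depth=depth,
        samples=samples,
        sexes=sexes,
        contigs=layout.chrom_lengths,
    )
    truth.true_regions = [
        (c, s, e, snp_type) for c, s, e in layout.sd_regions
    ]
    truth.validate()
    return matrix, SampleSheet(dict(zip(samples, sexes))), truth


# ---------------------------------------------------------------------------
# depth tracks


def simulate_depth_tracks(
    layout: GenomeLayout,
    pop: PopulationSpec,
    bin_size: int = 5000,
    female_factor: float = 1.0,
    male_factor: float = 1.0,
    repeat_spike: RepeatSpike | None = None,
    dispersion: float = 20.0,
) -> dict[str, pd.DataFrame]:
    """Per-individual binned depth tracks (negative binomial per bin).

    Outside special intervals both sexes draw from the same law.  Inside
    ``layout.y_insertion`` the expected depth is multiplied by
    ``female_factor`` (females) or ``male_factor`` (males); inside a
    ``repeat_spike`` both sexes are multiplied, males slightly more.
    """
    if not 0 <= female_factor <= male_factor:
        raise ValueError("require 0 <= female_factor <= male_factor")
    for _, length in layout.chromosomes:
        if bin_size > length:
            raise ValueError("bin_size larger than a chromosome")
    rng = np.random.default_rng(pop.seed)
    tracks: dict[str, pd.DataFrame] = {}
    for sample, sex in zip(pop.sample_names, pop.sexes):
        mu_i = max(0.5, rng.normal(pop.depth_mean, pop.depth_sd))
        frames = []
        for chrom, length in layout.chromosomes:
            n_bins = int(np.ceil(length / bin_size))
            starts = np.arange(n_bins, dtype=np.int64) * bin_size
            ends = np.minimum(starts + bin_size, length)
            mu = np.full(n_bins, mu_i)
            if layout.y_insertion is not None and layout.y_insertion[0] == chrom:
                _, s, e = layout.y_insertion
                inside = (starts < e) & (ends > s)
                mu[inside] *= male_factor if sex == "M" else female_factor
            if repeat_spike is not None and repeat_spike.chrom == chrom:
                inside = (starts < repeat_spike.end) & (ends > repeat_spike.start)
                mult = repeat_spike.multiplier * (
                    repeat_spike.male_extra if sex == "M" else 1.0
                )
                mu[inside] *= mult
            r = dispersion
            p = r / (r + np.maximum(mu, 1e-9))
            vals = rng.negative_binomial(r, p).astype(float)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "depth": vals}
                )
            )
        tracks[sample] = pd.concat(frames, ignore_index=True)
    return tracks


def write_depth_tracks(tracks: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, df in tracks.items():
        p = out_dir / f"{sample}.depth.bedgraph"
        write_bedgraph(df, p)
        paths[sample] = p
    return paths


# ---------------------------------------------------------------------------
# reference sequence and sexed reads


def simulate_reference(layout: GenomeLayout, seed: int) -> dict[str, str]:
    """Random reference sequence per chromosome (male-derived: includes
    the y_insertion interval when declared)."""
    rng = np.random.default_rng(seed)
    return {chrom: _dna.random_dna(rng, length) for chrom, length in layout.chromosomes}


def _haplotypes(
    layout: GenomeLayout, reference: dict[str, str], sex: str
) -> list[dict[str, str]]:
    """Two haplotype genomes for one individual.

    Females lack the y_insertion on both haplotypes; males carry it on
    exactly one.
    """
    if layout.y_insertion is None:
        return [dict(reference), dict(reference)]
    chrom, s, e = layout.y_insertion
    deleted = dict(reference)
    deleted[chrom] = reference[chrom][:s] + reference[chrom][e:]
    if sex == "M":
        return [dict(reference), deleted]
    return [deleted, dict(deleted)]


def y_insertion_kmers(
    layout: GenomeLayout, reference: dict[str, str], k: int = 31
) -> set[str]:
    """Canonical k-mers unique to the male-limited haplotype."""
    if layout.y_insertion is None:
        return set()
    chrom, s, e = layout.y_insertion
    male_codes = _dna.kmer_codes(_dna.encode(reference[chrom]), k)
    female_seq = reference[chrom][:s] + reference[chrom][e:]
    female_codes = _dna.kmer_codes(_dna.encode(female_seq), k)
    male_only = np.setdiff1d(male_codes, female_codes)
    return {_dna.unpack_kmer(int(c), k) for c in male_only}


def simulate_sexed_reads(
    layout: GenomeLayout,
    pop: PopulationSpec,
    out_dir,
    read_len: int = 100,
    fragment_len: int = 300,
    error_rate: float = 0.001,
    reference: dict[str, str] | None = None,
    kmer_k: int = 31,
) -> tuple[dict[str, Path], TruthSet, dict[str, str]]:
    """Per-individual single-end FASTQ read sets from diploid genomes.

    Reads are uniform random fragments of each individual's two haplotypes
    with per-base substitution errors; the number of reads per individual
    targets ``pop.depth_mean`` haploid coverage.  Returns FASTQ paths, a
    TruthSet carrying the male-limited (Y) k-mers, and the reference.
    """
    if read_len > fragment_len:
        raise ValueError("read_len cannot exceed fragment_len")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(pop.seed)
    if reference is None:
        reference = simulate_reference(layout, int(rng.integers(0, 2**31)))
    truth = TruthSet(
        sample_sexes=dict(zip(pop.sample_names, pop.sexes)),
        true_y_kmers=y_insertion_kmers(layout, reference, k=kmer_k),
    )
    paths = {}
    for sample, sex in zip(pop.sample_names, pop.sexes):
        haps = _haplotypes(layout, reference, sex)
        hap_codes = [
            {c: _dna.encode(s_) for c, s_ in hap.items()} for hap in haps
        ]
        mean_hap_len = sum(sum(len(s_) for s_ in h.values()) for h in haps) / 2
        n_reads = int(round(pop.depth_mean * mean_hap_len / read_len))
        path = out_dir / f"{sample}.fastq"
        with open(path, "wb") as fh:
            _write_reads(fh, sample, hap_codes, n_reads, read_len, error_rate, rng)
        paths[sample] = path
    return paths, truth, reference


def _write_reads(fh, sample, hap_codes, n_reads, read_len, error_rate, rng):
    # flatten haplotypes into (codes, weights) for uniform position sampling
    pieces = []
    for h, chroms in enumerate(hap_codes):
        for chrom, codes in chroms.items():
            if codes.size >= read_len:
                pieces.append(codes)
    lens = np.array([p.size - read_len + 1 for p in pieces], dtype=float)
    probs = lens / lens.sum()
    counts = rng.multinomial(n_reads, probs)
    read_no = 1
    for piece, cnt in zip(pieces, counts):
        if cnt == 0:
            continue
        starts = rng.integers(0, piece.size - read_len + 1, size=cnt, dtype=np.int64)
        mat = np.empty((cnt, read_len), dtype=np.uint8)
        fwd_off = np.arange(read_len, dtype=np.int64)
        step = 200_000  # bounds the index-matrix size
        for off in range(0, cnt, step):
            sl = slice(off, min(off + step, cnt))
            mat[sl] = piece[starts[sl, None] + fwd_off[None, :]]
        # strand
        flip = rng.random(cnt) < 0.5
        mat[flip] = (3 - mat[flip])[:, ::-1]
        # substitution errors
        n_err = rng.binomial(read_len, error_rate, size=cnt)
        tot = int(n_err.sum())
        if tot:
            ridx = np.repeat(np.arange(cnt), n_err)
            cidx = rng.integers(0, read_len, size=tot)
            mat[ridx, cidx] = (mat[ridx, cidx] + rng.integers(1, 4, size=tot)) % 4
        _write_fastq_records(fh, f"{sample}_", read_no, mat)
        read_no += cnt


# ---------------------------------------------------------------------------
# paralog pair


STOP_CODONS = {"TAA", "TAG", "TGA"}
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class ParalogPair:
    """A canonical gene and its derived (Y-like) paralog with truth."""

    canonical_name: str
    derived_name: str
    canonical_genomic: str
    derived_genomic: str
    canonical_exons: list[tuple[int, int]]  # 0-based half-open, genomic coords
    derived_exons: list[tuple[int, int]]
    domain_cds_interval: tuple[int, int]  # bp in canonical CDS, half-open
    variant_table: pd.DataFrame  # gene_pos(canonical,0-based), kind, ref, alt, exon
    spec: ParalogSpec

    @property
    def canonical_cds(self) -> str:
        return "".join(self.canonical_genomic[s:e] for s, e in self.canonical_exons)

    @property
    def derived_cds(self) -> str:
        return "".join(self.derived_genomic[s:e] for s, e in self.derived_exons)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.canonical_name}\n{self.canonical_genomic}\n")
            fh.write(f">{self.derived_name}\n{self.derived_genomic}\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq, exons in [
                (self.canonical_name, self.canonical_genomic, self.canonical_exons),
                (self.derived_name, self.derived_genomic, self.derived_exons),
            ]:
                fh.write(
                    f"{name}\tsimdata\tgene\t1\t{len(seq)}\t.\t+\t.\t"
                    f"ID=gene:{name}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{name}\tsimdata\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                        f"ID=exon:{name}.{i};Parent=gene:{name}\n"
                    )


def make_paralog_pair(
    spec: ParalogSpec,
    canonical_name: str = "foxl2_like",
    derived_name: str = "foxl2_like_Y",
) -> ParalogPair:
    """Build a canonical gene and its structurally divergent derived copy."""
    rng = np.random.default_rng(spec.seed)
    n_codons = sum(spec.exon_lengths) // 3
    # CDS: ATG, then stop-free codons, final stop codon
    body = rng.choice(len(_NONSTOP), size=n_codons - 2)
    cds = "ATG" + "".join(_NONSTOP[i] for i in body) + "TAA"
    exons = []
    off = 0
    for L in spec.exon_lengths:
        exons.append(cds[off : off + L])
        off += L
    introns = [
        "GT" + _dna.random_dna(rng, L - 4) + "AG" for L in spec.intron_lengths
    ]

    # canonical genomic sequence + exon coords
    canonical_pieces = []
    canonical_exons = []
    pos = 0
    for i, ex in enumerate(exons):
        canonical_exons.append((pos, pos + len(ex)))
        canonical_pieces.append(ex)
        pos += len(ex)
        if i < len(introns):
            canonical_pieces.append(introns[i])
            pos += len(introns[i])
    canonical_genomic = "".join(canonical_pieces)

    variants: list[dict] = []
    d_exons = list(exons)
    d_introns = list(introns)
    exon_offsets = [s for s, _ in canonical_exons]

    # premature stop (substitution) inside the domain interval, exon-resolved
    if spec.premature_stop_offset is not None:
        lo, hi = spec.domain_codon_interval
        codon_idx = lo + spec.premature_stop_offset
        cds_pos = codon_idx * 3
        ref_codon = cds[cds_pos : cds_pos + 3]
        new_codon = "TAA"
        ei, within = _cds_to_exon(cds_pos, spec.exon_lengths)
        ex = d_exons[ei]
        d_exons[ei] = ex[:within] + new_codon + ex[within + 3 :]
        for j in range(3):
            if ref_codon[j] != new_codon[j]:
                variants.append(
                    {
                        "gene_pos": exon_offsets[ei] + within + j,
                        "kind": "STOP",
                        "ref": ref_codon[j],
                        "alt": new_codon[j],
                        "exon": ei + 1,
                        "cds_pos": cds_pos + j,
                        "frame_preserving": True,
                    }
                )

    # background SNVs in the derived copy's exons (avoid creating extra
    # in-frame stops and avoid the planted stop codon)
    if spec.background_snv_rate > 0:
        stop_cds = (
            (spec.domain_codon_interval[0] + spec.premature_stop_offset) * 3
            if spec.premature_stop_offset is not None
            else -10
        )
        for ei in range(len(d_exons)):
            ex = list(d_exons[ei])
            hits = np.flatnonzero(rng.random(len(ex)) < spec.background_snv_rate)
            for p in hits:
                cds_pos = sum(spec.exon_lengths[:ei]) + int(p)
                if stop_cds <= cds_pos < stop_cds + 3:
                    continue
                old = ex[p]
                choices = [b for b in "ACGT" if b != old]
                rng.shuffle(choices)
                for newb in choices:
                    ex[p] = newb
                    full_cds = "".join(
                        "".join(ex) if j == ei else d_exons[j]
                        for j in range(len(d_exons))
                    )
                    if _codon_at(full_cds, (cds_pos // 3) * 3) in STOP_CODONS:
                        ex[p] = old  # would create a spurious stop; try next base
                        continue
                    variants.append(
                        {
                            "gene_pos": exon_offsets[ei] + int(p),
                            "kind": "SNV",
                            "ref": old,
                            "alt": newb,
                            "exon": ei + 1,
                            "cds_pos": cds_pos,
                            "frame_preserving": True,
                        }
                    )
                    break
            d_exons[ei] = "".join(ex)
        # intron background SNVs
        for ii in range(len(d_introns)):
            intr = list(d_introns[ii])
            hits = np.flatnonzero(rng.random(len(intr)) < spec.background_snv_rate)
            intron_start = canonical_exons[ii][1]
            for p in hits:
                old = intr[p]
                newb = rng.choice([b for b in "ACGT" if b != old])
                intr[p] = str(newb)
                variants.append(
                    {
                        "gene_pos": intron_start + int(p),
                        "kind": "SNV",
                        "ref": old,
                        "alt": str(newb),
                        "exon": 0,
                        "cds_pos": -1,
                        "frame_preserving": True,
                    }
                )
            d_introns[ii] = "".join(intr)

    # exon deletions (applied after substitutions; coordinates recorded in
    # canonical gene coordinates)
    if spec.exon1_deletion_len:
        s = spec.exon1_deletion_offset
        L = spec.exon1_deletion_len
        ref_seg = exons[0][s : s + L]
        d_exons[0] = d_exons[0][:s] + d_exons[0][s + L :]
        variants.append(
            {
                "gene_pos": exon_offsets[0] + s,
                "kind": "DEL",
                "ref": ref_seg,
                "alt": "",
                "exon": 1,
                "cds_pos": s,
                "frame_preserving": L % 3 == 0,
            }
        )
    if spec.exon2_deletion_len and len(d_exons) > 1:
        s = spec.exon2_deletion_offset
        L = spec.exon2_deletion_len
        ref_seg = exons[1][s : s + L]
        d_exons[1] = d_exons[1][:s] + d_exons[1][s + L :]
        variants.append(
            {
                "gene_pos": exon_offsets[1] + s,
                "kind": "DEL",
                "ref": ref_seg,
                "alt": "",
                "exon": 2,
                "cds_pos": spec.exon_lengths[0] + s,
                "frame_preserving": L % 3 == 0,
            }
        )

    # intron-1 repeat insertion at intron midpoint
    if spec.intron1_repeat_insertion_len and d_introns:
        L = spec.intron1_repeat_insertion_len
        unit = spec.repeat_unit
        ins = (unit * (L // len(unit) + 1))[:L]
        mid = len(d_introns[0]) // 2
        d_introns[0] = d_introns[0][:mid] + ins + d_introns[0][mid:]
        variants.append(
            {
                "gene_pos": canonical_exons[0][1] + mid,
                "kind": "INS",
                "ref": "",
                "alt": f"repeat:{unit}x{L // len(unit)}",
                "exon": 0,
                "cds_pos": -1,
                "frame_preserving": True,
            }
        )

    derived_pieces = []
    derived_exons = []
    pos = 0
    for i, ex in enumerate(d_exons):
        derived_exons.append((pos, pos + len(ex)))
        derived_pieces.append(ex)
        pos += len(ex)
        if i < len(d_introns):
            derived_pieces.append(d_introns[i])
            pos += len(d_introns[i])
    derived_genomic = "".join(derived_pieces)

    table = pd.DataFrame(
        variants,
        columns=[
            "gene_pos",
            "kind",
            "ref",
            "alt",
            "exon",
            "cds_pos",
            "frame_preserving",
        ],
    ).sort_values("gene_pos", kind="stable").reset_index(drop=True)

    lo, hi = spec.domain_codon_interval
    return ParalogPair(
        canonical_name=canonical_name,
        derived_name=derived_name,
        canonical_genomic=canonical_genomic,
        derived_genomic=derived_genomic,
        canonical_exons=canonical_exons,
        derived_exons=derived_exons,
        domain_cds_interval=(lo * 3, hi * 3),
        variant_table=table,
        spec=spec,
    )


def _cds_to_exon(cds_pos: int, exon_lengths: tuple[int, ...]) -> tuple[int, int]:
    off = 0
    for i, L in enumerate(exon_lengths):
        if cds_pos < off + L:
            return i, cds_pos - off
        off += L
    raise ValueError("cds position beyond gene")


def _codon_at(cds: str, start: int) -> str:
    return cds[start : start + 3]


# ---------------------------------------------------------------------------
# RNA-seq libraries


@dataclass(frozen=True)
class LibraryPlan:
    """Per-library read budget and per-transcript relative abundance."""

    lib_id: str
    n_reads: int
    abundances: dict[str, float]

    def __post_init__(self):
        total = sum(self.abundances.values())
        if self.abundances and not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"abundances of {self.lib_id} sum to {total}, not 1")


@dataclass
class SimulatedLibrary:
    lib_id: str
    r1: Path
    r2: Path
    n_reads: int
    true_counts: dict[str, int]


def _allocate(n_reads: int, abundances: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of read pairs to transcripts.

    Any transcript with nonzero abundance receives at least one fragment
    (presence at extremely low abundance is still presence); zero-abundance
    transcripts receive exactly zero.
    """
    names = sorted(abundances)
    exact = np.array([abundances[t] * n_reads for t in names])
    base = np.floor(exact).astype(int)
    nonzero = np.array([abundances[t] > 0 for t in names])
    base[nonzero & (base == 0)] = 1
    diff = n_reads - base.sum()
    order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    i = 0
    while diff != 0 and i < 10 * len(names):
        j = order[i % len(names)]
        if diff > 0:
            base[j] += 1
            diff -= 1
        elif base[j] > (1 if nonzero[j] else 0):
            base[j] -= 1
            diff += 1
        i += 1
    return {t: int(c) for t, c in zip(names, base)}


def simulate_rnaseq_libraries(
    transcripts: dict[str, str],
    plans: list[LibraryPlan],
    out_dir,
    read_len: int = 100,
    fragment_len: int = 300,
    error_rate: float = 0.001,
    seed: int = 0,
) -> list[SimulatedLibrary]:
    """Paired-end FASTQ libraries drawn from transcripts per abundance plan.

    Fragments start uniformly along each transcript (whole transcript when
    shorter than ``fragment_len``); mate 1 is the fragment 5' end, mate 2
    the reverse complement of its 3' end; substitution errors are uniform.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    t_codes = {t: _dna.encode(s) for t, s in transcripts.items()}
    results = []
    for plan in plans:
        unknown = set(plan.abundances) - set(transcripts)
        if unknown:
            raise ValueError(f"unknown transcripts in plan: {sorted(unknown)}")
        if plan.n_reads == 0:
            warnings.warn(f"library {plan.lib_id}: n_reads=0, writing empty files")
            counts = {t: 0 for t in plan.abundances}
        else:
            counts = _allocate(plan.n_reads, plan.abundances)
        r1_path = out_dir / f"{plan.lib_id}_R1.fastq"
        r2_path = out_dir / f"{plan.lib_id}_R2.fastq"
        with open(r1_path, "wb") as f1, open(r2_path, "wb") as f2:
            n_total = sum(counts.values())
            blocks1, blocks2 = [], []
            for t in sorted(counts):
                c = counts[t]
                if c == 0:
                    continue
                codes = t_codes[t]
                frag = min(fragment_len, codes.size)
                if read_len > frag:
                    raise ValueError(
                        f"read_len {read_len} exceeds fragment length {frag} "
                        f"for transcript {t}"
                    )
                starts = rng.integers(0, codes.size - frag + 1, size=c, dtype=np.int32)
                fwd_off = np.arange(read_len, dtype=np.int32)
                rev_off = (frag - 1 - np.arange(read_len)).astype(np.int32)
                m1 = np.empty((c, read_len), dtype=np.uint8)
                m2 = np.empty((c, read_len), dtype=np.uint8)
                step = 200_000  # bounds the int32 index matrix size
                for off in range(0, c, step):
                    sl = slice(off, min(off + step, c))
                    m1[sl] = codes[starts[sl, None] + fwd_off[None, :]]
                    m2[sl] = 3 - codes[starts[sl, None] + rev_off[None, :]]
                for m in (m1, m2):
                    n_err = rng.binomial(read_len, error_rate, size=c)
                    tot = int(n_err.sum())
                    if tot:
                        ridx = np.repeat(np.arange(c), n_err)
                        cidx = rng.integers(0, read_len, size=tot)
                        m[ridx, cidx] = (m[ridx, cidx] + rng.integers(1, 4, size=tot)) % 4
                blocks1.append(m1)
                blocks2.append(m2)
            if n_total:
                m1 = np.vstack(blocks1)
                m2 = np.vstack(blocks2)
                perm = rng.permutation(n_total)
                m1, m2 = m1[perm], m2[perm]
                chunk = 500_000
                for off in range(0, n_total, chunk):
                    _write_fastq_records(
                        f1, f"{plan.lib_id}_", off + 1, m1[off : off + chunk], "/1"
                    )
                    _write_fastq_records(
                        f2, f"{plan.lib_id}_", off + 1, m2[off : off + chunk], "/2"
                    )
        results.append(
            SimulatedLibrary(
                lib_id=plan.lib_id,
                r1=r1_path,
                r2=r2_path,
                n_reads=sum(counts.values()),
                true_counts=counts,
            )
        )
    return results
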