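"""VCF and sample-sheet I/O, variant/sample filtering, per-sample QC.

The central container is :class:`SexedGenotypeMatrix`: biallelic-capable
alt-allele dosages (0/1/2, -1 = missing) and per-genotype depths for a set
of individuals with known phenotypic sex.  Filtering follows VCFtools
semantics: the genotype-level depth mask is applied first, then site-level
QUAL, allele-count/type, missingness and MAF filters, with inclusive
boundaries throughout.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "is_snp", "n_alleles"]


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Mapping of sample id to phenotypic sex ('M' or 'F')."""

    entries: dict[str, str]

    def __post_init__(self):
        bad = {s: x for s, x in self.entries.items() if x not in ("M", "F")}
        if bad:
            raise ValueError(f"sex labels must be 'M' or 'F': {bad}")

    @property
    def males(self) -> list[str]:
        return [s for s, x in self.entries.items() if x == "M"]

    @property
    def females(self) -> list[str]:
        return [s for s, x in self.entries.items() if x == "F"]

    @classmethod
    def read(cls, path) -> "SampleSheet":
        entries = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                sample, sex = line.split("\t")[:2]
                if sample in entries:
                    raise ValueError(f"duplicate sample id {sample!r}")
                entries[sample] = sex
        return cls(entries)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for sample, sex in self.entries.items():
                fh.write(f"{sample}\t{sex}\n")


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class SexedGenotypeMatrix:
    """Genotypes x individuals with per-sample sex labels.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt (comma
        separated for multiallelics), qual, is_snp, n_alleles.
    dosage : int8 array (n_sites, n_samples); alt-allele dosage 0/1/2,
        -1 missing.  For multiallelic records the dosage counts non-reference
        alleles; such records are flagged by n_alleles > 2 and dropped by the
        strict filter preset.
    depth : int32 array (n_sites, n_samples); per-genotype DP, -1 missing.
    samples : sample ids, column order of the arrays.
    sexes : per-sample 'M'/'F' labels aligned with samples.
    contigs : optional mapping chrom -> length from the VCF header.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray
    samples: list[str]
    sexes: list[str]
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        n_sites, n_samples = self.dosage.shape
        if len(self.sites) != n_sites or self.depth.shape != (n_sites, n_samples):
            raise ValueError("sites / dosage / depth shapes disagree")
        if len(self.samples) != n_samples or len(self.sexes) != n_samples:
            raise ValueError("sample metadata does not match matrix width")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def male_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.sexes) == "M")

    @property
    def female_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.sexes) == "F")

    def take_sites(self, mask_or_index) -> "SexedGenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            depth=self.depth[idx],
        )

    def take_samples(self, keep: list[str]) -> "SexedGenotypeMatrix":
        pos = [self.samples.index(s) for s in keep]
        return replace(
            self,
            dosage=self.dosage[:, pos],
            depth=self.depth[:, pos],
            samples=list(keep),
            sexes=[self.sexes[i] for i in pos],
        )


# ---------------------------------------------------------------------------
# reading / writing


def read_vcf(path, sheet: SampleSheet) -> SexedGenotypeMatrix:
    """Load a (possibly gzipped) VCF into a :class:`SexedGenotypeMatrix`.

    Every sample in the VCF must be present in the sample sheet; offenders
    are reported together.  Malformed or half-missing genotypes become
    missing (-1).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing_sheet = [s for s in samples if s not in sheet.entries]
    if missing_sheet:
        raise ValueError(f"samples absent from sample sheet: {missing_sheet}")
    sexes = [sheet.entries[s] for s in samples]
    contigs = {}
    try:
        contigs = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:  # header without contig lengths
        contigs = {}

    rows = []
    dosages = []
    depths = []
    n = len(samples)
    for v in vcf:
        gts = v.genotype.array()  # (n, ploidy+1); last column = phased flag
        alleles = gts[:, :-1]
        dos = np.where(
            (alleles < 0).any(axis=1), MISSING, (alleles > 0).sum(axis=1)
        ).astype(np.int8)
        try:
            dp = v.format("DP")
            dp = np.full(n, MISSING, np.int32) if dp is None else dp[:, 0].astype(np.int32)
            dp[dp < 0] = MISSING
        except Exception:
            dp = np.full(n, MISSING, np.int32)
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                ",".join(v.ALT) if v.ALT else ".",
                float(v.QUAL) if v.QUAL is not None else np.nan,
                bool(v.is_snp),
                1 + len(v.ALT),
            )
        )
        dosages.append(dos)
        depths.append(dp)
    vcf.close()

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = np.vstack(dosages) if dosages else np.empty((0, n), np.int8)
    depth = np.vstack(depths) if depths else np.empty((0, n), np.int32)
    return SexedGenotypeMatrix(sites, dosage, depth, samples, sexes, contigs)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(m: SexedGenotypeMatrix, path) -> None:
    """Write a matrix as VCFv4.2 with GT:DP (plain or .gz by extension)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in m.contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        sites = m.sites
        for i in range(m.n_sites):
            s = sites.iloc[i]
            qual = "." if np.isnan(s.qual) else f"{s.qual:g}"
            cells = [
                f"{_GT[int(d)]}:{'.' if dp < 0 else int(dp)}"
                for d, dp in zip(m.dosage[i], m.depth[i])
            ]
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{qual}\t.\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterConfig:
    """Variant filter set.

    The strict default mirrors common practice for population resequencing:
    biallelic SNPs only, QUAL >= 30, per-genotype depth in [6, 17], site
    missingness <= 0.5, MAF >= 0.05.  The relaxed preset (for coverage
    analyses) keeps indels and multiallelics, MAF >= 0.01, missingness
    <= 0.2, no upper depth bound.
    """

    remove_indels: bool = True
    maf_min: float = 0.05
    max_missing_site: float = 0.5
    qual_min: float = 30.0
    depth_min: int | None = 6
    depth_max: int | None = 17
    min_alleles: int = 2
    max_alleles: int | None = 2

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if (
            self.depth_min is not None
            and self.depth_max is not None
            and self.depth_min > self.depth_max
        ):
            raise ValueError("depth_min > depth_max")

    @classmethod
    def strict(cls) -> "FilterConfig":
        return cls()

    @classmethod
    def relaxed(cls) -> "FilterConfig":
        return cls(
            remove_indels=False,
            maf_min=0.01,
            max_missing_site=0.2,
            qual_min=30.0,
            depth_min=6,
            depth_max=None,
            min_alleles=2,
            max_alleles=None,
        )


@dataclass
class FilterReport:
    """Per-criterion drop tally from :func:`apply_filters`."""

    n_in: int = 0
    n_out: int = 0
    dropped_qual: int = 0
    dropped_allele: int = 0
    dropped_missing: int = 0
    dropped_maf: int = 0
    genotypes_depth_masked: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_filters(
    m: SexedGenotypeMatrix, cfg: FilterConfig
) -> tuple[SexedGenotypeMatrix, FilterReport]:
    """Apply the filter set; returns the surviving matrix and a tally.

    Order: genotype depth mask, then QUAL, allele count/type, site
    missingness, MAF.  A site is counted against the first criterion it
    fails.  All boundaries are inclusive.
    """
    rep = FilterReport(n_in=m.n_sites)
    if m.n_sites == 0:
        return m, rep

    dosage = m.dosage.copy()
    depth = m.depth
    if cfg.depth_min is not None or cfg.depth_max is not None:
        bad = np.zeros_like(dosage, dtype=bool)
        if cfg.depth_min is not None:
            bad |= (depth != MISSING) & (depth < cfg.depth_min)
        if cfg.depth_max is not None:
            bad |= depth > cfg.depth_max
        bad &= dosage != MISSING
        rep.genotypes_depth_masked = int(bad.sum())
        dosage[bad] = MISSING

    sites = m.sites
    n_samples = m.n_samples
    called = dosage != MISSING
    n_called = called.sum(axis=1)

    qual_ok = np.nan_to_num(sites["qual"].to_numpy(), nan=np.inf) >= cfg.qual_min
    allele_ok = sites["n_alleles"].to_numpy() >= cfg.min_alleles
    if cfg.max_alleles is not None:
        allele_ok &= sites["n_alleles"].to_numpy() <= cfg.max_alleles
    if cfg.remove_indels:
        allele_ok &= sites["is_snp"].to_numpy()
    miss_frac = 1.0 - n_called / n_samples
    miss_ok = miss_frac <= cfg.max_missing_site
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_sum = np.where(called, dosage, 0).sum(axis=1)
        freq = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    maf = np.fmin(freq, 1.0 - freq)
    maf_ok = maf >= cfg.maf_min  # NaN -> False

    keep = qual_ok & allele_ok & miss_ok & maf_ok
    first_fail = np.select(
        [~qual_ok, ~allele_ok, ~miss_ok],
        ["qual", "allele", "missing"],
        default="maf",
    )
    dropped = first_fail[~keep]
    rep.dropped_qual = int((dropped == "qual").sum())
    rep.dropped_allele = int((dropped == "allele").sum())
    rep.dropped_missing = int((dropped == "missing").sum())
    rep.dropped_maf = int((dropped == "maf").sum())
    rep.n_out = int(keep.sum())

    out = replace(
        m,
        sites=sites.loc[keep].reset_index(drop=True),
        dosage=dosage[keep],
        depth=depth[keep],
    )
    return out, rep


# ---------------------------------------------------------------------------
# per-sample QC


def sample_qc(m: SexedGenotypeMatrix) -> pd.DataFrame:
    """Per-sample missingness fraction and mean depth over called genotypes."""
    called = m.dosage != MISSING
    dp_ok = called & (m.depth != MISSING)
    n_dp = dp_ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        miss = 1.0 - called.sum(axis=0) / max(m.n_sites, 1)
        sums = np.where(dp_ok, m.depth, 0).sum(axis=0)
        mean_dp = np.where(n_dp > 0, sums / np.maximum(n_dp, 1), np.nan)
    if m.n_sites == 0:
        miss = np.ones(m.n_samples)
    return pd.DataFrame(
        {
            "sample": m.samples,
            "sex": m.sexes,
            "missingness": miss if m.n_sites else np.ones(m.n_samples),
            "mean_depth": mean_dp,
        }
    )


def exclude_high_missing(
    m: SexedGenotypeMatrix, threshold: float = 0.7
) -> tuple[SexedGenotypeMatrix, list[str]]:
    """Drop samples with missingness strictly above ``threshold``.

    Returns the reduced matrix and the list of dropped sample ids.  Raises
    if no sample would survive.
    """
    qc = sample_qc(m)
    keep = qc.loc[qc["missingness"] <= threshold, "sample"].tolist()
    dropped = [s for s in m.samples if s not in keep]
    if not keep:
        raise ValueError("all samples exceed the missingness threshold")
    if not dropped:
        return m, []
    return m.take_samples(keep), dropped
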