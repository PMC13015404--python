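"""Sex-stratified allele counts, Weir-Cockerham F_ST, windowed pi,
and a per-SNP allelic sex-association test.

Males and females are treated as the two "populations" of the
Weir & Cockerham (1984) variance-component estimator.  For a fully
sex-linked SNP (heterogametic sex entirely heterozygous, homogametic sex
entirely homozygous) with equal sample sizes the estimator equals exactly
0.5, which is the working signature of sex linkage throughout the package.

The association test is a 1-df allelic chi-square on the 2x2 allele-by-sex
table, a deliberate stand-in for a full GWAS; its ranking of SNPs closely
tracks the F_ST ranking on sex-linked architectures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vcfio import MISSING, SexedGenotypeMatrix


@dataclass(frozen=True)
class AlleleCounts:
    """Per-sex called sample sizes, alt counts and heterozygote fractions."""

    n_m: int
    n_f: int
    alt_m: int
    alt_f: int
    het_m: int
    het_f: int

    @property
    def p_m(self) -> float:
        return self.alt_m / (2 * self.n_m) if self.n_m else np.nan

    @property
    def p_f(self) -> float:
        return self.alt_f / (2 * self.n_f) if self.n_f else np.nan

    @property
    def h_m(self) -> float:
        return self.het_m / self.n_m if self.n_m else np.nan

    @property
    def h_f(self) -> float:
        return self.het_f / self.n_f if self.n_f else np.nan


def sex_allele_counts(m: SexedGenotypeMatrix) -> pd.DataFrame:
    """Vectorized per-site allele counts per sex.

    Returns a frame aligned with ``m.sites`` with columns n_m, n_f, alt_m,
    alt_f, het_m, het_f, p_m, p_f, h_m, h_f (frequencies NaN when a sex has
    no called genotype).
    """
    out = {}
    for label, idx in (("m", m.male_idx), ("f", m.female_idx)):
        d = m.dosage[:, idx]
        called = d != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, d, 0).sum(axis=1)
        het = (d == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        out[f"n_{label}"] = n
        out[f"alt_{label}"] = alt
        out[f"het_{label}"] = het
        out[f"p_{label}"] = p
        out[f"h_{label}"] = h
    return pd.DataFrame(out)


def site_allele_counts(m: SexedGenotypeMatrix, i: int) -> AlleleCounts:
    """Allele counts for one site (non-missing genotypes only)."""
    row = sex_allele_counts(m.take_sites(np.array([i])))
    r = row.iloc[0]
    return AlleleCounts(
        n_m=int(r.n_m),
        n_f=int(r.n_f),
        alt_m=int(r.alt_m),
        alt_f=int(r.alt_f),
        het_m=int(r.het_m),
        het_f=int(r.het_f),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984), r = 2 populations


def wc_fst_components(
    n1, p1, h1, n2, p2, h2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components a (among-sex), b (among individuals within sex),
    c (within individuals) of the Weir & Cockerham (1984) estimator for two
    populations of diploids.

    Accepts scalars or aligned arrays of called sample sizes, alt-allele
    frequencies and observed heterozygote fractions.  Entries where a sex
    has no called individuals, or n_bar == 1, yield NaN components.
    """
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar)
        c = h_bar / 2.0
    invalid = (n1 < 1) | (n2 < 1) | (n_bar <= 1) | (n_c <= 0)
    a = np.where(invalid, np.nan, a)
    b = np.where(invalid, np.nan, b)
    c = np.where(invalid, np.nan, c)
    return a, b, c


def wc_fst_site(counts: AlleleCounts) -> tuple[float, float, float, float]:
    """(a, b, c, theta) for one site; theta NaN when a+b+c == 0 (e.g. the
    site is monomorphic across both sexes)."""
    a, b, c = wc_fst_components(
        counts.n_m, counts.p_m, counts.h_m, counts.n_f, counts.p_f, counts.h_f
    )
    a, b, c = float(a), float(b), float(c)
    denom = a + b + c
    theta = a / denom if denom != 0 and np.isfinite(denom) else np.nan
    return a, b, c, theta


def per_site_fst(m: SexedGenotypeMatrix) -> pd.DataFrame:
    """Per-site W&C components and theta, plus sex allele frequencies.

    Returns chrom, pos, p_m, p_f, a, b, c, theta (theta NaN where
    undefined); columns align with ``m.sites``.
    """
    counts = sex_allele_counts(m)
    a, b, c = wc_fst_components(
        counts["n_m"],
        counts["p_m"],
        counts["h_m"],
        counts["n_f"],
        counts["p_f"],
        counts["h_f"],
    )
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(
            np.isfinite(denom) & (denom != 0), a / np.where(denom == 0, np.nan, denom), np.nan
        )
    out = pd.DataFrame(
        {
            "chrom": m.sites["chrom"],
            "pos": m.sites["pos"],
            "p_m": counts["p_m"],
            "p_f": counts["p_f"],
            "n_m": counts["n_m"],
            "n_f": counts["n_f"],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )
    return out


def wc_fst_weighted(fst: pd.DataFrame) -> float:
    """Weighted (ratio-of-sums) W&C F_ST over sites with defined components.

    Sum(a) / Sum(a+b+c); may be slightly negative under no differentiation.
    NaN when no site is usable.
    """
    a = fst["a"].to_numpy(float)
    denom = a + fst["b"].to_numpy(float) + fst["c"].to_numpy(float)
    ok = np.isfinite(denom) & (denom != 0) & np.isfinite(a)
    if not ok.any():
        return np.nan
    return float(a[ok].sum() / denom[ok].sum())


# ---------------------------------------------------------------------------
# windowed nucleotide diversity


def windowed_pi(m: SexedGenotypeMatrix, window: int = 10_000) -> pd.DataFrame:
    """Nucleotide diversity per non-overlapping window.

    Per-site diversity is 2 * n_ref * n_alt / (n * (n-1)) over non-missing
    allele counts; the window value divides the summed site diversity by the
    full window span in bp (monomorphic and uncalled positions count in the
    denominator).
    """
    called = m.dosage != MISSING
    n_called_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, m.dosage, 0).sum(axis=1)
    ref = n_called_alleles - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(
            n_called_alleles > 1,
            2.0 * ref * alt / (n_called_alleles * (n_called_alleles - 1.0)),
            0.0,
        )
    rows = []
    chrom_len = m.contigs
    for chrom, grp_idx in m.sites.groupby("chrom", sort=False).indices.items():
        pos0 = m.sites["pos"].to_numpy()[grp_idx] - 1
        pis = site_pi[grp_idx]
        length = chrom_len.get(chrom, int(pos0.max()) + 1 if pos0.size else window)
        n_win = int(np.ceil(length / window))
        widx = pos0 // window
        sums = np.bincount(widx, weights=pis, minlength=n_win)
        counts = np.bincount(widx, minlength=n_win)
        for w in range(n_win):
            start = w * window
            end = min(start + window, length)
            rows.append((chrom, start, end, int(counts[w]), sums[w] / (end - start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


# ---------------------------------------------------------------------------
# sex association


def sex_association(m: SexedGenotypeMatrix) -> pd.DataFrame:
    """1-df allelic chi-square per site on the 2x2 allele-by-sex table.

    No continuity correction.  Zero-margin tables give chi2=0, p=1.
    Returns chrom, pos, chi2, p.
    """
    counts = sex_allele_counts(m)
    alt_m = counts["alt_m"].to_numpy(float)
    alt_f = counts["alt_f"].to_numpy(float)
    ref_m = 2.0 * counts["n_m"].to_numpy(float) - alt_m
    ref_f = 2.0 * counts["n_f"].to_numpy(float) - alt_f
    total = alt_m + alt_f + ref_m + ref_f
    row_m = alt_m + ref_m
    row_f = alt_f + ref_f
    col_alt = alt_m + alt_f
    col_ref = ref_m + ref_f
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (
            total
            * (alt_m * ref_f - alt_f * ref_m) ** 2
            / (row_m * row_f * col_alt * col_ref)
        )
    degenerate = (row_m == 0) | (row_f == 0) | (col_alt == 0) | (col_ref == 0)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"chrom": m.sites["chrom"], "pos": m.sites["pos"], "chi2": chi2, "p": p}
    )
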