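"""Sex-linked SNP classification, windowed XY/ZW model selection, and
candidate-region calling.

SNP classification uses allele-frequency windows: a SNP is called XY when
the male alt frequency lies in [0.45, 0.55] and the female frequency in
[0, 0.05] or [0.95, 1] (heterozygous in males, homozygous in females);
ZW with the sexes exchanged.  The tolerance absorbs genotyping error
without requiring the exact 0.5 / 0 frequencies.

Window model selection fits, per non-overlapping 10-kb window, three
genotype-likelihood models:

* NULL — every SNP follows Hardy-Weinberg at its pooled frequency;
* XY — each SNP is, with window-shared probability rho, fully sex-linked
  (males heterozygous, females homozygous, observed genotypes matching
  that expectation with probability 1-eps and each other state eps/2),
  otherwise the NULL term;
* ZW — the same with sexes exchanged.

Models are compared by BIC with the NULL nested at rho=0; dBIC =
BIC_null - BIC_model, so large positive values favor the sex model.  The
working threshold for strong support is dBIC > 2000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import MISSING, SexedGenotypeMatrix

BIC_THRESHOLD_DEFAULT = 2000.0


# ---------------------------------------------------------------------------
# SNP classification


@dataclass(frozen=True)
class ClassifyConfig:
    """Allele-frequency windows for XY/ZW SNP classification."""

    het_lo: float = 0.45
    het_hi: float = 0.55
    hom_tol: float = 0.05

    def __post_init__(self):
        if not 0 <= self.het_lo < self.het_hi <= 1:
            raise ValueError("need 0 <= het_lo < het_hi <= 1")
        if not 0 <= self.hom_tol < self.het_lo:
            raise ValueError("hom_tol must be below het_lo")


def classify_snps(freqs: pd.DataFrame, cfg: ClassifyConfig | None = None) -> pd.DataFrame:
    """Classify SNPs as XY / ZW / NONE from per-sex alt frequencies.

    ``freqs`` needs columns p_m and p_f (NaN frequencies give NONE); all
    bounds are inclusive.  Adds a ``call`` column; other columns (chrom,
    pos, theta, ...) pass through.
    """
    cfg = cfg or ClassifyConfig()
    p_m = freqs["p_m"].to_numpy(float)
    p_f = freqs["p_f"].to_numpy(float)

    def _het(p):
        return (p >= cfg.het_lo) & (p <= cfg.het_hi)

    def _hom(p):
        return (p <= cfg.hom_tol) | (p >= 1.0 - cfg.hom_tol)

    with np.errstate(invalid="ignore"):
        xy = _het(p_m) & _hom(p_f)
        zw = _het(p_f) & _hom(p_m)
    defined = np.isfinite(p_m) & np.isfinite(p_f)
    call = np.select([defined & xy, defined & zw], ["XY", "ZW"], default="NONE")
    out = freqs.copy()
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# window model fitting


@dataclass(frozen=True)
class ModelConfig:
    """Windowed model-selection settings."""

    window: int = 10_000
    epsilon: float = 0.01
    bic_threshold: float = BIC_THRESHOLD_DEFAULT
    min_obs: int = 1
    rho_tol: float = 1e-6

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


EPSILON_GRID = (0.001, 0.005, 0.01, 0.02, 0.05)


def _golden_max(f, lo=0.0, hi=1.0, tol=1e-6) -> tuple[float, float]:
    """Golden-section maximization of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    # include the boundaries: rho-hat is often exactly 0 or 1
    cands = [(f(lo), lo), (f(hi), hi), (max(fc, fd), (a + b) / 2.0)]
    best = max(cands)
    return best[1], best[0]


def _site_loglikes(
    dosage: np.ndarray, het_idx: np.ndarray, hom_idx: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP log-likelihood of the NULL and fully-sex-linked components.

    dosage: (m, n) with -1 missing.  het_idx/hom_idx index the
    heterogametic / homogametic individuals.  Returns (l_null, l_sex),
    each of length m.  The homozygote class of the homogametic sex (ref vs
    alt) is chosen per SNP to maximize the component likelihood, ties going
    to the reference class.
    """
    called = dosage != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
    # HWE genotype log-probs per SNP; clip to avoid log(0) at fixed sites
    tiny = 1e-12
    logp = np.stack(
        [
            np.log(np.clip((1 - p) ** 2, tiny, None)),
            np.log(np.clip(2 * p * (1 - p), tiny, None)),
            np.log(np.clip(p**2, tiny, None)),
        ],
        axis=1,
    )  # (m, 3)
    dos_idx = np.clip(dosage, 0, 2).astype(np.int64)
    l_null = np.where(called, np.take_along_axis(logp, dos_idx, axis=1), 0.0).sum(axis=1)

    log_match = np.log(1.0 - eps)
    log_miss = np.log(eps / 2.0)

    def _component(expected: np.ndarray, idx: np.ndarray) -> np.ndarray:
        d = dosage[:, idx]
        ok = d != MISSING
        match = d == expected[:, None]
        return np.where(ok, np.where(match, log_match, log_miss), 0.0).sum(axis=1)

    m = dosage.shape[0]
    ones = np.ones(m, dtype=np.int8)
    l_het = _component(ones, het_idx)
    l_hom_ref = _component(np.zeros(m, dtype=np.int8), hom_idx)
    l_hom_alt = _component(np.full(m, 2, dtype=np.int8), hom_idx)
    l_hom = np.maximum(l_hom_ref, l_hom_alt)  # ties resolve to ref value (equal)
    return l_null, l_het + l_hom


def fit_window_models(
    m: SexedGenotypeMatrix, cfg: ModelConfig | None = None
) -> pd.DataFrame:
    """Fit NULL / XY / ZW models per non-overlapping window.

    Returns one row per window that contains at least one usable SNP plus
    empty windows (dBIC 0) for completeness, with columns chrom, start,
    end, m (SNPs), n_obs, logl_null, logl_xy, logl_zw, rho_xy, rho_zw,
    dbic_xy, dbic_zw.
    """
    cfg = cfg or ModelConfig()
    male_idx = m.male_idx
    female_idx = m.female_idx
    rows = []
    pos = m.sites["pos"].to_numpy()
    for chrom, idx in m.sites.groupby("chrom", sort=False).indices.items():
        length = m.contigs.get(chrom, int(pos[idx].max()) if idx.size else cfg.window)
        n_win = int(np.ceil(length / cfg.window))
        widx = (pos[idx] - 1) // cfg.window
        for w in range(n_win):
            start = w * cfg.window
            end = min(start + cfg.window, length)
            snp_rows = idx[widx == w]
            if snp_rows.size == 0:
                rows.append(
                    (chrom, start, end, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
                )
                continue
            dosage = m.dosage[snp_rows]
            n_obs = int((dosage != MISSING).sum())
            if n_obs < cfg.min_obs:
                rows.append(
                    (chrom, start, end, int(snp_rows.size), n_obs, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
                )
                continue
            l_null_xy, l_sex_xy = _site_loglikes(dosage, male_idx, female_idx, cfg.epsilon)
            l_null_zw, l_sex_zw = _site_loglikes(dosage, female_idx, male_idx, cfg.epsilon)
            logl_null = float(l_null_xy.sum())

            def _fit(l_null, l_sex):
                delta = l_sex - l_null

                def ll(rho):
                    if rho <= 0.0:
                        return float(l_null.sum())
                    if rho >= 1.0:
                        return float(l_sex.sum())
                    # log((1-rho) e^{l_null} + rho e^{l_sex}) summed over SNPs
                    return float(
                        (l_null + np.logaddexp(np.log1p(-rho), np.log(rho) + delta)).sum()
                    )

                rho_hat, logl = _golden_max(ll, tol=cfg.rho_tol)
                logl = max(logl, float(l_null.sum()))  # nested model floor
                return rho_hat, logl

            rho_xy, logl_xy = _fit(l_null_xy, l_sex_xy)
            rho_zw, logl_zw = _fit(l_null_zw, l_sex_zw)
            penalty = np.log(n_obs)
            dbic_xy = 2.0 * (logl_xy - logl_null) - penalty
            dbic_zw = 2.0 * (logl_zw - logl_null) - penalty
            rows.append(
                (
                    chrom,
                    start,
                    end,
                    int(snp_rows.size),
                    n_obs,
                    logl_null,
                    logl_xy,
                    logl_zw,
                    rho_xy,
                    rho_zw,
                    dbic_xy,
                    dbic_zw,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "m",
            "n_obs",
            "logl_null",
            "logl_xy",
            "logl_zw",
            "rho_xy",
            "rho_zw",
            "dbic_xy",
            "dbic_zw",
        ],
    )


def estimate_epsilon(
    m: SexedGenotypeMatrix, cfg: ModelConfig | None = None, grid=EPSILON_GRID
) -> float:
    """Profile-likelihood choice of the genotype error rate on a coarse grid.

    Maximizes the summed best-model window log-likelihood over the grid.
    """
    best_eps, best_ll = grid[0], -np.inf
    for eps in grid:
        c = ModelConfig(
            window=(cfg or ModelConfig()).window,
            epsilon=eps,
            bic_threshold=(cfg or ModelConfig()).bic_threshold,
        )
        fits = fit_window_models(m, c)
        ll = float(np.maximum(fits["logl_xy"], fits["logl_zw"]).sum())
        if ll > best_ll:
            best_eps, best_ll = eps, ll
    return best_eps


# ---------------------------------------------------------------------------
# region calling


@dataclass(frozen=True)
class RegionCallConfig:
    """Clustering thresholds for candidate-region calling."""

    max_gap: int = 100_000
    min_snps: int = 10
    fst_min: float = 0.2
    bic_threshold: float = BIC_THRESHOLD_DEFAULT
    require_window_support: bool = False

    def __post_init__(self):
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


@dataclass
class CandidateRegion:
    """A called candidate sex-linked region (1-based inclusive coords)."""

    chrom: str
    start: int
    end: int
    system: str  # XY or ZW
    n_sexlinked_snps: int
    mean_fst: float
    n_support_windows: int
    n_gene_models: int | None = None
    species_label: str = ""
    region_name: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start


def call_candidate_regions(
    classified: pd.DataFrame,
    window_fits: pd.DataFrame | None,
    cfg: RegionCallConfig | None = None,
    expected_system: str = "auto",
) -> list[CandidateRegion]:
    """Cluster classified sex-linked SNPs into candidate regions.

    SNPs of the chosen type with theta >= fst_min are single-linkage
    clustered per chromosome with gap tolerance ``max_gap``; clusters with
    at least ``min_snps`` members become regions delimited by their first
    and last SNP (1-based inclusive).  Each region is annotated with the
    number of overlapping windows whose dBIC for the matching model
    exceeds ``bic_threshold``; regions without window support are kept by
    default (support is evidence, not a gate) unless
    ``require_window_support`` is set.

    ``expected_system`` 'auto' picks the type with more classified SNPs
    genome-wide.
    """
    cfg = cfg or RegionCallConfig()
    if expected_system not in ("XY", "ZW", "auto"):
        raise ValueError("expected_system must be XY, ZW or auto")
    if expected_system == "auto":
        n_xy = int((classified["call"] == "XY").sum())
        n_zw = int((classified["call"] == "ZW").sum())
        expected_system = "XY" if n_xy >= n_zw else "ZW"
    dbic_col = "dbic_xy" if expected_system == "XY" else "dbic_zw"

    sel = classified[
        (classified["call"] == expected_system)
        & (classified["theta"].to_numpy(float) >= cfg.fst_min)
    ]
    regions: list[CandidateRegion] = []
    for chrom, grp in sel.groupby("chrom", sort=False):
        ps = np.sort(grp["pos"].to_numpy())
        thetas = grp.sort_values("pos")["theta"].to_numpy(float)
        if ps.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(ps) > cfg.max_gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, ps.size - 1]
        for s_i, e_i in zip(starts, ends):
            n = int(e_i - s_i + 1)
            if n < cfg.min_snps:
                continue
            start, end = int(ps[s_i]), int(ps[e_i])
            n_support = 0
            if window_fits is not None and len(window_fits):
                wf = window_fits[window_fits["chrom"] == chrom]
                overlap = (wf["start"].to_numpy() < end) & (
                    wf["end"].to_numpy() > start - 1
                )
                n_support = int(
                    (wf.loc[overlap, dbic_col].to_numpy() > cfg.bic_threshold).sum()
                )
            if cfg.require_window_support and n_support == 0:
                continue
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    system=expected_system,
                    n_sexlinked_snps=n,
                    mean_fst=float(thetas[s_i : e_i + 1].mean()),
                    n_support_windows=n_support,
                )
            )
    for i, reg in enumerate(regions, 1):
        reg.region_name = f"{reg.system}.{reg.chrom}.{i}"
    return regions


def summarize_regions(
    regions: list[CandidateRegion],
    gff3_path=None,
    species_label: str = "",
) -> pd.DataFrame:
    """Tabular summary of candidate regions (1-based inclusive coordinates,
    size = end - start), optionally with gene-model overlap counts from a
    GFF3 annotation (half-open interval overlap of 'gene' features)."""
    genes: dict[str, list[tuple[int, int]]] = {}
    if gff3_path is not None:
        genes = _read_gff3_genes(gff3_path)
    rows = []
    for reg in regions:
        n_genes = None
        if gff3_path is not None:
            n_genes = sum(
                1
                for s, e in genes.get(reg.chrom, [])
                if s < reg.end and e > reg.start - 1
            )
        rows.append(
            (
                species_label or reg.species_label,
                reg.chrom,
                reg.region_name,
                reg.start,
                reg.end,
                reg.size,
                reg.n_sexlinked_snps,
                round(reg.mean_fst, 4),
                reg.n_support_windows,
                n_genes,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "linkage_group",
            "region_name",
            "start",
            "end",
            "size_bp",
            "n_sexlinked_snps",
            "mean_mf_fst",
            "n_support_windows",
            "n_gene_models",
        ],
    )


def _read_gff3_genes(path) -> dict[str, list[tuple[int, int]]]:
    """Parse 'gene' features from a GFF3 into 0-based half-open intervals."""
    genes: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 at line {ln}: {line[:80]!r}")
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"malformed GFF3 coordinates at line {ln}") from exc
            genes.setdefault(parts[0], []).append((start - 1, end))
    return genes
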