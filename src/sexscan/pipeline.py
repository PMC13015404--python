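"""End-to-end orchestration: simulate -> filter -> stats -> classify ->
model -> regions -> coverage (-> k-mers), with YAML config, a provenance
manifest and plain-text outputs.

Every stage is a pure function of (inputs, config, seed); rerunning with
the same config yields byte-identical tables.  All outputs are TSV / BED /
bedGraph / JSON for inspectability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, covscan, popstats, sdscan, simdata, vcfio

log = logging.getLogger("sexscan")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data run."""

    seed: int
    species_label: str = "synthetic"
    chromosomes: list = field(default_factory=lambda: [["chr1", 3_000_000]])
    architecture: str = "XY"
    sd_regions: list = field(default_factory=list)  # [chrom, start, end]
    y_insertion: list | None = None
    n_males: int = 20
    n_females: int = 20
    snp_density: float = 0.01
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.02
    depth_mean: float = 10.0
    depth_sd: float = 2.0
    filter_preset: str = "strict"
    sample_missing_threshold: float = 0.7
    expected_system: str = "auto"
    model_window: int = 10_000
    model_epsilon: float = 0.01
    bic_threshold: float = 2000.0
    region_max_gap: int = 100_000
    region_min_snps: int = 10
    region_fst_min: float = 0.2
    coverage_enabled: bool = True
    coverage_bin: int = 5000
    coverage_female_factor: float = 0.0
    coverage_male_factor: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def layout(self) -> simdata.GenomeLayout:
        return simdata.GenomeLayout(
            chromosomes=tuple((c, int(n)) for c, n in self.chromosomes),
            sd_architecture=simdata.SDArchitecture(self.architecture),
            sd_regions=tuple((c, int(s), int(e)) for c, s, e in self.sd_regions),
            y_insertion=tuple(self.y_insertion) if self.y_insertion else None,
        )

    def population(self) -> simdata.PopulationSpec:
        return simdata.PopulationSpec(
            seed=self.seed,
            n_males=self.n_males,
            n_females=self.n_females,
            snp_density=self.snp_density,
            genotype_error_rate=self.genotype_error_rate,
            missing_rate=self.missing_rate,
            depth_mean=self.depth_mean,
            depth_sd=self.depth_sd,
        )


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sexscan {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Run the full pipeline into ``out_dir``; returns a result summary.

    Stages: genotype simulation, VCF round-trip, filtering, sample QC,
    F_ST / pi / association, SNP classification, window model fits,
    region calling, and (optionally) coverage comparison.  A manifest
    with config hash and per-stage counts is written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    manifest: dict = {
        "version": __version__,
        "config_hash": h,
        "seed": cfg.seed,
        "stages": {},
    }

    def _stage(name, **counts):
        manifest["stages"][name] = {**counts, "t": round(time.time() - t0, 2)}
        log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))

    t0 = time.time()
    layout = cfg.layout()
    pop = cfg.population()
    matrix, sheet, truth = simdata.simulate_genotypes(layout, pop)
    vcf_path = out / "simulated.vcf"
    vcfio.write_vcf(matrix, vcf_path)
    sheet.write(out / "samples.tsv")
    truth.write(out / "truth.json")
    truth.write_regions_bed(out / "truth_regions.bed")
    _stage("simulate", sites=matrix.n_sites, samples=matrix.n_samples)

    matrix = vcfio.read_vcf(vcf_path, sheet)
    fcfg = (
        vcfio.FilterConfig.relaxed()
        if cfg.filter_preset == "relaxed"
        else vcfio.FilterConfig.strict()
    )
    filtered, report = vcfio.apply_filters(matrix, fcfg)
    _stage("filter", **report.as_dict())

    qc = vcfio.sample_qc(filtered)
    _write_tsv(qc, out / "sample_qc.tsv", h)
    filtered, dropped = vcfio.exclude_high_missing(
        filtered, cfg.sample_missing_threshold
    )
    _stage("sample_qc", dropped=len(dropped))

    fst = popstats.per_site_fst(filtered)
    weighted = popstats.wc_fst_weighted(fst)
    assoc = popstats.sex_association(filtered)
    fst["chi2"] = assoc["chi2"]
    fst["p"] = assoc["p"]
    _write_tsv(fst, out / "per_site_stats.tsv", h)
    pi = popstats.windowed_pi(filtered, window=cfg.model_window)
    _write_tsv(pi, out / "windowed_pi.tsv", h)
    _stage("popstats", sites=len(fst), weighted_fst=round(weighted, 6))

    classified = sdscan.classify_snps(fst)
    _write_tsv(
        classified[classified["call"] != "NONE"], out / "classified_snps.tsv", h
    )
    _stage(
        "classify",
        xy=int((classified["call"] == "XY").sum()),
        zw=int((classified["call"] == "ZW").sum()),
    )

    fits = sdscan.fit_window_models(
        filtered,
        sdscan.ModelConfig(
            window=cfg.model_window,
            epsilon=cfg.model_epsilon,
            bic_threshold=cfg.bic_threshold,
        ),
    )
    _write_tsv(fits, out / "window_fits.tsv", h)
    _stage(
        "sdmodel",
        windows=len(fits),
        xy_support=int((fits["dbic_xy"] > cfg.bic_threshold).sum()),
        zw_support=int((fits["dbic_zw"] > cfg.bic_threshold).sum()),
    )

    rcfg = sdscan.RegionCallConfig(
        max_gap=cfg.region_max_gap,
        min_snps=cfg.region_min_snps,
        fst_min=cfg.region_fst_min,
        bic_threshold=cfg.bic_threshold,
    )
    regions = sdscan.call_candidate_regions(
        classified, fits, rcfg, expected_system=cfg.expected_system
    )
    summary = sdscan.summarize_regions(regions, species_label=cfg.species_label)
    _write_tsv(summary, out / "candidate_regions.tsv", h)
    with open(out / "candidate_regions.bed", "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_name}\n")
    _stage("regions", called=len(regions))

    coverage_intervals = None
    if cfg.coverage_enabled and layout.y_insertion is not None:
        tracks = simdata.simulate_depth_tracks(
            layout,
            pop,
            bin_size=cfg.coverage_bin,
            female_factor=cfg.coverage_female_factor,
            male_factor=cfg.coverage_male_factor,
        )
        sexes = dict(zip(pop.sample_names, pop.sexes))
        male = [t for s, t in tracks.items() if sexes[s] == "M"]
        female = [t for s, t in tracks.items() if sexes[s] == "F"]
        cmp_ = covscan.sex_coverage_ratio(male, female)
        _write_tsv(cmp_.bins, out / "coverage_comparison.tsv", h)
        coverage_intervals = covscan.detect_depleted_intervals(cmp_)
        _write_tsv(coverage_intervals, out / "female_depleted_intervals.bed", h)
        _stage("coverage", depleted_intervals=len(coverage_intervals))

    manifest["inputs"] = {
        "vcf_sha256": hashlib.sha256(vcf_path.read_bytes()).hexdigest()[:16]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "matrix": filtered,
        "truth": truth,
        "fst": fst,
        "weighted_fst": weighted,
        "classified": classified,
        "window_fits": fits,
        "regions": regions,
        "region_summary": summary,
        "coverage_intervals": coverage_intervals,
        "manifest": manifest,
    }
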