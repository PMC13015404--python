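"""Bundled demonstration scenarios with known ground truth.

These are the package's reference study conditions: a male-heterogametic
(XY) species with a single localized sex-determining region, a
female-heterogametic species with a polygenic ZW architecture, a
male-limited insertion for coverage/k-mer analyses, and a divergent
Y-linked paralog screened across a panel of RNA-seq libraries.  Genome
sizes are Mb-scale stand-ins for Gb-scale genomes; sample sizes, error
rates, window sizes and thresholds keep their full-scale values so that
detection thresholds transfer.

All functions derive their randomness from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import simdata
from .pipeline import RunConfig


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.default_rng([seed, salt]).integers(0, 2**31 - 1))


def xy_localized(seed: int) -> RunConfig:
    """A quagga-mussel-like XY scenario: one 3-Mb chromosome with a single
    80-kb sex-determining region, 19 males / 19 females, genotyping error
    0.005."""
    return RunConfig(
        seed=seed,
        species_label="xy_demo",
        chromosomes=[["chr1", 3_000_000]],
        architecture="XY",
        sd_regions=[["chr1", 1_500_000, 1_580_000]],
        n_males=19,
        n_females=19,
        genotype_error_rate=0.005,
        expected_system="auto",
        coverage_enabled=False,
    )


def polygenic_zw(seed: int) -> RunConfig:
    """A zebra-mussel-like polygenic ZW scenario: three sex-linked regions
    spread over two of three chromosomes, 20 males / 20 females."""
    return RunConfig(
        seed=seed,
        species_label="zw_demo",
        chromosomes=[["chr1", 1_200_000], ["chr2", 1_200_000], ["chr3", 800_000]],
        architecture="POLYGENIC_ZW",
        sd_regions=[
            ["chr1", 300_000, 360_000],
            ["chr1", 700_000, 740_000],
            ["chr2", 500_000, 560_000],
        ],
        n_males=20,
        n_females=20,
        genotype_error_rate=0.005,
        expected_system="auto",
        coverage_enabled=False,
    )


def null_genome(seed: int, n_windows: int = 500, window: int = 10_000) -> RunConfig:
    """No sex-linked variation anywhere; sized to yield ``n_windows``
    model-selection windows."""
    return RunConfig(
        seed=seed,
        species_label="null_demo",
        chromosomes=[["chr1", n_windows * window]],
        architecture="NULL",
        sd_regions=[],
        n_males=20,
        n_females=20,
        genotype_error_rate=0.01,
        model_epsilon=0.01,
        snp_density=0.003,
        coverage_enabled=False,
    )


def y_insertion_layout(
    genome_len: int = 250_000, insertion: tuple[int, int] = (100_000, 120_000)
) -> simdata.GenomeLayout:
    """Layout for read-based coverage / k-mer analyses: one chromosome with
    a male-limited insertion (present in the male-derived reference,
    absent from females, hemizygous in males)."""
    return simdata.GenomeLayout(
        chromosomes=(("chr1", genome_len),),
        sd_architecture=simdata.SDArchitecture.XY,
        y_insertion=("chr1", insertion[0], insertion[1]),
    )


def y_insertion_population(seed: int, depth: float = 10.0) -> simdata.PopulationSpec:
    """19 males / 19 females at ~10x depth, matching the k-mer analysis
    design of equal-sized sex pools."""
    return simdata.PopulationSpec(
        seed=seed, n_males=19, n_females=19, depth_mean=depth, depth_sd=1.0
    )


def foxl2_like_panel(seed: int):
    """Paralog pair, diagnostic targets and a 23-library RNA-seq plan.

    The panel mirrors a developmental screening design: 21 libraries
    without the Y-paralog transcript and 2 early-development libraries
    carrying it at relative abundance 1e-5.  The two spiked libraries are
    deep (2M read pairs) so that an abundance of 1e-5 still yields ~20
    fragments; the null libraries are 1000x-scaled-down stand-ins for
    15M-100M-read libraries.

    Returns (pair, transcripts, alternatives, plans, spiked_ids).
    """
    rng = np.random.default_rng([seed, 101])
    pair = simdata.make_paralog_pair(simdata.ParalogSpec(seed=_sub_seed(seed, 7)))
    # a sister-species FoxL2 ortholog: canonical CDS with ~3% substitutions
    canon = pair.canonical_cds
    sister = list(canon)
    n_sub = int(0.03 * len(sister))
    pos = rng.choice(len(sister), size=n_sub, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != sister[p]]
        sister[p] = choices[int(rng.integers(0, 3))]
    sister = "".join(sister)
    transcripts = {
        "foxl2_y": pair.derived_cds,
        "foxl2": canon,
        "foxl2_sister": sister,
    }
    alternatives = {"foxl2": canon, "foxl2_sister": sister}
    spiked_ids = ["dev_trochophore", "dev_early_veliger"]
    plans = []
    null_sizes = rng.integers(15_000, 100_001, size=21)
    for i in range(21):
        plans.append(
            simdata.LibraryPlan(
                lib_id=f"lib{i + 1:02d}",
                n_reads=int(null_sizes[i]),
                abundances={"foxl2_y": 0.0, "foxl2": 0.7, "foxl2_sister": 0.3},
            )
        )
    for lib_id in spiked_ids:
        plans.append(
            simdata.LibraryPlan(
                lib_id=lib_id,
                n_reads=2_000_000,
                abundances={
                    "foxl2_y": 1e-5,
                    "foxl2": 0.7 - 1e-5,
                    "foxl2_sister": 0.3,
                },
            )
        )
    return pair, transcripts, alternatives, plans, spiked_ids
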