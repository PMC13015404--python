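import numpy as np
import pandas as pd
import pytest

from sexscan import sdscan, vcfio
from sexscan.vcfio import MISSING, SexedGenotypeMatrix


def _freqs(p_m, p_f):
    return pd.DataFrame({"chrom": ["chr1"], "pos": [100], "p_m": [p_m], "p_f": [p_f]})


class TestClassify:
    @pytest.mark.parametrize(
        "p_m,p_f,expected",
        [
            (0.50, 0.00, "XY"),
            (0.45, 0.05, "XY"),  # inclusive bounds
            (0.50, 0.97, "XY"),  # homozygous-alt females
            (1.00, 0.50, "ZW"),
            (0.02, 0.48, "ZW"),
            (0.50, 0.50, "NONE"),
            (0.44, 0.00, "NONE"),  # just outside the het window
            (0.50, 0.06, "NONE"),
            (np.nan, 0.0, "NONE"),
        ],
    )
    def test_call_from_frequency_pattern(self, p_m, p_f, expected):
        out = sdscan.classify_snps(_freqs(p_m, p_f))
        assert out["call"][0] == expected

    def test_xy_and_zw_mutually_exclusive_at_defaults(self, rng):
        freqs = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(500),
                "p_m": rng.random(500),
                "p_f": rng.random(500),
            }
        )
        out = sdscan.classify_snps(freqs)
        assert not ((out["call"] == "XY") & (out["call"] == "ZW")).any()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sdscan.ClassifyConfig(het_lo=0.6, het_hi=0.5)
        with pytest.raises(ValueError):
            sdscan.ClassifyConfig(hom_tol=0.5)


def _window_matrix(dosage, n_males=20, n_females=20, chrom_len=10_000):
    dosage = np.asarray(dosage, dtype=np.int8)
    m, n = dosage.shape
    pos = np.linspace(100, chrom_len - 100, m).astype(int)
    sites = pd.DataFrame(
        [("chr1", int(p), "A", "G", 50.0, True, 2) for p in pos],
        columns=vcfio.SITE_COLUMNS,
    )
    return SexedGenotypeMatrix(
        sites,
        dosage,
        np.full(dosage.shape, 10, np.int32),
        samples=[f"s{i}" for i in range(n)],
        sexes=["M"] * n_males + ["F"] * n_females,
        contigs={"chr1": chrom_len},
    )


def window_loglike_oracle(dosage, sexes, rho, eps):
    """Direct evaluation of the XY mixture log-likelihood on a rho value:
    per SNP, log[(1-rho) L_null + rho L_sex], products computed termwise."""
    total = 0.0
    for row in dosage:
        called = row != MISSING
        n = called.sum()
        if n == 0:
            continue
        p = row[called].sum() / (2 * n)
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        hwe = np.clip(hwe, 1e-12, None)
        l_null = 1.0
        l_sex_ref = 1.0
        l_sex_alt = 1.0
        for g, sex, ok in zip(row, sexes, called):
            if not ok:
                continue
            l_null *= hwe[g]
            if sex == "M":
                match = g == 1
                l_sex_ref *= (1 - eps) if match else eps / 2
                l_sex_alt *= (1 - eps) if match else eps / 2
            else:
                l_sex_ref *= (1 - eps) if g == 0 else eps / 2
                l_sex_alt *= (1 - eps) if g == 2 else eps / 2
        l_sex = max(l_sex_ref, l_sex_alt)
        total += np.log((1 - rho) * l_null + rho * l_sex)
    return total


class TestWindowFits:
    def test_empty_window_has_zero_dbic(self):
        # one SNP in the second 10-kb window; the first window has none
        dosage = np.array([[0, 1] * 20], dtype=np.int8)
        m = _window_matrix(dosage, chrom_len=20_000)
        m.sites.loc[0, "pos"] = 15_000
        fits = sdscan.fit_window_models(m)
        assert len(fits) == 2
        empty = fits.iloc[0]
        assert empty["m"] == 0 and empty["dbic_xy"] == 0.0 and empty["dbic_zw"] == 0.0

    def test_null_window_penalized(self, rng):
        p = rng.uniform(0.1, 0.9, size=50)
        dosage = rng.binomial(2, p[:, None], size=(50, 40)).astype(np.int8)
        m = _window_matrix(dosage)
        fits = sdscan.fit_window_models(m, sdscan.ModelConfig(epsilon=0.01))
        n_obs = 50 * 40
        assert fits["rho_xy"][0] < 0.02
        assert fits["dbic_xy"][0] <= 0.0
        assert fits["dbic_xy"][0] == pytest.approx(-np.log(n_obs), abs=1.0)

    def test_fully_linked_window_exceeds_bic_threshold(self):
        dosage = np.tile([1] * 20 + [0] * 20, (50, 1)).astype(np.int8)
        m = _window_matrix(dosage)
        fits = sdscan.fit_window_models(m, sdscan.ModelConfig(epsilon=0.01))
        assert fits["dbic_xy"][0] > 2000
        assert fits["dbic_zw"][0] < fits["dbic_xy"][0]

    def test_loglik_matches_direct_oracle_on_rho_grid(self, rng):
        # mixed window: 10 linked SNPs among 20 null SNPs
        p = rng.uniform(0.1, 0.9, size=20)
        null_part = rng.binomial(2, p[:, None], size=(20, 40)).astype(np.int8)
        linked = np.tile([1] * 20 + [0] * 20, (10, 1)).astype(np.int8)
        dosage = np.vstack([null_part, linked])
        m = _window_matrix(dosage)
        eps = 0.01
        fits = sdscan.fit_window_models(m, sdscan.ModelConfig(epsilon=eps))
        sexes = ["M"] * 20 + ["F"] * 20
        grid = np.linspace(0, 1, 101)
        oracle_best = max(
            window_loglike_oracle(dosage, sexes, r, eps) for r in grid
        )
        assert fits["logl_xy"][0] >= oracle_best - 1e-6
        # and the fitted logL is attainable: within tolerance of the grid max
        assert fits["logl_xy"][0] == pytest.approx(oracle_best, abs=0.01)

    def test_nesting_model_never_below_null(self, null_sim):
        matrix, _, _ = null_sim
        fits = sdscan.fit_window_models(matrix)
        used = fits[fits["m"] > 0]
        assert (used["logl_xy"] >= used["logl_null"] - 1e-9).all()
        assert (used["logl_zw"] >= used["logl_null"] - 1e-9).all()

    def test_sex_swap_duality_is_exact(self, rng):
        dosage = rng.integers(0, 3, size=(30, 40)).astype(np.int8)
        m = _window_matrix(dosage)
        swapped = SexedGenotypeMatrix(
            m.sites,
            m.dosage,
            m.depth,
            m.samples,
            ["F" if s == "M" else "M" for s in m.sexes],
            m.contigs,
        )
        f1 = sdscan.fit_window_models(m)
        f2 = sdscan.fit_window_models(swapped)
        assert f1["dbic_xy"][0] == pytest.approx(f2["dbic_zw"][0], abs=1e-9)
        assert f1["dbic_zw"][0] == pytest.approx(f2["dbic_xy"][0], abs=1e-9)

    def test_dbic_monotone_in_linked_snp_count(self):
        dbics = []
        for m_snps in (5, 10, 25, 50):
            dosage = np.tile([1] * 20 + [0] * 20, (m_snps, 1)).astype(np.int8)
            mat = _window_matrix(dosage)
            fits = sdscan.fit_window_models(mat, sdscan.ModelConfig(epsilon=0.01))
            dbics.append(fits["dbic_xy"][0])
        assert all(b > a for a, b in zip(dbics, dbics[1:]))

    def test_epsilon_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sdscan.ModelConfig(epsilon=0.5)


class TestRegions:
    def _classified(self, positions_kb, theta=0.5, call="XY"):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [p * 1000 for p in positions_kb],
                "theta": theta,
                "call": call,
            }
        )

    def test_no_classified_snps_gives_no_regions(self):
        out = sdscan.call_candidate_regions(
            self._classified([]), None, expected_system="XY"
        )
        assert out == []

    def test_hand_clustering_example(self):
        cl = self._classified([100, 110, 120, 900, 905, 912, 920])
        cfg = sdscan.RegionCallConfig(max_gap=50_000, min_snps=3)
        out = sdscan.call_candidate_regions(cl, None, cfg, expected_system="XY")
        assert [(r.start, r.end) for r in out] == [
            (100_000, 120_000),
            (900_000, 920_000),
        ]
        assert [r.n_sexlinked_snps for r in out] == [3, 4]

    def test_low_fst_snps_excluded(self):
        cl = self._classified([100, 101, 102, 103], theta=0.1)
        out = sdscan.call_candidate_regions(
            cl, None, sdscan.RegionCallConfig(min_snps=3), expected_system="XY"
        )
        assert out == []

    def test_window_support_counted_but_not_required(self):
        cl = self._classified([100, 101, 102])
        fits = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100_000, 110_000],
                "end": [110_000, 120_000],
                "dbic_xy": [2500.0, 100.0],
                "dbic_zw": [0.0, 0.0],
            }
        )
        cfg = sdscan.RegionCallConfig(min_snps=3)
        out = sdscan.call_candidate_regions(cl, fits, cfg, expected_system="XY")
        assert len(out) == 1 and out[0].n_support_windows == 1
        # no-support region survives by default ...
        fits.loc[0, "dbic_xy"] = 10.0
        out2 = sdscan.call_candidate_regions(cl, fits, cfg, expected_system="XY")
        assert len(out2) == 1 and out2[0].n_support_windows == 0
        # ... but is dropped when support is required
        cfg2 = sdscan.RegionCallConfig(min_snps=3, require_window_support=True)
        assert sdscan.call_candidate_regions(cl, fits, cfg2, expected_system="XY") == []

    def test_auto_picks_majority_type(self):
        xy = self._classified([100, 101, 102])
        zw = self._classified([300, 301, 302, 303, 304], call="ZW")
        both = pd.concat([xy, zw], ignore_index=True)
        out = sdscan.call_candidate_regions(
            both, None, sdscan.RegionCallConfig(min_snps=3), expected_system="auto"
        )
        assert {r.system for r in out} == {"ZW"}

    def test_regions_disjoint_and_sorted(self, rng):
        pos = np.sort(rng.choice(2_000_000, size=300, replace=False))
        cl = pd.DataFrame({"chrom": "chr1", "pos": pos, "theta": 0.5, "call": "XY"})
        out = sdscan.call_candidate_regions(
            cl, None, sdscan.RegionCallConfig(min_snps=5), expected_system="XY"
        )
        for r1, r2 in zip(out, out[1:]):
            assert r1.end < r2.start
        assert all(r.n_sexlinked_snps >= 5 for r in out)


class TestSummarize:
    @pytest.mark.parametrize(
        "start,end,size",
        [
            (20_109_000, 20_906_000, 797_000),
            (7_713_960, 8_190_025, 476_065),
            (61_720_161, 61_724_152, 3_991),
        ],
    )
    def test_size_is_end_minus_start(self, start, end, size):
        reg = sdscan.CandidateRegion(
            chrom="LG13", start=start, end=end, system="XY",
            n_sexlinked_snps=10, mean_fst=0.3, n_support_windows=1,
        )
        table = sdscan.summarize_regions([reg])
        assert int(table["size_bp"][0]) == size

    def test_gene_model_overlap_count(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t500\t1500\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t5000\t6000\t.\t+\t.\tID=g2\n"
            "chr1\tsrc\texon\t500\t800\t.\t+\t.\tID=e1\n"
            "chr2\tsrc\tgene\t100\t200\t.\t+\t.\tID=g3\n"
        )
        reg = sdscan.CandidateRegion(
            chrom="chr1", start=1000, end=2000, system="XY",
            n_sexlinked_snps=10, mean_fst=0.3, n_support_windows=0,
        )
        table = sdscan.summarize_regions([reg], gff3_path=gff)
        assert int(table["n_gene_models"][0]) == 1

    def test_empty_gff_gives_zero_counts(self, tmp_path):
        gff = tmp_path / "empty.gff3"
        gff.write_text("##gff-version 3\n")
        reg = sdscan.CandidateRegion(
            chrom="chr1", start=1, end=10, system="XY",
            n_sexlinked_snps=10, mean_fst=0.3, n_support_windows=0,
        )
        table = sdscan.summarize_regions([reg], gff3_path=gff)
        assert int(table["n_gene_models"][0]) == 0

    def test_malformed_gff_is_an_error(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("chr1\tgene\tonly-three-columns\n")
        reg = sdscan.CandidateRegion(
            chrom="chr1", start=1, end=10, system="XY",
            n_sexlinked_snps=10, mean_fst=0.3, n_support_windows=0,
        )
        with pytest.raises(ValueError, match="malformed"):
            sdscan.summarize_regions([reg], gff3_path=gff)
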