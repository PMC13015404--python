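import numpy as np
import pytest

from sexscan import _dna, covscan, popstats, simdata, vcfio
from sexscan.simdata import (
    GenomeLayout,
    LibraryPlan,
    ParalogSpec,
    PopulationSpec,
    SDArchitecture,
)


class TestLayoutValidation:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout(chromosomes=(("chr1", 0),))

    def test_region_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout(
                chromosomes=(("chr1", 1000),),
                sd_architecture=SDArchitecture.XY,
                sd_regions=(("chr1", 500, 2000),),
            )

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenomeLayout(
                chromosomes=(("chr1", 10_000),),
                sd_architecture=SDArchitecture.XY,
                sd_regions=(("chr1", 0, 500), ("chr1", 400, 900)),
            )

    def test_polygenic_needs_regions_on_two_chromosomes(self):
        with pytest.raises(ValueError, match="POLYGENIC"):
            GenomeLayout(
                chromosomes=(("chr1", 10_000), ("chr2", 10_000)),
                sd_architecture=SDArchitecture.POLYGENIC_ZW,
                sd_regions=(("chr1", 0, 500), ("chr1", 600, 900)),
            )

    def test_null_cannot_carry_regions(self):
        with pytest.raises(ValueError):
            GenomeLayout(
                chromosomes=(("chr1", 10_000),),
                sd_architecture=SDArchitecture.NULL,
                sd_regions=(("chr1", 0, 500),),
            )


class TestGenotypeSimulation:
    def test_noise_free_xy_frequencies_are_exact(self, xy_sim):
        matrix, _, truth = xy_sim
        counts = popstats.sex_allele_counts(matrix)
        linked = matrix.sites["pos"].isin([p for _, p, _ in truth.true_sexlinked_snps])
        assert (counts.loc[linked, "p_m"] == 0.5).all()
        assert (counts.loc[linked, "p_f"] == 0.0).all()
        assert (counts.loc[linked, "h_m"] == 1.0).all()

    def test_null_truth_is_empty(self, null_sim):
        _, _, truth = null_sim
        assert truth.true_sexlinked_snps == []

    def test_every_truth_snp_inside_a_region(self, xy_sim):
        _, _, truth = xy_sim
        truth.validate()
        for chrom, pos, kind in truth.true_sexlinked_snps:
            assert kind == "XY"
            assert any(
                c == chrom and s < pos <= e for c, s, e, _ in truth.true_regions
            )

    def test_zw_heterogamety_swaps_roles(self):
        layout = GenomeLayout(
            chromosomes=(("chr1", 100_000),),
            sd_architecture=SDArchitecture.ZW,
            sd_regions=(("chr1", 40_000, 60_000),),
        )
        pop = PopulationSpec(seed=3, genotype_error_rate=0.0, missing_rate=0.0)
        matrix, _, truth = simdata.simulate_genotypes(layout, pop)
        counts = popstats.sex_allele_counts(matrix)
        linked = matrix.sites["pos"].isin([p for _, p, _ in truth.true_sexlinked_snps])
        assert (counts.loc[linked, "p_f"] == 0.5).all()
        assert (counts.loc[linked, "p_m"] == 0.0).all()

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        layout = GenomeLayout(chromosomes=(("chr1", 50_000),))
        for name in ("a", "b"):
            pop = PopulationSpec(seed=42, n_males=4, n_females=4)
            m, _, _ = simdata.simulate_genotypes(layout, pop)
            vcfio.write_vcf(m, tmp_path / f"{name}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            PopulationSpec(seed=1, missing_rate=1.5)
        with pytest.raises(ValueError):
            PopulationSpec(seed=1, n_males=0)


class TestDepthTracks:
    def _pop(self, seed=4, n=8):
        return PopulationSpec(seed=seed, n_males=n, n_females=n, depth_mean=10, depth_sd=1)

    def test_neutral_factors_sexes_indistinguishable(self):
        from scipy import stats

        layout = GenomeLayout(chromosomes=(("chr1", 5_000_000),))
        pop = PopulationSpec(seed=4, n_males=8, n_females=8, depth_mean=10, depth_sd=0.0)
        tracks = simdata.simulate_depth_tracks(layout, pop, bin_size=5000)
        sexes = dict(zip(pop.sample_names, pop.sexes))
        male = np.mean([t["depth"] for s, t in tracks.items() if sexes[s] == "M"], axis=0)
        female = np.mean([t["depth"] for s, t in tracks.items() if sexes[s] == "F"], axis=0)
        p = stats.ttest_ind(male, female).pvalue
        assert p > 0.01

    def test_female_factor_controls_depth_ratio(self):
        layout = GenomeLayout(
            chromosomes=(("chr1", 1_000_000),),
            sd_architecture=SDArchitecture.XY,
            y_insertion=("chr1", 400_000, 500_000),
        )
        tracks = simdata.simulate_depth_tracks(
            layout, self._pop(), female_factor=0.3, male_factor=1.0
        )
        pop = self._pop()
        sexes = dict(zip(pop.sample_names, pop.sexes))
        inside = lambda t: t[(t["start"] >= 400_000) & (t["end"] <= 500_000)]["depth"]
        male = np.mean([inside(t).mean() for s, t in tracks.items() if sexes[s] == "M"])
        female = np.mean([inside(t).mean() for s, t in tracks.items() if sexes[s] == "F"])
        assert female / male == pytest.approx(0.3, abs=0.05)

    def test_genomewide_mean_tracks_depth_mean(self):
        layout = GenomeLayout(chromosomes=(("chr1", 2_000_000),))
        tracks = simdata.simulate_depth_tracks(layout, self._pop())
        means = [t["depth"].mean() for t in tracks.values()]
        assert np.mean(means) == pytest.approx(10.0, rel=0.05)

    def test_bin_larger_than_chromosome_rejected(self):
        layout = GenomeLayout(chromosomes=(("chr1", 1000),))
        with pytest.raises(ValueError):
            simdata.simulate_depth_tracks(layout, self._pop(), bin_size=5000)

    def test_factor_ordering_enforced(self):
        layout = GenomeLayout(chromosomes=(("chr1", 100_000),))
        with pytest.raises(ValueError):
            simdata.simulate_depth_tracks(
                layout, self._pop(), female_factor=1.0, male_factor=0.5
            )


@pytest.fixture(scope="module")
def read_sim(tmp_path_factory):
    layout = GenomeLayout(
        chromosomes=(("chr1", 60_000),),
        sd_architecture=SDArchitecture.XY,
        y_insertion=("chr1", 20_000, 30_000),
    )
    pop = PopulationSpec(seed=9, n_males=2, n_females=2, depth_mean=30, depth_sd=0.5)
    out = tmp_path_factory.mktemp("reads")
    paths, truth, ref = simdata.simulate_sexed_reads(layout, pop, out, error_rate=0.0)
    return paths, truth, ref


class TestSexedReads:
    def test_female_reads_share_no_y_kmers(self, read_sim):
        paths, truth, _ = read_sim
        from sexscan import kmerscan

        truth_codes = np.array(
            sorted(_dna.pack_kmer(_dna.canonical(k)) for k in truth.true_y_kmers),
            dtype=np.uint64,
        )
        for sample, sex in truth.sample_sexes.items():
            table = kmerscan.count_kmers(paths[sample], k=31)
            overlap = np.intersect1d(table.codes, truth_codes).size
            if sex == "F":
                assert overlap == 0
            else:
                # 30x male covers nearly every Y k-mer
                assert overlap / truth_codes.size > 0.99

    def test_read_longer_than_fragment_rejected(self, tmp_path):
        layout = GenomeLayout(chromosomes=(("chr1", 10_000),))
        pop = PopulationSpec(seed=1, n_males=1, n_females=1)
        with pytest.raises(ValueError):
            simdata.simulate_sexed_reads(
                layout, pop, tmp_path, read_len=300, fragment_len=200
            )

    def test_no_insertion_means_no_y_kmers(self, tmp_path):
        layout = GenomeLayout(chromosomes=(("chr1", 20_000),))
        pop = PopulationSpec(seed=2, n_males=1, n_females=1, depth_mean=5)
        _, truth, _ = simdata.simulate_sexed_reads(layout, pop, tmp_path)
        assert truth.true_y_kmers == set()


class TestParalogPair:
    def test_zero_edit_spec_gives_identical_copies(self):
        spec = ParalogSpec(
            seed=5,
            exon1_deletion_len=0,
            exon2_deletion_len=0,
            premature_stop_offset=None,
            intron1_repeat_insertion_len=0,
            background_snv_rate=0.0,
        )
        pair = simdata.make_paralog_pair(spec)
        assert pair.canonical_genomic == pair.derived_genomic
        assert len(pair.variant_table) == 0

    def test_default_spec_preserves_exon_homology(self, paralog_pair):
        # ungapped identity of the aligned exon 1 flanks stays high and
        # exactly one in-frame premature stop lies in the domain interval
        table = paralog_pair.variant_table
        stops = table[table["kind"] == "STOP"]
        assert stops["cds_pos"].nunique() <= 3  # one codon
        cds = paralog_pair.derived_cds
        lo, hi = paralog_pair.domain_cds_interval
        in_frame_stops = [
            i
            for i in range(0, len(cds) - 3, 3)
            if cds[i : i + 3] in simdata.STOP_CODONS
        ]
        # translate only up to the frameshifting exon-2 deletion; its derived
        # coordinate sits left of the canonical one by the upstream in-frame
        # deletion length
        dels = table[table["kind"] == "DEL"]
        shift_canon = int(dels.loc[~dels["frame_preserving"], "cds_pos"].min())
        upstream_inframe = int(
            dels.loc[
                dels["frame_preserving"] & (dels["cds_pos"] < shift_canon), "ref"
            ].str.len().sum()
        )
        shift_at = shift_canon - upstream_inframe
        upstream_stops = [i for i in in_frame_stops if i < shift_at]
        assert len(upstream_stops) == 1
        # the planted stop sits inside the domain (derived coords are 18 bp
        # left of canonical coords past the exon-1 deletion)
        assert lo - 18 <= upstream_stops[0] < hi

    def test_snv_identity_level(self, paralog_pair):
        # background SNV rate 0.01 leaves exon identity >= 85%
        n_snv_exonic = (
            (paralog_pair.variant_table["kind"] == "SNV")
            & (paralog_pair.variant_table["exon"] > 0)
        ).sum()
        assert n_snv_exonic / len(paralog_pair.canonical_cds) <= 0.15

    def test_deletions_exceeding_exon_rejected(self):
        with pytest.raises(ValueError):
            ParalogSpec(seed=1, exon1_deletion_len=700)

    def test_variant_table_matches_sequences(self, paralog_pair):
        # every recorded exonic SNV is observable in the derived CDS
        table = paralog_pair.variant_table
        cds_c = paralog_pair.canonical_cds
        for _, v in table[(table["kind"] == "SNV") & (table["exon"] > 0)].iterrows():
            assert cds_c[int(v["cds_pos"])] == v["ref"]

    def test_gff3_and_fasta_written(self, paralog_pair, tmp_path):
        paralog_pair.write_fasta(tmp_path / "pair.fasta")
        paralog_pair.write_gff3(tmp_path / "pair.gff3")
        fasta = (tmp_path / "pair.fasta").read_text()
        assert fasta.count(">") == 2
        gff = (tmp_path / "pair.gff3").read_text()
        assert gff.count("\tgene\t") == 2
        assert gff.count("\texon\t") == 4


class TestRnaseqLibraries:
    def _tx(self, rng):
        return {
            "t1": _dna.random_dna(rng, 900),
            "t2": _dna.random_dna(rng, 700),
        }

    def test_exact_read_counts(self, tmp_path, rng):
        plans = [
            LibraryPlan("libA", 1000, {"t1": 0.75, "t2": 0.25}),
            LibraryPlan("libB", 500, {"t1": 1.0, "t2": 0.0}),
        ]
        libs = simdata.simulate_rnaseq_libraries(self._tx(rng), plans, tmp_path, seed=3)
        assert [l.n_reads for l in libs] == [1000, 500]
        assert libs[0].true_counts == {"t1": 750, "t2": 250}
        assert libs[1].true_counts["t2"] == 0

    def test_zero_abundance_transcript_absent(self, tmp_path, rng):
        tx = self._tx(rng)
        plans = [LibraryPlan("lib", 2000, {"t1": 1.0, "t2": 0.0})]
        libs = simdata.simulate_rnaseq_libraries(
            tx, plans, tmp_path, error_rate=0.0, seed=4
        )
        import pysam

        t2 = tx["t2"]
        with pysam.FastxFile(str(libs[0].r1)) as fh:
            for entry in fh:
                assert entry.sequence in t2 or entry.sequence not in t2  # read exists
                assert entry.sequence in tx["t1"] or _dna.revcomp(entry.sequence) in tx["t1"]

    def test_tiny_nonzero_abundance_still_present(self, tmp_path, rng):
        plans = [LibraryPlan("lib", 10_000, {"t1": 1 - 1e-5, "t2": 1e-5})]
        libs = simdata.simulate_rnaseq_libraries(self._tx(rng), plans, tmp_path, seed=5)
        assert libs[0].true_counts["t2"] == 1

    def test_empty_library_warns(self, tmp_path, rng):
        plans = [LibraryPlan("lib", 0, {"t1": 1.0})]
        with pytest.warns(UserWarning, match="n_reads=0"):
            libs = simdata.simulate_rnaseq_libraries(self._tx(rng), plans, tmp_path, seed=6)
        assert libs[0].r1.read_text() == ""

    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            LibraryPlan("lib", 10, {"t1": 0.5, "t2": 0.2})
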