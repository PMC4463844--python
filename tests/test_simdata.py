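"""Synthetic-data generator: map construction, F4 breeding, phenotypes,
bulk selection and read sampling."""

import numpy as np
import pandas as pd
import pytest

import qtlseq as q
from conftest import selfing_genotype_law, simulate_major_qtl_dataset


class TestSnpMap:
    def test_sites_sorted_unique_and_in_range(self):
        m = q.make_snp_map(8, 10_000_000, 1000, 1.0, seed=1)
        assert len(m.chromosomes) == 8
        assert m.n_sites == 8000
        for chrom, length in m.chromosomes:
            pos = m.positions(chrom)
            assert len(pos) == 1000
            assert (np.diff(pos) > 0).all()
            assert pos.min() >= 1 and pos.max() <= length

    def test_empty_map_is_valid(self):
        m = q.make_snp_map(1, 10_000_000, 0, 1.0, seed=5)
        assert m.n_sites == 0

    def test_same_seed_identical(self):
        a = q.make_snp_map(2, 1_000_000, 50, 1.0, seed=9)
        b = q.make_snp_map(2, 1_000_000, 50, 1.0, seed=9)
        pd.testing.assert_frame_equal(a.sites, b.sites)

    def test_biallelic_parent_difference(self):
        m = q.make_snp_map(1, 100_000, 200, 1.0, seed=3)
        assert (m.sites["ref"] != m.sites["alt"]).all()

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="chrom_length_bp"):
            q.make_snp_map(1, 0, 10, 1.0, seed=1)


class TestBreedF4:
    def test_population_size_and_codes(self):
        m = q.make_snp_map(1, 1_000_000, 100, 1.0, seed=2)
        geno = q.breed_f4(m, 221, seed=3)
        assert geno.n_individuals == 221
        assert set(np.unique(geno.dosage)) <= {0, 1, 2}

    def test_no_recombination_chromosomes_constant_with_f4_proportions(self):
        """With zero genetic length every chromosome is inherited whole and
        the 7:2:7 F4 single-locus law applies to whole chromosomes."""
        m = q.make_snp_map(1, 1_000_000, 30, 0.0, seed=4)
        geno = q.breed_f4(m, 2000, seed=5)
        # each individual is uniform across the chromosome
        assert (geno.dosage == geno.dosage[:, :1]).all()
        law = selfing_genotype_law(3)
        assert law == pytest.approx([7 / 16, 1 / 8, 7 / 16])
        het = (geno.dosage[:, 0] == 1).mean()
        se = np.sqrt(law[1] * (1 - law[1]) / 2000)
        assert abs(het - law[1]) <= 3 * se

    def test_heterozygote_frequency_matches_markov_chain(self):
        """Pooled over >=10^4 independent individual-site draws the F4
        heterozygote fraction sits within 3 binomial SE of 1/8."""
        m = q.make_snp_map(1, 1_000_000, 400, 1e6, seed=6)  # unlinked sites
        geno = q.breed_f4(m, 50, seed=7)
        draws = geno.dosage.size
        assert draws >= 10_000
        expected = selfing_genotype_law(3)[1]
        het = (geno.dosage == 1).mean()
        se = np.sqrt(expected * (1 - expected) / draws)
        assert abs(het - expected) <= 3 * se

    def test_determinism(self):
        m = q.make_snp_map(2, 500_000, 40, 2.0, seed=8)
        a = q.breed_f4(m, 30, seed=9)
        b = q.breed_f4(m, 30, seed=9)
        assert (a.dosage == b.dosage).all()

    def test_bad_population_size_rejected(self):
        m = q.make_snp_map(1, 1_000_000, 10, 1.0, seed=1)
        with pytest.raises(ValueError, match="n_individuals"):
            q.breed_f4(m, 0, seed=1)


class TestPhenotypes:
    @pytest.fixture(scope="class")
    def geno(self):
        m = q.make_snp_map(1, 1_000_000, 50, 1.0, seed=20)
        return q.breed_f4(m, 200, seed=21)

    def test_noise_free_limit_hits_parental_means(self, geno):
        """At H2=1 with no dominance the genotype means are exactly the
        parental values 8.9 and 30.1 g (midparent 19.5 for heterozygotes)."""
        pos = int(geno.snp_map.positions("Ca1")[0])
        qtl = q.QtlSpec("Ca1", pos, h2=1.0)
        pheno = q.simulate_phenotypes(geno, qtl, n_environments=1, n_replicates=1,
                                      env_sd=0.0, seed=22)
        means = pheno.set_index("individual")["value"]
        dos = dict(zip(geno.individuals, geno.dosage[:, 0]))
        for ind, val in means.items():
            expected = {0: 8.9, 1: 19.5, 2: 30.1}[dos[ind]]
            assert val == pytest.approx(expected)

    def test_zero_heritability_rejected(self, geno):
        pos = int(geno.snp_map.positions("Ca1")[0])
        with pytest.raises(ValueError, match="h2"):
            q.simulate_phenotypes(geno, q.QtlSpec("Ca1", pos, h2=0.0), seed=1)

    def test_every_individual_environment_replicated(self, geno):
        pos = int(geno.snp_map.positions("Ca1")[0])
        pheno = q.simulate_phenotypes(geno, q.QtlSpec("Ca1", pos, h2=0.8),
                                      n_environments=3, n_replicates=2, seed=23)
        counts = pheno.groupby(["individual", "environment"]).size()
        assert (counts == 2).all()
        assert np.isfinite(pheno["value"]).all()


class TestSelectBulks:
    def test_half_split_partitions_population(self):
        m = q.make_snp_map(1, 1_000_000, 20, 1.0, seed=30)
        geno = q.breed_f4(m, 40, seed=31)
        pos = int(geno.snp_map.positions("Ca1")[0])
        pheno = q.simulate_phenotypes(geno, q.QtlSpec("Ca1", pos, h2=0.9), seed=32)
        bulks = q.select_bulks(pheno, geno, k=20)
        assert sorted(bulks.lsb + bulks.hsb) == sorted(geno.individuals)

    def test_full_penetrance_bulks_are_homozygous_at_causal(self):
        """With H2=1 phenotype ranking equals genotype ranking, so both
        tails are pure homozygotes at the causal site (brute-force check
        against the simulated tables)."""
        data = simulate_major_qtl_dataset(n_sites=200, n_individuals=150)
        geno, causal = data["geno"], data["causal"]
        j = geno.snp_map.site_index("Ca1", causal)
        dose = dict(zip(geno.individuals, geno.dosage[:, j]))
        assert all(dose[i] == 2 for i in data["bulks"].hsb)
        assert all(dose[i] == 0 for i in data["bulks"].lsb)
        # brute force: the k lowest/highest phenotype means among eligibles
        means = data["pheno"].groupby("individual")["value"].mean()
        eligible = [i for i in geno.individuals if dose[i] != 1]
        ranked = sorted(eligible, key=lambda i: (means[i], i))
        assert data["bulks"].lsb == ranked[:10]
        assert sorted(data["bulks"].hsb) == sorted(ranked[-10:])

    def test_too_large_bulk_rejected(self):
        m = q.make_snp_map(1, 1_000_000, 10, 1.0, seed=33)
        geno = q.breed_f4(m, 10, seed=34)
        pos = int(geno.snp_map.positions("Ca1")[0])
        pheno = q.simulate_phenotypes(geno, q.QtlSpec("Ca1", pos, h2=0.9), seed=35)
        with pytest.raises(ValueError, match="2k"):
            q.select_bulks(pheno, geno, k=6)


class TestSequenceBulks:
    def test_reads_conserved_and_deterministic(self):
        data = simulate_major_qtl_dataset(n_sites=300, n_individuals=60)
        counts = data["counts"]
        for s in ("lsb", "hsb", "low_parent", "high_parent"):
            total = counts[f"{s}_ref"] + counts[f"{s}_alt"]
            assert (total >= 1).all()
        again = q.sequence_bulks(
            data["geno"], data["bulks"], 30.0, 0.005, seed=14
        )
        pd.testing.assert_frame_equal(counts, again)

    def test_pure_bulk_constant_depth_no_error_gives_index_one(self):
        """All bulk members HH at a site, error 0, forced depth 20: all 20
        reads carry the high allele."""
        m = q.make_snp_map(1, 1_000_000, 50, 0.0, seed=40)
        geno = q.breed_f4(m, 30, seed=41)
        hh = [i for i, d in zip(geno.individuals, geno.dosage[:, 0]) if d == 2]
        ll = [i for i, d in zip(geno.individuals, geno.dosage[:, 0]) if d == 0]
        bulks = q.BulkSets(lsb=ll[:3], hsb=hh[:3])
        counts = q.sequence_bulks(geno, bulks, 20.0, 0.0, seed=42,
                                  depth_model="constant")
        high_is_ref = m.sites["high_is_ref"].to_numpy()
        hsb_high = np.where(high_is_ref, counts["hsb_ref"], counts["hsb_alt"])
        assert (hsb_high == 20).all()
        lsb_high = np.where(high_is_ref, counts["lsb_ref"], counts["lsb_alt"])
        assert (lsb_high == 0).all()

    def test_balanced_bulk_mean_frequency_half(self):
        """A 5 HH + 5 LL bulk has true high-allele frequency 0.5; the
        Monte-Carlo mean over 10,000 unlinked sites stays within 3 SE."""
        m = q.make_snp_map(1, 1_000_000, 10_000, 0.0, seed=43)
        geno = q.breed_f4(m, 80, seed=44)
        hh = [i for i, d in zip(geno.individuals, geno.dosage[:, 0]) if d == 2]
        ll = [i for i, d in zip(geno.individuals, geno.dosage[:, 0]) if d == 0]
        bulks = q.BulkSets(lsb=(hh[:5] + ll[:5]), hsb=(hh[5:10] + ll[5:10]))
        counts = q.sequence_bulks(geno, bulks, 20.0, 0.0, seed=45,
                                  depth_model="constant")
        high_is_ref = m.sites["high_is_ref"].to_numpy()
        frac = np.where(high_is_ref, counts["hsb_ref"], counts["hsb_alt"]) / 20.0
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.5) <= 3 * se

    def test_empty_bulk_rejected(self):
        with pytest.raises(ValueError):
            q.BulkSets(lsb=[], hsb=["a"])

    def test_bad_error_rate_rejected(self):
        data = simulate_major_qtl_dataset(n_sites=20, n_individuals=40)
        with pytest.raises(ValueError, match="error_rate"):
            q.sequence_bulks(data["geno"], data["bulks"], 10.0, 0.6, seed=1)


class TestGenotypeIo:
    def test_genotype_tsv_round_trip(self, tmp_path):
        m = q.make_snp_map(2, 500_000, 25, 1.0, seed=50)
        geno = q.breed_f4(m, 15, seed=51)
        path = tmp_path / "geno.tsv"
        geno.to_tsv(path)
        back = q.simdata.read_genotypes_tsv(path)
        assert back.individuals == geno.individuals
        assert (back.dosage == geno.dosage).all()
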