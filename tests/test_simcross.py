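"""Synthetic-data generator: meiosis, trait architectures, field designs."""

import numpy as np
import pandas as pd
import pytest

from vinegp import simcross as sc
from tests.conftest import stack_crosses


class TestFounders:
    def test_deterministic_and_shaped(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=1, snps_per_chromosome=10, seed=1)
        a = sc.simulate_founders(cfg)
        b = sc.simulate_founders(cfg)
        assert a.haplotypes.shape == (2, 2, 10)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_array_equal(a.allele_freq, b.allele_freq)

    def test_degenerate_maf_interval(self):
        cfg = sc.SimConfig(founder_maf_range=(0.5, 0.5), n_chromosomes=1,
                           snps_per_chromosome=20, seed=2)
        f = sc.simulate_founders(cfg)
        assert np.all(f.allele_freq == 0.5)

    def test_frequencies_within_range(self):
        cfg = sc.SimConfig(n_chromosomes=10, snps_per_chromosome=1000,
                           founder_maf_range=(0.05, 0.5), seed=3)
        f = sc.simulate_founders(cfg)
        assert f.allele_freq.min() >= 0.05 and f.allele_freq.max() <= 0.5

    def test_map_strictly_increasing(self, founders):
        for _, grp in founders.markers.groupby("chrom", sort=False):
            assert np.all(np.diff(grp["cm"].to_numpy()) > 0)
            assert np.all(np.diff(grp["pos"].to_numpy()) > 0)

    @pytest.mark.parametrize("bad", [
        dict(n_founders=0), dict(map_length_cM=0.0),
        dict(founder_maf_range=(0.3, 0.1)), dict(founder_maf_range=(0.0, 0.5)),
    ])
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            sc.SimConfig(**bad)


class TestCross:
    def test_unknown_parent(self, founders):
        with pytest.raises(KeyError):
            sc.simulate_cross(founders, "P1", "nope", 5, seed=0)

    def test_no_recombination_gives_parental_haplotypes(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=1, snps_per_chromosome=30,
                           map_length_cM=1e-9, seed=4)
        f = sc.simulate_founders(cfg)
        fam = sc.simulate_cross(f, "P1", "P2", 40, seed=5)
        haps = {tuple(f.haplotypes[i, j]) for i in range(2) for j in range(2)}
        for k in range(40):
            d = fam.dosages[k].astype(int)
            # dosage must decompose into one haplotype from each parent
            assert any(
                tuple(d - np.array(h1)) in {tuple(f.haplotypes[1, j]) for j in range(2)}
                for h1 in [f.haplotypes[0, 0], f.haplotypes[0, 1]]
            ), f"offspring {k} not a sum of parental haplotypes"

    def test_mendelian_fixed_locus(self, founders):
        f = founders
        # force both parents homozygous reference at the first SNP
        hap = f.haplotypes.copy()
        hap[:, :, 0] = 0
        f2 = sc.FounderSet(hap, f.markers, f.founder_ids, f.allele_freq, f.map_length_cM)
        fam = sc.simulate_cross(f2, "P1", "P2", 60, seed=6)
        assert np.all(fam.dosages[:, 0] == 0)

    def test_backcross_segregation_ratio(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=1, snps_per_chromosome=5, seed=7)
        f = sc.simulate_founders(cfg)
        hap = f.haplotypes.copy()
        hap[0, 0, :] = 1  # parent A heterozygous everywhere
        hap[0, 1, :] = 0
        hap[1, :, :] = 0  # parent B homozygous 0
        f2 = sc.FounderSet(hap, f.markers, f.founder_ids, f.allele_freq, f.map_length_cM)
        fam = sc.simulate_cross(f2, "P1", "P2", 10000, seed=8)
        frac = (fam.dosages == 1).mean(axis=0)
        assert np.all(np.abs(frac - 0.5) < 0.02)

    def test_mendelian_consistency_random_crosses(self, founders):
        fam = sc.simulate_cross(founders, "P2", "P5", 80, seed=9)
        pa = founders.dosages()[founders.founder_ids.index("P2")]
        pb = founders.dosages()[founders.founder_ids.index("P5")]
        for j in range(fam.n_markers):
            reach = {
                a + b
                for a in ({0} if pa[j] == 0 else {1} if pa[j] == 2 else {0, 1})
                for b in ({0} if pb[j] == 0 else {1} if pb[j] == 2 else {0, 1})
            }
            assert set(np.unique(fam.dosages[:, j])) <= reach

    def test_haldane_linkage_decay(self):
        """Recombination fraction between loci matches r = (1-exp(-2d/100))/2."""
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=1, snps_per_chromosome=21,
                           map_length_cM=100.0, seed=10)
        f = sc.simulate_founders(cfg)
        hap = f.haplotypes.copy()
        hap[0, 0, :] = 1  # parent A doubly heterozygous in coupling
        hap[0, 1, :] = 0
        hap[1, :, :] = 0  # parent B homozygous: offspring dosage = A's gamete
        f2 = sc.FounderSet(hap, f.markers, f.founder_ids, f.allele_freq, f.map_length_cM)
        fam = sc.simulate_cross(f2, "P1", "P2", 10000, seed=11)
        gametes = fam.dosages  # 0/1 = which haplotype of A
        cm = f.markers["cm"].to_numpy()
        for j, k in [(0, 2), (0, 6), (0, 12), (0, 20), (5, 15)]:
            d = cm[k] - cm[j]
            r_expect = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
            r_obs = np.mean(gametes[:, j] != gametes[:, k])
            se = np.sqrt(r_expect * (1 - r_expect) / 10000)
            assert abs(r_obs - r_expect) < 4 * se, (d, r_obs, r_expect)


class TestTrait:
    def test_zero_heritability_constant(self, multi_cross):
        arch = sc.TraitArchitecture(target_h2=0.0, n_qtl=50)
        tt = sc.simulate_trait(multi_cross, arch, seed=1)
        assert np.all(tt.genotypic_values == 0)

    def test_single_qtl_few_levels(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=1, target_h2=0.5, qtl_effect_distribution="equal")
        tt = sc.simulate_trait(multi_cross, arch, seed=2)
        for _, grp in tt.values.groupby("cross"):
            assert grp["g"].nunique() <= 3

    def test_inconsistent_h2_residual(self):
        with pytest.raises(ValueError):
            sc.TraitArchitecture(target_h2=1.0, residual_var=1.0)

    def test_realized_h2_matches_target(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=100, target_h2=0.5, residual_var=1.0)
        h2s = [
            sc.simulate_trait(multi_cross, arch, seed=s).realized_h2
            for s in range(20)
        ]
        assert abs(np.mean(h2s) - 0.5) < 0.05

    def test_cross_variance_fraction(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=100, target_h2=0.5,
                                    cross_variance_fraction=0.4)
        fracs = []
        for s in range(10):
            tt = sc.simulate_trait(multi_cross, arch, seed=s)
            fracs.append(tt.components["sigma2_C"] / tt.components["sigma2_g"])
        assert abs(np.mean(fracs) - 0.4) < 0.1

    def test_too_many_qtl(self, multi_cross):
        with pytest.raises(ValueError):
            sc.simulate_trait(
                multi_cross, sc.TraitArchitecture(n_qtl=10**6), seed=0
            )


class TestPhenotypes:
    def _design(self, truth, reps=1, years=(2018,), rows=25, cols=25, controls=()):
        return {
            "years": list(years), "grid_rows": rows, "grid_cols": cols,
            "control_ids": list(controls), "control_reps": reps,
        }

    def test_noise_free_phenotype_equals_truth(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=50, target_h2=1.0, residual_var=0.0)
        tt = sc.simulate_trait(multi_cross, arch, seed=3)
        rec = sc.simulate_phenotypes(tt, self._design(tt), arch, seed=4)
        expect = tt.genotypic_values[rec["genotype"]].to_numpy() + arch.mean
        np.testing.assert_allclose(rec["value"].to_numpy(), expect)

    def test_control_replicates(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=50, target_h2=0.5)
        tt = sc.simulate_trait(multi_cross, arch, seed=5)
        ctrl = tt.values.index[0]
        rec = sc.simulate_phenotypes(
            tt, self._design(tt, reps=5, years=(2018, 2019), controls=[ctrl]),
            arch, seed=6,
        )
        per_year = rec[rec["genotype"] == ctrl].groupby("year").size()
        assert (per_year == 5).all()
        # each replicate occupies its own cell
        cells = rec[rec["genotype"] == ctrl][["row", "col"]].drop_duplicates()
        assert len(cells) == 5

    def test_grid_overflow(self, multi_cross):
        arch = sc.TraitArchitecture()
        tt = sc.simulate_trait(multi_cross, arch, seed=7)
        with pytest.raises(ValueError, match="grid"):
            sc.simulate_phenotypes(
                tt, self._design(tt, rows=3, cols=3), arch, seed=8
            )

    def test_year_variance_anova(self, multi_cross):
        """Year effects inject between-year variance recoverable by ANOVA."""
        arch = sc.TraitArchitecture(n_qtl=50, target_h2=0.5, year_var=4.0)
        diffs = []
        for s in range(30):
            tt = sc.simulate_trait(multi_cross, arch, seed=s)
            rec = sc.simulate_phenotypes(
                tt, self._design(tt, years=(1, 2)), arch, seed=1000 + s
            )
            ym = rec.groupby("year")["value"].mean()
            diffs.append(ym.loc[1] - ym.loc[2])
        # difference of two year effects: variance 2 * 4 (+ small residual part)
        assert 0.4 * 8 < np.var(diffs, ddof=1) < 2.2 * 8

    def test_determinism(self, multi_cross):
        arch = sc.TraitArchitecture(n_qtl=30, target_h2=0.4)
        tt = sc.simulate_trait(multi_cross, arch, seed=9)
        r1 = sc.simulate_phenotypes(tt, self._design(tt), arch, seed=10)
        r2 = sc.simulate_phenotypes(tt, self._design(tt), arch, seed=10)
        pd.testing.assert_frame_equal(r1, r2)


class TestBinaryTrait:
    def test_full_penetrance_deterministic(self, multi_cross):
        m = multi_cross.marker_ids[3]
        lab = sc.simulate_binary_trait(multi_cross, m, 1.0, seed=1)
        d = multi_cross.dosages[:, 3]
        np.testing.assert_array_equal(lab.to_numpy(), (d > 0).astype(int))

    def test_half_penetrance_independent(self, multi_cross):
        m = multi_cross.marker_ids[3]
        lab = sc.simulate_binary_trait(multi_cross, m, 0.5, seed=2)
        d = multi_cross.dosages[:, 3]
        # agreement with carrier status should be ~50%
        agree = np.mean(lab.to_numpy() == (d > 0))
        assert abs(agree - 0.5) < 0.08

    def test_penetrance_agreement(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=1, snps_per_chromosome=10, seed=3)
        f = sc.simulate_founders(cfg)
        fam = sc.simulate_cross(f, "P1", "P2", 500, seed=4)
        m = fam.marker_ids[0]
        lab = sc.simulate_binary_trait(fam, m, 0.95, seed=5)
        agree = np.mean(lab.to_numpy() == (fam.dosages[:, 0] > 0))
        assert abs(agree - 0.95) < 0.03

    def test_invalid_penetrance(self, multi_cross):
        with pytest.raises(ValueError):
            sc.simulate_binary_trait(multi_cross, multi_cross.marker_ids[0], 1.5)


class TestDegrade:
    def test_rate_zero_identity(self, multi_cross):
        out = sc.degrade_genotypes(multi_cross, 0.0, seed=1)
        np.testing.assert_array_equal(out.dosages, multi_cross.dosages)

    def test_rate_one_all_missing(self, multi_cross):
        out = sc.degrade_genotypes(multi_cross, 1.0, seed=2)
        assert np.isnan(out.dosages).all()

    def test_intermediate_rate(self):
        cfg = sc.SimConfig(n_founders=2, n_chromosomes=2, snps_per_chromosome=500, seed=5)
        f = sc.simulate_founders(cfg)
        fam = sc.simulate_cross(f, "P1", "P2", 100, seed=6)
        out = sc.degrade_genotypes(fam, 0.05, seed=7)
        assert abs(np.isnan(out.dosages).mean() - 0.05) < 0.005

    def test_invalid_rate(self, multi_cross):
        with pytest.raises(ValueError):
            sc.degrade_genotypes(multi_cross, 1.5, seed=0)


class TestProgram:
    def test_program_structure(self, small_program):
        g = small_program.genotypes
        sets = g.individuals["set"]
        assert (sets == "parent").sum() == 6
        assert (sets == "TS").sum() == 140 and (sets == "VS").sum() == 60
        ph = small_program.phenotypes
        assert set(ph["trait"].unique()) == {"acidity", "berry_weight", "sugar"}
        # VS individuals are never phenotyped
        vs_ids = set(g.individual_ids[sets == "VS"])
        assert not (set(ph["genotype"]) & vs_ids)
        assert small_program.binary_labels is not None

    def test_program_deterministic(self, small_program):
        cfg = sc.SimConfig(n_founders=6, n_chromosomes=5, snps_per_chromosome=60, seed=11)
        again = sc.simulate_program(
            cfg,
            [
                {"parent_a": "P1", "parent_b": "P4", "n_ts": 35, "n_vs": 15},
                {"parent_a": "P1", "parent_b": "P5", "n_ts": 35, "n_vs": 15},
                {"parent_a": "P2", "parent_b": "P4", "n_ts": 35, "n_vs": 15},
                {"parent_a": "P2", "parent_b": "P6", "n_ts": 35, "n_vs": 15},
            ],
            [
                sc.TraitArchitecture(
                    name="acidity", n_qtl=120, target_h2=0.6,
                    cross_variance_fraction=0.3, spatial_row_var=0.1,
                    spatial_col_var=0.1, year_var=0.3,
                ),
                sc.TraitArchitecture(
                    name="berry_weight", n_qtl=20, target_h2=0.4,
                    cross_variance_fraction=0.2, year_var=0.2,
                ),
                sc.TraitArchitecture(
                    name="sugar", n_qtl=80, target_h2=0.3,
                    cross_variance_fraction=0.2,
                ),
            ],
            years=[2018, 2019], grid_rows=15, grid_cols=10,
            control_parents=["P1", "P2"], control_reps=5,
            missing_rate=0.03, binary_penetrance=0.95, seed=11,
        )
        np.testing.assert_array_equal(
            np.nan_to_num(again.genotypes.dosages, nan=-1),
            np.nan_to_num(small_program.genotypes.dosages, nan=-1),
        )
        pd.testing.assert_frame_equal(again.phenotypes, small_program.phenotypes)
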