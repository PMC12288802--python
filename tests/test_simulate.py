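"""Generator behaviour: lake chemistry, annotation geometry, Balding-Nichols
drift, planted ecotype divergence, delta and Hudson FST utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import humiclink as h
from humiclink.simulate import _assign_categories, simulate_samples
from humiclink.types import GenotypeMatrix


class TestSimulateLakes:
    def test_chemistry_ranges_disjoint_by_ecotype(self):
        lakes = h.simulate_lakes(8, 8, seed=1)
        assert len(lakes) == 16
        humic = [l for l in lakes if l.ecotype == "humic"]
        clear = [l for l in lakes if l.ecotype == "clear"]
        assert len(humic) == len(clear) == 8
        assert all(172.5 <= l.colour <= 752.5 for l in humic)
        assert all(15.0 <= l.colour <= 30.0 for l in clear)
        assert all(17.41 <= l.doc <= 66.10 for l in humic)
        assert all(5.27 <= l.doc <= 16.78 for l in clear)
        assert all(57.5 <= l.latitude <= 59.5 for l in lakes)

    def test_empty_and_deterministic(self):
        assert h.simulate_lakes(0, 0, seed=5) == []
        assert h.simulate_lakes(3, 2, seed=7) == h.simulate_lakes(3, 2, seed=7)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            h.simulate_lakes(-1, 8, seed=0)


class TestSimulateAnnotation:
    def test_category_coordinate_arithmetic(self):
        # one + strand gene on [1000, 2000] with 5 kb flanks
        rng = np.random.default_rng(0)
        cats = _assign_categories(
            np.array([1500, 500, 9000]),
            np.array([1000]), np.array([2000]), np.array(["+"]),
            flank=5000, probs={"intron": 1.0}, rng=rng,
        )
        assert cats[0] == "intron"  # inside the gene
        assert cats[1] == "5k-upstream"  # 500 bp before the start of a + gene
        assert cats[2] == "intergenic"  # 7 kb past the end

    def test_minus_strand_flank_labels(self):
        rng = np.random.default_rng(0)
        cats = _assign_categories(
            np.array([500, 2500]),
            np.array([1000]), np.array([2000]), np.array(["-"]),
            flank=5000, probs={"intron": 1.0}, rng=rng,
        )
        assert cats == ["5k-downstream", "5k-upstream"]

    def test_genes_non_overlapping_and_within_bounds(self, small_ds):
        for _, g in small_ds.genes.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"] <= g["end"]).all()
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()
            assert g["end"].max() <= small_ds.config.chrom_length_bp

    def test_zero_snps_allowed(self):
        cfg = h.SimulationConfig(n_genes=0, n_snps=0, n_chromosomes=1,
                                 chrom_length_bp=100_000, tissues=("gill",))
        genes, snps = h.simulate_annotation(cfg)
        assert genes.empty and snps.empty

    def test_capacity_error(self):
        cfg = h.SimulationConfig(
            n_genes=100, n_snps=100, n_chromosomes=1, chrom_length_bp=50_000,
            gene_length_range=(2_000, 2_000), tissues=("gill",),
        )
        with pytest.raises(ValueError, match="capacity"):
            h.simulate_annotation(cfg)

    def test_in_gene_category_histogram_matches_probs(self):
        cfg = h.SimulationConfig(
            n_genes=10, n_snps=4000, n_chromosomes=1, chrom_length_bp=400_000,
            gene_length_range=(20_000, 30_000), tissues=("gill",), seed=3,
        )
        _, snps = h.simulate_annotation(cfg)
        in_gene = snps[snps["category"].isin(cfg.category_probs)]
        n = len(in_gene)
        assert n > 500
        for cat, p in cfg.category_probs.items():
            k = int((in_gene["category"] == cat).sum())
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi, f"{cat}: {k} outside 99% CI [{lo}, {hi}]"


class TestSimulateGenotypes:
    def test_dosage_domain_and_determinism(self, small_ds, small_cfg):
        assert set(np.unique(small_ds.genotypes.dosages)) <= {0, 1, 2}
        again = h.simulate_dataset(small_cfg)
        assert np.array_equal(again.genotypes.dosages, small_ds.genotypes.dosages)
        assert again.snps["outlier"].equals(small_ds.snps["outlier"])

    def test_no_drift_limit_recovers_ancestral_frequency(self):
        cfg = h.SimulationConfig(
            n_humic_lakes=1, n_clear_lakes=0, n_ind_per_lake=50, drift_F=0.0,
            outlier_fraction=0.0, n_genes=10, n_snps=5000, n_chromosomes=1,
            chrom_length_bp=1_000_000, tissues=("gill",), seed=4,
        )
        lakes = h.simulate_lakes(1, 0, cfg.seed)
        genes, snps = h.simulate_annotation(cfg)
        sg = h.simulate_genotypes(cfg, lakes, snps)
        # with F = 0 the lake frequency equals the ancestral frequency exactly
        assert np.allclose(sg.lake_freqs.to_numpy()[0], sg.ancestral_freq)
        realized = sg.genotypes.alt_freq()
        n_alleles = 2 * 50
        se = np.sqrt(sg.ancestral_freq * (1 - sg.ancestral_freq) / n_alleles)
        z = (realized - sg.ancestral_freq) / se
        assert np.mean(np.abs(z) < 3.5) > 0.995

    def test_extreme_drift_rejected(self):
        with pytest.raises(ValueError):
            h.SimulationConfig(drift_F=1.0)

    def test_planted_outlier_delta(self):
        cfg = h.SimulationConfig(
            n_genes=20, n_snps=10_000, n_chromosomes=2, chrom_length_bp=2_500_000,
            outlier_delta=0.4, outlier_fraction=0.05, tissues=("gill",), seed=9,
        )
        lakes = h.simulate_lakes(8, 8, cfg.seed)
        _, snps = h.simulate_annotation(cfg)
        sg = h.simulate_genotypes(cfg, lakes, snps)
        delta = h.compute_delta(sg.lake_freqs, [l.ecotype for l in lakes])
        out = sg.snps["outlier"].to_numpy()
        assert abs(delta[out].mean() - 0.4) < 0.05
        assert delta[out].mean() > delta[~out].mean()

    def test_fst_increases_with_drift(self):
        means = []
        for F in (0.05, 0.1, 0.2, 0.3):
            cfg = h.SimulationConfig(
                n_humic_lakes=2, n_clear_lakes=0, n_ind_per_lake=20, drift_F=F,
                outlier_fraction=0.0, n_genes=10, n_snps=4000, n_chromosomes=1,
                chrom_length_bp=1_000_000, tissues=("gill",), seed=6,
            )
            lakes = h.simulate_lakes(2, 0, cfg.seed)
            _, snps = h.simulate_annotation(cfg)
            sg = h.simulate_genotypes(cfg, lakes, snps)
            samples = simulate_samples(cfg, lakes)
            fst = h.hudson_fst(sg.genotypes, samples["lake"].to_numpy())
            means.append(fst.iloc[0, 1])
        assert all(a < b for a, b in zip(means, means[1:]))


class TestComputeDelta:
    def test_pair_mean_brute_force(self):
        freqs = np.array([[0.8], [0.6], [0.2], [0.4]])
        eco = ["humic", "humic", "clear", "clear"]
        # all 4 pairs: |0.8-0.2|, |0.8-0.4|, |0.6-0.2|, |0.6-0.4|
        expected = np.mean([0.6, 0.4, 0.4, 0.2])
        assert h.compute_delta(freqs, eco)[0] == pytest.approx(expected)
        assert expected == pytest.approx(0.4)

    def test_extremes(self):
        freqs = np.array([[1.0], [1.0], [0.0], [0.0]])
        eco = ["humic", "humic", "clear", "clear"]
        assert h.compute_delta(freqs, eco)[0] == pytest.approx(1.0)
        same = np.full((4, 3), 0.37)
        assert np.allclose(h.compute_delta(same, eco), 0.0)

    def test_ecotype_mean_convention(self):
        freqs = np.array([[0.9], [0.1], [0.5], [0.5]])
        eco = ["humic", "humic", "clear", "clear"]
        assert h.compute_delta(freqs, eco, method="ecotype_mean")[0] == pytest.approx(0.0)

    def test_missing_ecotype_rejected(self):
        with pytest.raises(ValueError):
            h.compute_delta(np.array([[0.5], [0.5]]), ["humic", "humic"])


class TestFlagOutliers:
    def test_threshold_arithmetic(self):
        delta = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        # mean 0.2, sd 0.447 -> threshold 1.318: nothing flagged
        assert not h.flag_outliers_by_delta(delta).any()

    def test_constant_vector_no_flags(self):
        assert not h.flag_outliers_by_delta(np.full(50, 0.3)).any()

    def test_single_extreme_flagged(self):
        rng = np.random.default_rng(0)
        delta = np.abs(rng.normal(0, 0.01, size=100))
        delta[17] = 10.0
        flags = h.flag_outliers_by_delta(delta)
        assert flags[17] and flags.sum() == 1


def _gm_from_dosages(dosages):
    dosages = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=[f"i{j}" for j in range(dosages.shape[0])],
        snp_ids=[f"s{j}" for j in range(dosages.shape[1])],
        dosages=dosages,
    )


class TestHudsonFst:
    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(20, 200))
        gm = _gm_from_dosages(np.vstack([block, block]))
        pops = ["a"] * 20 + ["b"] * 20
        fst = h.hudson_fst(gm, pops)
        # identical samples: frequencies equal, only the sampling correction remains
        assert fst.loc["a", "b"] < 0.0
        assert abs(fst.loc["a", "b"]) < 0.05
        assert fst.loc["a", "a"] == 0.0

    def test_fixed_differences_give_one(self):
        gm = _gm_from_dosages(np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)]))
        pops = ["a"] * 5 + ["b"] * 5
        assert h.hudson_fst(gm, pops).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_two_pop_oracle(self):
        # five SNPs with controlled allele counts in two pops of 5 diploids
        d1 = np.array([
            [2, 1, 0, 1, 2], [1, 1, 0, 0, 2], [2, 0, 1, 1, 1],
            [1, 2, 0, 1, 0], [0, 1, 1, 2, 1],
        ])
        d2 = np.array([
            [0, 2, 2, 1, 0], [1, 2, 1, 1, 1], [0, 1, 2, 2, 0],
            [0, 2, 2, 1, 0], [1, 1, 1, 2, 1],
        ])
        gm = _gm_from_dosages(np.vstack([d1, d2]))
        pops = ["a"] * 5 + ["b"] * 5
        # independent per-SNP hand computation, aggregated ratio-of-averages
        n1 = n2 = 10.0
        p1 = d1.sum(axis=0) / n1
        p2 = d2.sum(axis=0) / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        expected = num.sum() / den.sum()
        assert h.hudson_fst(gm, pops).loc["a", "b"] == pytest.approx(expected)

    def test_monomorphic_everywhere_is_nan_with_warning(self):
        gm = _gm_from_dosages(np.zeros((8, 5)))
        with pytest.warns(UserWarning, match="monomorphic"):
            fst = h.hudson_fst(gm, ["a"] * 4 + ["b"] * 4)
        assert np.isnan(fst.loc["a", "b"])


class TestSimulateExpression:
    def test_truth_tables_and_count_domain(self, power_ds):
        assert (power_ds.deg_truth["log2fc"].abs() == 2.0).all()
        assert (power_ds.eqtl_truth["beta"].abs() == 1.0).all()
        counts = power_ds.counts["gill"]
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind == "i"

    def test_planted_eqtl_snps_inside_cis_window(self, power_ds):
        genes = power_ds.genes.set_index("gene_id")
        snps = power_ds.snps.set_index("snp_id")
        w = power_ds.config.cis_window_bp
        for row in power_ds.eqtl_truth.itertuples():
            gene, snp = genes.loc[row.gene_id], snps.loc[row.snp_id]
            assert snp.chrom == gene.chrom
            assert gene.start - w <= snp.pos <= gene.end + w

    def test_outside_window_plant_rejected(self, power_ds):
        from humiclink.simulate import validate_planted_eqtls

        genes = power_ds.genes
        far_gene = genes.iloc[0]
        snps = power_ds.snps
        far_snp = snps.loc[
            (snps["chrom"] != far_gene["chrom"]), "snp_id"
        ].iloc[0]
        bad = pd.DataFrame([{"gene_id": far_gene["gene_id"], "snp_id": far_snp, "beta": 1.0}])
        with pytest.raises(ValueError, match="cis"):
            validate_planted_eqtls(genes, snps, bad, 50_000)
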