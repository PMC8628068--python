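"""Synthetic competition experiments, plasmid records and depth tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import plasmidcost as pc
from plasmidcost.simulate import (
    WILDTYPE,
    derive_seed,
    read_competition_csv,
    write_competition_csv,
)


class TestSimulateCompetition:
    @given(w=st.floats(0.3, 2.0, exclude_min=True))
    def test_noise_free_round_trip(self, w, small_config):
        """Latent counts invert exactly through the estimator."""
        rec = pc.simulate_competition(w, small_config, seed=1)
        est = pc.relative_fitness(rec.latent_record())
        assert est.w == pytest.approx(w, abs=1e-12)

    def test_closed_form_expansion(self, small_config):
        # fold-expansions are G and G**w, so W = log(400**0.9)/log(400) = 0.9
        rec = pc.simulate_competition(0.9, small_config, seed=5)
        assert rec.latent_final_gfp_pos / rec.latent_initial_gfp_pos == pytest.approx(400)
        assert rec.latent_final_gfp_neg / rec.latent_initial_gfp_neg == pytest.approx(
            400**0.9
        )

    def test_invalid_parameters(self, small_config):
        with pytest.raises(ValueError):
            pc.simulate_competition(0.0, small_config, seed=1)
        with pytest.raises(ValueError):
            pc.SimulationConfig.factorial({"p": 0.9}, {}, expansion_factor=1.0)

    def test_determinism(self, small_config):
        a = pc.simulate_competition(0.8, small_config, seed=11)
        b = pc.simulate_competition(0.8, small_config, seed=11)
        assert a == b

    def test_sampling_unbiased_in_proportion(self, small_config):
        """Mean sampled GFP- fraction matches the latent fraction (MC check)."""
        fracs = []
        latent_frac = None
        for seed in range(2000):
            rec = pc.simulate_competition(0.8, small_config, seed=seed)
            total = rec.n_final_gfp_neg + rec.n_final_gfp_pos
            fracs.append(rec.n_final_gfp_neg / total)
            latent_frac = rec.latent_final_gfp_neg / (
                rec.latent_final_gfp_neg + rec.latent_final_gfp_pos
            )
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - latent_frac) < 3 * se + 1e-12

    def test_growth_noise_perturbs_latent(self):
        cfg = pc.SimulationConfig.factorial(
            {"p": 0.9}, {}, growth_noise_sd=0.1, seed=0
        )
        recs = [pc.simulate_competition(1.0, cfg, seed=s) for s in range(20)]
        folds = {r.latent_final_gfp_neg / r.latent_initial_gfp_neg for r in recs}
        assert len(folds) == 20  # lognormal noise: all fold-expansions differ


class TestSimulateExperiment:
    def test_block_structure_and_counts(self, small_config):
        df = pc.simulate_experiment(small_config)
        # 2 plasmids + 1 mutation + 2 combinations = 5 non-WT genotypes x 6 reps
        non_wt = df[~(df["plasmid"].isna() & df["mutation"].isna())]
        wt = df[df["plasmid"].isna() & df["mutation"].isna()]
        assert len(non_wt) == 5 * 6
        assert len(wt) == 36
        combos = df[df["plasmid"].notna() & df["mutation"].notna()]
        assert len(combos) == 12

    def test_combination_fitness_is_product_plus_shift(self):
        cfg = pc.SimulationConfig.factorial(
            {"pA": 0.9}, {"m1": 0.8}, epistasis_shift={("pA", "m1"): 0.1}, seed=3
        )
        assert cfg.true_fitness(("pA", "m1")) == pytest.approx(0.9 * 0.8 + 0.1)
        assert cfg.true_fitness(("pA", None)) == 0.9
        assert cfg.true_fitness(WILDTYPE) == 1.0

    def test_unknown_shift_genotype_rejected(self):
        with pytest.raises(ValueError, match="not in design"):
            pc.SimulationConfig.factorial(
                {"pA": 0.9}, {"m1": 0.8}, epistasis_shift={("pX", "m1"): 0.1}
            )

    def test_wildtype_fitness_fixed_at_one(self):
        with pytest.raises(ValueError, match="wild type"):
            pc.SimulationConfig(
                genotypes=(WILDTYPE,), true_w={WILDTYPE: 0.9}
            )

    def test_deterministic_and_order_independent_seeding(self, small_config):
        df1 = pc.simulate_experiment(small_config)
        df2 = pc.simulate_experiment(small_config)
        assert df1.equals(df2)
        # replicate streams depend only on (seed, genotype, replicate)
        assert derive_seed(42, ("pA", None), 3) == derive_seed(42, ("pA", None), 3)
        assert derive_seed(42, ("pA", None), 3) != derive_seed(42, ("pA", "m1"), 3)
        assert derive_seed(42, (None, None), 1) != derive_seed(43, (None, None), 1)

    def test_csv_round_trip_byte_identical(self, small_config, tmp_path):
        df = pc.simulate_experiment(small_config)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_competition_csv(df, p1, config=small_config)
        write_competition_csv(df, p2, config=small_config)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_competition_csv(p1)
        assert len(back) == len(df)
        np.testing.assert_allclose(
            back["n_final_gfp_neg"].to_numpy(), df["n_final_gfp_neg"].to_numpy()
        )
        assert back["plasmid"].iloc[0] is None  # wild-type rows come back as None


class TestSimulatePlasmidRecord:
    def test_gc_target_hit(self, reference_table):
        rec = pc.simulate_plasmid_record(
            20_000, 0.5, n_orfs=6, codon_bias_strength=0.3, seed=9,
            table=reference_table,
        )
        gc = pc.gc_content(rec.seq)
        assert 49.0 <= gc <= 51.0
        assert len(rec.seq) == 20_000
        assert rec.annotations["topology"] == "circular"

    def test_orf_structure(self, reference_table):
        rec = pc.simulate_plasmid_record(
            15_000, 0.5, n_orfs=5, codon_bias_strength=0.5, seed=2,
            table=reference_table,
        )
        orfs = pc.extract_orfs(rec)
        assert len(orfs) == 5
        for _, start, end, strand, seq in orfs:
            s = str(seq)
            assert len(s) % 3 == 0
            assert s.startswith("ATG")
            assert s[-3:] in {"TAA", "TAG", "TGA"}
            assert strand in "+-"
            assert 1 <= start < end <= 15_000

    def test_full_bias_gives_cai_one(self, reference_table):
        rec = pc.simulate_plasmid_record(
            12_000, 0.5, n_orfs=4, codon_bias_strength=1.0, seed=7,
            table=reference_table,
        )
        for feat in pc.orf_features(rec, reference_table):
            assert feat.cai == 1.0

    def test_same_seed_identical(self, reference_table):
        kw = dict(length_bp=11_000, gc_fraction=0.55, n_orfs=3,
                  codon_bias_strength=0.4, table=reference_table)
        a = pc.simulate_plasmid_record(seed=123, **kw)
        b = pc.simulate_plasmid_record(seed=123, **kw)
        assert str(a.seq) == str(b.seq)
        assert [str(f.location) for f in a.features] == [
            str(f.location) for f in b.features
        ]

    def test_impossible_packing(self, reference_table):
        with pytest.raises(ValueError, match="pack"):
            pc.simulate_plasmid_record(
                2_000, 0.5, n_orfs=10, codon_bias_strength=0.5, seed=1,
                table=reference_table,
            )


class TestSimulateDepthTable:
    def test_exact_ratio_without_noise(self):
        tables = pc.simulate_depth_table(15.0, 100.0, noise_cv=0.0, seed=0)
        assert tables.plasmid.mean_depth == pytest.approx(1500.0)
        assert pc.copy_number_proxy(tables.plasmid, tables.chromosome) == pytest.approx(
            15.0
        )

    def test_copy_number_one(self):
        tables = pc.simulate_depth_table(1.0, 80.0, noise_cv=0.0, seed=0)
        assert pc.copy_number_proxy(tables.plasmid, tables.chromosome) == 1.0

    def test_noisy_ratio_unbiased(self):
        ratios = [
            pc.copy_number_proxy(t.plasmid, t.chromosome)
            for t in (
                pc.simulate_depth_table(5.0, 50.0, noise_cv=0.1, seed=s)
                for s in range(100)
            )
        ]
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 5.0) < 3 * se + 1e-9

    def test_tsv_round_trip(self, tmp_path):
        tables = pc.simulate_depth_table(3.0, 40.0, noise_cv=0.05, seed=4)
        path = tmp_path / "depth.tsv"
        pc.write_depth_table(tables, path)
        profiles = pc.read_depth_table(path)
        assert profiles["plasmid"].mean_depth == pytest.approx(
            tables.plasmid.mean_depth
        )
        assert profiles["chromosome"].n_positions == 5000
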