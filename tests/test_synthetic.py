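"""Generators: determinism, schema guarantees, and planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from adaptomics import dea, quant, screen, synthetic
from adaptomics.quant import TMT_CHANNELS
from adaptomics.synthetic import REFERENCE_CHANNEL


class TestPsmTables:
    def test_seed_determinism(self):
        t1, _ = synthetic.generate_psm_tables(n_genes=30, seed=5)
        t2, _ = synthetic.generate_psm_tables(n_genes=30, seed=5)
        for set_id in t1:
            pd.testing.assert_frame_equal(t1[set_id], t2[set_id])

    def test_different_seed_differs(self):
        t1, _ = synthetic.generate_psm_tables(n_genes=30, seed=5)
        t2, _ = synthetic.generate_psm_tables(n_genes=30, seed=6)
        assert not t1["set1"].equals(t2["set1"])

    def test_null_noise_free_rows_constant(self):
        tables, _ = synthetic.generate_psm_tables(
            n_genes=10, noise_sd=0.0, shared_rate=0.0, seed=1)
        for table in tables.values():
            log2 = np.log2(table[TMT_CHANNELS].to_numpy())
            assert np.ptp(log2, axis=1).max() < 1e-9

    def test_intensities_positive_and_unique_flagged(self):
        tables, _ = synthetic.generate_psm_tables(n_genes=20, seed=2)
        for table in tables.values():
            assert (table[TMT_CHANNELS].to_numpy() > 0).all()
            assert table.loc[table["unique"], "gene"].notna().all()

    def test_reference_channel_is_pool_of_sample_expectations(self):
        effects = {"G00000": {"siKD_gef48": 2.0}}
        tables, _ = synthetic.generate_psm_tables(
            n_genes=3, effects=effects, noise_sd=0.0, shared_rate=0.0, seed=3)
        designs = {d.set_id: d for d in synthetic.default_psm_designs()}
        # the pool mixes all 18 samples of both sets, so for the affected
        # gene it carries the mean intensity over every condition
        for set_id, table in tables.items():
            sub = table[table["gene"] == "G00000"]
            sample_chs = [c for c in TMT_CHANNELS if c != REFERENCE_CHANNEL]
            all_conds = [d.condition_of(ch) for d in designs.values() for ch in sample_chs]
            for _, row in sub.iterrows():
                base = np.log2(row[sample_chs].astype(float)).min()  # unaffected level
                expected = 2.0 ** base * np.mean([2.0 ** effects["G00000"].get(c, 0.0)
                                                  for c in all_conds])
                assert row[REFERENCE_CHANNEL] == pytest.approx(expected, rel=1e-9)

    def test_planted_effect_exact_after_quantification(self):
        effects = {"G00001": {"siKD_gef48": 1.0}}
        tables, _ = synthetic.generate_psm_tables(
            n_genes=20, effects=effects, noise_sd=0.0, shared_rate=0.0, seed=4)
        designs = {d.set_id: d for d in synthetic.default_psm_designs()}
        mat = quant.quantify(tables["set2"])
        mat.values.columns = [designs["set2"].channels[c] for c in mat.values.columns]
        g = mat.values.loc["G00001"]
        treated = [c for c in g.index if c.startswith("siKD_gef48")]
        control = [c for c in g.index if c.startswith("siKD_untreated")]
        assert g[treated].mean() - g[control].mean() == pytest.approx(1.0, abs=1e-9)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            synthetic.generate_psm_tables(n_genes=5, noise_sd=-0.1)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            synthetic.generate_psm_tables(n_genes=5, designs=[])


class TestCountMatrix:
    def test_seed_determinism(self):
        c1, _ = synthetic.generate_count_matrix(n_genes=50, seed=7)
        c2, _ = synthetic.generate_count_matrix(n_genes=50, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_dispersion_is_poisson(self):
        counts, _ = synthetic.generate_count_matrix(
            n_genes=3000, dispersion=0.0, mean_expression=100.0, seed=8)
        sub = counts.to_numpy()[:, :3]  # one condition, three replicates
        ratio = sub.var(axis=1, ddof=1).mean() / sub.mean(axis=1).mean()
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_counts_are_nonnegative_integers(self):
        counts, _ = synthetic.generate_count_matrix(n_genes=100, seed=9)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_doubled_lib_size_doubles_size_factor(self):
        lib = {"ctrl_1": 2.0}
        counts, _ = synthetic.generate_count_matrix(
            n_genes=4000, lib_sizes=lib, dispersion=0.02, seed=10)
        sf = dea.size_factors(counts)
        others = sf.drop("ctrl_1").mean()
        assert sf["ctrl_1"] / others == pytest.approx(2.0, rel=0.05)

    def test_planted_lfc_recorded_in_truth(self):
        spec = {"G00002": {"gef24": 1.5}}
        _, truth = synthetic.generate_count_matrix(n_genes=10, lfc_spec=spec, seed=11)
        assert truth.de_genes == spec

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            synthetic.generate_count_matrix(n_genes=5, dispersion=-1)


class TestScreenPlates:
    def test_seed_determinism(self):
        w1, t1 = synthetic.generate_screen_plates(n_compounds=20, seed=13)
        w2, t2 = synthetic.generate_screen_plates(n_compounds=20, seed=13)
        pd.testing.assert_frame_equal(w1, w2)
        assert t1.synergist_compounds == t2.synergist_compounds

    def test_each_arm_has_exactly_n_doses(self):
        wells, _ = synthetic.generate_screen_plates(n_compounds=10, n_doses=5, seed=14)
        drugged = wells[wells["control"] == "none"]
        assert (drugged.groupby(["compound", "arm"]).size() == 5).all()

    def test_control_wells_flagged(self):
        wells, _ = synthetic.generate_screen_plates(n_compounds=10, seed=14)
        assert set(wells["control"]) == {"none", "neg", "pos"}

    def test_doses_span_10000_fold_range(self):
        wells, _ = synthetic.generate_screen_plates(n_compounds=4, seed=15)
        doses = sorted(wells.loc[wells["control"] == "none", "conc_molar"].unique())
        assert doses[-1] / doses[0] == pytest.approx(1e4)

    def test_non_synergist_has_equal_arms(self):
        wells, truth = synthetic.generate_screen_plates(
            n_compounds=10, n_synergists=2, noise_sd=0.0, seed=16)
        others = set(wells["compound"]) - truth.synergist_compounds - {"DMSO", "BzCl"}
        comp = sorted(others)[0]
        sub = wells[wells["compound"] == comp]
        mono = sub[sub["arm"] == "mono"].sort_values("conc_molar")["signal"].to_numpy()
        combo = sub[sub["arm"] == "combo"].sort_values("conc_molar")["signal"].to_numpy()
        np.testing.assert_allclose(mono, combo)

    def test_noise_free_sdss_matches_closed_form_on_true_curves(self):
        wells, truth = synthetic.generate_screen_plates(
            n_compounds=30, n_synergists=3, noise_sd=0.0, seed=17)
        _, calls = screen.score_screen(wells)
        x_lo, x_hi = truth.extras["x_window"]
        for call in calls:
            if call.compound not in truth.synergist_compounds:
                continue
            expected = 0.0
            dss = {}
            for arm in ("mono", "combo"):
                a, d, b, c = truth.extras["curves"][(call.compound, arm)]
                curve = screen.FittedCurve(a, d, b, c, True, 0.0)
                dss[arm] = screen.compute_dss(curve, x_lo, x_hi).dss
            expected = dss["combo"] - dss["mono"]
            assert call.sdss == pytest.approx(expected, abs=0.05)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError, match="doses"):
            synthetic.generate_screen_plates(n_doses=1)
        with pytest.raises(ValueError, match="dilution"):
            synthetic.generate_screen_plates(dilution=1.0)
        with pytest.raises(ValueError, match="efficacy_shift"):
            synthetic.generate_screen_plates(n_compounds=20, n_synergists=5,
                                             efficacy_shift=80.0, seed=1)


class TestChipExperiments:
    UNIVERSE = [f"g{i}" for i in range(200)]
    CONSENSUS = {f"g{i}" for i in range(20)}

    def test_zero_background_recovers_exactly_consensus(self):
        ev, _ = synthetic.generate_chip_experiments(
            self.UNIVERSE, self.CONSENSUS, background_rate=0.0, seed=20)
        from adaptomics.integrate import consensus_chip_targets
        assert consensus_chip_targets(ev, 4) == {g.upper() for g in self.CONSENSUS}

    def test_full_background_passes_everything(self):
        ev, _ = synthetic.generate_chip_experiments(
            self.UNIVERSE, self.CONSENSUS, background_rate=1.0, seed=21)
        from adaptomics.integrate import consensus_chip_targets
        assert consensus_chip_targets(ev, 4) == {g.upper() for g in self.UNIVERSE}

    def test_intermediate_background_is_superset(self):
        ev, _ = synthetic.generate_chip_experiments(
            self.UNIVERSE, self.CONSENSUS, background_rate=0.3, seed=22)
        from adaptomics.integrate import consensus_chip_targets
        assert consensus_chip_targets(ev, 4) >= {g.upper() for g in self.CONSENSUS}

    def test_consensus_genes_in_at_least_min_experiments(self):
        ev, _ = synthetic.generate_chip_experiments(
            self.UNIVERSE, self.CONSENSUS, background_rate=0.1, seed=23)
        per_gene = ev.groupby("gene")["experiment_id"].nunique()
        assert (per_gene[sorted(self.CONSENSUS)] >= 4).all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="background_rate"):
            synthetic.generate_chip_experiments(self.UNIVERSE, self.CONSENSUS,
                                                background_rate=1.5)

    def test_consensus_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            synthetic.generate_chip_experiments(["a"], {"zzz"})


class TestDecoyScores:
    def test_one_target_one_decoy_per_gene(self):
        scored, _ = synthetic.generate_decoy_scores(n_genes=100, seed=30)
        per_gene = scored.groupby("gene")["is_decoy"].agg(["sum", "count"])
        assert (per_gene["count"] == 2).all() and (per_gene["sum"] == 1).all()

    def test_separated_scores_give_zero_q(self):
        scored, _ = synthetic.generate_decoy_scores(n_genes=50, target_shift=100.0, seed=31)
        out = quant.picked_protein_fdr(scored)
        assert (out.loc[~out["is_decoy"], "q_value"] == 0.0).all()

    def test_seed_determinism(self):
        s1, _ = synthetic.generate_decoy_scores(n_genes=40, seed=32)
        s2, _ = synthetic.generate_decoy_scores(n_genes=40, seed=32)
        pd.testing.assert_frame_equal(s1, s2)
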