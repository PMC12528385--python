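import numpy as np
import pandas as pd
import pytest

from sortmave import synthetic_data as sd
from sortmave.library_design import Region, VariantSpec, enumerate_possible_variants
from sortmave.scoring import score_assay


def _variants(n=60, seed=0):
    region = Region(28, 28 + n // 20)
    seq = sd.random_protein_sequence(len(region), seed=seed, pin_controls=False)
    return enumerate_possible_variants(region, seq)[:n]


class TestEffects:
    def test_synonymous_and_wt_effects_are_zero(self):
        variants = [VariantSpec(10, "G", "="), VariantSpec(11, "A", "=")]
        effects = sd.sample_true_effects(variants, seed=1)
        assert (effects[[c for c in effects if c.startswith("effect_")]] == 0).all().all()

    def test_degenerate_lof_mixture(self):
        cfg = sd.EffectConfig(lof_fraction=1.0, gof_fraction=0.0,
                              lof_range=(-3.0, -3.0))
        effects = sd.sample_true_effects(_variants(), cfg, seed=2)
        mis = effects[effects["klass"] == "missense"]
        assert (mis["effect_bind_insulin"] == -3.0).all()

    def test_default_fractions_within_binomial_error(self):
        region = Region(28, 227)
        seq = sd.random_protein_sequence(len(region), seed=3, pin_controls=False)
        variants = [v for v in enumerate_possible_variants(region, seq)
                    if v.klass == "missense"]
        effects = sd.sample_true_effects(variants, seed=3)
        n = len(effects)
        lof = (effects["effect_bind_insulin"] < 0).mean()
        gof = (effects["effect_bind_insulin"] > 0).mean()
        for observed, p in [(lof, 0.32), (gof, 0.07)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 4 * se

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            sd.EffectConfig(lof_fraction=0.7, gof_fraction=0.4)

    def test_stop_codons_depleted_in_abundance(self):
        variants = _variants()
        effects = sd.sample_true_effects(variants, seed=1)
        stops = effects["klass"] == "nonsense"
        assert stops.any()
        assert (effects.loc[stops, "abundance"] == 0.05).all()
        assert (effects.loc[~stops, "abundance"] == 1.0).all()


class TestControls:
    def _effects_with_controls(self):
        variants = _variants() + [
            VariantSpec(119, "A", "V"),
            VariantSpec(350, "S", "L"),
            VariantSpec(734, "D", "A"),
        ]
        effects = sd.sample_true_effects(variants, seed=4)
        return sd.plant_controls(effects)

    def test_d734a_expression_unaffected_but_binding_lost(self):
        effects = self._effects_with_controls().set_index("variant")
        assert effects.loc["D734A", "effect_bind_83_7"] == 0
        assert effects.loc["D734A", "effect_sig_83_14"] == 0
        assert effects.loc["D734A", "effect_bind_insulin"] < 0
        assert effects.loc["D734A", "effect_sig_insulin"] < 0

    def test_expression_loss_controls_low_everywhere(self):
        effects = self._effects_with_controls().set_index("variant")
        for vid in ("A119V", "S350L"):
            assert (effects.loc[vid, [f"effect_{a}" for a in sd.ASSAYS]] < 0).all()

    def test_missing_control_raises(self):
        effects = sd.sample_true_effects(_variants(), seed=4)
        with pytest.raises(KeyError):
            sd.plant_controls(effects)

    def test_unlisted_variants_untouched(self):
        effects = self._effects_with_controls()
        raw = sd.sample_true_effects(
            _variants() + [VariantSpec(119, "A", "V"), VariantSpec(350, "S", "L"),
                           VariantSpec(734, "D", "A")], seed=4)
        others = ~effects["variant"].isin(["A119V", "S350L", "D734A"])
        pd.testing.assert_frame_equal(effects[others], raw[others])


class TestSortSimulation:
    def _setup(self, effects_override=None, **sim_kwargs):
        variants = _variants(40, seed=6)
        effects = sd.sample_true_effects(variants, seed=6)
        if effects_override is not None:
            effects = effects_override(effects)
        bvmap = sd.build_barcode_variant_map(effects, 2, 0.3, seed=6)
        config = sd.SortSimConfig(seed=6, **sim_kwargs)
        return effects, bvmap, config

    def test_reads_conserved_per_bin(self):
        effects, bvmap, config = self._setup()
        counts = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
        sums = counts[["bin1", "bin2", "bin3", "bin4"]].sum()
        assert (sums == config.reads_per_bin).all()

    def test_identical_seed_reproduces_counts_exactly(self):
        effects, bvmap, config = self._setup()
        a = sd.simulate_sort_counts(effects, bvmap, config, "sig_insulin", 2)
        b = sd.simulate_sort_counts(effects, bvmap, config, "sig_insulin", 2)
        pd.testing.assert_frame_equal(a, b)

    def test_replicates_and_assays_differ(self):
        effects, bvmap, config = self._setup()
        a = sd.simulate_sort_counts(effects, bvmap, config, "sig_insulin", 1)
        b = sd.simulate_sort_counts(effects, bvmap, config, "sig_insulin", 2)
        c = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
        assert not a.equals(b) and not a.equals(c)

    def test_extreme_effect_saturates_top_bin(self):
        def raise_all(effects):
            for col in effects.columns:
                if col.startswith("effect_"):
                    effects[col] = 50.0
            return effects

        effects, bvmap, config = self._setup(
            effects_override=raise_all, cell_noise_sd=0.01, wt_barcode_fraction=0.0
        )
        # keep only variant barcodes: every cell should land in bin 4
        counts = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
        variant_rows = counts.iloc[: len(effects) * 2]
        assert (variant_rows[["bin1", "bin2", "bin3"]].to_numpy() == 0).all()

    def test_midpoint_effect_splits_middle_bins(self):
        """Effect at the central gate with small noise: reads ~50/50 in bins 2-3."""
        def midpoint(effects):
            for col in effects.columns:
                if col.startswith("effect_"):
                    effects[col] = 0.0
            return effects

        effects, bvmap, _ = self._setup(effects_override=midpoint)
        config = sd.SortSimConfig(
            seed=6, gates=(-30.0, 0.0, 30.0), cell_noise_sd=1.0,
            reads_per_bin=40_000,
        )
        counts = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
        total = counts[["bin1", "bin2", "bin3", "bin4"]].to_numpy().sum()
        share2 = counts["bin2"].sum() / total
        assert abs(share2 - 0.5) < 0.01
        assert counts["bin1"].sum() == 0 and counts["bin4"].sum() == 0

    def test_depth_change_leaves_frequencies_stable(self):
        effects, bvmap, _ = self._setup()
        freqs = {}
        for depth in (50_000, 100_000):
            config = sd.SortSimConfig(seed=6, reads_per_bin=depth)
            counts = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
            freqs[depth] = counts["bin1"].to_numpy() / counts["bin1"].sum()
        # multinomial mean is depth-free; both draws carry sampling noise
        p = freqs[50_000]
        sigma = np.sqrt(np.maximum(p * (1 - p) * (1 / 50_000 + 1 / 100_000), 1e-12))
        assert np.all(np.abs(freqs[100_000] - p) < 5 * sigma + 1e-4)

    def test_nonincreasing_gates_rejected(self):
        effects, bvmap, _ = self._setup()
        config = sd.SortSimConfig(seed=6, gates=(0.5, 0.5, 1.0))
        with pytest.raises(ValueError):
            sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)

    def test_monotone_effect_monotone_score_end_to_end(self):
        """Raising a variant's latent effect never lowers its recovered score."""
        variants = _variants(30, seed=8)
        scores = []
        for effect in (-2.0, -1.0, 0.0, 1.0):
            effects = sd.sample_true_effects(variants, seed=8)
            cols = [c for c in effects.columns if c.startswith("effect_")]
            effects[cols] = 0.0
            effects.loc[0, "effect_bind_insulin"] = effect
            target = effects.loc[0, "variant"]
            bvmap = sd.build_barcode_variant_map(effects, 2, 0.3, seed=8)
            config = sd.SortSimConfig(seed=8, cell_noise_sd=0.5)
            counts = sd.simulate_sort_counts(effects, bvmap, config, "bind_insulin", 1)
            table, _ = score_assay({1: counts}, bvmap)
            scores.append(float(table.set_index("variant").loc[target, "score"]))
        assert scores == sorted(scores)


class TestBarcodeMap:
    def test_wt_fraction_and_barcode_uniqueness(self):
        effects = sd.sample_true_effects(_variants(50), seed=9)
        bvmap = sd.build_barcode_variant_map(effects, 3, 0.35, seed=9)
        assert bvmap["barcode"].is_unique
        assert bvmap["barcode"].str.len().eq(30).all()
        wt = (bvmap["wt_aa"] == "=").mean()
        assert abs(wt - 0.35) < 0.02
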