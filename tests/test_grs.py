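"""Weighted genetic risk scores: harmonization, scoring, strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refluxmr import (
    SimConfig,
    harmonize,
    instrument_strength,
    rescale_score,
    simulate_exposure_outcome,
    simulate_genotypes,
    weighted_score,
)


def make_instruments(betas, eas=None, oas=None):
    k = len(betas)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(k)],
            "effect_allele": eas or ["A"] * k,
            "other_allele": oas or ["G"] * k,
            "beta": betas,
        }
    )


def variants_from(inst, swap_idx=()):
    v = inst[["variant_id", "effect_allele", "other_allele"]].copy()
    for i in swap_idx:
        ea, oa = v.loc[i, "effect_allele"], v.loc[i, "other_allele"]
        v.loc[i, "effect_allele"], v.loc[i, "other_allele"] = oa, ea
    return v


class TestHarmonize:
    def test_aligned_table_identity(self):
        inst = make_instruments([0.1, 0.2])
        res = harmonize(inst, variants_from(inst))
        assert not res.flip.any()
        assert res.dropped == []

    def test_swap_recorded_as_flip(self):
        inst = make_instruments([0.1], eas=["A"], oas=["G"])
        var = pd.DataFrame({"variant_id": ["v0"], "effect_allele": ["G"],
                            "other_allele": ["A"]})
        res = harmonize(inst, var)
        assert res.flip.tolist() == [True]

    def test_mismatched_alleles_dropped_with_warning(self):
        inst = make_instruments([0.1, 0.2])
        var = variants_from(inst)
        var.loc[1, "effect_allele"] = "C"
        var.loc[1, "other_allele"] = "T"
        with pytest.warns(UserWarning, match="dropped"):
            res = harmonize(inst, var)
        assert res.dropped == ["v1"]
        assert len(res.instruments) == 1

    def test_ambiguous_flagged_and_strict_mode_drops(self):
        inst = make_instruments([0.1], eas=["A"], oas=["T"])
        with pytest.warns(UserWarning, match="ambiguous"):
            res = harmonize(inst, variants_from(inst))
        assert res.ambiguous.tolist() == [True]
        with pytest.warns(UserWarning):
            strict = harmonize(inst, variants_from(inst), strict_ambiguous=True)
        assert len(strict.instruments) == 0

    def test_idempotent(self):
        inst = make_instruments([0.1, 0.2, 0.3])
        var = variants_from(inst, swap_idx=[1])
        first = harmonize(inst, var)
        again = harmonize(first.instruments, var)
        pd.testing.assert_frame_equal(
            first.instruments.reset_index(drop=True),
            again.instruments.reset_index(drop=True))
        assert first.flip.tolist() == again.flip.tolist()

    def test_flipped_score_equals_hand_aligned_score(self):
        """10-variant fixture with 3 swaps: WGRS via harmonize equals WGRS
        on a manually re-oriented copy."""
        rng = np.random.default_rng(5)
        betas = rng.uniform(0.02, 0.3, 10)
        inst = make_instruments(list(betas))
        swaps = [2, 5, 7]
        var = variants_from(inst, swap_idx=swaps)
        dosages = rng.integers(0, 3, size=(50, 10)).astype(float)

        res = harmonize(inst, var)
        wgrs = rescale_score(
            weighted_score(dosages, res.instruments, res.flip),
            res.instruments)

        hand = dosages.copy()
        hand[:, swaps] = 2 - hand[:, swaps]
        wgrs_hand = rescale_score(weighted_score(hand, inst), inst)
        np.testing.assert_allclose(wgrs, wgrs_hand, rtol=1e-12)


class TestScoring:
    def test_hand_computed_two_variant_example(self):
        inst = make_instruments([0.1, 0.3])
        ws = weighted_score(np.array([[1.0, 2.0]]), inst)
        assert ws[0] == pytest.approx(0.7)
        wgrs = rescale_score(ws, inst)
        assert wgrs[0] == pytest.approx(0.7 * 2 / 0.4)  # 3.5

    def test_zero_dosages_zero_score(self):
        inst = make_instruments([0.1, 0.3])
        assert weighted_score(np.zeros((4, 2)), inst).tolist() == [0.0] * 4

    def test_equal_weights_reduce_to_allele_count(self):
        inst = make_instruments([0.05] * 4)
        dosages = np.random.default_rng(1).integers(0, 3, (30, 4)).astype(float)
        wgrs = rescale_score(weighted_score(dosages, inst), inst)
        np.testing.assert_allclose(wgrs, dosages.sum(axis=1), rtol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        inst = make_instruments([0.1])
        dosages = np.array([[0.0], [2.0], [np.nan], [2.0]])
        with pytest.warns(UserWarning, match="imputed"):
            ws = weighted_score(dosages, inst)
        # eaf from observed = (0+2+2)/6 -> fill 2*eaf = 4/3
        assert ws[2] == pytest.approx(0.1 * 4 / 3)

    def test_all_missing_variant_rejected(self):
        inst = make_instruments([0.1])
        with pytest.raises(ValueError, match="missing"):
            weighted_score(np.full((3, 1), np.nan), inst)

    def test_zero_weight_sum_rejected(self):
        inst = make_instruments([0.1, -0.1])
        with pytest.raises(ValueError):
            rescale_score(np.array([0.0]), inst)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_wgrs_invariant_to_positive_weight_scaling(self, c):
        rng = np.random.default_rng(9)
        betas = rng.uniform(0.01, 0.4, 6)
        dosages = rng.integers(0, 3, (20, 6)).astype(float)
        base = rescale_score(
            weighted_score(dosages, make_instruments(list(betas))),
            make_instruments(list(betas)))
        scaled_inst = make_instruments(list(betas * c))
        scaled = rescale_score(
            weighted_score(dosages, scaled_inst), scaled_inst)
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_nonnegative_weights_bound_score(self):
        rng = np.random.default_rng(2)
        betas = rng.uniform(0.0, 0.5, 8)
        inst = make_instruments(list(betas))
        dosages = rng.integers(0, 3, (40, 8)).astype(float)
        wgrs = rescale_score(weighted_score(dosages, inst), inst)
        assert np.all(wgrs >= -1e-9) and np.all(wgrs <= 16 + 1e-9)


class TestInstrumentStrength:
    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            instrument_strength(np.ones(10), np.random.default_rng(0).normal(size=10))

    def test_exposure_equal_to_score_degenerate_r2_one(self):
        g = np.random.default_rng(0).normal(size=200)
        res = instrument_strength(g, g)
        assert res["r2"] == pytest.approx(1.0)
        assert np.isinf(res["F"])

    def test_null_association_small_r2(self):
        rng = np.random.default_rng(3)
        res = instrument_strength(rng.normal(size=5000), rng.normal(size=5000))
        assert res["r2"] < 0.005
        assert res["F"] < 10

    def test_simulated_h2_recovered_with_large_f(self):
        cfg = SimConfig(n_individuals=100_000, n_variants=20,
                        h2_exposure=0.02, seed=13)
        dosages, _ = simulate_genotypes(cfg)
        table, tp = simulate_exposure_outcome(cfg, dosages)
        inst = make_instruments(list(tp.gamma))
        wgrs = rescale_score(weighted_score(dosages.astype(float), inst), inst)
        res = instrument_strength(wgrs, table["exposure"].to_numpy())
        assert abs(res["r2"] - 0.02) < 0.005
        assert res["F"] > 1000
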