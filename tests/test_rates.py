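import numpy as np
import pytest

from synbreak import rates
from synbreak.block_finder import count_blocks_raw
from synbreak.genome_io import Alignment
from synbreak.rates import (
    QuadraticModel,
    SimParams,
    calibrate_blocks_to_events,
    pairwise_substitutions,
    predict_events,
    rearrangement_rate,
    simulate_rearrangements,
)


class TestSimulate:
    def test_zero_events_is_identity(self):
        perm = simulate_rearrangements(50, 0, SimParams(C=50), np.random.default_rng(0))
        assert np.array_equal(perm, np.arange(1, 51))

    def test_one_inversion_gives_two_blocks(self):
        params = SimParams(C=100, p_inversion=1.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            perm = simulate_rearrangements(100, 1, params, rng)
            retained, singles = count_blocks_raw(perm)
            assert retained == 2 and singles == 0

    def test_one_translocation_gives_three_blocks(self):
        params = SimParams(C=100, p_inversion=0.0)
        rng = np.random.default_rng(2)
        counts = set()
        for _ in range(50):
            perm = simulate_rearrangements(100, 1, params, rng)
            retained, singles = count_blocks_raw(perm)
            counts.add((retained, singles))
        # 3 blocks, except when the excised arc lands next to a 1-gene
        # remainder, which is rare at C=100 with short segments
        assert (3, 0) in counts
        assert all(r in (2, 3) for r, _s in counts)

    def test_permutation_is_valid(self):
        params = SimParams(C=30)
        rng = np.random.default_rng(3)
        for k in (1, 5, 20):
            perm = simulate_rearrangements(30, k, params, rng)
            assert sorted(np.abs(perm)) == list(range(1, 31))

    def test_too_small_core_rejected(self):
        with pytest.raises(ValueError):
            SimParams(C=3)


class TestCalibration:
    def test_exact_quadratic_recovered(self):
        # bypass simulation noise: feed a noiseless linear map through the
        # same fitting path
        from synbreak.stats_kernel import fit_quadratic

        ks = np.arange(0, 10.0)
        blocks = 1 + 2 * ks
        a, b, c = fit_quadratic(ks, blocks)
        assert (a, b, c) == pytest.approx((1.0, 2.0, 0.0), abs=1e-9)

    def test_calibration_curve_monotone_and_positive_slope(self):
        model = calibrate_blocks_to_events(
            SimParams(C=300, k_grid=list(range(0, 13)), replicates=40, seed=4)
        )
        assert model.b > 0
        assert all(
            m2 >= m1 for m1, m2 in zip(model.mean_blocks, model.mean_blocks[1:])
        )

    def test_single_replicate_still_fits(self):
        model = calibrate_blocks_to_events(
            SimParams(C=100, k_grid=[0, 2, 4, 6, 8], replicates=1, seed=5)
        )
        assert np.isfinite(model.rmse)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            calibrate_blocks_to_events(SimParams(C=100, k_grid=[0, 1, 1, 1]))
        with pytest.raises(ValueError):
            calibrate_blocks_to_events(SimParams(C=100, k_grid=[1, 2, 3, 4]))


class TestPredictEvents:
    MODEL = QuadraticModel(a=1.0, b=2.0, c=0.0, rmse=0.0, C=100, k_grid=list(range(21)))

    def test_single_block_means_zero_events(self):
        assert predict_events(1, self.MODEL) == 0.0

    def test_linear_model_closed_form(self):
        assert predict_events(5, self.MODEL) == pytest.approx(2.0)

    def test_quadratic_root_selection_smallest_nonnegative(self):
        model = QuadraticModel(a=1.0, b=2.0, c=0.1, rmse=0.0, C=100, k_grid=list(range(21)))
        # 1 + 2k + 0.1k^2 = 3.1  ->  k = 1 (other root negative)
        assert predict_events(3.1, model) == pytest.approx(1.0)

    def test_three_blocks_about_one_event(self):
        model = calibrate_blocks_to_events(
            SimParams(C=500, k_grid=list(range(0, 16)), replicates=60, seed=6)
        )
        assert predict_events(3, model) == pytest.approx(1.0, abs=0.5)

    def test_round_trip_on_grid_within_rmse(self):
        model = calibrate_blocks_to_events(
            SimParams(C=400, k_grid=list(range(0, 13)), replicates=60, seed=7)
        )
        for k, mean_b in zip(model.k_grid, model.mean_blocks):
            if k == 0:
                continue
            k_hat = predict_events(mean_b, model)
            assert abs(model.blocks_at(k_hat) - mean_b) <= max(2.5 * model.rmse, 0.3)

    def test_saturating_block_count_extrapolates_with_warning(self):
        model = QuadraticModel(a=1.0, b=2.0, c=-0.05, rmse=0.0, C=100,
                               k_grid=list(range(21)))
        apex_blocks = model.blocks_at(20)
        with pytest.warns(UserWarning, match="calibrated range"):
            n = predict_events(apex_blocks + 10, model)
        assert n > 20


class TestParameterRecovery:
    def test_planted_event_counts_recovered(self):
        """Median predicted k within +/-1 for small k, 25% beyond."""
        params = SimParams(C=500, k_grid=list(range(0, 21)), replicates=60, seed=8)
        model = calibrate_blocks_to_events(params)
        rng = np.random.default_rng(9)
        for k in (1, 3, 5, 8):
            preds = []
            for _ in range(80):
                perm = simulate_rearrangements(500, k, params, rng)
                B, _ = count_blocks_raw(perm)
                preds.append(predict_events(B, model))
            med = float(np.median(preds))
            if k <= 5:
                assert abs(med - k) <= 1.0
            else:
                assert abs(med - k) / k <= 0.25


class TestSubstitutions:
    def _aln(self, rows):
        return Alignment(rows=rows, length=len(next(iter(rows.values()))))

    def test_identical_rows(self):
        S, L = pairwise_substitutions(self._aln({"a": "ACGT", "b": "ACGT"}), "a", "b")
        assert (S, L) == (0, 4)

    def test_single_difference(self):
        S, L = pairwise_substitutions(self._aln({"a": "ACGT", "b": "ACGA"}), "a", "b")
        assert (S, L) == (1, 4)

    def test_gap_and_ambiguity_columns_excluded(self):
        S, L = pairwise_substitutions(self._aln({"a": "AC-TN", "b": "ACGTA"}), "a", "b")
        assert (S, L) == (0, 3)

    def test_missing_genome_rejected(self):
        with pytest.raises(KeyError):
            pairwise_substitutions(self._aln({"a": "AC", "b": "AC"}), "a", "z")

    def test_matches_planted_truth(self, small_bundle):
        truth = small_bundle.truth["pairwise_substitutions"]
        for pair, rec in truth.items():
            g1, g2 = pair.split("|")
            S, _ = pairwise_substitutions(small_bundle.alignment, g1, g2)
            assert S == rec["observed"]
            # without collisions the union of planted positions is exact
            if rec["collisions"] == 0:
                assert S == rec["planted_union"]


class TestRateFormula:
    def test_zero_events_zero_rate(self):
        assert rearrangement_rate(0.0, 1000, 100, 10**6) == 0.0

    def test_arithmetic(self):
        assert rearrangement_rate(2.0, 1000, 100, 10**6) == pytest.approx(2e-11)

    def test_identical_genomes_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rearrangement_rate(1.0, 1000, 0, 10**6)

    def test_scaling_laws(self):
        base = rearrangement_rate(4.0, 1000, 100, 10**6)
        assert rearrangement_rate(4.0, 1000, 200, 10**6) == pytest.approx(base / 2)
        assert rearrangement_rate(4.0, 2000, 100, 10**6) == pytest.approx(base / 2)
        assert rearrangement_rate(4.0, 1000, 100, 2 * 10**6) == pytest.approx(base / 2)


def test_jukes_cantor_correction():
    assert rates.jukes_cantor(0.0) == 0.0
    assert rates.jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-4)
    with pytest.raises(ValueError):
        rates.jukes_cantor(0.8)
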