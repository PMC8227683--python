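"""Distances, model fitting, and the saturation screen."""

import math

import dendropy
import numpy as np
import pytest

from mitokit.saturation import (
    DISTANCE_CAP,
    SubstitutionModel,
    estimate_model,
    gamma_category_rates,
    gtr_gi_distance,
    gtr_gi_distance_matrix,
    jukes_cantor_model,
    p_distance,
    p_distance_matrix,
    rate_matrix,
    saturation_screen,
)
from mitokit.simulate import simulate_alignment, simulate_pair

MITO_MODEL = SubstitutionModel(
    pi=(0.39, 0.09, 0.09, 0.43),
    exchangeabilities=(1.5, 8.0, 1.5, 1.0, 10.0, 1.0),
    alpha=0.5,
    p_inv=0.15,
)


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("AAAA", "AATT", 0.5),
            ("AA-A", "AAGA", 0.0),  # gap column excluded -> 0 over 3 sites
            ("ANAA", "ATAA", 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_all_gap_pair_is_undefined(self):
        assert math.isnan(p_distance("---", "AAA"))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            p_distance("AAA", "AAAA")


class TestModelMachinery:
    def test_rate_matrix_rows_sum_to_zero_and_mean_rate_one(self):
        Q = rate_matrix(MITO_MODEL)
        assert np.allclose(Q.sum(axis=1), 0.0)
        pi = np.asarray(MITO_MODEL.pi)
        mean_rate = -(pi * np.diag(Q)).sum() * (1 - MITO_MODEL.p_inv)
        assert mean_rate == pytest.approx(1.0)

    def test_gamma_categories_are_mean_preserving(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = gamma_category_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(rates) > 0).all()

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel(pi=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            SubstitutionModel(alpha=-1.0)
        with pytest.raises(ValueError):
            SubstitutionModel(p_inv=1.0)


class TestGtrGiDistance:
    def test_identical_sequences_give_zero(self):
        assert gtr_gi_distance("ACGTACGT", "ACGTACGT", MITO_MODEL) == 0.0

    def test_jukes_cantor_closed_form_in_the_equal_rate_limit(self):
        """With equal frequencies, equal exchangeabilities, huge alpha and
        no invariant sites, the ML distance must match -3/4 ln(1 - 4p/3)."""
        model = jukes_cantor_model(alpha=1e6)
        n = 600
        for p in np.arange(0.05, 0.701, 0.05):
            k = round(p * n)
            a = "A" * n
            b = "C" * k + "A" * (n - k)
            d = gtr_gi_distance(a, b, model)
            jc = -0.75 * math.log(1 - 4 * (k / n) / 3)
            assert abs(d - jc) < 1e-3, p

    def test_symmetric_in_sequence_arguments(self):
        a, b = simulate_pair(MITO_MODEL, 0.4, 2000, seed=5)
        assert gtr_gi_distance(a, b, MITO_MODEL) == pytest.approx(
            gtr_gi_distance(b, a, MITO_MODEL), abs=1e-6
        )

    def test_corrected_at_least_p_distance(self):
        for seed, d in ((1, 0.1), (2, 0.5), (3, 1.5)):
            a, b = simulate_pair(MITO_MODEL, d, 3000, seed=seed)
            assert gtr_gi_distance(a, b, MITO_MODEL) >= p_distance(a, b) - 1e-8

    def test_recovers_true_distance_on_long_pair(self):
        a, b = simulate_pair(MITO_MODEL, 0.5, 50_000, seed=11)
        assert gtr_gi_distance(a, b, MITO_MODEL) == pytest.approx(0.5, abs=0.05)

    def test_estimate_converges_with_length(self):
        """RMSE over replicate pairs at true d = 0.5 decreases 1kb -> 100kb."""
        rmses = []
        for length in (1_000, 10_000, 100_000):
            errs = [
                gtr_gi_distance(*simulate_pair(MITO_MODEL, 0.5, length, seed=s), MITO_MODEL) - 0.5
                for s in (21, 22, 23)
            ]
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[2]

    def test_saturated_pair_capped_and_flagged(self):
        rng = np.random.default_rng(0)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        aln = {"a": a, "b": b, "c": a}
        dm = gtr_gi_distance_matrix(aln, jukes_cantor_model(alpha=0.3))
        assert dm.values.max() <= DISTANCE_CAP
        if dm.values.max() == DISTANCE_CAP:
            assert dm.saturated_pairs


class TestEstimateModel:
    def test_parameter_recovery_smoke(self):
        """On a small simulation the fitted model must land in the right
        region: transition exchangeabilities (AG, CT) clearly above the
        transversions, alpha within a factor ~2."""
        tree = dendropy.Tree.get(
            data="((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1,(e:0.15,f:0.15):0.05);",
            schema="newick",
        )
        aln = simulate_alignment(tree, MITO_MODEL, 8000, seed=3)
        est = estimate_model(aln, seed=0, maxiter=250)
        r = est.exchangeabilities
        assert r[1] > 2 * r[0] and r[4] > 2 * r[3]  # AG >> AC, CT >> CG
        assert 0.15 < est.alpha < 1.5

    def test_two_sequence_alignment_still_returns_model(self):
        a, b = simulate_pair(MITO_MODEL, 0.3, 1500, seed=9)
        est = estimate_model({"a": a, "b": b}, seed=0, maxiter=60)
        assert isinstance(est, SubstitutionModel)
        assert sum(est.pi) == pytest.approx(1.0)

    def test_constant_alignment_rejected(self):
        with pytest.raises(ValueError):
            estimate_model({"a": "AAAA", "b": "AAAA"})


@pytest.fixture(scope="module")
def screened():
    tree = dendropy.Tree.get(
        data="((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2,(e:0.4,f:0.4):0.1);",
        schema="newick",
    )
    partitions = {
        "slow": simulate_alignment(tree, MITO_MODEL, 4000, seed=1, multiplier=1.0),
        "medium": simulate_alignment(tree, MITO_MODEL, 4000, seed=2, multiplier=3.0),
        "fast": simulate_alignment(tree, MITO_MODEL, 4000, seed=3, multiplier=8.0),
    }
    return saturation_screen(partitions, MITO_MODEL, bottom_k=1)


class TestSaturationScreen:
    def test_slow_partition_is_nearly_linear(self, screened):
        assert screened.partitions["slow"]["correlation"] > 0.99

    def test_saturated_partition_ranks_below_slow(self, screened):
        assert (
            screened.partitions["fast"]["correlation"]
            < screened.partitions["slow"]["correlation"]
        )

    def test_bottom_rank_flagging(self, screened):
        assert "fast" in screened.flagged()
        assert "slow" not in screened.flagged()

    def test_constant_distance_partition_excluded(self):
        aln = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
        with pytest.warns(UserWarning):
            report = saturation_screen({"const": aln}, MITO_MODEL)
        assert report.excluded == ["const"]
        assert report.partitions == {}


def test_p_distance_matrix_is_symmetric_zero_diagonal():
    aln = {"a": "ACGTAC", "b": "ACGTTT", "c": "AAGTAC"}
    dm = p_distance_matrix(aln)
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0.0)
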