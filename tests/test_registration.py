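"""Registration to the polar cap, fraction normalization, cohort averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from polarcap import (
    RegisteredFractionProfile,
    average_distribution,
    normalize_fraction,
    peak_index,
    population_kymograph,
    register_to_reference,
    resample_to_grid,
)
from polarcap.errors import (
    DegenerateProfileError,
    EmptySelectionError,
    InconsistentInputError,
    ResolutionError,
)
from polarcap.registration import align_to_common_grid


def make_rfp(values, step_um=0.1, cell_id="c", frame_index=0):
    values = np.asarray(values, float)
    n = len(values)
    pos = (np.arange(n) - n // 2) * step_um
    return RegisteredFractionProfile(
        values / values.sum(), pos, cell_id, frame_index, perimeter_um=n * step_um
    )


class TestPeakIndex:
    def test_simple_and_tied_maxima(self):
        assert peak_index(np.array([0, 1, 3, 1, 0])) == 2
        assert peak_index(np.array([0, 3, 3, 0])) == 1  # first of ties

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(1000):
            v = rng.integers(0, 50, size=rng.integers(2, 40)).astype(float)
            if np.all(v == v[0]):
                continue
            brute = min(i for i in range(len(v)) if v[i] == v.max())
            assert peak_index(v) == brute

    def test_constant_profile_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            peak_index(np.full(10, 2.0))


class TestRegisterToReference:
    def test_peak_already_central_is_identity(self):
        v = np.arange(10.0)
        np.testing.assert_array_equal(register_to_reference(v, 5), v)

    def test_shift_definition(self):
        v = np.zeros(100)
        v[10], v[11] = 1.0, 2.0
        out = register_to_reference(v, 10)
        assert out[50] == 1.0 and out[51] == 2.0

    @given(
        hnp.arrays(float, st.integers(4, 60), elements=st.floats(0, 100)),
        st.integers(0, 59),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_and_multiset_conserved(self, v, peak):
        peak = peak % len(v)
        out = register_to_reference(v, peak)
        # pure circular permutation: multiset conserved exactly
        np.testing.assert_array_equal(np.sort(out), np.sort(v))
        # inverse shift restores the original exactly
        back = np.roll(out, peak - len(v) // 2)
        np.testing.assert_array_equal(back, v)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InconsistentInputError):
            register_to_reference(np.zeros(10), 2, n_reference=12)


class TestNormalizeFraction:
    def test_forced_by_formula(self):
        np.testing.assert_allclose(
            normalize_fraction(np.array([2.0, 4.0, 6.0])), [0, 1 / 3, 2 / 3]
        )

    @given(hnp.arrays(float, st.integers(2, 50), elements=st.floats(0, 1e6)))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one_min_zero(self, v):
        if np.all(v == v[0]):
            return
        out = normalize_fraction(v)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.min() == 0.0

    def test_matches_two_step_oracle(self, rng):
        for _ in range(50):
            v = rng.uniform(0, 100, rng.integers(3, 80))
            shifted = v - v.min()
            expected = shifted / shifted.sum()
            np.testing.assert_allclose(normalize_fraction(v), expected, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateProfileError):
            normalize_fraction(np.full(5, 3.0))


class TestResampleToGrid:
    def test_own_grid_identity(self):
        p = make_rfp(np.array([1, 2, 5, 2, 1.0]))
        out = resample_to_grid(p, 0.1)
        np.testing.assert_allclose(out.values, p.values, atol=1e-12)

    def test_resampled_sums_to_one(self, rng):
        p = make_rfp(rng.uniform(0.1, 1, 41))
        out = resample_to_grid(p, 0.07)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_down_up_round_trip(self):
        v = 1.0 + np.cos(np.linspace(-np.pi, np.pi, 40, endpoint=False))
        p = make_rfp(v)
        down = resample_to_grid(p, 0.2)
        up = resample_to_grid(down, 0.1)
        # compare shapes after renormalization on the common support
        k = (len(up) - 1) // 2
        c = p.center_index
        orig = p.values[c - k : c + k + 1]
        np.testing.assert_allclose(
            up.values / up.values.max(), orig / orig.max(), atol=0.05
        )

    def test_coarse_grid_rejected(self):
        p = make_rfp(np.array([1, 2, 1.0]))
        with pytest.raises(ResolutionError):
            resample_to_grid(p, 5.0)


class TestAverageDistribution:
    def test_identical_profiles_mean_equals_profile_zero_band(self):
        p = make_rfp(np.array([1, 2, 5, 2, 1.0]))
        profiles = [
            make_rfp(np.array([1, 2, 5, 2, 1.0]), cell_id=f"c{i}", frame_index=10)
            for i in range(4)
        ]
        avg = average_distribution(profiles, start_frame=9, n_boot=200, seed=0)
        np.testing.assert_allclose(avg.mean, p.values, atol=1e-12)
        np.testing.assert_allclose(avg.upper - avg.lower, 0.0, atol=1e-12)

    def test_start_frame_zero_matches_manual_mean(self, rng):
        profiles = [
            make_rfp(rng.uniform(0.1, 1, 11), cell_id=f"c{i}", frame_index=f)
            for i in range(3)
            for f in range(10)
        ]
        avg = average_distribution(profiles, start_frame=0, n_boot=50, seed=0)
        manual = np.mean([p.values for p in profiles], axis=0)
        np.testing.assert_allclose(avg.mean, manual, atol=1e-12)

    def test_band_brackets_mean_and_ordering_invariance(self, rng):
        profiles = [
            make_rfp(rng.uniform(0.1, 1, 11), cell_id=f"c{i}", frame_index=12)
            for i in range(6)
        ]
        a = average_distribution(profiles, n_boot=500, seed=3)
        b = average_distribution(profiles[::-1], n_boot=500, seed=3)
        assert np.all(a.lower <= a.mean) and np.all(a.mean <= a.upper)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.lower, b.lower, atol=1e-12)

    def test_empty_selection_rejected(self):
        p = make_rfp(np.array([1, 2, 1.0]), frame_index=2)
        with pytest.raises(EmptySelectionError):
            average_distribution([p], start_frame=9)


class TestPopulationKymograph:
    def test_single_cell_identity_and_frame_means(self, rng):
        profs = [
            make_rfp(rng.uniform(0.1, 1, 7), cell_id="a", frame_index=f) for f in range(3)
        ]
        mat, grid, frames = population_kymograph(profs)
        for f in range(3):
            np.testing.assert_allclose(mat[:, f], profs[f].values)

    def test_two_cell_mean_is_elementwise_average(self):
        a = make_rfp(np.array([1, 4, 1.0]), cell_id="a", frame_index=0)
        b = make_rfp(np.array([3, 2, 3.0]), cell_id="b", frame_index=0)
        mat, _, _ = population_kymograph([a, b])
        np.testing.assert_allclose(mat[:, 0], (a.values + b.values) / 2)

    def test_missing_frame_is_nan_column(self):
        a = make_rfp(np.array([1, 4, 1.0]), cell_id="a", frame_index=0)
        b = make_rfp(np.array([3, 2, 3.0]), cell_id="a", frame_index=2)
        mat, _, frames = population_kymograph([a, b])
        assert np.all(np.isnan(mat[:, 1]))


def test_align_to_common_grid_crops_to_shortest(rng):
    long = make_rfp(rng.uniform(0.1, 1, 41))
    short = make_rfp(rng.uniform(0.1, 1, 21), cell_id="s")
    out = align_to_common_grid([long, short], 0.1)
    assert len(out[0]) == len(out[1])
    np.testing.assert_allclose(out[0].positions_um, out[1].positions_um)
    for p in out:
        assert p.values.sum() == pytest.approx(1.0, abs=1e-9)
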