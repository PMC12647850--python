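"""Event statistics: spacings, fits, colocalization, CoC with brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadscan import (
    EventMap,
    adjacent_spacings,
    bp_to_um,
    chance_expectation,
    coc_curve,
    fit_gamma,
    fit_two_gaussian_spacings,
    generate_independent_events,
    l_coc,
    longer_vs_shorter_relation,
    modal_value,
    nearest_heterologous_distances,
    peaks_to_eventmap,
)
from triadscan.interference import CoCCurve
from triadscan.peaks import PeakSet

PX = 0.067


def em(chromosomes):
    return EventMap.from_dict(chromosomes)


def make_peakset(cid, channel, band, positions):
    positions = np.asarray(positions, dtype=float)
    return PeakSet(
        chromosome_id=cid,
        channel=channel,
        band=band,
        positions_um=positions,
        kinds=np.array(["maximum"] * positions.size),
        heights=np.ones(positions.size),
        pixel_size_um=PX,
    )


class TestPeaksToEventmap:
    def test_union_merges_bands(self):
        sets = [
            make_peakset("c1", "crossover", "shorter", [0.5, 1.0]),
            make_peakset("c1", "crossover", "longer", [1.5]),
        ]
        m = peaks_to_eventmap(sets, {"c1": 3.0}, mode="union")
        np.testing.assert_allclose(m.positions["c1"], [0.5, 1.0, 1.5])

    def test_duplicate_pixel_kept_once(self):
        sets = [
            make_peakset("c1", "crossover", "shorter", [0.5, 1.0]),
            make_peakset("c1", "crossover", "longer", [1.0]),
        ]
        m = peaks_to_eventmap(sets, {"c1": 3.0}, mode="union")
        np.testing.assert_allclose(m.positions["c1"], [0.5, 1.0])

    def test_empty_peakset_chromosome_retained(self):
        sets = [make_peakset("c1", "crossover", "shorter", [0.5])]
        m = peaks_to_eventmap(sets, {"c1": 3.0, "c2": 2.8})
        assert m.positions["c2"].size == 0
        assert m.n_chromosomes == 2

    def test_mixed_channels_rejected(self):
        sets = [
            make_peakset("c1", "crossover", "shorter", [0.5]),
            make_peakset("c1", "axis", "shorter", [0.6]),
        ]
        with pytest.raises(ValueError, match="channel"):
            peaks_to_eventmap(sets, {"c1": 3.0})

    def test_mixed_bands_without_union_rejected(self):
        sets = [
            make_peakset("c1", "crossover", "shorter", [0.5]),
            make_peakset("c1", "crossover", "longer", [1.5]),
        ]
        with pytest.raises(ValueError, match="union"):
            peaks_to_eventmap(sets, {"c1": 3.0})


class TestAdjacentSpacings:
    def test_hand_case(self):
        m = em({"c1": ([0.5, 1.0, 1.48], 3.0)})
        np.testing.assert_allclose(adjacent_spacings(m), [0.5, 0.48])

    def test_singletons_contribute_nothing(self):
        m = em({"c1": ([1.0], 3.0), "c2": ([], 3.0)})
        assert adjacent_spacings(m).size == 0

    def test_pooled_count_identity(self):
        rng = np.random.default_rng(0)
        chroms = {
            f"c{i}": (np.sort(rng.uniform(0, 3, rng.integers(0, 8))), 3.0)
            for i in range(20)
        }
        m = em(chroms)
        expected = sum(max(p.size - 1, 0) for p in m.positions.values())
        assert adjacent_spacings(m).size == expected


class TestFitGamma:
    def test_parameter_recovery_alpha9(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(9, 0.0625, 5000)  # mode (9-1)*0.0625 = 0.5
        fit = fit_gamma(x)
        assert 8 <= fit.alpha <= 10
        assert 0.48 <= fit.mode_um <= 0.52

    def test_exponential_boundary(self):
        rng = np.random.default_rng(43)
        fit = fit_gamma(rng.exponential(0.5, 5000))
        assert fit.alpha == pytest.approx(1.0, abs=0.1)
        assert fit.mode_um < 0.02

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma(np.concatenate([np.full(30, 0.5), [0.0]]))


class TestTwoGaussianSpacings:
    def test_two_tier_quantized_recovery(self):
        rng = np.random.default_rng(44)
        x = np.concatenate(
            [rng.normal(0.46, 0.03, 3000), rng.normal(0.69, 0.04, 1500)]
        )
        fit = fit_two_gaussian_spacings(x, seed=0)
        assert abs(fit.means[0] - 0.46) < 0.03
        assert abs(fit.means[1] - 0.69) < 0.03


class TestNearestHeterologous:
    def test_identical_sets_all_zero(self):
        d = nearest_heterologous_distances({"c": [0.5, 1.0]}, {"c": [0.5, 1.0]})
        np.testing.assert_array_equal(d, [0, 0])

    def test_hand_case(self):
        d = nearest_heterologous_distances({"c": [1.0]}, {"c": [0.8, 1.9]})
        np.testing.assert_allclose(d, [0.2])

    def test_missing_b_channel_skipped_and_logged(self):
        log = []
        d = nearest_heterologous_distances({"c": [1.0], "d": [2.0]}, {"c": [1.1]}, log=log)
        np.testing.assert_allclose(d, [0.1])
        assert any("d" in m for m in log)

    def test_jittered_triads_modal_distance_within_one_pixel(self, default_cohort):
        from triadscan import detect_band_peaks, split_bands

        profiles, _ = default_cohort
        pa, pb = {}, {}
        for p in profiles:
            pa[p.chromosome_id] = detect_band_peaks(split_bands(p, "crossover"), "shorter").positions_um
            pb[p.chromosome_id] = detect_band_peaks(split_bands(p, "axis"), "shorter").positions_um
        d = nearest_heterologous_distances(pa, pb)
        assert modal_value(d) <= PX + 1e-9


class TestChanceExpectation:
    def test_shift_destroys_coincidence(self):
        rng = np.random.default_rng(1)
        peaks = {f"c{i}": np.sort(rng.uniform(0, 3, 6)) for i in range(30)}
        lengths = {cid: 3.0 for cid in peaks}
        observed = nearest_heterologous_distances(peaks, peaks)
        null = chance_expectation(peaks, peaks, lengths, n_rounds=50, seed=0)
        assert observed.max() == 0
        assert null.median_um > 0.05

    def test_half_mean_spacing_reference_matches_reported_chance(self):
        """For regular ~0.55 um arrays the analytic chance reference lies in
        the reported 0.25-0.30 um window."""
        rng = np.random.default_rng(2)
        peaks = {}
        for i in range(60):
            gaps = rng.gamma(9, 0.55 / 9, 8)
            pos = np.cumsum(gaps)
            peaks[f"c{i}"] = pos[pos < 3.15]
        lengths = {cid: 3.15 for cid in peaks}
        null = chance_expectation(peaks, peaks, lengths, n_rounds=20, seed=0)
        assert 0.25 <= null.half_mean_spacing_um <= 0.30

    def test_monte_carlo_stability_of_median(self):
        rng = np.random.default_rng(3)
        a = {f"c{i}": np.sort(rng.uniform(0, 3, 5)) for i in range(20)}
        b = {f"c{i}": np.sort(rng.uniform(0, 3, 5)) for i in range(20)}
        lengths = {cid: 3.0 for cid in a}
        n1 = chance_expectation(a, b, lengths, n_rounds=200, seed=5)
        n2 = chance_expectation(a, b, lengths, n_rounds=400, seed=6)
        assert abs(n1.median_um - n2.median_um) < PX


class TestLongerVsShorter:
    def test_hand_case_counts_in_fraction(self):
        rel = longer_vs_shorter_relation({"c": [1.0]}, {"c": [0.77, 2.0]})
        np.testing.assert_allclose(rel.distances_um, [0.23])
        assert rel.fraction_ge_100nm == 1.0
        assert rel.median_um == pytest.approx(0.23)

    def test_coincident_peak_excluded_from_fraction(self):
        rel = longer_vs_shorter_relation({"c": [1.0, 2.0]}, {"c": [1.0, 2.3]})
        assert rel.fraction_ge_100nm == 0.5

    def test_count_ratio_median(self):
        rel = longer_vs_shorter_relation(
            {"c1": [1.0], "c2": [1.0, 2.0]}, {"c1": [0.5, 1.5], "c2": [0.5, 1.5]}
        )
        assert rel.median_ratio == pytest.approx(0.75)  # median of {0.5, 1.0}


def brute_force_coc(chromosomes, n_intervals):
    """Independent dict-based CoC enumeration (the oracle)."""
    ids = list(chromosomes)
    occupied = {}
    for cid in ids:
        pos, length = chromosomes[cid]
        bins = set()
        for x in pos:
            b = min(int(x / length * n_intervals), n_intervals - 1)
            bins.add(b)
        occupied[cid] = bins
    n = len(ids)
    per_sep = {}
    for i in range(n_intervals):
        for j in range(i + 1, n_intervals):
            fi = sum(1 for cid in ids if i in occupied[cid]) / n
            fj = sum(1 for cid in ids if j in occupied[cid]) / n
            if fi * fj == 0:
                continue
            fobs = sum(1 for cid in ids if i in occupied[cid] and j in occupied[cid]) / n
            per_sep.setdefault(j - i, []).append(fobs / (fi * fj))
    mean_len = np.mean([chromosomes[cid][1] for cid in ids])
    return {
        sep * mean_len / n_intervals: float(np.mean(v)) for sep, v in per_sep.items()
    }


class TestCoC:
    def test_four_chromosome_hand_instance_matches_oracle(self):
        chroms = {
            "a": (np.array([0.1, 1.1]), 2.0),
            "b": (np.array([0.6, 1.6]), 2.0),
            "c": (np.array([0.1, 0.6, 1.9]), 2.0),
            "d": (np.array([1.1]), 2.0),
        }
        curve = coc_curve(em(chroms), n_intervals=4)
        oracle = brute_force_coc(chroms, 4)
        for dist, coc in zip(curve.distances_um, curve.coc):
            if np.isnan(coc):
                assert not any(np.isclose(dist, d) for d in oracle)
            else:
                key = min(oracle, key=lambda d: abs(d - dist))
                assert coc == pytest.approx(oracle[key])

    @given(
        data=st.lists(
            st.lists(st.floats(min_value=0, max_value=1, exclude_max=True), max_size=6),
            min_size=2,
            max_size=10,
        ),
        n_intervals=st.integers(min_value=2, max_value=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_on_random_instances(self, data, n_intervals):
        length = 2.5
        chroms = {
            f"c{i}": (np.sort(np.array(pos) * length), length)
            for i, pos in enumerate(data)
        }
        curve = coc_curve(em(chroms), n_intervals=n_intervals)
        oracle = brute_force_coc(chroms, n_intervals)
        for dist, coc in zip(curve.distances_um, curve.coc):
            matches = [v for d, v in oracle.items() if abs(d - dist) < 1e-9]
            if np.isnan(coc):
                assert not matches
            else:
                assert matches and coc == pytest.approx(matches[0])

    def test_single_event_chromosomes_give_zero_coc(self):
        rng = np.random.default_rng(7)
        chroms = {f"c{i}": ([rng.uniform(0, 3)], 3.0) for i in range(200)}
        curve = coc_curve(em(chroms), n_intervals=10)
        valid = curve.coc[~np.isnan(curve.coc)]
        np.testing.assert_allclose(valid, 0.0)

    def test_independent_events_approach_unity(self):
        emap = generate_independent_events(1000, 3.15, 2.0, seed=5)
        curve = coc_curve(emap, n_intervals=30)
        # MC error grows where few interval pairs exist; check well-supported range
        supported = curve.n_pairs >= 10
        assert np.nanmax(np.abs(curve.coc[supported] - 1)) < 0.08

    def test_reversal_invariance(self):
        emap = generate_independent_events(200, 3.15, 2.0, seed=8)
        c1 = coc_curve(emap, n_intervals=12)
        c2 = coc_curve(emap.reversed(), n_intervals=12)
        np.testing.assert_allclose(c1.coc, c2.coc, equal_nan=True)


class TestLCoC:
    def test_linear_interpolation_hand_case(self):
        curve = CoCCurve(
            n_intervals=3,
            distances_um=np.array([0.1, 0.3]),
            coc=np.array([0.2, 0.6]),
            n_pairs=np.array([5, 5]),
            n_excluded=0,
            mean_length_um=3.0,
            n_chromosomes=10,
        )
        assert l_coc(curve) == pytest.approx(0.25)

    def test_no_crossing_gives_nan(self):
        curve = CoCCurve(
            n_intervals=3,
            distances_um=np.array([0.1, 0.3]),
            coc=np.array([0.2, 0.4]),
            n_pairs=np.array([5, 5]),
            n_excluded=0,
            mean_length_um=3.0,
            n_chromosomes=10,
        )
        assert np.isnan(l_coc(curve))


class TestBpToUm:
    def test_unit_definition(self):
        assert bp_to_um([324])[0] == pytest.approx(0.001)

    def test_chromosome_xv_scale(self):
        # 1.05 Mb at 324 bp/nm is 3.24 um, matching a ~3.2 um axis
        assert bp_to_um([1.05e6])[0] == pytest.approx(3.24, abs=0.005)

    def test_zero_maps_to_zero_and_negative_rejected(self):
        assert bp_to_um([0])[0] == 0
        with pytest.raises(ValueError):
            bp_to_um([-5])
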