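"""Two-region scaling, assignment and Fermi-resonance searches."""

import itertools

import numpy as np
import pytest

from flavokit import vibrational
from flavokit.errors import FlavokitError
from flavokit.synthetic_data import gen_spectrum
from flavokit.vibrational import (
    ScalingScheme,
    VibrationalMode,
    blumeatin_experimental_bands,
    blumeatin_modes,
    estimate_scale_factor,
    find_combination_bands,
    find_overtones,
    match_peaks,
    scale,
    scale_table,
)


class TestScale:
    @pytest.mark.parametrize(
        "unscaled, expected",
        [(3818, 3646), (1744, 1686), (14, 14), (417, 403), (2997, 2862)],
    )
    def test_anchor_values(self, unscaled, expected):
        assert scale(unscaled) == expected

    def test_region_boundary_convention(self):
        # below the boundary the low factor applies; at/above, the high one
        assert scale(1799.999) == round(1799.999 * 0.967)
        assert scale(1800) == round(1800 * 0.955)

    def test_non_positive_rejected(self):
        with pytest.raises(FlavokitError):
            scale(0)
        with pytest.raises(FlavokitError):
            scale(-100)

    def test_monotone_within_each_region(self):
        grid_low = np.linspace(1, 1799, 400)
        scaled_low = [scale(v) for v in grid_low]
        assert all(a <= b for a, b in zip(scaled_low, scaled_low[1:]))
        grid_high = np.linspace(1800, 4000, 400)
        scaled_high = [scale(v) for v in grid_high]
        assert all(a <= b for a, b in zip(scaled_high, scaled_high[1:]))

    def test_full_reference_table(self):
        """Rescaling all 102 tabulated unscaled wavenumbers reproduces the
        tabulated scaled column exactly (both factor regions exercised)."""
        modes = blumeatin_modes()
        assert len(modes) == 102
        rescaled = scale_table(modes)
        for original, redone in zip(modes, rescaled):
            assert redone.scaled == original.scaled, f"mode {original.index}"
        # the region split: modes 1-88 below 1800, modes 89-102 at/above
        assert modes[87].unscaled < 1800 <= modes[88].unscaled

    def test_scale_table_preserves_order_and_reports_mode_on_error(self):
        modes = [VibrationalMode(1, 500.0), VibrationalMode(2, -1.0)]
        with pytest.raises(FlavokitError, match="mode 2"):
            scale_table(modes)
        assert scale_table([]) == []


def _bruteforce_match(computed, experimental, tolerance):
    """Exhaustive assignment oracle: maximise matched pairs, then minimise
    total |delta|, then (among near-equal totals) minimise the squared index
    offset, which prefers the non-crossing pairing; returns the winning
    pair set."""
    n, m = len(computed), len(experimental)
    best = None  # (k, total, cross, pairs)
    for k in range(min(n, m), -1, -1):
        for comp_idx in itertools.combinations(range(n), k):
            for perm in itertools.permutations(range(m), k):
                deltas = [abs(computed[i] - experimental[j])
                          for i, j in zip(comp_idx, perm)]
                if any(d > tolerance for d in deltas):
                    continue
                cross = sum((i - j) ** 2 for i, j in zip(comp_idx, perm))
                pairs = tuple(sorted((computed[i], experimental[j])
                                     for i, j in zip(comp_idx, perm)))
                cand = (k, sum(deltas), cross, pairs)
                if best is None:
                    best = cand
                elif cand[0] > best[0]:
                    best = cand
                elif cand[0] == best[0]:
                    if cand[1] < best[1] - 1e-9:
                        best = cand
                    elif abs(cand[1] - best[1]) <= 1e-9 and cand[2] < best[2]:
                        best = cand
        if best is not None and best[0] == k:
            break
    return best[3] if best is not None else ()


class TestMatchPeaks:
    def test_reference_example(self):
        result = match_peaks([3072, 3046], [3076], tolerance=15)
        assert result.pairs == ((3072.0, 3076.0, 4.0),)
        assert result.unmatched_computed == (3046.0,)

    def test_empty_experimental(self):
        result = match_peaks([100.0, 200.0], [], tolerance=10)
        assert result.pairs == ()
        assert result.unmatched_computed == (100.0, 200.0)

    def test_tolerance_must_be_positive(self):
        with pytest.raises(FlavokitError):
            match_peaks([1.0], [1.0], tolerance=0)

    def test_agrees_with_bruteforce_on_random_instances(self):
        """Total-|delta|-optimal assignment matches exhaustive enumeration on
        500 random instances (continuous values, so optima are unique)."""
        rng = np.random.default_rng(1615)
        for _ in range(500):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 5))
            computed = sorted(rng.uniform(0, 100, size=n).tolist())
            experimental = sorted(rng.uniform(0, 100, size=m).tolist())
            tol = float(rng.uniform(2, 25))
            got = tuple(sorted((c, e) for c, e, _ in
                               match_peaks(computed, experimental, tol).pairs))
            assert got == _bruteforce_match(computed, experimental, tol)


class TestCombinationBands:
    def test_identifies_reported_pair(self):
        bands = blumeatin_experimental_bands()
        hits = find_combination_bands(bands, 1615, 5)
        assert (528.0, 1089.0, 1617.0) in hits
        # sorted by deviation then lower band
        devs = [abs(s - 1615) for _, _, s in hits]
        assert devs == sorted(devs)

    def test_empty_bands(self):
        assert find_combination_bands([], 1615, 5) == []

    def test_agrees_with_double_loop_oracle(self):
        rng = np.random.default_rng(528)
        for _ in range(500):
            bands = rng.uniform(100, 2000, size=int(rng.integers(1, 31))).tolist()
            target = float(rng.uniform(300, 3500))
            tol = float(rng.uniform(0, 20))
            got = set(find_combination_bands(bands, target, tol))
            sorted_bands = sorted(bands)
            expected = {
                (sorted_bands[i], sorted_bands[j], sorted_bands[i] + sorted_bands[j])
                for i in range(len(sorted_bands))
                for j in range(i, len(sorted_bands))
                if abs(sorted_bands[i] + sorted_bands[j] - target) <= tol
            }
            assert got == expected


class TestOvertones:
    def test_exact_second_harmonic(self):
        assert find_overtones([807.5], 1615, 1, max_order=3) == [(807.5, 2, 1615.0)]

    def test_reference_band_list_has_no_overtone_candidate(self):
        """No observed fundamental doubles or triples onto the 1615 cm-1
        band, supporting the combination-band reading of the splitting."""
        assert find_overtones(blumeatin_experimental_bands(), 1615, 5, 3) == []

    def test_empty_and_order_validation(self):
        assert find_overtones([], 1615, 5) == []
        with pytest.raises(FlavokitError):
            find_overtones([100.0], 1615, 5, max_order=1)


class TestScaleFactorEstimate:
    def test_exact_proportionality(self):
        assert estimate_scale_factor([(1000, 967), (2000, 1934)]) == pytest.approx(0.967)

    def test_single_pair_rejected(self):
        with pytest.raises(FlavokitError):
            estimate_scale_factor([(1000, 967)])

    def test_noise_free_round_trip(self):
        pairs = gen_spectrum(50, true_factor=0.955, noise_sd=0.0, seed=3)
        assert estimate_scale_factor(pairs) == pytest.approx(0.955, abs=1e-9)

    def test_recovery_is_calibrated(self):
        """With Gaussian noise the through-origin slope has standard error
        sd/sqrt(sum c^2).  Over 20 fixed seeds the estimator behaves like a
        calibrated unbiased estimator: the large majority of draws fall
        within 3 sigma (a strict per-seed 3-sigma cut would be expected to
        fail ~0.3% of draws even for a correct estimator) and none strays
        past 5 sigma."""
        true_factor, sd = 0.967, 2.0
        z_scores = []
        for seed in range(20):
            pairs = gen_spectrum(100, true_factor, sd, seed=seed)
            c = np.array([p[0] for p in pairs])
            sigma = sd / np.sqrt(np.sum(c * c))
            z_scores.append(abs(estimate_scale_factor(pairs) - true_factor) / sigma)
        assert sum(z <= 3 for z in z_scores) >= 18
        assert max(z_scores) < 5


def test_mode_table_round_trip(tmp_path):
    modes = blumeatin_modes()
    out = tmp_path / "modes.tsv"
    vibrational.write_mode_table(modes, out)
    back = vibrational.read_mode_table(out)
    assert back == modes
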