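import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import VAL_CFG, match_detections
from vesiq import (
    PreprocessConfig,
    Spot,
    analyze_channel,
    detect_spots,
    enlarge_spot,
    fit_background_model,
    generate_scene,
    integrate_spot,
    normalize_spot,
    preprocess,
    sample_background,
    scene_for_snr,
    threshold_map,
)
from vesiq.detect import BackgroundModel, BackgroundSample, occupied_mask, rolling_ball_baseline

# ---------------------------------------------------------------- oracles


def rolling_ball_oracle(column, radius, spacing=1.0):
    """Exhaustive ball placement: for every pixel, the highest ball surface
    over all center positions whose ball stays under the profile."""
    n = len(column)
    half = int(math.floor(radius / spacing))
    out = np.full(n, -np.inf)
    for p in range(n):
        # ball centred (horizontally) at p: highest height keeping it under f
        height = min(
            column[p + k] - math.sqrt(radius**2 - (k * spacing) ** 2)
            for k in range(-half, half + 1)
            if 0 <= p + k < n
        )
        for i in range(max(0, p - half), min(n, p + half + 1)):
            surf = height + math.sqrt(radius**2 - ((i - p) * spacing) ** 2)
            out[i] = max(out[i], surf)
    return out


def flood_fill_oracle(mask):
    """8-connected components by explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or visited[r0, c0]:
                continue
            stack = [(r0, c0)]
            visited[r0, c0] = True
            comp = []
            while stack:
                r, c = stack.pop()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and not visited[rr, cc]
                        ):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
            comps.append(frozenset(comp))
    return set(comps)


def dilation_oracle(pixels, shape):
    """Union of ±2 neighborhoods, clipped to bounds."""
    out = set()
    for r, c in pixels:
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    out.add((rr, cc))
    return out


def _th(values):
    """Threshold map with explicit per-pixel values, for isolated detection tests."""
    from vesiq.detect import ThresholdMap

    return ThresholdMap(values=values, sfr=1.0, fluctuation=values.copy())


# ---------------------------------------------------------------- preprocess


class TestPreprocess:
    def test_constant_image_gives_zero_corrected(self):
        grid = np.full((60, 60), 37.0)
        corrected, background = preprocess(grid, PreprocessConfig())
        np.testing.assert_allclose(background, 37.0, atol=1e-9)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)

    def test_impulse_removed_from_background(self):
        cfg = PreprocessConfig(lowpass_sigma=0.0, post_gauss_sigma=0.0, ball_radius=10.0)
        grid = np.full((50, 50), 5.0)
        grid[25, 25] = 500.0
        corrected, background = preprocess(grid, cfg)
        assert background[25, 25] == pytest.approx(5.0, abs=1e-9)
        assert corrected[25, 25] == pytest.approx(495.0, abs=1e-9)

    def test_ball_radius_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(ball_radius=0.0)
        with pytest.raises(ValueError, match="smaller than column"):
            rolling_ball_baseline(np.zeros((10, 10)), radius=10.0)

    def test_baseline_below_profile(self, rng):
        grid = rng.normal(100, 5, size=(80, 40))
        baseline = rolling_ball_baseline(grid, 15.0)
        assert np.all(baseline <= grid + 1e-9)

    @pytest.mark.parametrize("radius", [3.0, 7.5, 12.0])
    def test_baseline_matches_exhaustive_ball_placement(self, radius, rng):
        grid = rng.normal(50, 10, size=(64, 6)).cumsum(axis=0) / 5 + rng.normal(0, 3, (64, 6))
        baseline = rolling_ball_baseline(grid, radius)
        for col in range(grid.shape[1]):
            np.testing.assert_allclose(
                baseline[:, col], rolling_ball_oracle(grid[:, col], radius), atol=1e-9
            )


# ---------------------------------------------------------------- threshold


class TestThresholdMap:
    def test_constant_image_zero_threshold(self):
        th = threshold_map(np.full((20, 20), 4.0), sfr=2.0)
        np.testing.assert_allclose(th.values, 0.0)

    def test_column_median_min_example(self):
        # one column with median 10 and min 6 at SFR 2 -> threshold 16
        col = np.array([6.0, 8.0, 10.0, 12.0, 14.0])
        grid = np.column_stack([col, np.zeros(5)])
        th = threshold_map(grid, sfr=2.0)
        np.testing.assert_allclose(th.values[:, 0], 16.0)
        np.testing.assert_allclose(th.values[:, 1], 0.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_linear_in_sfr(self, seed):
        grid = np.random.default_rng(seed).uniform(0, 100, size=(16, 16))
        np.testing.assert_allclose(
            threshold_map(grid, sfr=3.0).values, 1.5 * threshold_map(grid, sfr=2.0).values
        )

    def test_threshold_constant_within_column(self, rng):
        grid = rng.uniform(0, 50, size=(30, 10))
        th = threshold_map(grid, 2.0)
        assert np.all(np.ptp(th.values, axis=0) == 0)


# ---------------------------------------------------------------- detection


class TestDetectSpots:
    def test_zero_grid_no_spots(self):
        grid = np.zeros((32, 32))
        assert detect_spots(grid, _th(np.zeros((32, 32)))) == []

    def test_two_separated_blocks_two_spots(self):
        grid = np.zeros((20, 20))
        grid[2:5, 2:5] = 10.0
        grid[10:13, 10:13] = 10.0
        spots = detect_spots(grid, _th(np.full((20, 20), 1.0)))
        assert len(spots) == 2

    def test_min_core_px_filters_small_components(self):
        grid = np.zeros((10, 10))
        grid[5, 5] = 10.0
        assert detect_spots(grid, _th(np.full((10, 10), 1.0)), min_core_px=2) == []
        assert len(detect_spots(grid, _th(np.full((10, 10), 1.0)), min_core_px=1)) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_components_match_flood_fill_oracle(self, seed):
        gen = np.random.default_rng(seed)
        mask = gen.random((64, 64)) < 0.18
        grid = mask.astype(float)
        spots = detect_spots(grid, _th(np.full((64, 64), 0.5)), min_core_px=1)
        got = {frozenset(map(tuple, s.core)) for s in spots}
        assert got == flood_fill_oracle(mask)

    def test_intensity_weighted_centroid(self):
        grid = np.zeros((10, 10))
        grid[4, 4] = 1.0
        grid[4, 5] = 3.0
        spots = detect_spots(grid, _th(np.full((10, 10), 0.5)), min_core_px=1)
        assert spots[0].centroid == (4.0, pytest.approx(4.75))


class TestEnlargeSpot:
    def test_center_pixel_sigma_25(self):
        s = Spot(id=0, core=np.array([[10, 10]]), image_shape=(21, 21))
        assert enlarge_spot(s).sigma == 25
        assert not s.border_flag

    def test_corner_pixel_clipped_to_9(self):
        s = Spot(id=0, core=np.array([[0, 0]]), image_shape=(21, 21))
        assert enlarge_spot(s).sigma == 9
        assert s.border_flag

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_neighborhood_union_oracle(self, seed):
        gen = np.random.default_rng(seed)
        shape = (30, 30)
        n = gen.integers(1, 20)
        pixels = np.unique(gen.integers(0, 30, size=(n, 2)), axis=0)
        s = enlarge_spot(Spot(id=0, core=pixels, image_shape=shape))
        assert {tuple(p) for p in s.enlarged} == dilation_oracle(map(tuple, pixels), shape)

    def test_empty_core_rejected(self):
        with pytest.raises(ValueError):
            enlarge_spot(Spot(id=0, core=np.empty((0, 2), dtype=int), image_shape=(5, 5)))


class TestIntegrateSpot:
    def test_uniform_values(self):
        grid = np.full((10, 10), 5.0)
        s = Spot(id=0, core=np.array([[5, 5]]), image_shape=(10, 10))
        s.enlarged = np.array([[5, 5], [5, 6], [6, 5], [6, 6]])
        integrate_spot(grid, s)
        assert s.i_int == 20.0
        assert s.i_max == 5.0

    def test_isolated_pixel(self):
        grid = np.zeros((11, 11))
        grid[5, 5] = 100.0
        s = enlarge_spot(Spot(id=0, core=np.array([[5, 5]]), image_shape=(11, 11)))
        integrate_spot(grid, s)
        assert s.i_int == 100.0
        assert s.i_max == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_sum_oracle(self, seed):
        gen = np.random.default_rng(seed)
        grid = gen.uniform(0, 10, size=(25, 25))
        pixels = np.unique(gen.integers(0, 25, size=(12, 2)), axis=0)
        s = enlarge_spot(Spot(id=0, core=pixels, image_shape=(25, 25)))
        integrate_spot(grid, s)
        assert s.i_int == pytest.approx(sum(grid[r, c] for r, c in s.enlarged), rel=1e-12)
        assert s.i_max == max(grid[r, c] for r, c in pixels)

    def test_enlarged_sum_at_least_core_sum(self, rng):
        grid = rng.uniform(0, 10, size=(25, 25))
        pixels = np.unique(rng.integers(2, 23, size=(8, 2)), axis=0)
        s = enlarge_spot(Spot(id=0, core=pixels, image_shape=(25, 25)))
        integrate_spot(grid, s)
        assert s.i_int >= grid[pixels[:, 0], pixels[:, 1]].sum()
        assert s.i_int >= s.i_max >= 0


# ---------------------------------------------------------------- background


class TestSampleBackground:
    def test_zero_image_zero_sums(self, rng):
        samples = sample_background(np.zeros((80, 80)), np.zeros((80, 80), bool), rng=rng)
        assert len(samples) == 100
        assert all(s.intensity == 0.0 for s in samples)
        assert all(10 <= s.sigma <= 100 for s in samples)

    def test_constant_background_integrates_exactly(self, rng):
        samples = sample_background(np.full((80, 80), 3.0), np.zeros((80, 80), bool),
                                    n_samples=20, rng=rng)
        for s in samples:
            assert s.intensity == pytest.approx(3.0 * s.sigma)

    def test_samples_avoid_occupied_masks_dense_scene(self):
        gen = np.random.default_rng(0)
        occupied = np.zeros((120, 120), bool)
        # adversarial scatter of occupied blocks, ~25% of the image
        for _ in range(60):
            r, c = gen.integers(0, 114, size=2)
            occupied[r : r + 6, c : c + 6] = True
        samples = sample_background(
            gen.uniform(0, 5, (120, 120)), occupied, n_samples=50, rng=gen
        )
        occ = {tuple(p) for p in np.argwhere(occupied)}
        for s in samples:
            assert not occ.intersection(map(tuple, s.pixels))

    def test_reproducible_under_seed(self):
        grid = np.random.default_rng(3).uniform(0, 5, (80, 80))
        a = sample_background(grid, np.zeros((80, 80), bool), seed=42)
        b = sample_background(grid, np.zeros((80, 80), bool), seed=42)
        assert [(s.sigma, s.intensity) for s in a] == [(s.sigma, s.intensity) for s in b]

    def test_insufficient_free_area_reports_occupancy(self, rng):
        occupied = np.ones((60, 60), bool)
        occupied[:4, :4] = False
        with pytest.raises(RuntimeError, match="free fraction"):
            sample_background(np.zeros((60, 60)), occupied, rng=rng)


class TestBackgroundModel:
    def test_exact_line_recovered(self):
        samples = [
            BackgroundSample(sigma=s, intensity=3.0 * s, pixels=np.empty((0, 2)))
            for s in range(10, 60, 5)
        ]
        model = fit_background_model(samples)
        assert model.a0 == pytest.approx(0.0, abs=1e-9)
        assert model.a1 == pytest.approx(3.0)

    def test_constant_scene_slope_near_level(self, rng):
        grid = np.full((80, 80), 2.5) + rng.normal(0, 0.01, (80, 80))
        samples = sample_background(grid, np.zeros((80, 80), bool), rng=rng)
        model = fit_background_model(samples)
        assert model.a1 == pytest.approx(2.5, rel=0.05)
        assert abs(model.a0) < 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        gen = np.random.default_rng(seed)
        sigma = gen.integers(10, 100, size=40)
        values = 20.0 + 2.0 * sigma + gen.normal(0, 3, size=40)
        samples = [
            BackgroundSample(sigma=int(s), intensity=float(v), pixels=np.empty((0, 2)))
            for s, v in zip(sigma, values)
        ]
        model = fit_background_model(samples)
        x = sigma.astype(float)
        n = len(x)
        sxx = (x**2).sum() - x.sum() ** 2 / n
        sxy = (x * values).sum() - x.sum() * values.sum() / n
        a1 = sxy / sxx
        a0 = values.mean() - a1 * x.mean()
        assert model.a1 == pytest.approx(a1, rel=1e-12)
        assert model.a0 == pytest.approx(a0, rel=1e-9)

    def test_too_few_samples(self):
        samples = [BackgroundSample(10, 1.0, np.empty((0, 2)))] * 5
        with pytest.raises(ValueError, match=">= 10"):
            fit_background_model(samples)

    def test_degenerate_sizes(self):
        samples = [BackgroundSample(20, float(i), np.empty((0, 2))) for i in range(12)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_background_model(samples)

    def test_negative_intercept_projected_to_origin(self):
        gen = np.random.default_rng(0)
        sigma = gen.integers(10, 100, size=30)
        values = np.clip(1.0 * sigma - 40.0, 0, None)  # strongly negative OLS intercept
        samples = [
            BackgroundSample(int(s), float(v), np.empty((0, 2))) for s, v in zip(sigma, values)
        ]
        model = fit_background_model(samples)
        assert model.a0 == 0.0
        assert model.predict(1.0) > 0


class TestNormalizeSpot:
    def model(self):
        return BackgroundModel(a0=0.0, a1=2.0)

    def spot_with(self, i_int, i_max, sigma=50):
        s = Spot(id=0, core=np.array([[1, 1]]), image_shape=(9, 9))
        s.sigma = sigma
        s.i_int = i_int
        s.i_max = i_max
        return s

    def test_itot_zero_when_equal_to_background(self):
        s = normalize_spot(self.spot_with(100.0, 10.0), self.model())  # I_BG(50) = 100
        assert s.i_tot == pytest.approx(0.0)

    def test_itot_one_at_twice_background(self):
        s = normalize_spot(self.spot_with(200.0, 10.0), self.model())
        assert s.i_tot == pytest.approx(1.0)

    def test_ipeak_formula(self):
        s = normalize_spot(self.spot_with(100.0, 6.0), self.model())  # I_BG(1) = 2
        assert s.i_peak == pytest.approx((6.0 - 2.0) / 2.0)

    def test_invalid_model_rejected(self):
        bad = BackgroundModel(a0=-10.0, a1=0.1)
        with pytest.raises(ValueError, match="non-positive"):
            normalize_spot(self.spot_with(10.0, 1.0, sigma=20), bad)


# ---------------------------------------------------------------- pipeline


class TestChannelPipeline:
    def scene(self, seed=21, **kwargs):
        params = dict(
            image_shape=(300, 300),
            n_vesicles=80,
            frac_colocalized=0.0,
            frac_blue_only=1.0,
            frac_red_only=0.0,
            seed=seed,
        )
        params.update(kwargs)
        return generate_scene(scene_for_snr(12, **params))

    def test_spot_count_non_increasing_in_sfr(self):
        frame, _ = self.scene()
        counts = []
        for sfr in (1.5, 2.0, 3.0, 4.0, 6.0, 10.0):
            cfg = dataclasses.replace(VAL_CFG, sfr=sfr)
            corrected, _ = preprocess(frame.blue, cfg)
            th = threshold_map(corrected, cfg.sfr)
            counts.append(len(detect_spots(corrected, th, min_core_px=cfg.min_core_px)))
        assert counts == sorted(counts, reverse=True)

    def test_recall_and_false_positives_on_good_scene(self):
        frame, truth = self.scene(seed=31, n_vesicles=150, image_shape=(400, 400))
        spots, *_ = analyze_channel(frame.blue, VAL_CFG, channel="blue", seed=7)
        matched, n_truth, n_spots = match_detections(spots, truth.rows, truth.cols)
        assert matched / n_truth >= 0.95
        assert (n_spots - matched) / n_spots <= 0.02

    def test_itot_proportional_to_flux(self):
        # noise kept tiny so the relation is essentially deterministic; a wide
        # flux spread keeps the mild spot-size dependence of the
        # normalization denominator negligible against the signal range
        frame, truth = generate_scene(
            scene_for_snr(
                15, weibull_shape=2.0, image_shape=(400, 400), n_vesicles=60,
                frac_colocalized=0.0, frac_blue_only=1.0, frac_red_only=0.0,
                noise_model=("gaussian", 0.5), seed=41,
            )
        )
        spots, *_ = analyze_channel(frame.blue, VAL_CFG, channel="blue", seed=9)
        cents = np.array([s.centroid for s in spots])
        flux, itot = [], []
        for r, c, f in zip(truth.rows, truth.cols, truth.flux_blue):
            d = np.hypot(cents[:, 0] - r, cents[:, 1] - c)
            j = int(np.argmin(d))
            if d[j] <= 2:
                flux.append(f)
                itot.append(spots[j].i_tot)
        assert len(flux) >= 50
        r = np.corrcoef(flux, itot)[0, 1]
        assert r**2 > 0.99

    def test_constant_offset_absorbed_by_background(self):
        # adding a constant to the raw image moves the baseline, not the
        # corrected grid, so spot normalization is unchanged
        frame, _ = self.scene(seed=51)
        spots_a, model_a, corr_a, bg_a = analyze_channel(frame.blue, VAL_CFG, seed=13)
        spots_b, model_b, corr_b, bg_b = analyze_channel(frame.blue + 50.0, VAL_CFG, seed=13)
        np.testing.assert_allclose(corr_a, corr_b, atol=1e-8)
        np.testing.assert_allclose(bg_b - bg_a, 50.0, atol=1e-8)
        assert len(spots_a) == len(spots_b)
        for sa, sb in zip(spots_a, spots_b):
            assert sb.i_tot == pytest.approx(sa.i_tot, rel=1e-6)

    def test_enlarged_superset_of_core(self):
        frame, _ = self.scene(seed=61)
        spots, *_ = analyze_channel(frame.blue, VAL_CFG, seed=15)
        for s in spots:
            core = {tuple(p) for p in s.core}
            enlarged = {tuple(p) for p in s.enlarged}
            assert core <= enlarged
            assert s.sigma >= s.core_size

    def test_occupied_mask_covers_spots(self):
        frame, _ = self.scene(seed=71)
        spots, *_ = analyze_channel(frame.blue, VAL_CFG, seed=17)
        occ = occupied_mask(frame.blue.shape, spots)
        for s in spots:
            assert occ[s.enlarged[:, 0], s.enlarged[:, 1]].all()
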