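import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal

from radpt import features as F
from radpt.features import (BatteryConfig, FeatureSpec, aggregate,
                            aggregate_over_roi, battery_map_ids, battery_specs,
                            collage_maps, dominant_orientation,
                            first_order_maps, gabor_bank, gabor_maps, glcm,
                            haralick_maps, haralick_stats, laws_kernels,
                            laws_maps, quantize)

# ---------------------------------------------------------------------------
# independent oracles (naive reimplementations, kept loop-based on purpose)
# ---------------------------------------------------------------------------

OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def naive_glcm(window, n_levels, offsets=OFFSETS):
    """Brute-force pair enumeration over a quantized window."""
    L = n_levels
    mat = np.zeros((L, L))
    h, w = window.shape
    for y in range(h):
        for x in range(w):
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    a, b = window[y, x], window[yy, xx]
                    mat[a, b] += 1
                    mat[b, a] += 1  # symmetric
    return mat / mat.sum()


def naive_haralick(p):
    """Literal transcription of the 13 co-occurrence statistics."""
    L = p.shape[0]
    idx = np.arange(L)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = sum(i * px[i] for i in idx)
    muy = sum(j * py[j] for j in idx)
    sx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in idx))
    sy = np.sqrt(sum((j - muy) ** 2 * py[j] for j in idx))
    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    for i in idx:
        for j in idx:
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]

    def ent(v):
        return -sum(x * np.log(x) for x in np.ravel(v) if x > 0)

    out = {}
    out["energy"] = (p ** 2).sum()
    out["contrast"] = sum(p[i, j] * (i - j) ** 2 for i in idx for j in idx)
    if sx > 0 and sy > 0:
        out["correlation"] = (
            sum(i * j * p[i, j] for i in idx for j in idx) - mux * muy
        ) / (sx * sy)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mux) ** 2 * p[i, j] for i in idx for j in idx)
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in idx for j in idx)
    ks = np.arange(2 * L - 1)
    out["sum_average"] = float(psum @ ks)
    out["sum_variance"] = float(((ks - out["sum_average"]) ** 2) @ psum)
    out["sum_entropy"] = ent(psum)
    hxy = ent(p)
    out["entropy"] = hxy
    kd = np.arange(L)
    davg = float(pdiff @ kd)
    out["difference_variance"] = float(((kd - davg) ** 2) @ pdiff)
    out["difference_entropy"] = ent(pdiff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i, j] * np.log(px[i] * py[j])
        for i in idx for j in idx if p[i, j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log(px[i] * py[j])
        for i in idx for j in idx if px[i] * py[j] > 0
    )
    out["info_measure_1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["info_measure_2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    return out


def naive_haralick_map_value(img, mask, y, x, window, n_levels):
    """Per-pixel oracle: quantize over the mask, window clipped at borders."""
    q = quantize(img, mask, n_levels)
    half = window // 2
    h, w = img.shape
    ys0, ys1 = max(0, y - half), min(h, y + half + 1)
    xs0, xs1 = max(0, x - half), min(w, x + half + 1)
    win = q[ys0:ys1, xs0:xs1]
    return naive_haralick(naive_glcm(win, n_levels))


# ---------------------------------------------------------------------------
# quantize / glcm / haralick
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_constant_roi_all_zero(self):
        img = np.full((6, 6), 4.2)
        assert np.all(quantize(img, np.ones_like(img, bool), 16) == 0)

    def test_two_values(self):
        img = np.array([[1.0, 5.0], [5.0, 1.0]])
        q = quantize(img, np.ones_like(img, bool), 2)
        assert set(q.ravel()) == {0, 1}

    def test_uniform_flat_histogram(self, rng):
        from scipy import stats

        img = rng.random((64, 64))
        q = quantize(img, np.ones_like(img, bool), 64)
        counts = np.bincount(q.ravel(), minlength=64)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_shift_invariance(self, rng):
        img = rng.random((8, 8))
        mask = np.ones_like(img, bool)
        assert np.array_equal(quantize(img, mask, 32),
                              quantize(img + 100.0, mask, 32))

    @given(
        img=hnp.arrays(np.float64, (6, 6),
                       elements=st.floats(-1e6, 1e6, allow_nan=False)),
        n_levels=st.integers(2, 64),
    )
    @settings(max_examples=50, deadline=None)
    def test_levels_always_in_range(self, img, n_levels):
        q = quantize(img, np.ones_like(img, dtype=bool), n_levels)
        assert q.min() >= 0
        assert q.max() <= n_levels - 1


class TestGLCM:
    def test_constant_window_single_cell(self):
        g = glcm(np.zeros((4, 4), dtype=int), n_levels=4)
        assert g[0, 0] == 1.0
        assert g.sum() == pytest.approx(1.0)

    def test_checkerboard_off_diagonal(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        g = glcm(board, offsets=((0, 1),), n_levels=2)
        assert g[0, 0] == 0 and g[1, 1] == 0
        assert g[0, 1] + g[1, 0] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        win = rng.integers(0, 5, size=(5, 5))
        g = glcm(win, n_levels=5)
        assert np.allclose(g, naive_glcm(win, 5), atol=0)

    def test_too_small_window_errors(self):
        with pytest.raises(ValueError, match="pairs"):
            glcm(np.zeros((1, 1), dtype=int), offsets=((5, 5),), n_levels=2)


class TestHaralickStats:
    def test_constant_image_values(self):
        g = glcm(np.zeros((5, 5), dtype=int), n_levels=8)
        st = haralick_stats(g)
        assert st["energy"] == pytest.approx(1.0)
        assert st["entropy"] == pytest.approx(0.0)
        assert st["contrast"] == pytest.approx(0.0)

    def test_uniform_glcm_entropy(self):
        L = 8
        g = np.full((L, L), 1.0 / L**2)
        st = haralick_stats(g)
        assert st["entropy"] == pytest.approx(2 * np.log(L))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_13_match_transcription_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((7, 7))
        p = (raw + raw.T)  # symmetric like the implementation's GLCMs
        p /= p.sum()
        got = haralick_stats(p)
        want = naive_haralick(p)
        for name in F.HARALICK_STATS:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestHaralickMaps:
    def test_constant_image(self):
        img = np.full((10, 10), 3.0)
        mask = np.ones_like(img, bool)
        maps = haralick_maps(img, mask, window_sizes=(3,), n_levels=8)
        assert np.allclose(maps["energy_w3"], 1.0)
        assert np.allclose(maps["entropy_w3"], 0.0)

    def test_interior_pixel_consistency(self, rng):
        img = rng.random((16, 16))
        mask = np.ones_like(img, bool)
        maps = haralick_maps(img, mask, window_sizes=(5,), n_levels=8)
        st = naive_haralick_map_value(img, mask, 8, 7, 5, 8)
        for name in F.HARALICK_STATS:
            assert maps[f"{name}_w5"][8, 7] == pytest.approx(st[name],
                                                             abs=1e-10), name

    def test_full_map_matches_naive_oracle(self, rng):
        img = rng.random((16, 16))
        mask = np.ones_like(img, bool)
        maps = haralick_maps(img, mask, window_sizes=(3,), n_levels=6)
        for y in range(16):
            for x in range(16):
                want = naive_haralick_map_value(img, mask, y, x, 3, 6)
                for name in F.HARALICK_STATS:
                    assert maps[f"{name}_w3"][y, x] == pytest.approx(
                        want[name], abs=1e-8), (name, y, x)

    def test_masked_region_nan_outside(self, rng):
        img = rng.random((12, 12))
        mask = np.zeros_like(img, bool)
        mask[4:8, 4:8] = True
        maps = haralick_maps(img, mask, window_sizes=(3,), n_levels=8)
        assert np.all(np.isnan(maps["entropy_w3"][~mask]))
        assert np.all(np.isfinite(maps["entropy_w3"][mask]))

    def test_intensity_shift_invariance(self, rng):
        img = rng.random((12, 12))
        mask = np.ones_like(img, bool)
        a = haralick_maps(img, mask, window_sizes=(3,), n_levels=8)
        b = haralick_maps(img + 57.0, mask, window_sizes=(3,), n_levels=8)
        for k in a:
            assert np.allclose(a[k], b[k], equal_nan=True)


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

class TestGabor:
    def test_bank_size_is_76(self):
        assert len(gabor_bank()) == 76

    def test_kernels_zero_dc_unit_norm(self):
        for _, k in gabor_bank():
            assert abs(k.sum()) < 1e-12
            assert np.linalg.norm(k) == pytest.approx(1.0)

    def test_constant_image_zero_response(self):
        img = np.full((40, 40), 9.0)
        for _, resp in gabor_maps(img):
            assert np.max(np.abs(resp)) < 1e-9

    def test_matched_grating_beats_orthogonal(self):
        lam, theta = 4.0, 0.6
        yy, xx = np.mgrid[0:48, 0:48]
        xr = xx * np.cos(theta) + yy * np.sin(theta)
        grating = np.cos(2 * np.pi * xr / lam)
        k_match = F.gabor_kernel(lam, theta)
        k_orth = F.gabor_kernel(lam, theta + np.pi / 2)
        r_match = np.abs(F._correlate2d_reflect(grating, k_match))[8:-8, 8:-8]
        r_orth = np.abs(F._correlate2d_reflect(grating, k_orth))[8:-8, 8:-8]
        assert r_match.mean() > 5 * r_orth.mean()

    def test_linearity(self, rng):
        img = rng.random((30, 30))
        bank = gabor_bank()[:3]
        r1 = [m for _, m in gabor_maps(img, bank)]
        r3 = [m for _, m in gabor_maps(3.0 * img, bank)]
        for a, b in zip(r1, r3):
            assert np.allclose(3.0 * a, b)

    def test_non76_bank_rejected(self):
        with pytest.raises(ValueError, match="76"):
            BatteryConfig(gabor_wavelengths=(3.0,), gabor_n_orientations=5)

    def test_non76_bank_allowed_with_flag(self):
        cfg = BatteryConfig(gabor_wavelengths=(3.0,), gabor_n_orientations=5,
                            allow_any_bank=True)
        assert len(gabor_bank(cfg)) == 5


# ---------------------------------------------------------------------------
# Laws
# ---------------------------------------------------------------------------

class TestLaws:
    def test_kernel_count_25(self):
        assert len(laws_kernels()) == 25
        assert len(laws_maps(np.zeros((8, 8)))) == 25

    def test_constant_image_responses(self):
        img = np.full((9, 9), 2.0)
        maps = laws_maps(img)
        for name, m in maps.items():
            if name == "L5L5":
                assert np.allclose(m, 2.0 * 256)
            elif name.startswith("L5") or name.endswith("L5"):
                continue  # one zero-sum factor -> 0, covered below
        zero_sum = [n for n in maps if "L5" not in n or n.count("L5") == 0]
        for name in zero_sum:
            assert np.allclose(maps[name], 0.0), name

    def test_zero_sum_kernels_kill_constants(self):
        img = np.full((9, 9), 5.0)
        maps = laws_maps(img)
        for name, m in maps.items():
            if name != "L5L5":
                assert np.allclose(m, 0.0), name

    def test_e5l5_on_vertical_ramp_hand_computed(self):
        # ramp img[y,x] = 0.5*y; E5 vertically x L5 horizontally:
        # response = slope * sum(L5) * sum(E5[k]*(k-2)) = 0.5 * 16 * 8 = 64
        img = 0.5 * np.arange(9)[:, None] * np.ones((1, 9))
        maps = laws_maps(img)
        interior = maps["E5L5"][2:-2, 2:-2]
        assert np.allclose(interior, 64.0)

    def test_matches_direct_correlation(self, rng):
        img = rng.random((12, 12))
        maps = laws_maps(img)
        for name, kern in laws_kernels().items():
            pad = np.pad(img, 2, mode="symmetric")
            want = signal.correlate2d(pad, kern, mode="valid")
            assert np.allclose(maps[name], want), name


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_image(self):
        img = np.full((8, 8), 3.3)
        maps, sig = first_order_maps(img, np.ones_like(img, bool))
        assert sig == pytest.approx(3.3)
        assert np.allclose(maps["mean3"], 3.3)
        assert np.allclose(maps["median5"], 3.3)
        for k in ("sd3", "range3", "sobel_x", "sobel_y", "sobel_mag"):
            assert np.allclose(maps[k], 0.0), k

    def test_ramp_sobel_constant(self):
        img = np.arange(10, dtype=float)[None, :] * np.ones((10, 1))
        maps, _ = first_order_maps(img, np.ones((10, 10), bool))
        assert np.allclose(maps["sobel_x"][1:-1, 1:-1], 8.0)  # 4*2*slope
        assert np.allclose(maps["sobel_y"][1:-1, 1:-1], 0.0)

    def test_matches_naive_loops(self, rng):
        img = rng.random((10, 10))
        maps, _ = first_order_maps(img, np.ones_like(img, bool))
        pad1 = np.pad(img, 1, mode="symmetric")
        pad2 = np.pad(img, 2, mode="symmetric")
        for y in range(10):
            for x in range(10):
                w3 = pad1[y:y + 3, x:x + 3]
                w5 = pad2[y:y + 5, x:x + 5]
                assert maps["mean3"][y, x] == pytest.approx(w3.mean())
                assert maps["median3"][y, x] == pytest.approx(np.median(w3))
                assert maps["sd3"][y, x] == pytest.approx(w3.std(), abs=1e-10)
                assert maps["range3"][y, x] == pytest.approx(np.ptp(w3))
                assert maps["mean5"][y, x] == pytest.approx(w5.mean())
                assert maps["median5"][y, x] == pytest.approx(np.median(w5))
                sob = np.outer([1, 2, 1], [-1, 0, 1])
                assert maps["sobel_x"][y, x] == pytest.approx((w3 * sob).sum())
                assert maps["sobel_y"][y, x] == pytest.approx((w3 * sob.T).sum())


# ---------------------------------------------------------------------------
# CoLlAGe
# ---------------------------------------------------------------------------

class TestCollage:
    def test_global_gradient_entropy_zero(self):
        img = np.arange(20, dtype=float)[None, :] * np.ones((20, 1))
        mask = np.ones((20, 20), bool)
        maps = collage_maps(img, mask)
        assert np.nanmax(np.abs(maps["entropy"])) <= 1e-6

    def test_rotation_equivariance_entropy(self, rng):
        img = rng.random((20, 20))
        img = np.asarray(np.kron(img, np.ones((2, 2))))  # smooth-ish
        mask = np.ones_like(img, bool)
        a = collage_maps(img, mask)["entropy"]
        b = collage_maps(np.rot90(img).copy(), mask)["entropy"]
        inner = slice(4, -4)
        assert np.allclose(np.rot90(a)[inner, inner], b[inner, inner],
                           atol=1e-8)

    def test_orientation_matches_eigen_oracle(self, rng):
        img = rng.random((16, 16))
        theta = dominant_orientation(img, window=5)
        gy, gx = np.gradient(img)
        pad = 2
        gxp = np.pad(gx, pad, mode="symmetric")
        gyp = np.pad(gy, pad, mode="symmetric")
        for y in range(2, 14):
            for x in range(2, 14):
                wx = gxp[y:y + 5, x:x + 5].ravel()
                wy = gyp[y:y + 5, x:x + 5].ravel()
                Jm = np.array([[wx @ wx, wx @ wy], [wx @ wy, wy @ wy]])
                evals, evecs = np.linalg.eigh(Jm)
                v = evecs[:, np.argmax(evals)]
                want = np.mod(np.arctan2(v[1], v[0]), np.pi)
                got = theta[y, x]
                diff = min(abs(got - want), np.pi - abs(got - want))
                assert diff < 1e-8

    def test_zero_gradient_bin_zero(self):
        img = np.full((10, 10), 1.0)
        theta = dominant_orientation(img, 5)
        assert np.all(theta == 0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregate:
    def test_constant_map(self):
        m = np.full((5, 5), 2.5)
        roi = np.ones_like(m, bool)
        assert aggregate_over_roi(m, roi, "mean") == pytest.approx(2.5)
        assert aggregate_over_roi(m, roi, "sd") == pytest.approx(0.0)

    def test_normal_kurtosis_three(self, rng):
        v = rng.standard_normal(100_000)
        assert aggregate(v, "kurtosis") == pytest.approx(3.0, abs=0.1)
        assert aggregate(v, "skewness") == pytest.approx(0.0, abs=0.05)

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty ROI"):
            aggregate_over_roi(np.ones((3, 3)), np.zeros((3, 3), bool), "mean")


# ---------------------------------------------------------------------------
# battery enumeration / naming
# ---------------------------------------------------------------------------

class TestBattery:
    def test_150_maps_per_sequence_per_roi(self):
        assert len(battery_map_ids(BatteryConfig())) == 150

    def test_family_counts_match_composition(self):
        ids = battery_map_ids(BatteryConfig())
        fams = [f for f, _ in ids]
        assert fams.count("signal") == 1
        assert fams.count("first_order") == 9
        assert fams.count("gabor") == 76
        assert fams.count("haralick") == 39
        assert fams.count("laws") == 25

    def test_collage_adds_13(self):
        ids = battery_map_ids(BatteryConfig(include_collage=True))
        assert len(ids) == 163

    def test_full_spec_enumeration(self):
        specs = battery_specs()
        assert len(specs) == 150 * 2 * 5
        names = [s.name for s in specs]
        assert len(set(names)) == len(names)  # unique

    def test_names_roundtrip(self):
        for spec in battery_specs()[::97]:
            back = FeatureSpec.from_name(spec.name)
            assert back == spec

    def test_four_aggregators_quadruple_columns(self):
        cfg = BatteryConfig(aggregators=("mean", "sd", "skewness", "kurtosis"))
        assert len(battery_specs(cfg)) == 150 * 2 * 5 * 4
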