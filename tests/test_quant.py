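"""Intensity quantifications: N:C ratio, PZ counting, assay arithmetic."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from gspcmitosis.quant import (
    assay_ratios,
    count_pz_nuclei,
    embryonic_lethality,
    error_rate_exact_test,
    measure_depletion_fi,
    measure_nc_ratio,
    mitotic_index,
    premitotic_nc,
    PZCount,
)
from gspcmitosis.synthetic import (
    NucleusRenderParams,
    PZFieldParams,
    render_nucleus_image,
    simulate_pz_stack,
)

CENTER = (8.0, 8.0)  # default render places the nucleus mid-image (16 μm field)


class TestNCRatio:
    def test_analytic_disk_annulus(self):
        img, _ = render_nucleus_image(NucleusRenderParams())
        m = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=0.0)
        assert m.nc_ratio == pytest.approx(2.0)

    def test_background_invariance(self):
        img, _ = render_nucleus_image(NucleusRenderParams(background_intensity=50.0))
        m = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=50.0)
        assert m.nc_ratio == pytest.approx(2.0)

    def test_affine_intensity_invariance(self):
        img, _ = render_nucleus_image(NucleusRenderParams())
        m1 = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=0.0)
        m2 = measure_nc_ratio(img * 3.0 + 20.0, CENTER, pixel_size=0.1,
                              background_value=20.0)
        assert m2.nc_ratio == pytest.approx(m1.nc_ratio)

    def test_background_from_rectangular_rois(self):
        img, _ = render_nucleus_image(NucleusRenderParams(background_intensity=7.0))
        # corners of the 160x160 px field are outside the 9 μm cell
        rois = [(0, 0, 10, 10), (0, 150, 10, 160), (150, 0, 160, 10)]
        m = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_rois=rois)
        assert m.background_fi == pytest.approx(7.0)
        assert m.nc_ratio == pytest.approx(2.0)

    def test_neighbor_exclusion_matches_mask_oracle_within_1pct(self):
        params = NucleusRenderParams(neighbor_centers=((12.6, 8.0), (8.0, 3.4)),
                                     noise_sd=2.0, seed=5)
        img, masks = render_nucleus_image(params)
        m = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=0.0,
                             neighbor_masks=[masks["neighbors"]])
        # oracle: classify pixels by the ground-truth masks
        r_out = (params.nucleus_diameter / 2 + 1.0)
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        dist2 = ((xx + 0.5) * 0.1 - 8.0) ** 2 + ((yy + 0.5) * 0.1 - 8.0) ** 2
        annulus = (dist2 <= r_out ** 2) & ~masks["nucleus"] & ~masks["neighbors"]
        want = img[masks["nucleus"]].mean() / img[annulus].mean()
        assert m.nc_ratio == pytest.approx(want, rel=0.01)

    def test_annulus_fully_covered_by_neighbors_errors(self):
        img, _ = render_nucleus_image(NucleusRenderParams())
        with pytest.raises(ValueError, match="annulus"):
            measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=0.0,
                             neighbor_masks=[np.ones_like(img, bool)])

    def test_cytoplasm_at_background_flagged_undefined(self):
        img = np.full((160, 160), 10.0)
        m = measure_nc_ratio(img, CENTER, pixel_size=0.1, background_value=10.0)
        assert math.isnan(m.nc_ratio)
        assert "cytoplasm_at_or_below_background" in m.flags

    def test_roi_outside_image_rejected(self):
        img = np.zeros((40, 40))
        with pytest.raises(ValueError, match="outside image"):
            measure_nc_ratio(img, (1.0, 1.0), pixel_size=0.1, background_value=0.0)


class TestPremitoticNC:
    def test_mean_of_top3_eligible(self):
        t = np.array([0.0, 2.0, 4.0, 6.0, 20.0])
        r = np.array([1.0, 1.5, 2.0, 2.5, 9.9])  # last frame not eligible
        val, flags = premitotic_nc(t, r, t_nebd=16.0)
        assert val == pytest.approx(np.mean([2.5, 2.0, 1.5]))
        assert not flags

    def test_all_equal_values(self):
        val, _ = premitotic_nc([0.0, 1.0, 2.0], [1.3, 1.3, 1.3], t_nebd=20.0)
        assert val == pytest.approx(1.3)

    def test_fewer_than_three_flagged(self):
        val, flags = premitotic_nc([0.0, 1.0], [1.0, 2.0], t_nebd=10.0 + 1.0)
        assert val == pytest.approx(1.5)
        assert "fewer_than_3_premitotic_frames" in flags

    def test_no_eligible_frames_errors(self):
        with pytest.raises(ValueError, match="before NEBD"):
            premitotic_nc([5.0], [1.0], t_nebd=10.0)

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            t = np.sort(rng.uniform(0, 30, 15))
            r = rng.uniform(0.5, 3.0, 15)
            t_nebd = rng.uniform(15, 29)
            elig = sorted(r[t <= t_nebd - 10.0], reverse=True)
            if not elig:
                continue
            val, _ = premitotic_nc(t, r, t_nebd)
            assert val == pytest.approx(sum(elig[:3]) / len(elig[:3]))


class TestPZCounting:
    def test_truly_empty_stack_counts_zero(self):
        stack, _ = simulate_pz_stack(PZFieldParams(n_nuclei=0, snr=np.inf))
        count, centers = count_pz_nuclei(stack, pixel_size_xy=0.4, z_step=0.75)
        assert count == 0 and centers.shape == (0, 3)

    def test_noise_only_field_counts_zero(self):
        stack, _ = simulate_pz_stack(PZFieldParams(n_nuclei=0, snr=5, seed=8))
        count, _ = count_pz_nuclei(stack, pixel_size_xy=0.4, z_step=0.75)
        assert count == 0

    def test_well_separated_noise_free_blobs_counted_exactly(self):
        params = PZFieldParams(n_nuclei=50, snr=np.inf, min_spacing=7.0, seed=1)
        stack, _ = simulate_pz_stack(params)
        count, _ = count_pz_nuclei(stack, pixel_size_xy=0.4, z_step=0.75)
        assert count == 50

    def test_intensity_rescale_invariance(self):
        params = PZFieldParams(n_nuclei=30, snr=8, min_spacing=6.0, seed=5)
        stack, _ = simulate_pz_stack(params)
        c1, _ = count_pz_nuclei(stack, pixel_size_xy=0.4, z_step=0.75)
        c2, _ = count_pz_nuclei(stack * 41.7, pixel_size_xy=0.4, z_step=0.75)
        assert c1 == c2

    def test_pz_roi_restricts_count(self):
        params = PZFieldParams(n_nuclei=30, snr=np.inf, min_spacing=7.0, seed=2)
        stack, centers = simulate_pz_stack(params)
        roi = (0.0, 0.0, 42.5, 35.0)  # left half of the 85 μm field
        count, _ = count_pz_nuclei(stack, pixel_size_xy=0.4, z_step=0.75, pz_roi=roi)
        want = ((centers[:, 0] >= 0) & (centers[:, 0] < 42.5)).sum()
        assert abs(count - want) <= 1  # jittered tracks near the cut line

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            count_pz_nuclei(np.zeros((3, 8, 20, 20)), pixel_size_xy=0.4, z_step=0.75)

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel sizes"):
            count_pz_nuclei(np.zeros((6, 8, 20, 20)), pixel_size_xy=0.0, z_step=0.75)


class TestRatios:
    def test_mitotic_index_examples(self):
        assert mitotic_index(10, 200) == pytest.approx(0.05)
        assert mitotic_index(0, 200) == 0.0

    def test_mitotic_exceeding_nuclei_rejected(self):
        with pytest.raises(ValueError):
            mitotic_index(10, 5)
        with pytest.raises(ValueError):
            PZCount(n_pz_nuclei=5, n_mitotic=10)

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            mitotic_index(0, 0)

    def test_error_class_percentages(self):
        out = assay_ratios({"none": 18, "meta": 1, "ana": 1})
        assert out == {"none": 90.0, "meta": 5.0, "ana": 5.0}
        assert sum(out.values()) == pytest.approx(100.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assay_ratios({"a": -1, "b": 2})

    def test_lethality(self):
        assert embryonic_lethality(0, 120) == 0.0
        assert embryonic_lethality(30, 120) == pytest.approx(25.0)

    def test_exact_test_matches_hypergeometric_enumeration(self):
        a, na, b, nb = 7, 20, 1, 18
        p = error_rate_exact_test(a, na, b, nb)
        # brute-force: enumerate all tables with fixed margins
        total_err = a + b
        n_tot = na + nb
        probs = {k: hypergeom.pmf(k, n_tot, total_err, na)
                 for k in range(max(0, total_err - nb), min(na, total_err) + 1)}
        p_obs = probs[a]
        want = sum(v for v in probs.values() if v <= p_obs + 1e-12)
        assert p == pytest.approx(want, rel=1e-6)


class TestDepletion:
    def test_three_roi_means_minus_background_normalized(self):
        img = np.zeros((30, 30))
        img[0:10, 0:10] = 10.0
        img[0:10, 10:20] = 12.0
        img[0:10, 20:30] = 14.0
        rois = [(0, 0, 10, 10), (0, 10, 10, 20), (0, 20, 10, 30)]
        val = measure_depletion_fi(img, rois, background_value=6.0)
        assert val == pytest.approx(6.0)
        assert measure_depletion_fi(img, rois, 6.0, reference_group_mean=12.0) \
            == pytest.approx(0.5)

    def test_fi_at_background_clamped_to_zero(self):
        img = np.full((20, 20), 5.0)
        val = measure_depletion_fi(img, [(0, 0, 5, 5)], background_value=5.0)
        assert val == 0.0

    def test_nonpositive_reference_rejected(self):
        img = np.full((20, 20), 9.0)
        with pytest.raises(ValueError, match="reference"):
            measure_depletion_fi(img, [(0, 0, 5, 5)], 1.0, reference_group_mean=0.0)

    def test_matches_pixel_mean_oracle(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 50, (40, 40))
        rois = [(2, 3, 12, 15), (20, 5, 30, 17), (8, 25, 18, 37)]
        want = np.mean([img[a:c, b:d].mean() for a, b, c, d in rois]) - 4.0
        assert measure_depletion_fi(img, rois, 4.0) == pytest.approx(max(want, 0.0))
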