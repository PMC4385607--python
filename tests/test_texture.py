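"""Unit and property tests of the LBP / contrast operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wmtex as w
from helpers_reference import (
    ref_contrast,
    ref_riu2_code,
    ref_texture_slice,
    ref_uniformity,
)

SPEC81 = w.NeighborhoodSpec(8, 1)


class TestNeighborhoodGeometry:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            w.NeighborhoodSpec(1, 1.0)
        with pytest.raises(ValueError):
            w.NeighborhoodSpec(8, 0.0)

    @pytest.mark.parametrize(
        "P,R,p,expected",
        [
            (8, 1, 0, (0.0, 1.0)),
            (8, 1, 2, (-1.0, 0.0)),
            (12, 2, 3, (-2.0, 0.0)),
            (8, 1, 4, (0.0, -1.0)),
        ],
    )
    def test_neighbor_coordinates(self, P, R, p, expected):
        coords = w.neighbor_coordinates(w.NeighborhoodSpec(P, R))
        assert coords.shape == (P, 2)
        np.testing.assert_allclose(coords[p], expected, atol=1e-12)

    def test_axis_aligned_offsets_are_exact_integers(self):
        coords = w.neighbor_coordinates(SPEC81)
        for p in (0, 2, 4, 6):
            assert coords[p][0] == int(coords[p][0])
            assert coords[p][1] == int(coords[p][1])


class TestSampling:
    def test_constant_slice(self):
        s = w.sample_neighborhood(np.full((5, 5), 7.0), (2, 2), SPEC81)
        assert s.g_c == 7.0
        np.testing.assert_array_equal(s.g, np.full(8, 7.0))

    def test_column_ramp_direct_and_bilinear(self):
        ramp = np.tile(np.arange(6.0), (6, 1))
        s = w.sample_neighborhood(ramp, (2, 2), SPEC81)
        assert s.g[0] == 3.0  # integer offset (0, 1): direct read
        assert s.g[1] == pytest.approx(2.0 + np.sqrt(2) / 2)  # hand bilinear

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="slice bounds"):
            w.sample_neighborhood(np.zeros((5, 5)), (0, 2), SPEC81)


class TestBitOperators:
    def test_sign_threshold_tie_is_one(self):
        s = w.NeighborhoodSample(g_c=3.0, g=np.full(8, 3.0))
        np.testing.assert_array_equal(w.sign_threshold(s), np.ones(8, np.uint8))

    def test_sign_threshold_mixed(self):
        s = w.NeighborhoodSample(g_c=3.0, g=np.array([5, 5, 5, 5, 1, 1, 1, 1.0]))
        np.testing.assert_array_equal(w.sign_threshold(s), [1, 1, 1, 1, 0, 0, 0, 0])

    @pytest.mark.parametrize(
        "bits,code",
        [([1] * 8, 255), ([0] * 8, 0), ([0, 0, 0, 1, 0, 0, 0, 0], 8)],
    )
    def test_lbp_code(self, bits, code):
        assert w.lbp_code(bits) == code
        np.testing.assert_array_equal(w.bits_from_code(code, 8), bits)

    @pytest.mark.parametrize(
        "x,i,P,expected",
        [(1, 0, 8, 1), (1, 1, 8, 128), (0b00000011, 1, 8, 0b10000001)],
    )
    def test_ror(self, x, i, P, expected):
        assert w.ror(x, i, P) == expected

    @pytest.mark.parametrize(
        "x,P,expected", [(0, 8, 0), (255, 8, 255), (0b10000000, 8, 1)]
    )
    def test_rotation_invariant_code(self, x, P, expected):
        assert w.rotation_invariant_code(x, P) == expected

    @pytest.mark.parametrize(
        "code,circular,linear",
        [
            (0b00000000, 0, 0),
            (0b11111111, 0, 0),
            (0b00000011, 2, 1),  # the wrap term: prose reading counts 1
            (0b10000111, 2, 2),
            (0b10101010, 8, 7),
        ],
    )
    def test_uniformity_both_conventions(self, code, circular, linear):
        bits = w.bits_from_code(code, 8)
        assert w.uniformity(bits) == circular
        assert w.uniformity_linear(bits) == linear

    @pytest.mark.parametrize(
        "code,expected",
        [(0b11111111, 8), (0b00000000, 0), (0b10101010, 9)],
    )
    def test_riu2_code(self, code, expected):
        assert w.riu2_code(w.bits_from_code(code, 8)) == expected

    def test_local_contrast(self):
        s = w.NeighborhoodSample(g_c=0.0, g=np.array([0, 0, 0, 0, 2, 2, 2, 2.0]))
        assert w.local_contrast(s) == pytest.approx(1.0)
        shifted = w.NeighborhoodSample(g_c=5.0, g=s.g + 5.0)
        assert w.local_contrast(shifted) == pytest.approx(1.0)
        assert w.local_contrast(w.NeighborhoodSample(0.0, np.full(8, 3.0))) == 0.0


@settings(derandomize=True, max_examples=200)
@given(x=st.integers(0, 255), i=st.integers(0, 16))
def test_ror_roundtrip_and_ri_properties(x, i):
    assert w.ror(w.ror(x, i, 8), 8 - (i % 8), 8) == x
    ri = w.rotation_invariant_code(x, 8)
    assert ri <= x
    assert w.rotation_invariant_code(ri, 8) == ri  # idempotent on its outputs
    # ri is constant on the rotation orbit
    assert w.rotation_invariant_code(w.ror(x, i, 8), 8) == ri


@settings(derandomize=True, max_examples=200)
@given(code=st.integers(0, 2**12 - 1))
def test_riu2_matches_reference_p12(code):
    bits = w.bits_from_code(code, 12)
    assert w.uniformity(bits) == ref_uniformity(list(bits))
    assert w.riu2_code(bits) == ref_riu2_code(list(bits))


def test_riu2_label_set_is_exactly_0_to_9():
    labels = {w.riu2_code(w.bits_from_code(c, 8)) for c in range(256)}
    assert labels == set(range(10))
    # exactly P+1 uniform patterns map below the miscellaneous label... per orbit:
    uniform_counts = [w.riu2_code(w.bits_from_code(c, 8)) for c in range(256)]
    assert sorted(set(u for u in uniform_counts if u <= 8)) == list(range(9))


class TestTextureMaps:
    @pytest.mark.parametrize("variant", ["ri", "riu2"])
    def test_constant_volume(self, variant):
        vol = np.full((10, 10, 3), 5.0)
        mask = np.zeros_like(vol, bool)
        mask[3:7, 3:7, :] = True
        maps = w.compute_texture_maps(vol, mask, SPEC81, variant=variant)
        all_ones = w.lbp_code([1] * 8)
        expected = (
            w.rotation_invariant_code(all_ones, 8)
            if variant == "ri"
            else w.riu2_code([1] * 8)
        )
        assert set(maps.lbp) == {expected}
        np.testing.assert_array_equal(maps.contrast, 0.0)

    def test_single_voxel_mask(self, rng):
        vol = rng.normal(size=(9, 9, 3))
        mask = np.zeros_like(vol, bool)
        mask[4, 4, 1] = True
        maps = w.compute_texture_maps(vol, mask, SPEC81)
        assert len(maps) == 1
        assert maps.n_skipped == 0
        np.testing.assert_array_equal(maps.voxels[0], [4, 4, 1])

    def test_border_voxels_skipped_not_padded(self, rng):
        vol = rng.normal(size=(8, 8, 2))
        mask = np.ones_like(vol, bool)
        spec = w.NeighborhoodSpec(8, 2.0)
        maps = w.compute_texture_maps(vol, mask, spec)
        assert maps.n_skipped == 2 * (64 - 16)  # only the 4x4 core survives per slice
        assert len(maps) == 2 * 16

    def test_errors(self, rng):
        vol = rng.normal(size=(8, 8, 2))
        with pytest.raises(ValueError, match="empty"):
            w.compute_texture_maps(vol, np.zeros_like(vol, bool), SPEC81)
        with pytest.raises(ValueError, match="differ"):
            w.compute_texture_maps(vol, np.ones((8, 8, 3), bool), SPEC81)

    @pytest.mark.parametrize("variant", ["ri", "riu2"])
    @pytest.mark.parametrize("spec", [SPEC81, w.NeighborhoodSpec(12, 2.0)])
    def test_matches_brute_force_oracle(self, rng, variant, spec):
        """Vectorized maps equal a literal per-pixel evaluation."""
        vol = rng.normal(size=(16, 16, 2))
        mask = np.zeros_like(vol, bool)
        mask[1:15, 1:15, :] = True
        maps = w.compute_texture_maps(vol, mask, spec, variant=variant)
        got = {
            tuple(vx): (code, con)
            for vx, code, con in zip(maps.voxels, maps.lbp, maps.contrast)
        }
        n_checked = 0
        for s in range(2):
            ref = ref_texture_slice(vol[:, :, s], mask[:, :, s], spec.P, spec.R, variant)
            for (r, c), (code, con) in ref.items():
                assert got[(r, c, s)][0] == code
                assert got[(r, c, s)][1] == pytest.approx(con, abs=1e-12)
                n_checked += 1
        assert n_checked == len(maps)

    def test_gray_shift_invariance(self, small_volume):
        vol, mask = small_volume
        for variant in ("ri", "riu2"):
            a = w.compute_texture_maps(vol, mask, SPEC81, variant=variant)
            b = w.compute_texture_maps(vol + 37.5, mask, SPEC81, variant=variant)
            np.testing.assert_array_equal(a.lbp, b.lbp)
            np.testing.assert_allclose(a.contrast, b.contrast, atol=1e-9)

    def test_monotone_affine_invariance(self, small_volume):
        """Positive affine transforms commute with bilinear sampling exactly."""
        vol, mask = small_volume
        a = w.compute_texture_maps(vol, mask, SPEC81, variant="riu2")
        b = w.compute_texture_maps(3.0 * vol + 17.0, mask, SPEC81, variant="riu2")
        np.testing.assert_array_equal(a.lbp, b.lbp)

    def test_monotone_nonlinear_invariance_exact_sampling(self, small_volume):
        """General strictly increasing transforms leave LBP maps identical
        wherever samples are exact pixel reads (all-integer offsets, P=4 R=1)."""
        vol, mask = small_volume
        spec = w.NeighborhoodSpec(4, 1.0)
        a = w.compute_texture_maps(vol, mask, spec, variant="ri")
        b = w.compute_texture_maps(vol**3, mask, spec, variant="ri")
        np.testing.assert_array_equal(a.lbp, b.lbp)

    def test_rotation_invariance_of_code_multiset(self, rng):
        """90-degree slice rotation permutes, but preserves, the ri codes."""
        vol = rng.normal(size=(16, 16, 1))
        mask = np.zeros_like(vol, bool)
        mask[3:13, 3:13, :] = True
        a = w.compute_texture_maps(vol, mask, SPEC81, variant="ri")
        vol_r = np.rot90(vol, axes=(0, 1)).copy()
        mask_r = np.rot90(mask, axes=(0, 1)).copy()
        b = w.compute_texture_maps(vol_r, mask_r, SPEC81, variant="ri")
        assert sorted(a.lbp) == sorted(b.lbp)

    def test_slice_axis_choices_agree(self, rng):
        vol = rng.normal(size=(12, 12, 12))
        mask = np.zeros_like(vol, bool)
        mask[4:8, 4:8, 4:8] = True
        a = w.compute_texture_maps(vol, mask, SPEC81, slice_axis=2)
        b = w.compute_texture_maps(
            np.moveaxis(vol, 2, 0).copy(), np.moveaxis(mask, 2, 0).copy(),
            SPEC81, slice_axis=0,
        )
        assert sorted(a.lbp) == sorted(b.lbp)
        np.testing.assert_allclose(sorted(a.contrast), sorted(b.contrast))
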