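"""Skin masks, cylinder placement and masks, pairwise comparison masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepclust import (
    CylinderRegion,
    GridSpec,
    RegionMask,
    SkinParams,
    compute_skin_mask,
    cylinder_mask,
    pair_mask,
    place_cylinder,
)
from mepclust.errors import DataError, EmptyMaskError

from conftest import structure_from_coords


def line_spec(x0, n, spacing=1.0):
    """1-D lattice along x at y = z = 0."""
    return GridSpec(origin=(x0, 0.0, 0.0), spacing=spacing, dims=(n, 1, 1))


class TestSkinMask:
    def test_single_atom_inclusion_boundaries(self):
        # R=1.5, sigma=1 -> SAS at 2.5; delta=25 -> outer bound 27.5
        s = structure_from_coords([[0, 0, 0]])
        s.atoms[0].radius = 1.5
        spec = line_spec(2.0, 27)  # x = 2..28
        mask = compute_skin_mask(s, spec, SkinParams(probe_radius=1.0, thickness=25.0))
        included_x = {2.0 + i for i in range(27) if mask.included[i, 0, 0]}
        assert 2.0 not in included_x  # inside the SAS
        assert 3.0 in included_x
        assert 27.0 in included_x  # 27 - 2.5 = 24.5 <= 25
        assert 28.0 not in included_x  # 25.5 > 25

    def test_huge_thickness_gives_sas_complement(self):
        s = structure_from_coords([[0, 0, 0]])
        s.atoms[0].radius = 1.5
        spec = GridSpec(origin=(-6.0, -6.0, -6.0), spacing=1.0, dims=(13, 13, 13))
        mask = compute_skin_mask(s, spec, SkinParams(probe_radius=1.0, thickness=1e9))
        dist = np.linalg.norm(spec.points(), axis=1).reshape(spec.shape)
        np.testing.assert_array_equal(mask.included, dist > 2.5)

    def test_point_inside_either_atoms_sas_is_excluded(self):
        s = structure_from_coords([[0, 0, 0], [6, 0, 0]])
        for a in s.atoms:
            a.radius = 1.5
        spec = line_spec(0.0, 10)
        mask = compute_skin_mask(s, spec, SkinParams(probe_radius=1.0, thickness=25.0))
        xs_included = {float(i) for i in range(10) if mask.included[i, 0, 0]}
        # expected: strictly outside min over both SAS spheres, within delta
        expected = set()
        for i in range(10):
            d = min(abs(i - 0), abs(i - 6)) - 2.5
            if 0 < d <= 25:
                expected.add(float(i))
        assert xs_included == expected

    def test_empty_skin_is_an_error(self):
        s = structure_from_coords([[100.0, 100.0, 100.0]])
        s.atoms[0].radius = 1.5
        spec = line_spec(0.0, 3)
        with pytest.raises(EmptyMaskError):
            compute_skin_mask(s, spec, SkinParams(probe_radius=1.0, thickness=2.0))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_skin_invariant_to_atom_order(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=3.0, size=(6, 3))
        spec = GridSpec(origin=(-8.0, -8.0, -8.0), spacing=2.0, dims=(9, 9, 9))
        s1 = structure_from_coords(coords)
        s2 = structure_from_coords(coords[rng.permutation(6)])
        m1 = compute_skin_mask(s1, spec, SkinParams(1.0, 10.0))
        m2 = compute_skin_mask(s2, spec, SkinParams(1.0, 10.0))
        np.testing.assert_array_equal(m1.included, m2.included)

    def test_single_atom_count_matches_shell_volume(self):
        # oracle: analytic spherical-shell volume times lattice density
        s = structure_from_coords([[0, 0, 0]])
        s.atoms[0].radius = 1.5
        sigma, delta, spacing = 1.0, 5.0, 0.5
        half = 9.0
        n = int(2 * half / spacing) + 1
        spec = GridSpec(origin=(-half, -half, -half), spacing=spacing, dims=(n, n, n))
        mask = compute_skin_mask(s, spec, SkinParams(sigma, delta))
        r_in, r_out = 1.5 + sigma, 1.5 + sigma + delta
        volume = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
        expected = volume / spacing**3
        assert mask.count == pytest.approx(expected, rel=0.05)


class TestCylinder:
    def test_mask_boundary_conventions(self):
        cyl = CylinderRegion(center=(0, 0, 0), axis=(0, 0, 1), radius=4.0, length=6.0)
        spec = GridSpec(origin=(-6.0, 0.0, -5.0), spacing=1.0, dims=(13, 1, 11))
        mask = cylinder_mask(spec, cyl)
        at = lambda x, z: mask.included[int(x + 6), 0, int(z + 5)]
        assert at(0, 0)  # center
        assert at(4, 0)  # radial distance exactly r
        assert not at(5, 0)  # r + spacing
        assert at(0, 3)  # axial offset exactly L/2
        assert not at(0, 4)  # L/2 + spacing

    def test_empty_cylinder_mask_is_an_error(self):
        cyl = CylinderRegion(center=(100, 100, 100), axis=(0, 0, 1), radius=1.0, length=1.0)
        spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(3, 3, 3))
        with pytest.raises(EmptyMaskError):
            cylinder_mask(spec, cyl)

    def test_explicit_override_passes_through(self):
        ref = structure_from_coords([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        cyl = place_cylinder(ref, center=(1, 2, 3), axis=(0, 1, 0), radius=7, length=9)
        assert cyl.center == (1.0, 2.0, 3.0)
        assert cyl.axis == (0.0, 1.0, 0.0)
        assert (cyl.radius, cyl.length) == (7, 9)

    def test_planar_peptide_gives_plane_normal_axis(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(scale=4, size=(9, 2))
        coords = np.column_stack([xy, np.zeros(9)])
        ref = structure_from_coords(coords, chain="P")
        cyl = place_cylinder(ref)
        np.testing.assert_allclose(np.abs(cyl.axis), [0, 0, 1], atol=1e-12)
        assert cyl.axis[2] > 0  # canonical sign

    def test_center_is_peptide_centroid(self):
        coords = np.array([[1.0 + i * 0.1, 2.0 - i * 0.05, 3.0 + (i % 2)] for i in range(9)])
        ref = structure_from_coords(coords, chain="P")
        cyl = place_cylinder(ref)
        np.testing.assert_allclose(cyl.center, coords.mean(axis=0))

    def test_no_peptide_chain_and_no_override_is_an_error(self):
        ref = structure_from_coords(np.random.default_rng(1).normal(size=(20, 3)))
        with pytest.raises(DataError):
            place_cylinder(ref)

    def test_axis_is_normalised(self):
        cyl = CylinderRegion(center=(0, 0, 0), axis=(0, 0, 5.0), radius=1, length=1)
        assert cyl.axis == (0.0, 0.0, 1.0)


class TestPairMask:
    def spec(self):
        return GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(4, 1, 1))

    def mask_from_bits(self, bits):
        return RegionMask(self.spec(), np.array(bits, dtype=bool).reshape(4, 1, 1))

    def test_idempotent_with_full_cylinder(self):
        m = self.mask_from_bits([1, 0, 1, 0])
        full = self.mask_from_bits([1, 1, 1, 1])
        np.testing.assert_array_equal(pair_mask(m, m, full).included, m.included)

    def test_commutative_and_bounded(self):
        a = self.mask_from_bits([1, 1, 0, 0])
        b = self.mask_from_bits([0, 1, 1, 0])
        full = self.mask_from_bits([1, 1, 1, 1])
        ab = pair_mask(a, b, full)
        ba = pair_mask(b, a, full)
        np.testing.assert_array_equal(ab.included, ba.included)
        assert ab.count <= min(a.count, b.count, full.count)

    def test_disjoint_skins_raise_naming_the_pair(self):
        a = self.mask_from_bits([1, 1, 0, 0])
        b = self.mask_from_bits([0, 0, 1, 1])
        full = self.mask_from_bits([1, 1, 1, 1])
        with pytest.raises(EmptyMaskError, match="left.*right"):
            pair_mask(a, b, full, labels=("left", "right"))

    def test_mismatched_specs_cannot_combine(self):
        a = self.mask_from_bits([1, 1, 1, 1])
        other = GridSpec(origin=(0.0, 0.0, 0.0), spacing=2.0, dims=(4, 1, 1))
        b = RegionMask(other, np.ones((4, 1, 1), dtype=bool))
        with pytest.raises(DataError):
            pair_mask(a, b, a)
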