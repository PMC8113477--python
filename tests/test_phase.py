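"""Bond-order water-phase classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from icepept.phase import (PhaseCutoffs, bond_correlation, classify_waters,
                           clathrate_fraction, q3_vector)


def _brute_force_q3(center, neighbors):
    """Independent oracle: direct summation of Y_3m from the series
    expansion in Cartesian form (no scipy special functions)."""
    import math
    out = np.zeros(7, dtype=complex)
    for nb in np.atleast_2d(neighbors):
        v = np.asarray(nb, float) - np.asarray(center, float)
        x, y, z = v / np.linalg.norm(v)
        r_xy = complex(x, y)
        # explicit l=3 spherical harmonics (physics convention)
        y3 = {
            0: 0.25 * math.sqrt(7 / math.pi) * (5 * z**3 - 3 * z),
            1: -0.125 * math.sqrt(21 / math.pi) * r_xy * (5 * z**2 - 1),
            2: 0.25 * math.sqrt(105 / (2 * math.pi)) * r_xy**2 * z,
            3: -0.125 * math.sqrt(35 / math.pi) * r_xy**3,
        }
        for m in range(-3, 4):
            if m >= 0:
                out[m + 3] += y3[m]
            else:
                out[m + 3] += (-1) ** m * np.conj(y3[-m])
    return out / len(np.atleast_2d(neighbors))


TETRAHEDRON = np.array([
    [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)


class TestQ3Vector:
    def test_single_neighbor_along_z_only_m0(self):
        q3 = q3_vector([0, 0, 0], [[0, 0, 2.8]])
        nonzero = np.abs(q3) > 1e-12
        assert nonzero.tolist() == [False, False, False, True, False, False, False]

    def test_matches_brute_force_on_tetrahedron(self):
        q3 = q3_vector([0, 0, 0], TETRAHEDRON * 2.76)
        oracle = _brute_force_q3([0, 0, 0], TETRAHEDRON * 2.76)
        np.testing.assert_allclose(q3, oracle, atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_q3_norm_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        nbrs = rng.normal(size=(4, 3))
        rot = Rotation.random(rng=np.random.default_rng(seed + 1))
        a = np.linalg.norm(q3_vector(np.zeros(3), nbrs))
        b = np.linalg.norm(q3_vector(np.zeros(3), rot.apply(nbrs)))
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_length_bond_is_an_error(self):
        with pytest.raises(ValueError):
            q3_vector([0, 0, 0], [[0, 0, 0]])


class TestBondCorrelation:
    def test_identical_vectors_give_one(self):
        q3 = q3_vector([0, 0, 0], TETRAHEDRON)
        assert bond_correlation(q3, q3) == pytest.approx(1.0)

    def test_ideal_lattice_bond_classes(self, ice_lattice):
        """Off-axis (staggered) bonds of perfect ice Ih sit at c=-1, the
        c-axis (eclipsed) bond at c=-0.11."""
        labels = classify_waters(ice_lattice.oxygen_positions, ice_lattice.box)
        c = labels.correlations.ravel()
        stag = c[c <= -0.8]
        ecl = c[(c >= -0.35) & (c <= 0.25)]
        assert len(stag) + len(ecl) == len(c)
        assert np.allclose(stag, -1.0, atol=0.01)
        assert np.allclose(ecl, -0.11, atol=0.01)

    def test_zero_norm_is_an_error(self):
        with pytest.raises(ValueError):
            bond_correlation(np.zeros(7), np.ones(7))


class TestClassifyWaters:
    def test_ih_interior_is_hexagonal(self, ice_lattice):
        labels = classify_waters(ice_lattice.oxygen_positions, ice_lattice.box)
        assert labels.fraction("HEX") >= 0.95

    def test_liquid_box_has_no_spurious_ice(self, liquid_box):
        """False-ice control: a disordered box must contain <5% ice-like
        labels (the quantity front tracking and the census rely on)."""
        labels = classify_waters(liquid_box.water_oxygens(0), liquid_box.box)
        assert labels.ice_like_mask().mean() < 0.05

    def test_label_counts_conserved(self, liquid_box):
        labels = classify_waters(liquid_box.water_oxygens(0), liquid_box.box)
        assert sum(labels.counts().values()) == len(labels)

    def test_fewer_than_four_molecules_all_liquid(self):
        with pytest.warns(UserWarning, match="LIQ"):
            labels = classify_waters(np.eye(3) * 3.0, np.array([20.0] * 3))
        assert (labels.labels == "LIQ").all()

    def test_rotation_translation_invariance(self, ice_lattice):
        """Classification must not depend on global orientation.  Rotating
        by 90° about z maps the orthorhombic box onto (Ly, Lx, Lz)."""
        pos = ice_lattice.oxygen_positions
        box = ice_lattice.box
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pos @ rot.T + np.array([3.0, -7.0, 11.0])
        a = classify_waters(pos, box)
        b = classify_waters(moved, box[[1, 0, 2]])
        assert (a.labels == b.labels).all()

    def test_periodic_image_shift_invariance(self, ice_lattice):
        pos = ice_lattice.oxygen_positions
        box = ice_lattice.box
        a = classify_waters(pos, box)
        b = classify_waters(pos + box * np.array([2.0, -1.0, 3.0]), box)
        assert (a.labels == b.labels).all()

    def test_melting_never_increases_hex_fraction(self, ice_lattice):
        """Increasing jitter on an Ih slab monotonically destroys the
        hexagonal signal, on average over seeds."""
        fracs = []
        for sigma in (0.0, 0.25, 0.6):
            vals = []
            for seed in range(3):
                rng = np.random.default_rng(seed)
                pos = ice_lattice.oxygen_positions + rng.normal(
                    scale=sigma, size=ice_lattice.oxygen_positions.shape)
                vals.append(
                    classify_waters(pos, ice_lattice.box).fraction("HEX"))
            fracs.append(np.mean(vals))
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_correlation_symmetry(self, ice_lattice):
        labels = classify_waters(ice_lattice.oxygen_positions, ice_lattice.box)
        c = labels.correlations
        nbr = labels.neighbors
        for i in range(0, len(labels), 17):
            for slot, j in enumerate(nbr[i]):
                back = np.flatnonzero(nbr[j] == i)
                if len(back):
                    assert c[i, slot] == pytest.approx(c[j, back[0]], abs=1e-9)

    def test_correlations_bounded(self, liquid_box):
        labels = classify_waters(liquid_box.water_oxygens(0), liquid_box.box)
        c = labels.correlations[np.isfinite(labels.correlations)]
        assert (np.abs(c) <= 1.0 + 1e-9).all()


class TestClathrateFraction:
    def test_all_liquid_shell_is_zero(self, liquid_box):
        pos = liquid_box.water_oxygens(0)
        labels = classify_waters(pos, liquid_box.box)
        labels.labels[:] = "LIQ"
        assert clathrate_fraction(labels, pos, pos[0], 5.0, liquid_box.box) == 0.0

    def test_constructed_half_clathrate(self, liquid_box):
        pos = liquid_box.water_oxygens(0)
        labels = classify_waters(pos, liquid_box.box)
        labels.labels[:] = "LIQ"
        labels.labels[::2] = "CLATH"
        frac = clathrate_fraction(labels, pos, pos, 1e6, liquid_box.box)
        assert frac == pytest.approx(np.mean(labels.labels == "CLATH"))

    def test_probe_in_bulk_ice_sees_no_clathrate(self, ice_lattice):
        pos = ice_lattice.oxygen_positions
        labels = classify_waters(pos, ice_lattice.box)
        frac = clathrate_fraction(labels, pos, pos.mean(axis=0), 6.0,
                                  ice_lattice.box)
        assert frac == pytest.approx(0.0, abs=0.02)

    def test_empty_shell_is_nan_not_zero(self, ice_lattice):
        pos = ice_lattice.oxygen_positions
        labels = classify_waters(pos, ice_lattice.box)
        far = pos.mean(axis=0)
        assert np.isnan(clathrate_fraction(labels, pos, far, 1e-3,
                                           ice_lattice.box))

    def test_nonpositive_radius_is_an_error(self, ice_lattice):
        labels = classify_waters(ice_lattice.oxygen_positions, ice_lattice.box)
        with pytest.raises(ValueError):
            clathrate_fraction(labels, ice_lattice.oxygen_positions,
                               np.zeros(3), 0.0)
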