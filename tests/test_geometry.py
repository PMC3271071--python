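"""Dihedral geometry, torsion extraction and angle normalisation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tangle.geometry import (AngleNormalizer, BackboneChain, Residue,
                             UndefinedAngleError, angular_difference,
                             build_backbone_chain, compute_backbone_torsions,
                             dihedral, fit_normalizer, read_pdb_backbone,
                             target_mask, wrap_angle)

from conftest import write_pdb


def _atan2_oracle(p1, p2, p3, p4):
    """Independent reference: textbook atan2 cross-product formula."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    return math.degrees(math.atan2(y, x))


class TestDihedral:
    @pytest.mark.parametrize("p4, expected", [
        ((0, 1, 0), 0.0),      # planar cis: fourth point on same side
        ((2, 1, 0), 180.0),    # planar trans: opposite sides
        ((1, 1, 1), 90.0),     # out of plane: sign fixed by the convention
    ])
    def test_planar_and_perpendicular_cases(self, p4, expected):
        ang = dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), p4)
        assert ang == pytest.approx(expected)
        assert ang == pytest.approx(
            wrap_angle(_atan2_oracle((0, 0, 0), (1, 0, 0), (1, 1, 0), p4)))

    def test_matches_biopython_on_random_quadruples(self, rng):
        from Bio.PDB.vectors import Vector, calc_dihedral
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            ours = dihedral(*pts)
            ref = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
            assert angular_difference(ours, ref) < 1e-8

    def test_range_reversal_and_mirror_symmetry(self, rng):
        for _ in range(30):
            pts = rng.normal(size=(4, 3)) * 2
            ang = dihedral(*pts)
            assert -180 < ang <= 180
            assert dihedral(*pts[::-1]) == pytest.approx(ang)
            mirrored = pts * np.array([1, 1, -1])
            assert dihedral(*mirrored) == pytest.approx(-ang) or \
                abs(abs(ang) - 180) < 1e-9

    def test_degenerate_geometry_raises(self):
        with pytest.raises(UndefinedAngleError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))  # collinear
        with pytest.raises(UndefinedAngleError):
            dihedral((0, 0, 0), (0, 0, 0), (1, 1, 0), (2, 1, 0))  # coincident


class TestBackboneTorsions:
    def test_single_residue_chain_has_no_defined_angles(self):
        chain = build_backbone_chain([0.0], [0.0])
        recs = compute_backbone_torsions(chain)
        assert len(recs) == 1
        assert math.isnan(recs[0].phi) and math.isnan(recs[0].psi)

    def test_three_residue_chain_boundary_rule(self):
        chain = build_backbone_chain([-60, -60, -60], [-45, -45, -45])
        recs = compute_backbone_torsions(chain)
        assert math.isnan(recs[0].phi) and math.isfinite(recs[0].psi)
        assert math.isfinite(recs[1].phi) and math.isfinite(recs[1].psi)
        assert math.isfinite(recs[2].phi) and math.isnan(recs[2].psi)

    def test_ideal_helix_recovers_canonical_angles(self):
        chain = build_backbone_chain([-57.0] * 8, [-47.0] * 8)
        recs = compute_backbone_torsions(chain)
        for r in recs[1:-1]:
            assert angular_difference(r.phi, -57.0) < 2.0
            assert angular_difference(r.psi, -47.0) < 2.0

    def test_complete_chain_yields_n_minus_1_defined_angles(self):
        n = 6
        chain = build_backbone_chain([-120.0] * n, [135.0] * n)
        recs = compute_backbone_torsions(chain)
        assert sum(math.isfinite(r.phi) for r in recs) == n - 1
        assert sum(math.isfinite(r.psi) for r in recs) == n - 1

    def test_incomplete_residue_marks_angles_undefined(self):
        chain = build_backbone_chain([-60] * 4, [-45] * 4)
        chain.residues[2].ca = None
        recs = compute_backbone_torsions(chain)
        assert math.isnan(recs[2].phi) and math.isnan(recs[2].psi)

    def test_pdb_round_trip(self, tmp_path):
        chain = build_backbone_chain([-57.0] * 5, [-47.0] * 5)
        path = tmp_path / "toy.pdb"
        write_pdb(chain, path)
        chains = read_pdb_backbone(str(path))
        assert len(chains) == 1 and len(chains[0].residues) == 5
        recs = compute_backbone_torsions(chains[0])
        # PDB files carry 3-decimal coordinates, so allow small distortion
        assert recs[2].phi == pytest.approx(-57.0, abs=0.1)
        assert recs[2].psi == pytest.approx(-47.0, abs=0.1)


class TestNormalizer:
    def test_two_point_statistics(self):
        norm = fit_normalizer([-60.0, -80.0], [100.0, 140.0])
        assert norm.mu_phi == pytest.approx(-70.0)
        assert norm.sigma_phi == pytest.approx(np.std([-60, -80], ddof=1))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            fit_normalizer([-70.0, -70.0], [0.0, 10.0])

    def test_mean_of_normalized_sample_is_half(self, rng):
        phis = rng.uniform(-180, 180, 100)
        psis = rng.uniform(-180, 180, 100)
        norm = fit_normalizer(phis, psis)
        assert np.mean(norm.normalize(phis, "phi")) == pytest.approx(0.5)

    def test_centering_and_span_boundary(self):
        norm = AngleNormalizer(mu_phi=-70, sigma_phi=20, mu_psi=50,
                               sigma_psi=30, span_multiplier=6.0)
        assert norm.normalize(-70.0, "phi") == pytest.approx(0.5)
        assert norm.normalize(-70 + 3 * 20, "phi") == pytest.approx(1.0)

    @given(st.floats(min_value=-179.999, max_value=180.0))
    def test_round_trip_identity(self, theta):
        norm = AngleNormalizer(mu_phi=-65, sigma_phi=35, mu_psi=40,
                               sigma_psi=70)
        back = norm.denormalize(norm.normalize(theta, "phi"), "phi")
        assert abs(back - theta) < 1e-9

    def test_denormalize_wraps_onto_circle(self):
        norm = AngleNormalizer(mu_phi=170, sigma_phi=10, mu_psi=0, sigma_psi=10)
        # v=0.833 -> 170 + 20 = 190 pre-wrap -> -170
        assert norm.denormalize(0.5 + 20 / 60, "phi") == pytest.approx(-170.0)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_normalize_inverts_denormalize_without_wrap(self, v):
        norm = AngleNormalizer(mu_phi=0, sigma_phi=30, mu_psi=0, sigma_psi=30)
        # mu=0, sigma=30, span 6: v in [0,1] -> theta in [-90, 90], no wrap
        assert norm.normalize(norm.denormalize(v, "phi"), "phi") == \
            pytest.approx(v, abs=1e-12)


class TestAngularDifference:
    @pytest.mark.parametrize("a, b, mode, expected", [
        (10, 10, "circular", 0.0),
        (-175, 175, "circular", 10.0),
        (-175, 175, "linear", 350.0),
        (20, 10, "linear", 10.0),
    ])
    def test_examples(self, a, b, mode, expected):
        assert angular_difference(a, b, mode) == pytest.approx(expected)

    def test_circular_difference_is_a_metric_on_a_grid(self):
        grid = np.arange(-180.0, 180.0, 7.0)
        d = angular_difference(grid[:, None], grid[None, :])
        assert np.allclose(d, d.T)
        assert np.all(d >= 0) and np.all(d <= 180)
        assert np.allclose(np.diag(d), 0)
        # triangle inequality over all grid triples
        assert np.all(d[:, None, :] <= d[:, :, None] + d[None, :, :] + 1e-9)


def test_target_mask_extra_trim():
    chain = build_backbone_chain([-60.0] * 8, [-45.0] * 8)
    recs = compute_backbone_torsions(chain)
    assert target_mask(recs, "phi").sum() == 7
    trimmed = target_mask(recs, "phi", extra_trim=2)
    assert trimmed.sum() == 4 and not trimmed[0] and not trimmed[-1]


def test_wrap_angle_half_open_interval():
    assert wrap_angle(180.0) == 180.0
    assert wrap_angle(-180.0) == 180.0
    assert wrap_angle(190.0) == pytest.approx(-170.0)
    assert wrap_angle(540.0) == 180.0
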