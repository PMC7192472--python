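"""Implicit-solvent backend: Born limits, descreening oracle, SASA, ΔG_solv."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from stapletherm import (
    SolvationModelConfig,
    born_self_energy,
    dehydration_penalty,
    descreening_integral,
    direct_interaction_energy,
    effective_born_radii,
    gb_polar_energy,
    sasa,
    solvation_free_energy,
)
from stapletherm.solvation import (
    BORN_CONSTANT,
    SolvationError,
    _OBC_ALPHA,
    _OBC_BETA,
    _OBC_GAMMA,
    _gb_pair_function,
)
from tests.conftest import make_point_structure


def quadrature_descreening(d: float, ri: float, rj: float) -> float:
    """Direct numerical integration of the descreening volume integral."""
    if d + rj <= ri:
        return 0.0
    if d >= rj:
        lo = max(ri, d - rj)
        extra = 0.0
    elif rj - d > ri:
        lo = rj - d
        extra = 1.0 / ri - 1.0 / lo
    else:
        lo = ri
        extra = 0.0

    def shell(r):
        cos_t = (r * r + d * d - rj * rj) / (2.0 * r * d)
        return (1.0 - cos_t) / 2.0 / r ** 2

    val, _ = quad(shell, lo, d + rj, limit=200)
    return val + extra


class TestBornSelfEnergy:
    def test_closed_form(self):
        got = born_self_energy(1.0, 2.0)
        assert got == pytest.approx(-166.0318 * (1 - 1 / 78.5) / 2.0, rel=1e-12)

    def test_zero_charge(self):
        assert born_self_energy(0.0, 1.5) == 0.0

    def test_charge_squared_scaling(self):
        assert born_self_energy(2.0, 1.5) == pytest.approx(
            4.0 * born_self_energy(1.0, 1.5), rel=1e-12
        )

    def test_non_positive_radius_rejected(self):
        with pytest.raises(SolvationError):
            born_self_energy(1.0, 0.0)


class TestEffectiveBornRadii:
    def test_isolated_atom_keeps_intrinsic_radius(self):
        s = make_point_structure([[0, 0, 0]], radius=1.7)
        np.testing.assert_allclose(effective_born_radii(s, s.coordinates), [1.7])

    def test_distant_pair_approaches_intrinsic(self):
        s = make_point_structure([[0, 0, 0], [1e3, 0, 0]], radius=1.7)
        radii = effective_born_radii(s, s.coordinates)
        np.testing.assert_allclose(radii, 1.7, atol=1e-6)

    @pytest.mark.parametrize("d,ri,rj", [
        (3.0, 1.5, 1.5), (2.0, 1.5, 1.5), (4.0, 1.2, 2.0),
        (1.0, 1.0, 2.5), (0.6, 0.8, 2.5),
    ])
    def test_analytic_integral_matches_quadrature(self, d, ri, rj):
        assert descreening_integral(d, ri, rj) == pytest.approx(
            quadrature_descreening(d, ri, rj), abs=1e-10
        )

    def test_two_sphere_radii_match_quadrature_oracle(self):
        """Analytic effective radii vs numerical-quadrature descreening, 1e-4 Å."""
        s = make_point_structure([[0, 0, 0], [3.0, 0, 0]], radius=1.5)
        got = effective_born_radii(s, s.coordinates)
        psi = quadrature_descreening(3.0, 1.5, 1.5) * 1.5
        scale = math.tanh(_OBC_ALPHA * psi - _OBC_BETA * psi ** 2
                          + _OBC_GAMMA * psi ** 3)
        expected = 1.5 / (1.0 - scale)
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_overlap_rejected(self):
        s = make_point_structure([[0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(SolvationError):
            effective_born_radii(s, s.coordinates)


class TestGBPolar:
    def test_single_ion_equals_born_energy(self):
        s = make_point_structure([[0, 0, 0]], charges=[1.0], radius=2.0)
        decomp = gb_polar_energy(s, s.coordinates)
        assert decomp.total == pytest.approx(born_self_energy(1.0, 2.0), rel=1e-12)

    def test_zero_charges_zero_everywhere(self):
        s = make_point_structure(np.random.default_rng(0).normal(scale=4, size=(4, 3)))
        decomp = gb_polar_energy(s, s.coordinates)
        assert decomp.total == 0.0
        assert all(v == 0.0 for v in decomp.per_atom.values())

    def test_five_atom_toy_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=3.0, size=(5, 3))
        charges = rng.normal(scale=0.4, size=5)
        s = make_point_structure(coords, charges=charges, radius=1.6)
        decomp = gb_polar_energy(s, s.coordinates)
        radii = effective_born_radii(s, s.coordinates)
        tau = BORN_CONSTANT * (1.0 - 1.0 / 78.5)
        expected = 0.0
        for i in range(5):
            for j in range(5):
                if i == j:
                    f = radii[i]
                else:
                    d = np.linalg.norm(coords[i] - coords[j])
                    f = _gb_pair_function(np.array(d), radii[i], radii[j])
                expected += -tau * charges[i] * charges[j] / f / (1 if i == j else 1)
        # double loop counts each ordered pair once; self terms once
        assert decomp.total == pytest.approx(expected, rel=1e-10)
        assert sum(decomp.per_atom.values()) == pytest.approx(decomp.total,
                                                              rel=1e-12)


class TestSasa:
    def test_isolated_sphere_area(self):
        s = make_point_structure([[0, 0, 0]], radius=1.5)
        area = sasa(s, s.coordinates, probe=1.4)[0]
        assert area == pytest.approx(4 * math.pi * 2.9 ** 2, rel=0.01)

    def test_fully_caged_atom_is_buried(self):
        # central atom enclosed by a tight octahedral + cubic cage
        cage = [[2.0, 0, 0], [-2.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0],
                [0, 0, 2.0], [0, 0, -2.0]]
        cage += [[s1 * 1.4, s2 * 1.4, s3 * 1.4]
                 for s1 in (-1, 1) for s2 in (-1, 1) for s3 in (-1, 1)]
        s = make_point_structure([[0.0, 0, 0]] + cage, radius=1.8)
        areas = sasa(s, s.coordinates, probe=1.4)
        assert areas[0] == 0.0

    def test_two_sphere_self_convergence(self):
        """Default 960-point lattice vs a 10⁴-point reference, within 2 %."""
        s = make_point_structure([[0, 0, 0], [2.5, 0, 0]], radius=1.6)
        coarse = sasa(s, s.coordinates, n_points=960)
        fine = sasa(s, s.coordinates, n_points=10_000)
        np.testing.assert_allclose(coarse, fine, rtol=0.02)


class TestSolvationFreeEnergy:
    def test_zero_charges_zero_gamma(self):
        s = make_point_structure([[0, 0, 0], [4.0, 0, 0]])
        cfg = SolvationModelConfig(surface_tension_gamma=0.0)
        assert solvation_free_energy(s, s.coordinates, cfg).total == 0.0

    def test_zero_charges_positive_gamma_is_gamma_times_sasa(self):
        s = make_point_structure([[0, 0, 0], [4.0, 0, 0]])
        cfg = SolvationModelConfig()
        total = solvation_free_energy(s, s.coordinates, cfg).total
        areas = sasa(s, s.coordinates, cfg.probe_radius, cfg.n_sasa_points)
        assert total == pytest.approx(cfg.surface_tension_gamma * areas.sum(),
                                      rel=1e-12)

    def test_total_is_polar_plus_gamma_sasa(self, synthetic_complex):
        system, _ = synthetic_complex
        topo = system.topology
        frame = system.trajectory.frames[0]
        cfg = SolvationModelConfig()
        total = solvation_free_energy(topo, frame, cfg).total
        polar = gb_polar_energy(topo, frame, cfg).total
        nonpolar = cfg.surface_tension_gamma * sasa(
            topo, frame, cfg.probe_radius, cfg.n_sasa_points
        ).sum()
        assert total == pytest.approx(polar + nonpolar, rel=1e-10)

    def test_unknown_backend_rejected(self):
        s = make_point_structure([[0, 0, 0]])
        with pytest.raises(SolvationError, match="unknown solvation backend"):
            solvation_free_energy(s, s.coordinates,
                                  SolvationModelConfig(backend="rism"))


class TestDehydrationPenalty:
    def test_separated_limit_is_zero(self, synthetic_complex):
        system, _ = synthetic_complex
        frame = system.trajectory.frames[0].copy()
        frame[system.peptide_index] += np.array([1e4, 0.0, 0.0])
        assert abs(dehydration_penalty(system, frame).total) < 1e-4

    def test_exact_additivity_and_partition(self, synthetic_complex):
        system, _ = synthetic_complex
        decomp = dehydration_penalty(system, system.trajectory.frames[0])
        assert sum(decomp.per_atom.values()) == pytest.approx(decomp.total,
                                                              rel=1e-12)
        pep_ids = system.peptide_atom_ids
        pep_sum = sum(v for i, v in decomp.per_atom.items() if i in pep_ids)
        rec_sum = sum(v for i, v in decomp.per_atom.items() if i not in pep_ids)
        assert pep_sum + rec_sum == pytest.approx(decomp.total, rel=1e-12)

    def test_positive_for_default_complex(self, synthetic_complex):
        """Dehydration penalty of the planted complex is positive."""
        system, _ = synthetic_complex
        assert dehydration_penalty(system, system.trajectory.frames[0]).total > 0

    def test_buried_charged_atoms_pay_the_penalty(self, synthetic_complex):
        """ΔG_solv localizes positively on the buried charged probe/epitope atoms."""
        system, _ = synthetic_complex
        decomp = dehydration_penalty(system, system.trajectory.frames[0])
        for a in system.topology.atoms:
            if a.atom_name in ("SCE", "P1"):
                assert decomp.per_atom[a.atom_id] > 0

    def test_null_backend_isolates_direct_component(self, synthetic_complex):
        """Swapping the backend changes only the solvation component."""
        system, _ = synthetic_complex
        frame = system.trajectory.frames[0]
        null = dehydration_penalty(system, frame,
                                   SolvationModelConfig(backend="null"))
        assert null.total == 0.0
        assert all(v == 0.0 for v in null.per_atom.values())
        d_default = direct_interaction_energy(system, frame).total
        assert d_default == direct_interaction_energy(system, frame).total
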