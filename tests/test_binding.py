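"""Δf assembly, grouping, replica statistics and ΔG_bind bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stapletherm import (
    binding_free_energy,
    dehydration_penalty,
    direct_interaction_energy,
    effective_binding_energy,
    ensemble_estimate,
    group_decomposition,
    rank_groups,
    trajectory_binding_profile,
)
from stapletherm.binding import BindingError, BindingEstimate


class TestEffectiveBindingEnergy:
    def test_definitional_identity(self, synthetic_complex):
        """Δf = ΔE_u + ΔG_solv atom-by-atom and in total."""
        system, _ = synthetic_complex
        frame = system.trajectory.frames[0]
        eff = effective_binding_energy(system, frame)
        direct = direct_interaction_energy(system, frame)
        solv = dehydration_penalty(system, frame)
        assert eff.total == pytest.approx(direct.total + solv.total, rel=1e-12)
        for atom_id in eff.per_atom:
            assert eff.per_atom[atom_id] == pytest.approx(
                direct.per_atom[atom_id] + solv.per_atom[atom_id], abs=1e-12
            )

    def test_separated_limit(self, synthetic_complex):
        system, _ = synthetic_complex
        frame = system.trajectory.frames[0].copy()
        frame[system.peptide_index] += np.array([1e4, 0.0, 0.0])
        assert abs(effective_binding_energy(system, frame).total) < 1e-4

    def test_planted_complex_binds_favourably(self, synthetic_complex):
        system, _ = synthetic_complex
        assert effective_binding_energy(system, system.trajectory.frames[0]).total < 0


class TestGroupDecomposition:
    def test_group_sums_equal_total(self, synthetic_complex):
        system, _ = synthetic_complex
        eff = effective_binding_energy(system, system.trajectory.frames[0])
        grouped = group_decomposition(eff, system.topology)
        assert grouped.total == pytest.approx(eff.total, rel=1e-12)
        assert sum(grouped.per_group.values()) == pytest.approx(eff.total,
                                                                rel=1e-10)

    def test_linker_negative_and_among_top_four(self, synthetic_complex):
        system, truth = synthetic_complex
        eff = effective_binding_energy(system, system.trajectory.frames[0])
        grouped = group_decomposition(eff, system.topology)
        assert grouped.per_group["LINKER"] < 0
        pep_groups = {a.group_label for a in system.topology.atoms
                      if a.atom_id in system.peptide_atom_ids}
        top4 = sorted((g for g in pep_groups),
                      key=lambda g: abs(grouped.per_group[g]), reverse=True)[:4]
        assert "LINKER" in top4


class TestTrajectoryProfile:
    def test_stride_indexing(self, small_ensemble):
        _, _, replicas = small_ensemble
        profile = trajectory_binding_profile(replicas[0], frame_stride=2)
        assert profile.frame_indices == [0, 2, 4]
        full = trajectory_binding_profile(replicas[0], frame_stride=1)
        assert len(full.frame_indices) == 5

    def test_noise_free_frames_give_identical_totals(self, synthetic_complex):
        from dataclasses import replace
        from stapletherm import ComplexSystem, SyntheticSpec, generate_trajectory

        system, _ = synthetic_complex
        spec = replace(SyntheticSpec(), noise_sigma=0.0, n_frames=3)
        traj = generate_trajectory(system, spec, 1)
        cs = ComplexSystem(traj, system.peptide_atom_ids,
                           system.receptor_atom_ids)
        profile = trajectory_binding_profile(cs)
        assert np.ptp(profile.totals) == pytest.approx(0.0, abs=1e-9)

    def test_group_split_sums_to_group_delta_f(self, small_ensemble):
        """Per group, the ΔE_u part + ΔG_solv part equals the group's Δf."""
        _, _, replicas = small_ensemble
        profile = trajectory_binding_profile(replicas[0])
        for k in range(len(profile.frame_indices)):
            for g in profile.group_effective[k]:
                assert profile.group_direct[k][g] + profile.group_solvation[k][g] \
                    == pytest.approx(profile.group_effective[k][g], abs=1e-9)

    def test_oversized_stride_rejected(self, small_ensemble):
        _, _, replicas = small_ensemble
        with pytest.raises(BindingError, match="stride"):
            trajectory_binding_profile(replicas[0], frame_stride=99)


class TestEnsembleEstimate:
    def test_identical_replicas_zero_se(self):
        est = ensemble_estimate([-10.0] * 10)
        assert est.mean_delta_f == -10.0
        assert est.standard_error == 0.0
        assert est.n_replicas == 10

    def test_two_point_closed_form(self):
        est = ensemble_estimate([-10.0, -12.0])
        assert est.mean_delta_f == pytest.approx(-11.0)
        assert est.standard_error == pytest.approx(1.0)

    def test_single_replica_reports_zero_se(self):
        est = ensemble_estimate([-5.0])
        assert est.standard_error == 0.0 and est.n_replicas == 1

    def test_empty_rejected(self):
        with pytest.raises(BindingError):
            ensemble_estimate([])

    def test_monte_carlo_se_matches_sigma_over_sqrt_n(self):
        """SE of 10 replica means from N(−18.7, 1.58²) ≈ 1.58/√10 = 0.5."""
        rng = np.random.default_rng(42)
        sigma, n = 1.58, 10
        estimates = [
            ensemble_estimate(rng.normal(-18.7, sigma, n)).standard_error
            for _ in range(200)
        ]
        assert np.mean(estimates) == pytest.approx(sigma / np.sqrt(n), rel=0.15)

    def test_per_group_statistics(self):
        maps = [{"A": -1.0, "B": 2.0}, {"A": -3.0, "B": 2.0}]
        est = ensemble_estimate([-1.0, -3.0], maps)
        assert est.per_group_mean == {"A": -2.0, "B": 2.0}
        assert est.per_group_se["A"] == pytest.approx(1.0)
        assert est.per_group_se["B"] == 0.0


class TestBindingFreeEnergy:
    def _estimate(self, mean):
        return BindingEstimate(mean, 0.5, 10, {}, {})

    def test_zero_entropies_give_delta_f(self):
        assert binding_free_energy(self._estimate(-18.7), 300.0, 0.0, 0.0) \
            == pytest.approx(-18.7)

    def test_defining_formula(self):
        # Δf − T(ΔS_config + ΔS_ext) with ΔS sum −0.01 kcal/(mol·K) at 300 K
        assert binding_free_energy(self._estimate(-18.7), 300.0, -0.004, -0.006) \
            == pytest.approx(-15.7)

    def test_negative_entropy_sum_never_improves_binding(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mean = rng.normal(-15, 5)
            s1, s2 = -abs(rng.normal(0, 0.01)), -abs(rng.normal(0, 0.01))
            assert binding_free_energy(self._estimate(mean), 300.0, s1, s2) >= mean

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(BindingError):
            binding_free_energy(self._estimate(-10.0), 0.0, 0.0, 0.0)


class TestRankGroups:
    def test_single_group(self):
        est = BindingEstimate(-1.0, 0.0, 1, {"A": -1.0}, {})
        assert rank_groups(est, 1) == ["A"]

    def test_most_negative_first(self):
        est = BindingEstimate(-4.0, 0.0, 1, {"A": -5.0, "B": -1.0, "C": 2.0}, {})
        assert rank_groups(est, 2) == ["A", "B"]

    def test_ties_break_by_key(self):
        est = BindingEstimate(0.0, 0.0, 1, {"B": -1.0, "A": -1.0}, {})
        assert rank_groups(est, 2) == ["A", "B"]

    def test_within_filter(self):
        est = BindingEstimate(0.0, 0.0, 1, {"A": -5.0, "B": -4.0, "C": -3.0}, {})
        assert rank_groups(est, 2, within={"B", "C"}) == ["B", "C"]


@given(
    values=hst.lists(hst.floats(-50, 50), min_size=2, max_size=12),
    shift=hst.floats(-30, 30),
)
@settings(deadline=None, derandomize=True, max_examples=50)
def test_ensemble_estimate_shift_equivariance(values, shift):
    """Shifting every replica mean shifts the estimate; the SE is unchanged."""
    base = ensemble_estimate(values)
    moved = ensemble_estimate([v + shift for v in values])
    assert moved.mean_delta_f == pytest.approx(base.mean_delta_f + shift,
                                               abs=1e-9)
    assert moved.standard_error == pytest.approx(base.standard_error, abs=1e-9)


@given(scale=hst.floats(0.1, 5.0), q=hst.floats(-2.0, 2.0),
       radius=hst.floats(0.5, 5.0))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_born_energy_quadratic_charge_scaling(scale, q, radius):
    """The Born self energy scales with the square of the charge."""
    from stapletherm import born_self_energy

    assert born_self_energy(scale * q, radius) == pytest.approx(
        scale ** 2 * born_self_energy(q, radius), rel=1e-9, abs=1e-12
    )


def test_full_additivity_chain(small_ensemble):
    """Atom → group → total → replica mean additivity holds exactly."""
    system, _, replicas = small_ensemble
    replica_means, group_means = [], []
    for cs in replicas:
        profile = trajectory_binding_profile(cs)
        replica_means.append(profile.mean_total)
        group_means.append(profile.group_means())
    est = ensemble_estimate(replica_means, group_means)
    assert sum(est.per_group_mean.values()) == pytest.approx(est.mean_delta_f,
                                                             rel=1e-9)
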