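"""Weighted scaling, χ², display conventions, grid scan, repeat statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilayerfit.fitting import (
    chi_squared,
    interpolate_to_experiment,
    scale_factor,
    scale_for_display,
    scan,
    summarize_repeats,
)
from bilayerfit.formfactor import FormFactor, default_qz_grid, experimental_qz_grid
from bilayerfit.model import condition_model, model_formfactor, synthesize_experiment


def ff(qz, amp, delta=None, status="arbitrary"):
    return FormFactor(np.asarray(qz, float), np.asarray(amp, float),
                      delta=None if delta is None else np.asarray(delta, float),
                      scale_status=status)


TWO_POINT_EXP = ff([0.1, 0.2], [1.0, 0.5], delta=[0.05, 0.05])
TWO_POINT_SIM = ff([0.1, 0.2], [0.8, 0.6])


class TestInterpolation:
    def test_linear_midpoint(self):
        sim = ff([0.1, 0.2], [1.0, 2.0])
        out = interpolate_to_experiment(sim, np.array([0.15]))
        assert out.amplitude[0] == pytest.approx(1.5)

    def test_identity_on_same_grid(self):
        sim = ff([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        out = interpolate_to_experiment(sim, sim.qz)
        assert np.array_equal(out.amplitude, sim.amplitude)

    def test_extrapolation_rejected_with_points_named(self):
        sim = ff(np.linspace(0.0, 0.8, 9), np.ones(9))
        with pytest.raises(ValueError, match="0.9"):
            interpolate_to_experiment(sim, np.array([0.5, 0.9]))


class TestScaleFactor:
    def test_identity(self):
        exp = ff([0.1, 0.2], [1.0, 0.5], delta=[0.05, 0.05])
        assert scale_factor(exp, ff([0.1, 0.2], [1.0, 0.5])) == pytest.approx(1.0)

    def test_inverse_scaling(self):
        exp = ff([0.1, 0.2], [1.0, 0.5], delta=[0.05, 0.05])
        assert scale_factor(exp, ff([0.1, 0.2], [2.0, 1.0])) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        assert scale_factor(TWO_POINT_EXP, TWO_POINT_SIM) == pytest.approx(1.1, abs=1e-12)

    def test_all_zero_sim_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            scale_factor(TWO_POINT_EXP, ff([0.1, 0.2], [0.0, 0.0]))


class TestChiSquared:
    def test_proportional_sim_gives_zero(self):
        exp = ff([0.1, 0.2, 0.3], [1.0, 0.5, 0.25], delta=[0.05, 0.05, 0.05])
        for c in (0.2, 1.0, 7.0):
            sim = ff(exp.qz, c * exp.amplitude)
            assert chi_squared(exp, sim).chi2 == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_value(self):
        fit = chi_squared(TWO_POINT_EXP, TWO_POINT_SIM)
        assert fit.a_sim == pytest.approx(1.1, abs=1e-12)
        assert fit.chi2 == pytest.approx(16.0, abs=1e-9)
        assert fit.residuals == pytest.approx([0.12, -0.16], abs=1e-12)

    def test_point_duplication_rescales_by_dof(self):
        fit1 = chi_squared(TWO_POINT_EXP, TWO_POINT_SIM)
        exp2 = ff([0.1, 0.2, 0.3, 0.4], [1.0, 0.5, 1.0, 0.5],
                  delta=[0.05] * 4)
        sim2 = ff([0.1, 0.2, 0.3, 0.4], [0.8, 0.6, 0.8, 0.6])
        fit2 = chi_squared(exp2, sim2)
        n = fit1.n_points
        assert fit2.chi2 == pytest.approx(fit1.chi2 * (n - 1) / (2 * n - 1) * 2)

    def test_root_variant(self):
        fit = chi_squared(TWO_POINT_EXP, TWO_POINT_SIM, root=True)
        assert fit.chi2 == pytest.approx(4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            chi_squared(ff([0.1], [1.0], delta=[0.05]), ff([0.1], [1.0]))

    def test_scale_invariance_of_simulation(self):
        rng = np.random.default_rng(14)
        qz = np.linspace(0.1, 0.8, 50)
        exp = ff(qz, rng.random(50) + 0.1, delta=np.full(50, 0.05))
        sim_amp = rng.random(50) + 0.1
        ref = chi_squared(exp, ff(qz, sim_amp)).chi2
        for c in (0.1, 1.0, 10.0):
            got = chi_squared(exp, ff(qz, c * sim_amp)).chi2
            assert abs(got - ref) < 1e-10 * ref

    def test_invariance_under_joint_exp_delta_scaling(self):
        rng = np.random.default_rng(15)
        qz = np.linspace(0.1, 0.8, 40)
        amp = rng.random(40) + 0.1
        delta = np.full(40, 0.05)
        sim = ff(qz, rng.random(40) + 0.1)
        ref = chi_squared(ff(qz, amp, delta=delta), sim).chi2
        for c in (0.3, 5.0):
            got = chi_squared(ff(qz, c * amp, delta=c * delta), sim).chi2
            assert got == pytest.approx(ref, rel=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        # Direct two-pass evaluation of the weighted-scaling + reduced-χ²
        # definitions on 1000 random small instances.
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(2, 11)
            qz = np.sort(rng.random(n)) + np.arange(n) * 1e-3
            e = rng.random(n) + 0.05
            s = rng.random(n) + 0.05
            d = rng.random(n) * 0.1 + 0.01
            w = 1.0 / d**2
            a = np.sum(w * e * s) / np.sum(w * s**2)
            expected = np.sum(((e - a * s) / d) ** 2) / (n - 1)
            fit = chi_squared(ff(qz, e, delta=d), ff(qz, s))
            assert fit.a_sim == pytest.approx(a, rel=1e-12)
            assert fit.chi2 == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0.05, 1.0),  # |F_exp|
            st.floats(0.05, 1.0),  # |F_sim|
            st.floats(0.01, 0.2),  # Δ
        ),
        min_size=2,
        max_size=10,
    )
)
def test_chi_squared_equals_direct_definition(points):
    """Property: the fit result equals a direct evaluation of the weighted
    scale factor and reduced χ² definitions on arbitrary small instances."""
    e, s, d = (np.array(col) for col in zip(*points))
    qz = 0.1 + 0.01 * np.arange(e.size)
    w = 1.0 / d**2
    a = np.sum(w * e * s) / np.sum(w * s**2)
    expected = np.sum(((e - a * s) / d) ** 2) / (e.size - 1)
    fit = chi_squared(ff(qz, e, delta=d), ff(qz, s))
    assert fit.a_sim == pytest.approx(a, rel=1e-12)
    assert fit.chi2 == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestScaleForDisplay:
    def test_single_simulation(self):
        exp = ff([0.1, 0.2], [1.0, 0.5], delta=[0.05, 0.05])
        sim = ff([0.1, 0.2], [2.0, 1.0], status="absolute")
        fit = chi_squared(exp, sim)
        disp = scale_for_display([fit], [sim], exp)
        assert np.array_equal(disp.simulations[0].amplitude, sim.amplitude)
        assert np.allclose(disp.experiment.amplitude, exp.amplitude / fit.a_sim)

    def test_other_sims_scaled_by_ratio(self):
        exp = ff([0.1, 0.2], [1.0, 0.5], delta=[0.05, 0.05])
        sims = [ff([0.1, 0.2], [1.0, 0.5]), ff([0.1, 0.2], [0.4, 0.1])]
        fits = [chi_squared(exp, s) for s in sims]
        assert fits[0].chi2 < fits[1].chi2
        disp = scale_for_display(fits, sims, exp)
        ratio = fits[1].a_sim / fits[0].a_sim
        assert np.allclose(disp.simulations[1].amplitude, sims[1].amplitude * ratio)

    def test_chi2_invariant_under_display_rescaling(self):
        exp = ff([0.1, 0.2, 0.3], [1.0, 0.5, 0.3], delta=[0.05, 0.05, 0.1])
        sim = ff([0.1, 0.2, 0.3], [0.8, 0.6, 0.2])
        fit = chi_squared(exp, sim)
        disp = scale_for_display([fit], [sim], exp)
        refit = chi_squared(disp.experiment, disp.simulations[0])
        assert refit.chi2 == pytest.approx(fit.chi2, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scale_for_display([], [], TWO_POINT_EXP)


class TestSummarizeRepeats:
    def test_hand_computed(self):
        s = summarize_repeats([2.0, 4.0, 6.0])
        assert (s.mean, s.std, s.min, s.max, s.n) == (4.0, 2.0, 2.0, 6.0, 3)

    def test_constant_list(self):
        s = summarize_repeats([3.0, 3.0, 3.0])
        assert s.mean == 3.0 and s.std == 0.0

    def test_single_value(self):
        s = summarize_repeats([2.8])
        assert s.mean == s.min == s.max == 2.8
        assert s.std == 0.0 and s.n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_repeats([])


class TestScan:
    def setup_candidates(self, zs, als, replicates=1):
        qz = default_qz_grid()
        return {
            (z, al, rep): model_formfactor(
                condition_model(al, peptide_depth=z, n_peptides=2), qz
            )
            for z in zs
            for al in als
            for rep in range(replicates)
        }

    def test_noise_free_self_scan_recovers_truth_exactly(self):
        truth = condition_model(68.0, peptide_depth=18.0, n_peptides=2)
        exp = synthesize_experiment(truth, experimental_qz_grid(), noise_level=0.0,
                                    arbitrary_scale=2.3)
        cands = self.setup_candidates([8.0, 18.0], [66.0, 68.0])
        table = scan(exp, cands)
        assert table.best_cell == (18.0, 68.0)
        assert table.stats[table.best_cell].mean < 1e-10

    def test_cutoff_is_inclusive(self):
        truth = condition_model(68.0, peptide_depth=18.0, n_peptides=2)
        exp = synthesize_experiment(truth, experimental_qz_grid(), noise_seed=2)
        cands = self.setup_candidates([18.0], [68.0])
        chi2 = scan(exp, cands).cells[0].chi2
        table = scan(exp, cands, cutoff=chi2)
        assert table.cells[0].accepted  # χ² == cutoff counts as accepted
        table_below = scan(exp, cands, cutoff=chi2 * 0.999)
        assert not table_below.cells[0].accepted

    def test_grid_cardinality_with_replicates(self):
        truth = condition_model(68.0, peptide_depth=18.0, n_peptides=2)
        exp = synthesize_experiment(truth, experimental_qz_grid(), noise_seed=0)
        cands = self.setup_candidates([8.0, 18.0], [66.0, 68.0], replicates=2)
        table = scan(exp, cands)
        assert len(table.cells) == 2 * 2 * 2
        assert all(s.n == 2 for s in table.stats.values())

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            scan(TWO_POINT_EXP, {})
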