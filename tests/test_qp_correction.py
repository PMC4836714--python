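"""Range-weighted QP projection onto the stoichiometric polytope."""

import numpy as np
import pytest

from fluxcast._qp_solver import QPInfeasibleError, solve_qp
from fluxcast.qp_correction import (
    FluxBounds,
    apply_knockout,
    assemble_qp,
    correct,
    default_bounds,
    rmse,
)
from fluxcast.stoichiometry import (
    FLUX_IDS,
    N_FLUXES,
    FluxVector,
    SubstrateMix,
    assemble_constraints,
    check_feasibility,
)
from fluxcast.synthetic_data import ResponseKernel, sample_feasible_flux

from conftest import random_mix


class TestBounds:
    def test_columnwise_extremes(self, table):
        b = default_bounds(table)
        for j, fid in enumerate(FLUX_IDS):
            assert b.lower[j] == table[fid].min()
            assert b.upper[j] == table[fid].max()
        # containment of every training value
        vals = table[list(FLUX_IDS)].to_numpy(float)
        assert np.all(vals >= b.lower) and np.all(vals <= b.upper)

    def test_single_row_degenerate_ranges_floored(self, table):
        b = default_bounds(table.iloc[:1])
        assert np.all(b.lower == b.upper)
        assert np.all(b.ranges() > 0)  # strict convexity preserved

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            FluxBounds(
                lower=np.ones(N_FLUXES),
                upper=np.zeros(N_FLUXES),
                use_box=np.ones(N_FLUXES, bool),
            )

    def test_knockout_pins_and_preserves_original(self, table):
        b = default_bounds(table)
        lo, hi = b.lower.copy(), b.upper.copy()
        kb = apply_knockout(b, "v10")
        j = FLUX_IDS.index("v10")
        assert kb.lower[j] == kb.upper[j] == 0.0 and kb.use_box[j] and kb.forced[j]
        # original untouched, so dropping the knockout restores the bounds
        np.testing.assert_array_equal(b.lower, lo)
        np.testing.assert_array_equal(b.upper, hi)

    def test_unknown_flux_rejected(self, table):
        with pytest.raises(KeyError):
            apply_knockout(default_bounds(table), "v30")


class TestAssembleQP:
    def test_unit_ranges_give_euclidean_objective(self, rng):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        vhat = FluxVector(rng.normal(0, 10, N_FLUXES))
        qp = assemble_qp(vhat, cs, FluxBounds.unit(), use_boxes=False)
        np.testing.assert_allclose(qp.H_diag, 1.0)
        np.testing.assert_allclose(qp.q, -vhat.values)

    def test_doubling_range_quarters_weight(self):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        vhat = FluxVector(np.zeros(N_FLUXES))
        b1 = FluxBounds.unit()
        b2 = FluxBounds(
            lower=b1.lower, upper=b1.upper * 2, use_box=b1.use_box, source="x"
        )
        w1 = assemble_qp(vhat, cs, b1).H_diag
        w2 = assemble_qp(vhat, cs, b2).H_diag
        np.testing.assert_allclose(w2, w1 / 4)


class TestToyProjection:
    """3-variable systems where the QP answer is checkable by hand and by
    dense grid search."""

    def test_matches_closed_form_halfplane_line(self):
        # minimize ||x - t||^2  s.t.  x0 + x1 + x2 = 1,  x0 - x1 >= 0.5
        t = np.array([0.1, 0.8, 0.3])
        E = np.array([[1.0, 1.0, 1.0]])
        d = np.array([1.0])
        A = np.array([[1.0, -1.0, 0.0]])
        c = np.array([0.5])
        sol = solve_qp(np.ones(3), -t, E, d, A, c)
        # by hand: project onto the plane, then onto the active halfplane
        # within the plane (the inequality is active for this target)
        p = t - (t.sum() - 1) / 3
        a_in_plane = np.array([1.0, -1.0, 0.0])  # already orthogonal to (1,1,1)
        gap = c[0] - a_in_plane @ p
        x_hand = p + gap * a_in_plane / (a_in_plane @ a_in_plane)
        np.testing.assert_allclose(sol.x, x_hand, atol=1e-10)

    def test_matches_dense_grid_search(self, rng):
        E = np.array([[1.0, 1.0, 1.0]])
        d = np.array([1.0])
        A = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
        c = np.array([0.3, -0.2])
        w = np.array([1.0, 4.0, 0.25])
        for _ in range(3):
            t = rng.normal(0, 1, 3)
            sol = solve_qp(w, -w * t, E, d, A, c)

            def objective(y, z):
                x0 = 1.0 - y - z
                val = 0.5 * (w[0] * x0**2 + w[1] * y**2 + w[2] * z**2)
                val -= w[0] * t[0] * x0 + w[1] * t[1] * y + w[2] * t[2] * z
                feas = ((1 - y - z) - y >= c[0] - 1e-12) & (z >= c[1] - 1e-12)
                return np.where(feas, val, np.inf)

            # coarse scan then 1e-4 refinement around the incumbent
            ys = np.arange(-2, 2, 1e-2)
            zs = np.arange(-2, 2, 1e-2)
            Y, Z = np.meshgrid(ys, zs, indexing="ij")
            V = objective(Y, Z)
            iy, iz = np.unravel_index(np.argmin(V), V.shape)
            y0, z0 = ys[iy], zs[iz]
            ys = np.arange(y0 - 0.02, y0 + 0.02, 1e-4)
            zs = np.arange(z0 - 0.02, z0 + 0.02, 1e-4)
            Y, Z = np.meshgrid(ys, zs, indexing="ij")
            V = objective(Y, Z)
            iy, iz = np.unravel_index(np.argmin(V), V.shape)
            x_grid = np.array([1 - ys[iy] - zs[iz], ys[iy], zs[iz]])
            np.testing.assert_allclose(sol.x, x_grid, atol=1e-3)


@pytest.fixture(scope="module")
def glucose_cs():
    return assemble_constraints(SubstrateMix.single("glucose"))


class TestCorrect:
    def test_feasible_prediction_is_fixed_point(self, glucose_cs, rng):
        v = sample_feasible_flux(SubstrateMix.single("glucose"), ResponseKernel(), rng)
        res = correct(v, glucose_cs, FluxBounds.unit(), use_boxes=False)
        assert np.max(np.abs(res.corrected.values - v.values)) <= 1e-6

    def test_glucose_mix_forces_v1_100(self, glucose_cs, rng):
        for _ in range(5):
            vhat = FluxVector(rng.normal(0, 80, N_FLUXES))
            res = correct(vhat, glucose_cs)
            assert res.corrected["v1"] == pytest.approx(100.0, abs=1e-6)
            assert res.feasibility.feasible

    def test_idempotence(self, glucose_cs, rng):
        vhat = FluxVector(rng.normal(20, 40, N_FLUXES))
        once = correct(vhat, glucose_cs)
        twice = correct(once.corrected, glucose_cs)
        np.testing.assert_allclose(
            twice.corrected.values, once.corrected.values, atol=1e-6
        )

    def test_projection_optimality_against_random_perturbations(self, glucose_cs, rng):
        """No feasible perturbation of the minimizer lowers the objective."""
        vhat = FluxVector(rng.normal(10, 50, N_FLUXES))
        bounds = FluxBounds.unit()
        res = correct(vhat, glucose_cs, bounds, use_boxes=False)
        v_star = res.corrected.values
        w = 1.0 / bounds.ranges() ** 2

        def obj(v):
            return float(np.sum(w * (v - vhat.values) ** 2))

        base = obj(v_star)
        # feasible directions: convex steps from v* toward random feasible
        # anchors (stay in the polytope by convexity), plus null-space moves
        anchors = [
            sample_feasible_flux(
                SubstrateMix.single("glucose"), ResponseKernel(), rng
            ).values
            for _ in range(10)
        ]
        _, _, VT = np.linalg.svd(glucose_cs.S)
        null = VT[glucose_cs.S.shape[0]:]
        checked = 0
        for i in range(1000):
            if i % 2 == 0:
                w_mix = rng.dirichlet(np.ones(len(anchors)))
                target = np.sum([wi * a for wi, a in zip(w_mix, anchors)], axis=0)
                step = target - v_star
                step *= rng.uniform(0, 1e-3) / max(np.linalg.norm(step), 1e-12)
            else:
                step = null.T @ rng.normal(0, 1, null.shape[0])
                step *= rng.uniform(0, 1e-3) / np.linalg.norm(step)
            cand = v_star + step
            if check_feasibility(FluxVector(cand), glucose_cs, tol=1e-9).feasible:
                checked += 1
                assert obj(cand) >= base - 1e-12
        assert checked >= 400  # the sampler really explored feasible moves

    def test_scale_invariance_of_minimizer(self, glucose_cs, rng, table):
        vhat = FluxVector(rng.normal(10, 40, N_FLUXES))
        b = default_bounds(table, use_box=False)
        b10 = FluxBounds(
            lower=b.lower * 10, upper=b.upper * 10, use_box=b.use_box, source="x"
        )
        r1 = correct(vhat, glucose_cs, b, use_boxes=False)
        r2 = correct(vhat, glucose_cs, b10, use_boxes=False)
        np.testing.assert_allclose(
            r1.corrected.values, r2.corrected.values, atol=1e-6
        )

    def test_knockout_zeroes_flux_even_for_negative_prediction(self, glucose_cs, table, rng):
        bounds = apply_knockout(default_bounds(table, use_box=False), "v24")
        vhat_arr = rng.normal(20, 30, N_FLUXES)
        vhat_arr[FLUX_IDS.index("v24")] = -8.0  # the negative-shunt pathology
        res = correct(FluxVector(vhat_arr), glucose_cs, bounds, use_boxes=False)
        assert res.corrected["v24"] == pytest.approx(0.0, abs=1e-8)
        assert res.feasibility.feasible

    def test_infeasible_user_bounds_raise_named_error(self, glucose_cs, table):
        bounds = default_bounds(table)
        bounds.lower[0], bounds.upper[0] = 0.0, 50.0  # contradicts v1 = 100
        bounds.use_box[:] = True
        with pytest.raises(QPInfeasibleError, match="v1|G6P entry"):
            correct(FluxVector(np.zeros(N_FLUXES)), glucose_cs, bounds)

    def test_auto_relax_recovers_from_tight_boxes(self, glucose_cs, table):
        bounds = default_bounds(table)
        bounds.lower[0], bounds.upper[0] = 0.0, 50.0
        bounds.use_box[:] = True
        res = correct(
            FluxVector(np.zeros(N_FLUXES)), glucose_cs, bounds, auto_relax_boxes=True
        )
        assert res.feasibility.feasible
        assert res.notes  # the relaxation is recorded

    def test_correction_reduces_error_on_noisy_ensembles(self, rng, table):
        """Truth feasible, prediction = truth + noise: projecting back onto
        the polytope shrinks the mean RMSE to truth (statistical check)."""
        kernel = ResponseKernel()
        bounds = default_bounds(table, use_box=False)
        before, after = [], []
        for _ in range(40):
            mix = random_mix(rng)
            cs = assemble_constraints(mix)
            truth = sample_feasible_flux(mix, kernel, rng)
            vhat = FluxVector(truth.values + rng.normal(0, 2.0, N_FLUXES))
            res = correct(vhat, cs, bounds, use_boxes=False)
            before.append(rmse(vhat, truth))
            after.append(rmse(res.corrected, truth))
        assert np.mean(after) < np.mean(before)


class TestRMSE:
    def test_identical_vectors_zero(self, rng):
        v = FluxVector(rng.normal(0, 10, N_FLUXES))
        assert rmse(v, v) == 0.0

    def test_constant_offset(self, rng):
        v = FluxVector(rng.normal(0, 10, N_FLUXES))
        w = FluxVector(v.values + 3.5)
        assert rmse(v, w) == pytest.approx(3.5)

    def test_matches_independent_recomputation(self, rng):
        a = FluxVector(rng.normal(0, 10, N_FLUXES))
        b = FluxVector(rng.normal(0, 10, N_FLUXES))
        expected = float(np.sqrt(((a.values - b.values) ** 2).sum() / N_FLUXES))
        assert rmse(a, b) == pytest.approx(expected, rel=1e-12)
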