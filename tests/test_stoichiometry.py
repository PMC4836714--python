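"""Network structure, constraint assembly and feasibility checking."""

import numpy as np
import pytest
from scipy import optimize

from fluxcast.stoichiometry import (
    FLUX_IDS,
    N_FLUXES,
    FluxVector,
    SubstrateMix,
    assemble_constraints,
    balance_residuals,
    build_network,
    check_feasibility,
    export_lp,
    write_flux_table,
)

from conftest import random_mix
from oracle_constraints import (
    equality_residuals,
    inequality_values,
    suc_inequality_value,
)


class TestNetwork:
    def test_pool_count_and_flux_coverage(self):
        net = build_network()
        assert len(net) == 21
        ids = set()
        for bal in net:
            ids |= set(bal.terms)
        assert ids == set(FLUX_IDS)

    def test_drained_partition(self):
        net = build_network()
        drained = {b.metabolite for b in net if b.drain}
        assert drained == {
            "G6P", "F6P/FBP", "GAP", "3PG", "PEP", "PYR", "AceCoA",
            "R5P", "E4P", "AKG", "OAA", "SUC", "FUM",
        }
        undrained = {b.metabolite for b in net if not b.drain}
        assert undrained == {"DHAP", "Ru5P", "S7P", "X5P", "6PG", "CIT", "ICIT", "MAL"}

    def test_g6p_balance_terms(self):
        g6p = next(b for b in build_network() if b.metabolite == "G6P")
        assert g6p.terms == {"v1": 1, "v2": -1, "v10": -1}
        assert g6p.drain

    def test_s7p_is_strict_equality(self):
        s7p = next(b for b in build_network() if b.metabolite == "S7P")
        assert not s7p.drain
        assert s7p.terms == {"v14": 1, "v16": -1}

    def test_drain_partition_explains_constraint_split(self):
        """Undrained pools become equalities; drained pools inequalities,
        with the SUC pool the single drained balance lacking a row."""
        net = build_network()
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        # 8 undrained balances + the substrate-entry row = 9 equalities
        assert cs.S.shape == (9, N_FLUXES)
        # 13 drained balances minus the SUC exception = 12 inequalities
        assert cs.A.shape == (12, N_FLUXES)
        assert sum(1 for b in net if b.drain) == 13
        cs13 = assemble_constraints(SubstrateMix.single("glucose"), suc_inequality=True)
        assert cs13.A.shape == (13, N_FLUXES)


class TestAssembly:
    def test_glucose_entry_forces_v1(self):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        np.testing.assert_allclose(cs.S[0], np.eye(N_FLUXES)[0])
        assert cs.b_eq[0] == 100.0
        # co-metabolism of both C6 sugars shares the same entry row
        cs2 = assemble_constraints(SubstrateMix({"glucose": 0.5, "galactose": 0.5}))
        assert cs2.b_eq[0] == 100.0

    def test_zero_mix_gives_zero_rhs(self):
        cs = assemble_constraints(SubstrateMix({}))
        assert np.all(cs.b_eq == 0) and np.all(cs.b_in == 0)

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="unknown option"):
            assemble_constraints(SubstrateMix.single("glucose"), zwf=True)

    @pytest.mark.parametrize("mapping", [True, False])
    def test_rows_match_handwritten_oracle(self, rng, mapping):
        """S·v − b_eq and A·v − b_in reproduce every canonical constraint
        expression term for term, for random fluxes and random mixes."""
        for _ in range(100):
            mix = random_mix(rng)
            v = rng.normal(0, 60, N_FLUXES)
            cs = assemble_constraints(
                mix, lactate_to_pyruvate=mapping, acetate_to_accoa=mapping
            )
            r = mix.ratios
            np.testing.assert_allclose(
                cs.S @ v - cs.b_eq, equality_residuals(v, r), atol=1e-10
            )
            np.testing.assert_allclose(
                cs.A @ v - cs.b_in,
                inequality_values(v, r, mapping, mapping),
                atol=1e-10,
            )

    def test_optional_suc_row_matches_oracle(self, rng):
        mix = SubstrateMix({"succinate": 0.7, "glucose": 0.3})
        v = rng.normal(0, 40, N_FLUXES)
        cs = assemble_constraints(mix, suc_inequality=True)
        assert cs.A.shape[0] == 13
        np.testing.assert_allclose(
            cs.A[12] @ v - cs.b_in[12], suc_inequality_value(v, mix.ratios), atol=1e-10
        )

    def test_zwf_mode_reverses_oaa_row(self):
        mix = SubstrateMix.single("glucose")
        cs = assemble_constraints(mix)
        csz = assemble_constraints(mix, zwf_knockout=True)
        i = cs.in_labels.index("OAA drain")
        np.testing.assert_allclose(csz.A[i], -cs.A[i])
        assert csz.b_in[i] == -cs.b_in[i]

    def test_rhs_linear_in_ratios(self):
        """b_eq/b_in are linear in the substrate ratios: a mix's constants are
        the ratio-weighted sum of the single-substrate constants."""
        mix = SubstrateMix({"glucose": 0.2, "xylose": 0.3, "malate": 0.5})
        cs = assemble_constraints(mix)
        b_eq = sum(
            mix.ratio(s) * assemble_constraints(SubstrateMix.single(s)).b_eq
            for s in ("glucose", "xylose", "malate")
        )
        b_in = sum(
            mix.ratio(s) * assemble_constraints(SubstrateMix.single(s)).b_in
            for s in ("glucose", "xylose", "malate")
        )
        np.testing.assert_allclose(cs.b_eq, b_eq, atol=1e-12)
        np.testing.assert_allclose(cs.b_in, b_in, atol=1e-12)


class TestSubstrateMix:
    def test_ratio_bounds_enforced(self):
        with pytest.raises(ValueError):
            SubstrateMix({"glucose": 1.4})
        with pytest.raises(ValueError):
            SubstrateMix({"glucose": 0.5, "xylose": 0.2})
        with pytest.raises(ValueError):
            SubstrateMix({"butyrate": 1.0})

    def test_lenient_mode_skips_sum_check(self):
        mix = SubstrateMix({"glucose": 0.5, "xylose": 0.9}, strict=False)
        assert mix.ratio("glucose") == 0.5


class TestFeasibility:
    def test_wrong_entry_flux_flagged(self):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        v = np.zeros(N_FLUXES)
        v[0] = 50.0
        report = check_feasibility(FluxVector(v), cs, tol=1e-6)
        assert not report.feasible
        assert any(viol.row == 0 and viol.kind == "equality" for viol in report.violations)

    def test_lp_vertex_is_feasible(self, rng):
        """A vertex found by an independent LP (random objective over the same
        constraints) passes check_feasibility."""
        for _ in range(5):
            mix = random_mix(rng)
            cs = assemble_constraints(mix)
            res = optimize.linprog(
                rng.normal(size=N_FLUXES),
                A_ub=-cs.A,
                b_ub=-cs.b_in,
                A_eq=cs.S,
                b_eq=cs.b_eq,
                bounds=[(-200, 400)] * N_FLUXES,
                method="highs",
            )
            assert res.status == 0
            assert check_feasibility(FluxVector(res.x), cs, tol=1e-6).feasible

    def test_tolerance_must_be_positive(self):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        with pytest.raises(ValueError):
            check_feasibility(FluxVector(np.zeros(N_FLUXES)), cs, tol=0.0)


class TestBalanceResiduals:
    def test_glutamate_entry_becomes_akg_slack(self):
        mix = SubstrateMix({"glutamate": 0.4, "glucose": 0.6})
        res = balance_residuals(FluxVector(np.zeros(N_FLUXES)), mix)
        assert res["AKG"]["drained"]
        assert res["AKG"]["value"] == pytest.approx(40.0)

    def test_g6p_slack_recomputed_independently(self, rng):
        v = FluxVector(rng.normal(0, 30, N_FLUXES))
        res = balance_residuals(v, SubstrateMix.single("glucose"))
        assert res["G6P"]["value"] == pytest.approx(v["v1"] - v["v2"] - v["v10"])

    def test_feasible_vector_balances(self, rng):
        from fluxcast.synthetic_data import ResponseKernel, sample_feasible_flux

        mix = SubstrateMix.single("glucose")
        v = sample_feasible_flux(mix, ResponseKernel(), rng)
        res = balance_residuals(v, mix)
        for name, rec in res.items():
            if not rec["drained"]:
                assert abs(rec["value"]) <= 1e-6, name
            elif name != "SUC":  # the SUC drain is unconstrained by default
                assert rec["value"] >= -1e-6, name


class TestExports:
    def test_flux_annotation_table(self, tmp_path):
        path = tmp_path / "fluxes.tsv"
        write_flux_table(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 30  # header + 29 fluxes
        assert lines[0].startswith("flux_id\tlabel")

    def test_lp_dump_lists_all_rows(self, tmp_path):
        cs = assemble_constraints(SubstrateMix.single("glucose"))
        path = tmp_path / "model.lp"
        export_lp(cs, path)
        text = path.read_text()
        assert text.count(" = ") == 9 and text.count(" >= ") == 12
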