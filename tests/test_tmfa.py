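import math

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from thermolump import (
    DeltaGRange,
    Lump,
    TMFAConfig,
    TMFAInfeasibleError,
    ThermoData,
    build_tmfa,
    classify_reversibility,
    dG_variability,
    fba_optimum,
    lump_dG0,
    make_synthetic_gem,
    split_reversible,
    tmfa_optimum,
)
from thermolump.cli import run_lump
from thermolump.model_io import Model


def two_path_model():
    """a -> (objective sink) with an optional side conversion a -> b.

    The side reaction 'conv' carries no required flux, so its Gibbs energy
    range is set by the concentration bounds alone (no coupling).
    """
    S = sp.csc_array(
        np.array(
            [
                #  src  sinka conv  sinkb
                [1.0, -1.0, -1.0, 0.0],  # a_c
                [0.0, 0.0, 1.0, -1.0],  # b_c
            ]
        )
    )
    return Model(
        metabolite_ids=["a_c", "b_c"],
        reaction_ids=["src", "sink_a", "conv", "sink_b"],
        S=S,
        lb=np.zeros(4),
        ub=np.array([10.0, 10.0, 10.0, 10.0]),
        compartments={"a_c": "c", "b_c": "c"},
        objective_reaction="sink_a",
    )


class TestLumpDG0:
    def test_zero_net_gives_zero(self):
        thermo = ThermoData(dfG0={"p_c": -10.0})
        assert lump_dG0(Lump("L", {}, {}, []), thermo) == 0.0

    def test_weighted_sum(self):
        thermo = ThermoData(dfG0={"p_c": -10.0, "q_c": -30.0})
        lump = Lump("L", {}, {"p_c": 1.0, "q_c": -1.0}, [])
        assert lump_dG0(lump, thermo) == pytest.approx(20.0)

    def test_unannotated_net_metabolite_is_an_error(self):
        lump = Lump("L", {}, {"mystery_c": 1.0}, [])
        with pytest.raises(ValueError, match="mystery_c"):
            lump_dG0(lump, ThermoData())

    def test_metabolite_wise_equals_alpha_weighted_reaction_sum(self, annotated_gem):
        """On a fully annotated model, dG0(R alpha) == sum_j alpha_j dG0_j."""
        model = split_reversible(annotated_gem.model)
        thermo = annotated_gem.thermo
        rng = np.random.default_rng(42)
        rxns = [r for r in model.reaction_ids if not r.startswith(("EX", "biomass"))]
        for _ in range(10):
            chosen = rng.choice(len(rxns), size=4, replace=False)
            alpha = rng.uniform(0.1, 3.0, size=4)
            net: dict[str, float] = {}
            reaction_sum = 0.0
            for a, idx in zip(alpha, chosen):
                rid = rxns[idx]
                reaction_sum += a * thermo.reaction_dG0(model, rid)
                for met, coef in model.reaction_stoichiometry(rid).items():
                    net[met] = net.get(met, 0.0) + a * coef
            lump = Lump("L", {}, {m: c for m, c in net.items() if abs(c) > 1e-12}, [])
            met_wise = lump_dG0(lump, thermo)
            assert met_wise == pytest.approx(reaction_sum, rel=1e-8, abs=1e-8)


class TestBuildTMFA:
    def test_no_lumps_no_unknowns_is_standard_tmfa(self, annotated_gem):
        split = split_reversible(annotated_gem.model)
        cfg = TMFAConfig()
        problem = build_tmfa(split, [], annotated_gem.thermo, cfg)
        assert problem.y_index == {}
        assert tmfa_optimum(problem, cfg) <= fba_optimum(split) + 1e-6

    def test_lumps_carry_no_flux_variable(self, toy):
        report, _ = run_lump(toy.model, toy.thermo, "combined")
        split = split_reversible(toy.model)
        with_l = build_tmfa(split, report.lumps, toy.thermo)
        without = build_tmfa(split, [], toy.thermo)
        # flux block identical; lumps only add dG variables and binaries
        assert with_l.lnx_offset == without.lnx_offset == split.n_reactions

    def test_infeasible_lump_forces_a_member_inactive(self, toy):
        """Fixing y_k = 0 must inactivate one member reaction (here, the
        E-G-H cycle dies and no biomass precursor z is produced)."""
        report, _ = run_lump(toy.model, toy.thermo, "combined")
        split = split_reversible(toy.model)
        cfg = TMFAConfig()
        problem = build_tmfa(split, report.lumps, toy.thermo, cfg)
        base = tmfa_optimum(problem, cfg)
        assert base == pytest.approx(30.0)
        y2 = problem.y_index["LUMP_S1_g_c"]
        sel = sp.csr_array(
            (np.array([1.0]), (np.array([0]), np.array([y2]))),
            shape=(1, problem.n_vars),
        )
        problem.constraints.append(LinearConstraint(sel, 0.0, 0.0))
        forced = tmfa_optimum(problem, cfg)
        assert forced == pytest.approx(0.0, abs=1e-6)

    def test_lump_referencing_missing_reaction_is_an_error(self, toy):
        split = split_reversible(toy.model)
        bogus = Lump("L", {"nope": 1.0}, {"p_c": 1.0}, [])
        with pytest.raises(ValueError, match="nope"):
            build_tmfa(split, [bogus], toy.thermo)


class TestOptima:
    def test_tmfa_never_exceeds_fba(self, toy, small_gem):
        for model, thermo in [(toy.model, toy.thermo), (small_gem.model, small_gem.thermo)]:
            split = split_reversible(model)
            cfg = TMFAConfig()
            problem = build_tmfa(split, [], thermo, cfg)
            assert tmfa_optimum(problem, cfg) <= fba_optimum(split) + 1e-6

    def test_wide_bounds_and_lumps_recover_fba_optimum(self, toy):
        """With generous concentration bounds every Gibbs constraint can be
        satisfied, so adding lumps leaves the flux optimum untouched."""
        report, _ = run_lump(toy.model, toy.thermo, "combined")
        split = split_reversible(toy.model)
        cfg = TMFAConfig(conc_lb=1e-30, conc_ub=1e30, bigM=1e6)
        problem = build_tmfa(split, report.lumps, toy.thermo, cfg)
        assert tmfa_optimum(problem, cfg) == pytest.approx(fba_optimum(split))


class TestVariability:
    def test_uncoupled_reaction_range_is_closed_form(self):
        model = two_path_model()
        thermo = ThermoData(
            dfG0={"a_c": -10.0, "b_c": -15.0}  # conv dG0 = -5
        )
        cfg = TMFAConfig()
        problem = build_tmfa(model, [], thermo, cfg)
        ranges = {r.reaction_id: r for r in dG_variability(problem, cfg)}
        rt = cfg.RT
        span = rt * math.log(cfg.conc_ub / cfg.conc_lb)
        assert ranges["conv"].dG_min == pytest.approx(-5.0 - span, rel=1e-6)
        assert ranges["conv"].dG_max == pytest.approx(-5.0 + span, rel=1e-6)
        assert ranges["conv"].dG_min <= ranges["conv"].dG_max

    def test_temperature_scales_the_concentration_term_linearly(self):
        model = two_path_model()
        thermo = ThermoData(dfG0={"a_c": -10.0, "b_c": -15.0})
        widths = []
        for temp in (298.15, 596.30):
            cfg = TMFAConfig(temperature=temp)
            ranges = {
                r.reaction_id: r
                for r in dG_variability(build_tmfa(model, [], thermo, cfg), cfg)
            }
            widths.append(ranges["conv"].dG_max - ranges["conv"].dG_min)
        assert widths[1] == pytest.approx(2 * widths[0], rel=1e-6)

    def test_lump_ranges_nest_within_no_lump_ranges(self, toy):
        report, _ = run_lump(toy.model, toy.thermo, "combined")
        split = split_reversible(toy.model)
        cfg = TMFAConfig()
        base = {
            r.reaction_id: r
            for r in dG_variability(build_tmfa(split, [], toy.thermo, cfg), cfg)
        }
        with_l = dG_variability(
            build_tmfa(split, report.lumps, toy.thermo, cfg), cfg
        )
        assert base  # toy has determined internal reactions
        for r in with_l:
            if r.reaction_id in base:
                assert r.dG_min >= base[r.reaction_id].dG_min - 1e-6
                assert r.dG_max <= base[r.reaction_id].dG_max + 1e-6

    def test_higher_biomass_fraction_nests_ranges(self, toy):
        split = split_reversible(toy.model)
        results = {}
        for frac in (0.9, 1.0):
            cfg = TMFAConfig(biomass_fraction=frac)
            results[frac] = {
                r.reaction_id: r
                for r in dG_variability(build_tmfa(split, [], toy.thermo, cfg), cfg)
            }
        for rid, tight in results[1.0].items():
            loose = results[0.9][rid]
            assert tight.dG_min >= loose.dG_min - 1e-6
            assert tight.dG_max <= loose.dG_max + 1e-6

    def test_infeasible_base_problem_raises_with_guidance(self):
        # the only route to biomass has a strongly positive dG0: no
        # concentration assignment within bounds can activate it
        S = sp.csc_array(np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]))
        model = Model(
            metabolite_ids=["a_c", "b_c"],
            reaction_ids=["src", "conv", "bio"],
            S=S,
            lb=np.zeros(3),
            ub=np.full(3, 10.0),
            compartments={"a_c": "c", "b_c": "c"},
            objective_reaction="bio",
        )
        thermo = ThermoData(dfG0={"a_c": -10.0, "b_c": 490.0})
        cfg = TMFAConfig()
        problem = build_tmfa(model, [], thermo, cfg)
        with pytest.raises(TMFAInfeasibleError, match="concentration bounds"):
            dG_variability(problem, cfg)

    def test_transport_lump_warns_without_adjustment_hook(self):
        model = two_path_model()
        thermo = ThermoData(dfG0={"a_c": -10.0, "b_c": -15.0})
        lump = Lump("L", {"conv": 1.0}, {"a_c": -1.0, "b_c": 1.0}, [])
        lump.net = {"a_c": -1.0, "b_c": 1.0}
        model.compartments["b_c"] = "e"
        with pytest.warns(UserWarning, match="membrane-transport"):
            build_tmfa(model, [lump], thermo)


class TestClassify:
    @pytest.mark.parametrize(
        "rng,expected",
        [
            ((-3.0, -1.0), "irreversible"),
            ((-3.0, 1.0), "reversible"),
            ((-3.0, 0.0), "reversible"),  # boundary: not strictly negative
        ],
    )
    def test_strict_negativity_rule(self, rng, expected):
        assert DeltaGRange("r", *rng).classification == expected

    def test_tally(self):
        ranges = [
            DeltaGRange("r1", -3, -1),
            DeltaGRange("r2", -3, 1),
            DeltaGRange("r3", -3, 0),
        ]
        assert classify_reversibility(ranges) == {
            "irreversible": 1,
            "reversible": 2,
        }


def test_config_validation():
    with pytest.raises(ValueError, match="biomass_fraction"):
        TMFAConfig(biomass_fraction=0.0)
    with pytest.raises(ValueError, match="bounds"):
        TMFAConfig(conc_overrides={"w_c": (1.0, 0.5)})
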