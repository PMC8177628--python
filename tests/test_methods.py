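import numpy as np
import pytest

from multibof.bof import BiomassComposition, BofEntry, bof_mass, bof_to_reaction
from multibof.fba import EnvironmentPoint, apply_environment, solve_fba
from multibof.methods import (
    BOFMeasurement,
    MeasurementSet,
    build_btw,
    fit_affine_map,
    hip_bof,
    hip_i_solve,
    hip_solve,
    solve_btw,
)
from multibof.model_io import MetabolicModel, Metabolite, Reaction

DIMS = ["EX_glc__D_e", "EX_nh4_e"]


def _single_bof_growth(model, bof, env):
    work = model.copy()
    work.add_reaction(bof_to_reaction(bof, "BOF_SINGLE"))
    return solve_fba(apply_environment(work, env), {"BOF_SINGLE": 1.0})


@pytest.fixture()
def two_resource_model():
    """Two resources, two biomass routes: BOF1 is carbon-cheap (1 C + 3 N),
    BOF2 nitrogen-cheap (3 C + 1 N); caps 10/10."""
    return MetabolicModel(
        metabolites=[
            Metabolite("cres", molecular_weight=100.0),
            Metabolite("nres", molecular_weight=100.0),
        ],
        reactions=[
            Reaction("EX_c", {"cres": -1.0}, -10.0, 0.0),
            Reaction("EX_n", {"nres": -1.0}, -10.0, 0.0),
        ],
    )


def _resource_bof(c_coef, n_coef, label):
    return BiomassComposition(
        entries={
            "cres": BofEntry(c_coef, "consumed", "Others", 100.0),
            "nres": BofEntry(n_coef, "consumed", "Others", 100.0),
        },
        label=label,
    )


class TestBtw:
    def test_single_bof_reduces_to_fba(self, core_model, bof_a):
        env = EnvironmentPoint({DIMS[0]: 8.0, DIMS[1]: 4.0}, "fixed")
        combined = build_btw(core_model, [bof_a])
        btw = solve_btw(combined, env)
        single = _single_bof_growth(core_model, bof_a, env)
        assert btw.objective_value == pytest.approx(single.objective_value, rel=1e-9)

    def test_duplicate_bofs_degenerate(self, core_model, bof_a):
        env = EnvironmentPoint({DIMS[0]: 8.0, DIMS[1]: 4.0}, "fixed")
        combined = build_btw(core_model, [bof_a, bof_a.scaled(1.0, label="A2")])
        btw = solve_btw(combined, env)
        single = _single_bof_growth(core_model, bof_a, env)
        assert btw.objective_value == pytest.approx(single.objective_value, rel=1e-9)

    def test_two_resource_strict_gain_hand_lp(self, two_resource_model):
        # singles: max x s.t. x+3x-coefs <= caps -> 10/3 each
        # BTW: x + y s.t. x+3y <= 10, 3x+y <= 10 -> x=y=2.5, total 5
        bof1 = _resource_bof(1.0, 3.0, "B1")
        bof2 = _resource_bof(3.0, 1.0, "B2")
        combined = build_btw(two_resource_model, [bof1, bof2])
        sol = solve_btw(combined)
        assert sol.objective_value == pytest.approx(5.0, abs=1e-8)
        singles = []
        for bof in (bof1, bof2):
            work = two_resource_model.copy()
            work.add_reaction(bof_to_reaction(bof, "B"))
            singles.append(solve_fba(work, {"B": 1.0}).objective_value)
        assert all(s == pytest.approx(10.0 / 3.0, abs=1e-8) for s in singles)
        assert sol.objective_value > max(singles) + 0.5

    def test_optimum_on_one_bof_zeroes_other(self, two_resource_model):
        # nitrogen nearly absent: the carbon-cheap/nitrogen-hungry BOF1 is
        # useless, everything goes through BOF2
        model = two_resource_model.copy()
        model.reaction("EX_n").lower_bound = -30.0
        model.reaction("EX_c").lower_bound = -3.0
        bof1 = _resource_bof(2.0, 30.0, "B1")
        bof2 = _resource_bof(1.0, 1.0, "B2")
        sol = solve_btw(build_btw(model, [bof1, bof2]))
        assert sol.bof_fluxes["BTW_BIOMASS_B2"] == pytest.approx(3.0, abs=1e-8)
        assert sol.bof_fluxes["BTW_BIOMASS_B1"] == pytest.approx(0.0, abs=1e-8)

    def test_closed_exchanges_zero(self, core_model, bof_a, bof_b):
        combined = build_btw(core_model, [bof_a, bof_b])
        for rxn in combined.exchanges():
            rxn.lower_bound = 0.0
        sol = solve_btw(combined)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_dominance_over_singles_grid(self, core_model, bof_a, bof_b):
        combined = build_btw(core_model, [bof_a, bof_b])
        for c in (0.0, 2.5, 5.0, 10.0):
            for n in (0.0, 2.0, 8.0):
                env = EnvironmentPoint({DIMS[0]: c, DIMS[1]: n}, "fixed")
                btw = solve_btw(combined, env)
                for bof in (bof_a, bof_b):
                    single = _single_bof_growth(core_model, bof, env)
                    if not single.optimal:
                        continue
                    # any single-BOF solution is feasible in the BTW model
                    assert btw.optimal
                    assert (
                        btw.objective_value
                        >= single.objective_value - 1e-8
                    )

    def test_missing_compound_listed(self, two_resource_model):
        bad = BiomassComposition(
            {"ghost": BofEntry(1.0, "consumed", "Others", 10.0)}, label="G"
        )
        with pytest.raises(KeyError, match="ghost"):
            build_btw(two_resource_model, [bad])

    def test_no_bofs_rejected(self, two_resource_model):
        with pytest.raises(ValueError, match="at least one"):
            build_btw(two_resource_model, [])

    def test_solve_requires_build(self, core_model):
        with pytest.raises(ValueError, match="build_btw"):
            solve_btw(core_model)


class TestAffineFit:
    def test_interpolation_property(self, hip_map, measurement_set):
        for meas in measurement_set.measurements:
            coords = meas.environment.coordinates(DIMS)
            raw = dict(zip(hip_map.compounds, hip_map.raw_coefficients(coords)))
            for cid, entry in meas.composition.entries.items():
                assert raw[cid] == pytest.approx(entry.coefficient, abs=1e-9)

    def test_centroid_is_mean(self, hip_map, measurement_set):
        coords = measurement_set.coordinates()
        centroid = coords.mean(axis=0)
        raw = hip_map.raw_coefficients(centroid)
        for i, cid in enumerate(hip_map.compounds):
            mean_coef = np.mean(
                [
                    m.composition.entries[cid].coefficient
                    if cid in m.composition.entries
                    else 0.0
                    for m in measurement_set.measurements
                ]
            )
            assert raw[i] == pytest.approx(mean_coef, abs=1e-9)

    def test_least_squares_vs_normal_equations(self, bof_a, bof_b, measurement_set):
        extra = BOFMeasurement(
            EnvironmentPoint({DIMS[0]: 6.0, DIMS[1]: 6.0}, "upper_bound"), bof_a
        )
        ms = MeasurementSet(
            measurements=measurement_set.measurements + [extra],
            dimensions=list(DIMS),
        )
        fitted = fit_affine_map(ms, bof_a)
        assert fitted.fit_mode == "least_squares"
        X = np.hstack([np.ones((4, 1)), ms.coordinates()])
        for i, cid in enumerate(fitted.compounds):
            y = np.array(
                [
                    m.composition.entries[cid].coefficient
                    if cid in m.composition.entries
                    else 0.0
                    for m in ms.measurements
                ]
            )
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fitted.coefficients[i], oracle, atol=1e-8)

    def test_collinear_points_rejected(self, bof_a, bof_b):
        ms = MeasurementSet(
            measurements=[
                BOFMeasurement(
                    EnvironmentPoint({DIMS[0]: float(v), DIMS[1]: float(v)}, "upper_bound"),
                    bof_a,
                )
                for v in (1, 2, 3)
            ],
            dimensions=list(DIMS),
        )
        with pytest.raises(np.linalg.LinAlgError, match="affinely dependent"):
            fit_affine_map(ms, bof_a)

    def test_too_few_points_rejected(self, bof_a, measurement_set):
        ms = MeasurementSet(
            measurements=measurement_set.measurements[:2], dimensions=list(DIMS)
        )
        with pytest.raises(ValueError, match="at least 3 measurements"):
            fit_affine_map(ms, bof_a)

    def test_unnormalized_measurement_rejected(self, bof_a, measurement_set):
        bad = measurement_set.measurements[0].composition.scaled(2.0)
        ms = MeasurementSet(
            measurements=[
                BOFMeasurement(measurement_set.measurements[0].environment, bad),
                *measurement_set.measurements[1:],
            ],
            dimensions=list(DIMS),
        )
        with pytest.raises(ValueError, match="not unit-mass normalized"):
            fit_affine_map(ms, bof_a)


class TestHipBof:
    def test_reproduces_measurements_after_renormalization(
        self, hip_map, measurement_set
    ):
        for meas in measurement_set.measurements:
            bof = hip_bof(hip_map, meas.environment)
            for cid, entry in meas.composition.entries.items():
                assert bof.entries[cid].coefficient == pytest.approx(
                    entry.coefficient, abs=1e-9
                )

    def test_unit_mass_always(self, hip_map):
        rng = np.random.default_rng(0)
        for _ in range(20):
            coords = rng.uniform(0.0, 12.0, size=2)
            assert bof_mass(hip_bof(hip_map, coords)) == pytest.approx(1.0, abs=1e-9)

    def test_affinity_between_clamp_free_points(self, hip_map):
        p = np.array([8.0, 6.0])
        q = np.array([4.0, 3.0])
        lam = 0.3
        mid = hip_bof(hip_map, lam * p + (1 - lam) * q, renormalize=False)
        bp = hip_bof(hip_map, p, renormalize=False)
        bq = hip_bof(hip_map, q, renormalize=False)
        for cid in mid.entries:
            expected = lam * bp.entries[cid].coefficient + (1 - lam) * bq.entries[
                cid
            ].coefficient
            assert mid.entries[cid].coefficient == pytest.approx(expected, abs=1e-9)

    def test_negative_extrapolation_clamped_to_reference_fraction(self, bof_a):
        # 1-D line through (0 -> 1.0) and (1 -> 0.2): raw alpha < 0 at x >= 1.25
        ref = BiomassComposition(
            {"x": BofEntry(0.5, "consumed", "Others", 100.0)}, label="ref"
        )
        ms = MeasurementSet(
            measurements=[
                BOFMeasurement(
                    EnvironmentPoint({"EX_d": 0.0}, "upper_bound"),
                    BiomassComposition(
                        {
                            "x": BofEntry(1.0, "consumed", "Others", 100.0),
                            "y": BofEntry(9.0, "consumed", "Others", 100.0),
                        },
                        label="m0",
                    ),
                ),
                BOFMeasurement(
                    EnvironmentPoint({"EX_d": 1.0}, "upper_bound"),
                    BiomassComposition(
                        {
                            "x": BofEntry(0.2, "consumed", "Others", 100.0),
                            "y": BofEntry(9.8, "consumed", "Others", 100.0),
                        },
                        label="m1",
                    ),
                ),
            ],
            dimensions=["EX_d"],
        )
        fitted = fit_affine_map(ms, ref, clamp_fraction=0.01)
        out = hip_bof(fitted, np.array([2.0]), renormalize=False)
        # raw x coefficient is 1.0 - 0.8*2 = -0.6 -> clamp to 1% of ref 0.5
        assert out.entries["x"].coefficient == pytest.approx(0.01 * 0.5, abs=1e-12)

    def test_clamp_with_zero_reference_is_zero(self):
        ref = BiomassComposition(
            {"y": BofEntry(1.0, "consumed", "Others", 1000.0)}, label="ref"
        )
        ms = MeasurementSet(
            measurements=[
                BOFMeasurement(
                    EnvironmentPoint({"EX_d": float(x)}, "upper_bound"),
                    BiomassComposition(
                        {
                            "x": BofEntry(a, "consumed", "Others", 100.0),
                            "y": BofEntry(1.0, "consumed", "Others", 900.0),
                        },
                        label=f"m{x}",
                    ),
                )
                for x, a in ((0.0, 1.0), (1.0, 0.0))
            ],
            dimensions=["EX_d"],
        )
        # measurements are unit mass: 1*100/1000 + 1*900/1000 = 1 at x=0;
        # at x=1 mass is 0.9 -> tweak y weight so both are unit mass
        ms.measurements[1].composition.entries["y"] = BofEntry(
            1.0, "consumed", "Others", 1000.0
        )
        fitted = fit_affine_map(ms, ref, clamp_fraction=0.01)
        out = hip_bof(fitted, np.array([5.0]), renormalize=False)
        assert "x" not in out.entries  # clamped to exactly zero

    def test_clamped_never_negative(self, hip_map):
        rng = np.random.default_rng(1)
        for _ in range(50):
            coords = rng.uniform(-5.0, 30.0, size=2)
            bof = hip_bof(hip_map, coords, renormalize=False)
            assert all(e.coefficient >= 0 for e in bof.entries.values())

    def test_dimension_mismatch(self, hip_map):
        with pytest.raises(ValueError, match="dimensions"):
            hip_bof(hip_map, np.array([1.0, 2.0, 3.0]))


class TestHipSolve:
    def test_matches_single_bof_at_measurement_coordinate(
        self, core_model, hip_map, measurement_set
    ):
        for meas in measurement_set.measurements:
            hip = hip_solve(core_model, hip_map, meas.environment)
            direct = _single_bof_growth(core_model, meas.composition, meas.environment)
            assert hip.objective_value == pytest.approx(
                direct.objective_value, rel=1e-8
            )

    def test_midpoint_matches_averaged_bof(
        self, core_model, hip_map, measurement_set
    ):
        m0, m1 = measurement_set.measurements[:2]
        mid_coords = 0.5 * (
            m0.environment.coordinates(DIMS) + m1.environment.coordinates(DIMS)
        )
        env = EnvironmentPoint(dict(zip(DIMS, mid_coords)), "upper_bound")
        hip = hip_solve(core_model, hip_map, env)
        averaged = hip_bof(hip_map, mid_coords)
        direct = _single_bof_growth(core_model, averaged, env)
        assert hip.objective_value == pytest.approx(direct.objective_value, rel=1e-8)


class TestHipI:
    def test_fixed_point_is_k0_and_equals_hip(self, core_model, hip_map):
        seed_env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        first = hip_i_solve(core_model, hip_map, seed_env)
        assert first.converged
        fixed_coords = first.final_uptakes
        env = EnvironmentPoint(dict(zip(DIMS, fixed_coords)), "upper_bound")
        rerun = hip_i_solve(core_model, hip_map, env)
        assert rerun.converged
        assert rerun.iterations == 0
        hip = hip_solve(core_model, hip_map, env)
        assert rerun.solution.objective_value == pytest.approx(
            hip.objective_value, rel=1e-6
        )

    def test_k_max_zero_at_unstable_point(self, core_model, hip_map):
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        result = hip_i_solve(core_model, hip_map, env, k_max=0)
        assert not result.converged
        assert result.iterations == 0

    def test_nitrogen_wasting_start_contracts(self, core_model, contractive_map):
        # high-N / low-C start: realized nitrogen uptake falls monotonically
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        result = hip_i_solve(core_model, contractive_map, env)
        assert result.converged
        assert result.iterations <= 5
        n_uptakes = [v[1] for v in result.trajectory]
        assert all(a >= b - 1e-9 for a, b in zip(n_uptakes, n_uptakes[1:]))
        assert n_uptakes[-1] < 8.0

    def test_converged_satisfies_epsilon(self, core_model, hip_map):
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        result = hip_i_solve(core_model, hip_map, env, eps=1e-3)
        assert result.converged
        if result.iterations > 0:
            last, prev = result.trajectory[-1], result.trajectory[-2]
            assert float(np.max(np.abs(last - prev))) <= 1e-3

    def test_compositions_unit_mass(self, core_model, hip_map):
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        result = hip_i_solve(core_model, hip_map, env)
        for comp in result.compositions:
            assert bof_mass(comp) == pytest.approx(1.0, abs=1e-9)

    def test_requires_upper_bound_mode(self, core_model, hip_map):
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "fixed")
        with pytest.raises(ValueError, match="upper_bound"):
            hip_i_solve(core_model, hip_map, env)

    def test_deterministic_uptake_flag(self, core_model, hip_map):
        env = EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 8.0}, "upper_bound")
        a = hip_i_solve(core_model, hip_map, env, deterministic_uptake=True)
        b = hip_i_solve(core_model, hip_map, env, deterministic_uptake=True)
        assert a.converged and b.converged
        assert np.allclose(a.final_uptakes, b.final_uptakes)
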