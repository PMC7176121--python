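"""The ten closed-form solution sets and the interval sweep."""

import numpy as np
import pytest

from prevalid import (
    ALL_COMBOS,
    check_consistency,
    combo_key,
    derive_over_interval,
    forward_model,
    rogan_gladen,
    solve,
    solve_many,
)
from prevalid.exceptions import (
    ConstraintViolationError,
    DegenerateCombinationError,
    DomainError,
)
from .conftest import full_parameter_arrays


class TestSolveCaseStudies:
    """Scalar solves at the published case-study inputs."""

    def test_intussusception_p_se_ppv(self):
        # rare outcome: true prevalence from observed prevalence, SE, PPV
        prof = solve(185 / 417997, {"se": 0.893, "ppv": 0.724})
        assert 100 * prof.pi == pytest.approx(0.036, abs=5e-4)
        assert prof.sp > 0.999 and prof.npv > 0.999

    def test_pneumonia_p_ppv_npv(self):
        prof = solve(0.0202, {"ppv": 0.808, "npv": 0.991})
        assert 100 * prof.pi == pytest.approx(2.51, abs=5e-3)
        assert 100 * prof.sp == pytest.approx(99.6, abs=5e-2)

    def test_intussusception_se_from_rounded_prevalences(self):
        prof = solve(0.00044, {"pi": 0.00036, "ppv": 0.724})
        assert 100 * prof.se == pytest.approx(88.5, abs=5e-2)

    def test_perfect_test(self):
        prof = solve(0.3, {"se": 1.0, "sp": 1.0})
        assert prof.pi == pytest.approx(0.3, abs=1e-12)
        assert prof.ppv == 1.0 and prof.npv == 1.0


class TestSolveAlgebra:
    @pytest.mark.parametrize("key", ALL_COMBOS, ids="-".join)
    def test_round_trip_recovers_forward_profile(self, key, valid_triples):
        """Any pair extracted from a forward profile reproduces all six."""
        pi, se, sp, p = valid_triples
        full = full_parameter_arrays(pi, se, sp)
        sol = solve_many(p, full[key[0]], full[key[1]], key)
        for name, truth in full.items():
            err = np.abs(sol[name] - truth)
            assert np.nanmax(err) < 1e-9, (name, float(np.nanmax(err)))

    def test_scalar_solve_matches_forward_model(self, valid_triples):
        """Strict scalar solve on a subsample round-trips and is consistent."""
        pi, se, sp, p = (a[:40] for a in valid_triples)
        for i in range(len(pi)):
            full = forward_model(pi[i], se[i], sp[i]).to_dict()
            for key in ALL_COMBOS:
                prof = solve(p[i], {key[0]: full[key[0]], key[1]: full[key[1]]})
                for name, truth in full.items():
                    assert getattr(prof, name) == pytest.approx(truth, abs=1e-9)
                ok, violations = check_consistency(prof, tol=1e-9)
                assert ok, violations

    def test_mutual_consistency_across_combos(self):
        """All ten combos return the identical profile for one classifier."""
        full = forward_model(0.07, 0.82, 0.96).to_dict()
        profiles = [
            solve(full["p"], {a: full[a], b: full[b]}).to_dict()
            for a, b in ALL_COMBOS
        ]
        for name in full:
            values = [pr[name] for pr in profiles]
            assert max(values) - min(values) < 1e-9

    def test_idempotence_on_own_values(self):
        prof = forward_model(0.2, 0.9, 0.85)
        again = solve(prof.p, {"se": prof.se, "ppv": prof.ppv})
        for name, value in prof.to_dict().items():
            assert getattr(again, name) == pytest.approx(value, abs=1e-12)


class TestSolveErrors:
    def test_strict_raises_on_out_of_range(self):
        with pytest.raises(ConstraintViolationError) as exc:
            solve(0.95, {"se": 0.9, "sp": 0.9})
        assert any("pi" in v for v in exc.value.violations)

    def test_non_strict_returns_flagged(self):
        prof = solve(0.95, {"se": 0.9, "sp": 0.9}, strict=False)
        assert prof.pi == pytest.approx(1.0625)
        assert "pi" in prof.out_of_range()

    def test_degenerate_denominator_named(self):
        with pytest.raises(DegenerateCombinationError):
            solve(0.3, {"se": 0.4, "sp": 0.6})  # SE + SP = 1
        with pytest.raises(DegenerateCombinationError):
            solve(0.3, {"pi": 0.0, "ppv": 0.5})  # SE = P*PPV/pi at pi = 0

    def test_input_validation(self):
        with pytest.raises(DomainError):
            solve(0.5, {"se": 0.9})
        with pytest.raises(DomainError):
            solve(0.5, {"se": 0.9, "p": 0.5})
        with pytest.raises(DomainError):
            solve(1.5, {"se": 0.9, "sp": 0.9})


class TestRoganGladen:
    def test_inverse_of_forward_model(self):
        assert rogan_gladen(0.0174, 0.75, 0.99) == pytest.approx(0.01, abs=1e-12)

    def test_boundary_identities(self):
        # P = 1 - SP means every positive is false: pi = 0
        assert rogan_gladen(0.1, 0.8, 0.9) == pytest.approx(0.0, abs=1e-12)
        # P = SE is the all-diseased boundary: pi = 1
        assert rogan_gladen(0.8, 0.8, 0.9) == pytest.approx(1.0, abs=1e-12)

    def test_equals_solver_row(self, valid_triples):
        pi, se, sp, p = (a[:200] for a in valid_triples)
        sol = solve_many(p, se, sp, ("se", "sp"))
        rg = np.array([rogan_gladen(p[i], se[i], sp[i]) for i in range(len(p))])
        np.testing.assert_array_equal(sol["pi"], rg)

    def test_uninformative_classifier(self):
        with pytest.raises(DegenerateCombinationError):
            rogan_gladen(0.3, 0.5, 0.5)


class TestDeriveOverInterval:
    def test_pneumonia_true_prevalence_interval(self):
        """Sweeping pi over 2-3% with P and PPV fixed brackets SE and NPV."""
        res = derive_over_interval(
            0.0202, ("ppv", 0.808), "pi", (0.02, 0.03), n_grid=101
        )
        lo, hi = res.ranges["se"]
        assert (100 * lo, 100 * hi) == pytest.approx((54.4, 81.6), abs=5e-2)
        lo, hi = res.ranges["npv"]
        assert (100 * lo, 100 * hi) == pytest.approx((98.6, 99.6), abs=5e-2)
        lo, hi = res.ranges["sp"]
        assert 100 * lo == pytest.approx(99.6, abs=5e-2)
        assert 100 * hi == pytest.approx(99.6, abs=5e-2)
        assert res.n_valid == res.n_grid == 101

    def test_extrema_at_endpoints(self):
        """Each expression is monotone in the swept input, so the grid
        extrema coincide with the endpoint evaluations."""
        p = 0.0202
        res = derive_over_interval(p, ("ppv", 0.808), "pi", (0.02, 0.03))
        end_lo = solve(p, {"pi": 0.02, "ppv": 0.808}).to_dict()
        end_hi = solve(p, {"pi": 0.03, "ppv": 0.808}).to_dict()
        for name, (vmin, vmax) in res.ranges.items():
            ends = sorted([end_lo[name], end_hi[name]])
            assert vmin == pytest.approx(ends[0], abs=1e-12)
            assert vmax == pytest.approx(ends[1], abs=1e-12)

    def test_degenerate_interval_collapses_to_point(self):
        point = solve(0.0174, {"se": 0.75, "sp": 0.99}).to_dict()
        res = derive_over_interval(0.0174, ("se", 0.75), "sp", (0.99, 0.99))
        for name, (lo, hi) in res.ranges.items():
            assert lo == hi == pytest.approx(point[name], abs=1e-12)

    def test_invalid_points_reported_and_excluded(self):
        # large pi with small P forces SE = P*PPV/pi valid but SP/NPV out of
        # range near the top of the sweep for extreme PPV
        res = derive_over_interval(0.5, ("se", 0.6), "sp", (0.0, 1.0), n_grid=51)
        assert res.n_valid + len(res.invalid_points) == res.n_grid
        assert res.n_valid < res.n_grid  # some sp values are incompatible

    def test_empty_valid_set_raises(self):
        with pytest.raises(ConstraintViolationError):
            derive_over_interval(0.9, ("se", 0.1), "sp", (0.9, 0.95), n_grid=11)
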