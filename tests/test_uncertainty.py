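"""Beta moment fits and Monte-Carlo uncertainty propagation."""

import numpy as np
import pytest

from prevalid import (
    ParameterSpec,
    beta_from_mean_ci,
    forward_model,
    propagate,
)
from prevalid.exceptions import (
    DegeneratePropagationError,
    DomainError,
    InfeasibleMomentsError,
)


class TestBetaFit:
    def test_symmetric_case_forces_equal_shapes(self):
        b = beta_from_mean_ci(0.5, 0.4, 0.6)
        assert b.alpha == pytest.approx(b.beta)
        assert b.mean == pytest.approx(0.5)

    def test_case_study_ppv_fit(self):
        # PPV 72.4% (65.4-78.7): shapes frozen from the moment formulas
        # alpha = m*k, beta = (1-m)*k, k = m(1-m)/v - 1, sd = width/3.92
        b = beta_from_mean_ci(0.724, 0.654, 0.787)
        assert b.alpha == pytest.approx(124.95, abs=0.05)
        assert b.beta == pytest.approx(47.63, abs=0.05)
        assert b.mean == pytest.approx(0.724, abs=1e-12)
        assert b.sd == pytest.approx((0.787 - 0.654) / 3.92, rel=1e-9)

    def test_infeasible_moments(self):
        # mean 0.02 with CI (0,1): v = 0.0651 >= m(1-m) = 0.0196
        with pytest.raises(InfeasibleMomentsError):
            beta_from_mean_ci(0.02, 0.0, 1.0)
        with pytest.raises(InfeasibleMomentsError):
            beta_from_mean_ci(0.5, 0.5, 0.5)  # zero width
        # but a wide CI around 0.5 is fine: v = 0.0651 < 0.25
        b = beta_from_mean_ci(0.5, 0.0, 1.0)
        assert b.alpha > 0 and b.beta > 0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            beta_from_mean_ci(0.0, 0.0, 0.1)
        with pytest.raises(DomainError):
            beta_from_mean_ci(0.5, 0.6, 0.9)


def _pneumonia_specs():
    return (
        ParameterSpec("p", 0.0202),
        (
            ParameterSpec("ppv", 0.808, 0.751, 0.855),
            ParameterSpec("npv", 0.991, 0.989, 0.993),
        ),
    )


class TestPropagate:
    def test_same_seed_is_bit_identical(self):
        p, known = _pneumonia_specs()
        a = propagate(p, known, n_samples=5000, seed=42)
        b = propagate(p, known, n_samples=5000, seed=42)
        assert a == b

    def test_zero_width_cis_collapse_to_point(self):
        res = propagate(
            ParameterSpec("p", 0.0174),
            (ParameterSpec("se", 0.75), ParameterSpec("sp", 0.99)),
            n_samples=1000,
            seed=0,
        )
        for name, (lo, hi) in res.ui_range.items():
            point = getattr(res.point, name)
            assert lo == pytest.approx(point, abs=1e-12)
            assert hi == pytest.approx(point, abs=1e-12)
        assert res.rejection_pct_range == 0.0
        assert res.rejection_pct_chance == 0.0

    def test_rejection_ordering(self):
        # wide CIs produce rejections; the better-than-chance region is
        # nested, so its rejection percentage can only be larger
        res = propagate(
            ParameterSpec("p", 0.3),
            (
                ParameterSpec("se", 0.55, 0.2, 0.9),
                ParameterSpec("sp", 0.55, 0.2, 0.9),
            ),
            n_samples=20_000,
            seed=3,
        )
        assert res.rejection_pct_chance >= res.rejection_pct_range
        assert res.rejection_pct_chance > 0.0

    def test_intussusception_ui_soft_check(self):
        """The published 95% UI for the true prevalence, (0.034-0.038)%, is
        reproduced approximately (the exact MC configuration behind the
        printed interval is not fully specified)."""
        res = propagate(
            ParameterSpec("p", 185 / 417997),
            (
                ParameterSpec("se", 0.893, 0.833, 0.938),
                ParameterSpec("ppv", 0.724, 0.654, 0.787),
            ),
            n_samples=50_000,
            seed=11,
        )
        lo, hi = (100 * v for v in res.ui_range["pi"])
        assert 0.030 <= lo <= 0.036
        assert 0.036 <= hi <= 0.042
        assert lo < 0.036 < hi  # the point estimate sits inside the UI

    def test_monotone_shrinkage_of_uis(self):
        """Halving all CI widths around fixed means cannot widen any UI."""

        def run(scale):
            res = propagate(
                ParameterSpec("p", 0.0202),
                (
                    ParameterSpec("ppv", 0.808, 0.808 - scale * 0.052, 0.808 + scale * 0.052),
                    ParameterSpec("npv", 0.991, 0.991 - scale * 0.002, 0.991 + scale * 0.002),
                ),
                n_samples=50_000,
                seed=99,
            )
            return res

        wide = run(1.0)
        narrow = run(0.5)
        for name in wide.ui_range:
            w_wide = wide.ui_range[name][1] - wide.ui_range[name][0]
            w_narrow = narrow.ui_range[name][1] - narrow.ui_range[name][0]
            assert w_narrow <= w_wide + 1e-3

    def test_accepted_draws_all_satisfy_constraints(self):
        from prevalid.solver import solve_many
        from prevalid.constraints import range_mask
        from prevalid.uncertainty import _sample

        rng = np.random.default_rng(5)
        se = ParameterSpec("se", 0.55, 0.2, 0.9)
        sp = ParameterSpec("sp", 0.55, 0.2, 0.9)
        p = np.full(5000, 0.3)
        x = _sample(se, 5000, rng)
        y = _sample(sp, 5000, rng)
        mask = range_mask(p, x, y, ("se", "sp"))
        sol = solve_many(p, x, y, ("se", "sp"))
        for name in ("pi", "ppv", "npv"):
            assert np.all(sol[name][mask] >= -1e-12)
            assert np.all(sol[name][mask] <= 1 + 1e-12)

    def test_all_draws_rejected_is_an_error(self):
        # p far above se: pi = (p+sp-1)/(se+sp-1) > 1 for every draw
        with pytest.raises(DegeneratePropagationError):
            propagate(
                ParameterSpec("p", 0.99),
                (
                    ParameterSpec("se", 0.3, 0.28, 0.32),
                    ParameterSpec("sp", 0.9, 0.88, 0.92),
                ),
                n_samples=1000,
                seed=1,
            )

    def test_seed_required_when_sampling(self):
        p, known = _pneumonia_specs()
        with pytest.raises(DomainError):
            propagate(p, known, n_samples=1000, seed=None)

    def test_counts_based_p_sampling(self):
        res = propagate(
            ParameterSpec("p", 219 / 10828),
            (
                ParameterSpec("ppv", 0.808, 0.751, 0.855),
                ParameterSpec("npv", 0.991, 0.989, 0.993),
            ),
            n_samples=20_000,
            seed=8,
            p_counts=(219, 10828),
        )
        lo, hi = res.ui_range["p"]
        assert lo < 219 / 10828 < hi
        assert hi - lo > 0  # P now carries sampling uncertainty

    def test_coverage_of_derived_true_values(self):
        """With inputs drawn from their own sampling distributions and CIs
        matching those distributions, the 95% UI of each derived parameter
        covers the truth in at least ~90% of replicates (loose bound)."""
        truth = forward_model(0.1, 0.8, 0.9)
        sd_se, sd_ppv = 0.02, 0.03
        rng = np.random.default_rng(31)
        n_rep, n_mc = 200, 2000
        hits = {"pi": 0, "sp": 0, "npv": 0}
        for rep in range(n_rep):
            se_hat = float(np.clip(rng.normal(truth.se, sd_se), 0.02, 0.98))
            ppv_hat = float(np.clip(rng.normal(truth.ppv, sd_ppv), 0.02, 0.98))
            res = propagate(
                ParameterSpec("p", truth.p),
                (
                    ParameterSpec(
                        "se",
                        se_hat,
                        max(se_hat - 1.96 * sd_se, 0.0),
                        min(se_hat + 1.96 * sd_se, 1.0),
                    ),
                    ParameterSpec(
                        "ppv",
                        ppv_hat,
                        max(ppv_hat - 1.96 * sd_ppv, 0.0),
                        min(ppv_hat + 1.96 * sd_ppv, 1.0),
                    ),
                ),
                n_samples=n_mc,
                seed=1000 + rep,
            )
            for name in hits:
                lo, hi = res.ui_range[name]
                hits[name] += lo <= getattr(truth, name) <= hi
        for name, count in hits.items():
            assert count / n_rep >= 0.90, (name, count / n_rep)
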