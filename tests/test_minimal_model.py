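import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from tgfsmad.errors import DomainError, UndefinedElasticityError
from tgfsmad.minimal_model import (
    MinimalParams,
    log_elasticity,
    lrc_equilibrium,
    receptor_grid_scan,
    signaling_activity,
)


def lrc_oracle(p: MinimalParams) -> float:
    """Independent equilibrium solver: bisection on the defining relation.

    f(x) = K1*L*(R1-x)*(R2-x) - x is strictly decreasing on
    [0, min(R1, R2)] with f(0) >= 0 and f(min) <= 0.
    """
    a = p.K1 * p.L
    if a == 0 or p.R1tot == 0 or p.R2tot == 0:
        return 0.0
    hi = min(p.R1tot, p.R2tot)

    def f(x):
        return a * (p.R1tot - x) * (p.R2tot - x) - x

    if f(hi) >= 0:
        return hi
    return brentq(f, 0.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=500)


class TestLrcEquilibrium:
    def test_no_type1_receptor_gives_zero(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=0, R2tot=1e4)
        assert lrc_equilibrium(p) == 0.0

    def test_zero_ligand_gives_zero(self):
        p = MinimalParams(L=0.0, K1=1000, K2=10, R1tot=10, R2tot=10)
        assert lrc_equilibrium(p) == 0.0

    def test_high_affinity_limit_is_min_receptor(self):
        # K1*L -> large: LRC -> min(R1tot, R2tot); checked against the oracle
        for k1l in (1e4, 1e6, 1e8):
            p = MinimalParams(L=1.0, K1=k1l, K2=10, R1tot=100, R2tot=1e4)
            lrc = lrc_equilibrium(p)
            assert lrc == pytest.approx(lrc_oracle(p), rel=1e-10)
        assert lrc == pytest.approx(100.0, rel=1e-4)

    def test_receptor_exchange_symmetry(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=3.0, R2tot=777.0)
        q = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=777.0, R2tot=3.0)
        assert lrc_equilibrium(p) == pytest.approx(lrc_equilibrium(q), rel=1e-14)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            MinimalParams(L=-1.0, K1=1000, K2=10, R1tot=1, R2tot=1)

    @settings(max_examples=100, deadline=None)
    @given(
        logl=st.floats(-6, 2),
        logk1=st.floats(-3, 6),
        logr1=st.floats(-3, 6),
        logr2=st.floats(-3, 6),
    )
    def test_matches_bisection_oracle(self, logl, logk1, logr1, logr2):
        p = MinimalParams(L=10**logl, K1=10**logk1, K2=1.0,
                          R1tot=10**logr1, R2tot=10**logr2)
        lrc = lrc_equilibrium(p)
        assert 0.0 <= lrc <= min(p.R1tot, p.R2tot)
        assert lrc == pytest.approx(lrc_oracle(p), rel=1e-10, abs=1e-300)

    def test_small_affinity_limit_proportional_to_product(self):
        # K1*L*max(R) < 1e-3  =>  LRC ~ K1*L*R1*R2 within 1%
        for r1, r2 in ((1.0, 2.0), (0.1, 500.0), (30.0, 30.0)):
            k1 = 1e-3 / max(r1, r2) / 10.0
            p = MinimalParams(L=1.0, K1=k1, K2=1.0, R1tot=r1, R2tot=r2)
            ratio = lrc_equilibrium(p) / (k1 * r1 * r2)
            assert 0.99 <= ratio <= 1.0

    def test_tiny_product_linearized_without_cancellation(self):
        # a * R1 * R2 = 1e-320 < 1e-300: short-circuits to the linear solution
        p = MinimalParams(L=1.0, K1=1e-140, K2=1.0, R1tot=1e-90, R2tot=1e-90)
        lrc = lrc_equilibrium(p)
        assert lrc == pytest.approx(1e-320, rel=1e-3)


class TestSignalingActivity:
    def test_zero_when_no_complex(self):
        p = MinimalParams(L=0.0, K1=1000, K2=10, R1tot=5, R2tot=5, Stot=3.0)
        assert signaling_activity(p) == 0.0

    def test_saturation_limit(self):
        p = MinimalParams(L=1.0, K1=1e9, K2=1e9, R1tot=100, R2tot=1e4, Stot=2.0)
        assert signaling_activity(p) == pytest.approx(2.0, rel=1e-6)
        assert signaling_activity(p) < 2.0

    def test_fraction_option(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=10, R2tot=10, Stot=7.0)
        assert signaling_activity(p, as_fraction=True) == pytest.approx(
            signaling_activity(p) / 7.0, rel=1e-14)

    def test_fig_setting_symmetry_and_asymmetric_sensitivity(self):
        # K1=1000, K2=10, L=0.1: Sa symmetric on the diagonal's reflection,
        # and reducing the scarcer receptor 10x hurts far more than the
        # abundant one
        def sa(r1, r2):
            return signaling_activity(
                MinimalParams(L=0.1, K1=1000, K2=10, R1tot=r1, R2tot=r2))

        assert sa(1e2, 1e4) == pytest.approx(sa(1e4, 1e2), rel=1e-12)
        base = sa(1e2, 1e4)
        assert sa(1e1, 1e4) < sa(1e2, 1e3)  # scarce 10x down vs abundant 10x down
        assert base - sa(1e1, 1e4) > 100 * (base - sa(1e2, 1e3))

    @settings(max_examples=50, deadline=None)
    @given(f=st.floats(1.05, 10.0), which=st.sampled_from(
        ["L", "K1", "K2", "R1tot", "R2tot"]))
    def test_monotone_nondecreasing_in_each_argument(self, f, which):
        base = dict(L=0.05, K1=100.0, K2=2.0, R1tot=3.0, R2tot=40.0)
        lo = signaling_activity(MinimalParams(**base))
        base[which] *= f
        hi = signaling_activity(MinimalParams(**base))
        assert hi >= lo - 1e-12


class TestReceptorGridScan:
    def test_shape_and_bounds(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=1, R2tot=1, Stot=5.0)
        res = receptor_grid_scan(p, 3, 5)
        assert res.sa_matrix.shape == (3, 3)
        assert np.all(res.sa_matrix >= 0)
        assert np.all(res.sa_matrix <= 5.0)

    def test_symmetric_under_transposition(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=1, R2tot=1)
        res = receptor_grid_scan(p, 7, 4)
        np.testing.assert_allclose(res.sa_matrix, res.sa_matrix.T, rtol=1e-12)

    def test_balanced_diagonal_monotone(self):
        p = MinimalParams(L=1.0, K1=1e4, K2=10, R1tot=1, R2tot=1)
        res = receptor_grid_scan(p, 21, 5)
        diag = np.diag(res.sa_matrix)
        assert np.all(np.diff(diag) > 0)

    def test_low_affinity_slopes_are_one(self):
        # LRC proportional to R1tot * R2tot: log-log slope 1 on each axis
        # for tiny LRC, Sa = Stot*K2*LRC/(1 + K2*LRC) ~ K2*LRC, a valid proxy
        p = MinimalParams(L=1e-8, K1=1e-3, K2=1.0, R1tot=1, R2tot=1)
        res = receptor_grid_scan(p, 9, 2, center=1.0)
        logs = np.log10(res.sa_matrix)
        slope_r1 = np.polyfit(np.log10(res.r1_axis), logs[:, 0], 1)[0]
        slope_r2 = np.polyfit(np.log10(res.r2_axis), logs[0, :], 1)[0]
        assert slope_r1 == pytest.approx(1.0, abs=0.01)
        assert slope_r2 == pytest.approx(1.0, abs=0.01)

    def test_invalid_grid_rejected(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=1, R2tot=1)
        with pytest.raises(DomainError):
            receptor_grid_scan(p, 1, 5)
        with pytest.raises(DomainError):
            receptor_grid_scan(p, 3, 0.5)
        with pytest.raises(DomainError):
            receptor_grid_scan(p, 3, 5, center=0.0)


class TestLogElasticity:
    def test_balanced_receptors_symmetric(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=50.0, R2tot=50.0)
        e1 = log_elasticity(p, "R1")
        e2 = log_elasticity(p, "R2")
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_imbalanced_ratio_at_least_ten(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=1e2, R2tot=1e4)
        ratio = log_elasticity(p, "R1") / log_elasticity(p, "R2")
        assert ratio >= 10.0

    def test_richardson_order(self):
        # halving the step shrinks the error ~4x (second-order accurate)
        p = MinimalParams(L=0.1, K1=10.0, K2=1.0, R1tot=2.0, R2tot=9.0)
        e_fine = log_elasticity(p, "R1", rel_step=0.001)
        err1 = abs(log_elasticity(p, "R1", rel_step=0.08) - e_fine)
        err2 = abs(log_elasticity(p, "R1", rel_step=0.04) - e_fine)
        assert err2 < err1 / 2.5

    def test_zero_sa_raises(self):
        p = MinimalParams(L=0.0, K1=1000, K2=10, R1tot=1, R2tot=1)
        with pytest.raises(UndefinedElasticityError):
            log_elasticity(p, "R1")

    def test_bad_arguments(self):
        p = MinimalParams(L=0.1, K1=1000, K2=10, R1tot=1, R2tot=1)
        with pytest.raises(DomainError):
            log_elasticity(p, "R3")
        with pytest.raises(DomainError):
            log_elasticity(p, "R1", rel_step=0.9)
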