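"""NMR fitting: deconvolution, isotherms, displacement, CPMG dispersion."""

import numpy as np
import pytest

from cation_allostery import fixtures, nmr


# --- deconvolution ----------------------------------------------------------

FREQ = np.linspace(-600.0, 600.0, 1201)
THREE = [(-150.0, 60.0, 3.0), (40.0, 90.0, 1.5), (220.0, 70.0, 0.8)]


def _spectrum(components, noise=0.0, seed=0):
    spec = fixtures.SyntheticCurveSpec(
        model="lorentzian_mix", truth={"components": components},
        design={"freq_hz": FREQ}, noise=noise, seed=seed)
    return fixtures.gen_curve(spec)


def test_single_lorentzian_recovered_exactly():
    df = _spectrum([(25.0, 80.0, 2.0)])
    mix = nmr.deconvolve(df["freq_hz"], df["intensity"], k=1)
    assert mix.centers[0] == pytest.approx(25.0, rel=1e-6)
    assert mix.fwhms[0] == pytest.approx(80.0, rel=1e-6)
    assert mix.areas[0] == pytest.approx(2.0, rel=1e-6)


def test_three_state_populations_recovered():
    df = _spectrum(THREE)
    mix = nmr.deconvolve(df["freq_hz"], df["intensity"], k=3)
    order = np.argsort(mix.centers)
    pops = np.array(mix.areas)[order] / sum(mix.areas)
    truth = np.array([a for _, _, a in THREE]) / sum(a for _, _, a in THREE)
    np.testing.assert_allclose(pops, truth, atol=1e-3)
    assert sum(mix.populations.values()) == pytest.approx(1.0, abs=1e-9)
    assert set(mix.populations) == {"S1-2", "S3", "S3p"}


def test_width_constraints_are_honoured():
    df = _spectrum(THREE)
    cons = [{"fwhm_bounds": (0.9 * w, 1.1 * w)} for _, w, _ in THREE]
    mix = nmr.deconvolve(df["freq_hz"], df["intensity"], k=3, constraints=cons)
    order = np.argsort(mix.centers)
    for idx, (_, w, _) in zip(order, THREE):
        assert 0.9 * w - 1e-9 <= mix.fwhms[idx] <= 1.1 * w + 1e-9


def test_populations_invariant_under_intensity_scaling():
    df = _spectrum(THREE, noise=0.02, seed=5)
    m1 = nmr.deconvolve(df["freq_hz"], df["intensity"], k=3)
    m2 = nmr.deconvolve(df["freq_hz"], 37.5 * df["intensity"], k=3)
    for lab in m1.populations:
        # equality up to optimizer stopping tolerance (absolute parameter
        # steps in leastsq are not scale-free)
        assert m2.populations[lab] == pytest.approx(m1.populations[lab], abs=1e-4)


# --- isotherm ---------------------------------------------------------------

def test_isotherm_exact_and_midpoint():
    x = np.array([10.0, 30.0, 61.0, 150.0, 500.0])
    y = nmr.hyperbola(x, 150.0, 61.0)
    fit = nmr.fit_isotherm(x, y)
    assert fit.kd_mM == pytest.approx(61.0, rel=1e-9)
    assert fit.amplitude == pytest.approx(150.0, rel=1e-9)
    assert nmr.hyperbola(np.array([61.0]), 150.0, 61.0)[0] == pytest.approx(75.0)


def test_isotherm_kd_scales_with_concentration_units():
    rng = np.random.default_rng(2)
    x = np.array([10.0, 25.0, 80.0, 200.0, 900.0])
    y = nmr.hyperbola(x, 120.0, 55.0) * (1 + 0.03 * rng.standard_normal(5))
    f1 = nmr.fit_isotherm(x, y)
    f2 = nmr.fit_isotherm(1000.0 * x, y)  # mM -> uM
    assert f2.kd_mM == pytest.approx(1000.0 * f1.kd_mM, rel=1e-6)


def test_isotherm_needs_three_distinct_points():
    with pytest.raises(ValueError):
        nmr.fit_isotherm([1.0, 1.0, 2.0], [0.1, 0.1, 0.2])


# --- displacement -----------------------------------------------------------

def test_displacement_exact_and_midpoint():
    x = np.array([0.5, 2.0, 8.0, 30.0, 120.0, 500.0])
    ki, y0, yinf = 12.0, 90.0, 10.0
    y = yinf + (y0 - yinf) * ki / (ki + x)
    fit = nmr.fit_displacement(x, y)
    assert fit.ki == pytest.approx(ki, rel=1e-8)
    mid = yinf + (y0 - yinf) * ki / (ki + ki)
    assert mid == pytest.approx((y0 + yinf) / 2)


def test_displacement_noisy_median_recovery():
    x = np.geomspace(0.5, 500, 10)
    ki, y0, yinf = 12.0, 90.0, 10.0
    y_true = yinf + (y0 - yinf) * ki / (ki + x)
    fits = []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        y = y_true * (1 + 0.05 * rng.standard_normal(x.size))
        fits.append(nmr.fit_displacement(x, y).ki)
    assert abs(np.median(fits) - ki) / ki < 0.15


# --- CPMG -------------------------------------------------------------------

def _model(p_b=3e-4, tau_us=480.0, dw=2e4):
    return nmr.DispersionModel(
        p_b=p_b, tau_b=tau_us * 1e-6, dw_ref=dw, ref_field=158.7,
        r2_0={158.7: 22.0, 185.2: 25.0})


def test_cpmg_refocusing_limit():
    m = _model()
    r2 = nmr.cpmg_forward(m, [10 * m.k_ex], 158.7)[0]
    assert r2 == pytest.approx(22.0, rel=0.01)


def test_cpmg_no_exchange_is_flat():
    m = _model(p_b=1e-12)
    nu = np.geomspace(50, 2000, 8)
    r2 = nmr.cpmg_forward(m, nu, 158.7)
    np.testing.assert_allclose(r2, 22.0, atol=1e-6)


def test_cpmg_population_symmetry():
    """Phi_ex = p(1-p)dw^2 makes the profile invariant under p <-> 1-p at
    fixed k_ex."""
    nu = np.geomspace(50, 2000, 8)
    k_ex = 2000.0
    r2_0 = {158.7: 22.0, 185.2: 25.0}
    m_lo = nmr.DispersionModel(p_b=0.2, tau_b=1.0 / (k_ex * (1 - 0.2)),
                               dw_ref=2e4, ref_field=158.7, r2_0=r2_0)
    m_hi = nmr.DispersionModel(p_b=0.8, tau_b=1.0 / (k_ex * (1 - 0.8)),
                               dw_ref=2e4, ref_field=158.7, r2_0=r2_0)
    assert m_lo.k_ex == pytest.approx(m_hi.k_ex)
    assert m_lo.phi(158.7) == pytest.approx(m_hi.phi(158.7))
    np.testing.assert_allclose(
        nmr.cpmg_forward(m_lo, nu, 158.7), nmr.cpmg_forward(m_hi, nu, 158.7),
        rtol=1e-12,
    )


def test_cpmg_monotone_nonincreasing_over_parameter_grid():
    nu = np.geomspace(20, 5000, 40)
    for p_b in (1e-4, 5e-3, 0.1):
        for tau_us in (100.0, 480.0, 2000.0):
            r2 = nmr.cpmg_forward(_model(p_b=p_b, tau_us=tau_us), nu, 158.7)
            assert np.all(np.diff(r2) <= 1e-9)
            assert np.all(r2 >= 22.0 - 1e-9)


def test_cpmg_global_fit_noiseless_exact():
    truth = {"p_b": 3e-4, "tau_b_s": 480e-6, "dw_ref_rad_s": 2e4,
             "ref_field_MHz": 158.7, "r2_0_s1": {158.7: 22.0, 185.2: 25.0}}
    spec = fixtures.SyntheticCurveSpec(
        model="cpmg_dispersion", truth=truth,
        design={"fields_MHz": [158.7, 185.2],
                "nu_cpmg_Hz": list(np.geomspace(50, 2000, 12))},
        noise=0.0, seed=0)
    df = fixtures.gen_curve(spec)
    fit = nmr.cpmg_global_fit(df, dw_ref=2e4, ref_field=158.7)
    assert not fit.no_exchange
    assert fit.model.p_b == pytest.approx(3e-4, rel=1e-6)
    assert fit.model.tau_b == pytest.approx(480e-6, rel=1e-6)
    assert fit.model.r2_0[158.7] == pytest.approx(22.0, rel=1e-6)


def test_cpmg_flat_data_flagged_no_exchange():
    nu = np.geomspace(50, 2000, 8)
    rows = [(158.7, v, 22.0) for v in nu] + [(185.2, v, 25.0) for v in nu]
    import pandas as pd

    df = pd.DataFrame(rows, columns=["field_MHz", "nu_cpmg_Hz", "R2eff_s1"])
    fit = nmr.cpmg_global_fit(df, dw_ref=2e4, ref_field=158.7)
    assert fit.no_exchange


def test_dispersion_model_validation():
    with pytest.raises(ValueError):
        nmr.DispersionModel(p_b=0.0, tau_b=1e-4, dw_ref=1e4, ref_field=158.7, r2_0={})
    with pytest.raises(ValueError):
        nmr.DispersionModel(p_b=0.1, tau_b=-1.0, dw_ref=1e4, ref_field=158.7, r2_0={})
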