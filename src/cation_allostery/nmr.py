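"""Quantitative NMR analysis.

Three fit families used throughout the analysis:

* multi-Lorentzian spectral deconvolution with area-based populations
  (¹⁹F spectra resolved into the inactive ensemble S₁₋₂, the activation
  intermediate S₃ and the active state S₃′);
* fast-exchange binding isotherms, y = A·x/(K_d + x), for linewidth or
  chemical-shift titrations (²³Na, ²⁵Mg), plus the one-site displacement
  curve used for Ca²⁺/Mg²⁺ competition (K_i);
* global two-field CPMG relaxation-dispersion fitting of a two-site
  fast-exchange (Luz-Meiboom) model for the ion bound fraction and
  bound-state lifetime.

Identifiability note: in the fast-exchange limit a dispersion profile
determines only Φ_ex = p_b(1−p_b)·Δω² and k_ex (Φ scales exactly with B², so
a second field constrains the model but cannot split p_b from Δω).  The
global fitter therefore takes the chemical-shift difference Δω as a known
constant — in practice obtained from the fast-exchange shift titration — and
converts the fitted (Φ_ex, k_ex) into (p_b, τ_b).
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import lmfit

__all__ = [
    "lorentzian",
    "hyperbola",
    "StateMix",
    "deconvolve",
    "IsothermFit",
    "fit_isotherm",
    "DisplacementFit",
    "fit_displacement",
    "DispersionModel",
    "cpmg_forward",
    "DispersionFit",
    "cpmg_global_fit",
    "FitError",
]

DEFAULT_STATE_LABELS = ("S1-2", "S3", "S3p")


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge or is degenerate."""


def lorentzian(freq: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    """Area-normalized Lorentzian: integrates to `area`, FWHM `fwhm`."""
    hw = fwhm / 2.0
    return area * hw / (np.pi * ((freq - center) ** 2 + hw**2))


def hyperbola(x: np.ndarray, amplitude: float, kd: float) -> np.ndarray:
    """Fast-exchange saturation hyperbola y = A·x/(K_d + x)."""
    return amplitude * x / (kd + x)


# ---------------------------------------------------------------------------
# Spectral deconvolution
# ---------------------------------------------------------------------------

@dataclass
class StateMix:
    """Lorentzian component set with normalized state populations."""

    labels: List[str]
    centers: List[float]
    fwhms: List[float]
    areas: List[float]
    baseline: float
    populations: Dict[str, float]
    residual_norm: float
    degenerate: bool = False

    def component(self, label: str) -> Tuple[float, float, float]:
        i = self.labels.index(label)
        return self.centers[i], self.fwhms[i], self.areas[i]


def _initial_centers(freq, intensity, k):
    """k most intense well-separated local maxima (fallback: quantiles)."""
    from scipy.signal import find_peaks

    span = float(freq.max() - freq.min())
    min_sep_pts = max(1, int(0.03 * len(freq)))
    idx, _ = find_peaks(intensity, distance=min_sep_pts)
    idx = sorted(idx, key=lambda i: -intensity[i])
    picked: List[float] = []
    for i in idx:
        f = float(freq[i])
        if all(abs(f - p) > 0.04 * span for p in picked):
            picked.append(f)
        if len(picked) == k:
            break
    while len(picked) < k:
        picked.append(float(np.quantile(freq, (len(picked) + 1) / (k + 1))))
    return sorted(picked)


def deconvolve(
    freq: Sequence[float],
    intensity: Sequence[float],
    k: int = 3,
    constraints: Optional[Sequence[dict]] = None,
    labels: Optional[Sequence[str]] = None,
    fit_baseline: bool = True,
    n_starts: int = 4,
) -> StateMix:
    """Least-squares decomposition of a spectrum into k Lorentzians + flat
    baseline, with populations as area fractions.

    `constraints` is an optional per-component list of dicts with any of
    ``center``, ``fwhm`` (fixed value) or ``center_bounds``, ``fwhm_bounds``
    ((lo, hi) tuples) — the mechanism by which independently measured T₂
    linewidths stabilise the deconvolution.  Initialisation is multi-start
    with a deterministic jitter; the best residual wins.  A fit in which two
    components collapse onto each other or an area vanishes is flagged
    ``degenerate`` rather than silently returned.
    """
    freq = np.asarray(freq, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if freq.shape != intensity.shape or freq.size < 3 * k + 1:
        raise ValueError("spectrum too short for requested component count")
    constraints = list(constraints or [{} for _ in range(k)])
    if len(constraints) != k:
        raise ValueError("need one constraint dict per component")
    if labels is None:
        labels = list(DEFAULT_STATE_LABELS) if k == 3 else [f"C{i+1}" for i in range(k)]
    labels = list(labels)

    span = float(freq.max() - freq.min())
    total_area = float(np.trapezoid(np.clip(intensity, 0, None), freq))
    centers0 = _initial_centers(freq, intensity, k)
    # honour explicit center hints in the initial guess
    for i, con in enumerate(constraints):
        if "center" in con:
            centers0[i] = float(con["center"])
        elif "center_bounds" in con:
            lo, hi = con["center_bounds"]
            centers0[i] = 0.5 * (lo + hi)

    def build_params(jitter_rng, width_scale=1.0) -> lmfit.Parameters:
        p = lmfit.Parameters()
        for i, con in enumerate(constraints):
            c0 = centers0[i] + (jitter_rng.uniform(-0.02, 0.02) * span if jitter_rng else 0.0)
            w0 = con.get("fwhm", None)
            if w0 is None:
                wb = con.get("fwhm_bounds")
                w0 = 0.5 * (wb[0] + wb[1]) if wb else max(width_scale * span / (6 * k), 1e-6)
            p.add(f"c{i}", value=c0)
            if "center" in con:
                p[f"c{i}"].set(value=float(con["center"]), vary=False)
            elif "center_bounds" in con:
                p[f"c{i}"].set(min=con["center_bounds"][0], max=con["center_bounds"][1])
            else:
                p[f"c{i}"].set(min=freq.min(), max=freq.max())
            p.add(f"w{i}", value=float(w0), min=1e-9)
            if "fwhm" in con:
                p[f"w{i}"].set(value=float(con["fwhm"]), vary=False)
            elif "fwhm_bounds" in con:
                p[f"w{i}"].set(min=con["fwhm_bounds"][0], max=con["fwhm_bounds"][1])
            else:
                p[f"w{i}"].set(max=2 * span)
            # area from the local peak height: h = 2A/(pi w)
            h = float(np.interp(c0, freq, intensity))
            a0 = max(h * math.pi * float(p[f"w{i}"].value) / 2.0, total_area / (10 * k), 1e-12)
            p.add(f"a{i}", value=a0, min=0.0)
        p.add("base", value=0.0, vary=fit_baseline)
        return p

    def residual(p):
        y = np.full_like(freq, p["base"].value)
        for i in range(k):
            y = y + lorentzian(freq, p[f"c{i}"].value, p[f"w{i}"].value, p[f"a{i}"].value)
        return y - intensity

    starts = [(None, 1.0), (None, 0.5), (None, 2.0)]
    for s in range(max(0, n_starts - 3)):
        starts.append((np.random.default_rng(1234 + s), 1.0 + 0.5 * (s % 3)))
    best = None
    for rng, wscale in starts:
        try:
            res = lmfit.minimize(residual, build_params(rng, wscale), method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("deconvolution failed to converge from any start")

    p = best.params
    centers = [float(p[f"c{i}"].value) for i in range(k)]
    fwhms = [float(p[f"w{i}"].value) for i in range(k)]
    areas = [float(p[f"a{i}"].value) for i in range(k)]
    area_sum = sum(areas)
    degenerate = area_sum <= 0
    if not degenerate:
        for i in range(k):
            for j in range(i + 1, k):
                if abs(centers[i] - centers[j]) < 0.05 * min(fwhms[i], fwhms[j]):
                    degenerate = True
        if min(areas) < 1e-9 * area_sum and k > 1:
            degenerate = True
    pops = {lab: (a / area_sum if area_sum > 0 else np.nan) for lab, a in zip(labels, areas)}
    return StateMix(
        labels=labels,
        centers=centers,
        fwhms=fwhms,
        areas=areas,
        baseline=float(p["base"].value),
        populations=pops,
        residual_norm=float(np.sqrt(best.chisqr)),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Binding isotherms
# ---------------------------------------------------------------------------

@dataclass
class IsothermFit:
    kd_mM: float
    amplitude: float
    kd_stderr: Optional[float]
    amplitude_stderr: Optional[float]
    kd_ci95: Tuple[float, float]
    residuals: np.ndarray


def fit_isotherm(x: Sequence[float], y: Sequence[float]) -> IsothermFit:
    """Nonlinear least-squares fit of y = A·x/(K_d + x).

    The K_d confidence interval is the ±1.96·stderr band from the fit
    covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x[x > 0]).size < 3:
        raise ValueError("need at least 3 distinct positive concentrations")

    model = lmfit.Model(lambda x, amplitude, kd: hyperbola(x, amplitude, kd))
    params = model.make_params(
        amplitude=dict(value=float(np.max(y)), min=0),
        kd=dict(value=float(np.median(x)), min=1e-12),
    )
    res = model.fit(y, params, x=x)
    if not res.success:
        raise FitError(f"isotherm fit failed: {res.message}")
    kd = float(res.params["kd"].value)
    kerr = res.params["kd"].stderr
    ci = (kd - 1.96 * kerr, kd + 1.96 * kerr) if kerr else (np.nan, np.nan)
    return IsothermFit(
        kd_mM=kd,
        amplitude=float(res.params["amplitude"].value),
        kd_stderr=float(kerr) if kerr else None,
        amplitude_stderr=float(res.params["amplitude"].stderr)
        if res.params["amplitude"].stderr
        else None,
        kd_ci95=ci,
        residuals=np.asarray(res.residual),
    )


@dataclass
class DisplacementFit:
    ki: float
    y0: float
    y_inf: float
    ki_stderr: Optional[float]


def fit_displacement(x: Sequence[float], y: Sequence[float]) -> DisplacementFit:
    """One-site displacement curve y = y_inf + (y0 − y_inf)·K_i/(K_i + x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def f(x, y0, y_inf, ki):
        return y_inf + (y0 - y_inf) * ki / (ki + x)

    model = lmfit.Model(f)
    params = model.make_params(
        y0=float(y[np.argmin(x)]),
        y_inf=float(y[np.argmax(x)]),
        ki=dict(value=float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, min=1e-12),
    )
    res = model.fit(y, params, x=x)
    if not res.success:
        raise FitError(f"displacement fit failed: {res.message}")
    return DisplacementFit(
        ki=float(res.params["ki"].value),
        y0=float(res.params["y0"].value),
        y_inf=float(res.params["y_inf"].value),
        ki_stderr=float(res.params["ki"].stderr) if res.params["ki"].stderr else None,
    )


# ---------------------------------------------------------------------------
# CPMG relaxation dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Two-site fast-exchange parameters.

    p_b       bound fraction (0..1)
    tau_b     bound-state lifetime in s (τ_b = 1/k_off; k_ex = k_off/(1−p_b))
    dw_ref    chemical-shift difference in rad/s at `ref_field`; Δω scales
              linearly with the field
    ref_field reference field as the nuclear Larmor frequency in MHz
    r2_0      baseline transverse relaxation per field, s⁻¹
    """

    p_b: float
    tau_b: float
    dw_ref: float
    ref_field: float
    r2_0: Dict[float, float]

    def __post_init__(self):
        if not 0 < self.p_b < 1:
            raise ValueError("p_b must lie strictly between 0 and 1")
        if self.tau_b <= 0:
            raise ValueError("tau_b must be positive")

    @property
    def k_off(self) -> float:
        return 1.0 / self.tau_b

    @property
    def k_ex(self) -> float:
        return self.k_off / (1.0 - self.p_b)

    def phi(self, field: float) -> float:
        dw = self.dw_ref * field / self.ref_field
        return self.p_b * (1.0 - self.p_b) * dw**2


def _luz_meiboom(nu, r2_0, phi, k_ex):
    nu = np.asarray(nu, dtype=float)
    x = k_ex / (4.0 * nu)
    return r2_0 + (phi / k_ex) * (1.0 - np.tanh(x) / x)


def cpmg_forward(model: DispersionModel, nu_cpmg: Sequence[float], field: float) -> np.ndarray:
    """Luz-Meiboom R2eff(ν) = R2,0 + (Φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)]."""
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_CPMG must be strictly positive")
    fld = float(field)
    if fld not in model.r2_0:
        raise KeyError(f"no R2,0 recorded for field {field} MHz")
    return _luz_meiboom(nu, model.r2_0[fld], model.phi(fld), model.k_ex)


@dataclass
class DispersionFit:
    """Global fit result: physical model plus the directly fitted exchange
    observables and diagnostics."""

    model: Optional[DispersionModel]
    phi_ref: float
    k_ex: float
    phi_stderr: Optional[float]
    k_ex_stderr: Optional[float]
    redchi: float
    no_exchange: bool = False

    @property
    def p_b(self) -> float:
        return self.model.p_b

    @property
    def tau_b(self) -> float:
        return self.model.tau_b


def _pb_from_phi(phi_ref: float, dw_ref: float) -> float:
    """Solve Φ = p(1−p)Δω² for the dilute (p < 1/2) branch."""
    q = phi_ref / dw_ref**2
    if q >= 0.25:
        return 0.5
    return 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * q))


K_EX_STARTS = (200.0, 500.0, 1000.0, 2000.0, 5000.0, 10000.0)


def cpmg_global_fit(
    data,
    dw_ref: float,
    ref_field: Optional[float] = None,
    min_dispersion: float = 0.05,
) -> DispersionFit:
    """Global two-site fast-exchange fit across one or more fields.

    Parameters
    ----------
    data:
        DataFrame with columns field_MHz, nu_cpmg_Hz, R2eff_s1 (≥ 6 ν points
        per field recommended).
    dw_ref:
        Known chemical-shift difference (rad/s) at `ref_field`; see module
        docstring for why this is supplied rather than fitted.
    ref_field:
        Larmor frequency (MHz) at which dw_ref is quoted; defaults to the
        lowest field present.
    min_dispersion:
        Smallest fitted dispersion amplitude Φ/k_ex (s⁻¹) still considered
        evidence of exchange; below it the result is flagged ``no_exchange``.

    Shared (Φ_ref, k_ex) and a per-field R2,0 are fitted with a deterministic
    multi-start over k_ex; the physical (p_b, τ_b) are recovered from Φ_ref
    via the known Δω.
    """
    import pandas as pd

    df = pd.DataFrame(data)
    fields = sorted(df["field_MHz"].unique())
    if ref_field is None:
        ref_field = float(fields[0])
    for fld in fields:
        if (df["field_MHz"] == fld).sum() < 6:
            raise ValueError("need at least 6 nu_CPMG points per field")

    def residual(p):
        out = []
        for i, fld in enumerate(fields):
            sub = df[df["field_MHz"] == fld]
            phi = p["phi_ref"].value * (fld / ref_field) ** 2
            y = _luz_meiboom(sub["nu_cpmg_Hz"].values, p[f"r2_0_{i}"].value, phi, p["k_ex"].value)
            out.append(y - sub["R2eff_s1"].values)
        return np.concatenate(out)

    amp_guess = max(
        float(df.groupby("field_MHz")["R2eff_s1"].agg(lambda s: s.max() - s.min()).max()),
        1e-6,
    )
    best = None
    for k0 in K_EX_STARTS:
        p = lmfit.Parameters()
        p.add("phi_ref", value=amp_guess * k0, min=0.0)
        p.add("k_ex", value=k0, min=1.0, max=1e7)
        for i, fld in enumerate(fields):
            r2_min = float(df.loc[df["field_MHz"] == fld, "R2eff_s1"].min())
            p.add(f"r2_0_{i}", value=r2_min, min=0.0)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("CPMG global fit failed from every start")

    phi_ref = float(best.params["phi_ref"].value)
    k_ex = float(best.params["k_ex"].value)
    amp0 = phi_ref / k_ex  # dispersion amplitude at nu -> 0
    no_exchange = amp0 < min_dispersion
    model = None
    if not no_exchange:
        p_b = _pb_from_phi(phi_ref, dw_ref)
        if 0 < p_b < 1:
            k_off = k_ex * (1.0 - p_b)
            model = DispersionModel(
                p_b=p_b,
                tau_b=1.0 / k_off,
                dw_ref=dw_ref,
                ref_field=ref_field,
                r2_0={
                    float(fld): float(best.params[f"r2_0_{i}"].value)
                    for i, fld in enumerate(fields)
                },
            )
        else:
            no_exchange = True
    perr = best.params["phi_ref"].stderr
    kerr = best.params["k_ex"].stderr
    return DispersionFit(
        model=model,
        phi_ref=phi_ref,
        k_ex=k_ex,
        phi_stderr=float(perr) if perr else None,
        k_ex_stderr=float(kerr) if kerr else None,
        redchi=float(best.redchi),
        no_exchange=no_exchange,
    )
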