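"""Binding, labeling, and thermal-stability assay quantification.

Three estimators:

* :func:`fit_homologous_competition` — bounded nonlinear least squares of
  scintillation counts against the homologous-competition binding model
  ``CPM = Bmax·[hot] / ([hot] + [cold] + K_D) + background`` (all
  concentrations in the same unit, typically nM), giving the dissociation
  constant with standard errors from the local curvature.
* :func:`labeling_efficiency` — cysteine-alkylation efficiency from gel
  band densitometry, the sample labeled-fraction over the SDS-denatured
  control labeled-fraction, in percent.
* :func:`melt_temperature` — melting temperature as the interior maximum
  of the smoothed first derivative of a dye-fluorescence melting curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "BindingFit",
    "fit_homologous_competition",
    "labeling_efficiency",
    "melt_temperature",
    "MeltResult",
    "dilution_concentration",
]


@dataclass(frozen=True)
class BindingFit:
    """Fitted homologous-competition parameters.

    Standard errors come from the covariance of the least-squares
    solution; ``identifiable`` is False when the data carry no binding
    signal (flat counts) and the reported Kd is then meaningless.
    """

    kd: float
    bmax: float
    background: float
    kd_stderr: float | None
    bmax_stderr: float | None
    background_stderr: float | None
    hot_conc: float
    residuals: np.ndarray
    success: bool
    identifiable: bool
    message: str = ""

    def predict(self, cold):
        cold = np.asarray(cold, float)
        return (self.bmax * self.hot_conc
                / (self.hot_conc + cold + self.kd) + self.background)


def fit_homologous_competition(cold, cpm, hot_conc: float,
                               weights=None, init: str | dict = "auto") -> BindingFit:
    """Fit the homologous-competition binding equation.

    Parameters
    ----------
    cold, cpm
        Competitor concentrations and counts; replicates are fitted
        jointly as individual points.
    hot_conc
        Fixed labeled-ligand concentration (same unit as ``cold``).
    weights
        Optional per-point weights (e.g. 1/SEM); default unweighted.
    init
        ``"auto"`` starts from background = min(CPM), Bmax = max − min,
        Kd = hot concentration; or a dict with keys kd/bmax/background.

    Raises on invalid inputs; non-convergence returns ``success=False``
    with the solver message rather than silent defaults.  Kd is constrained
    positive by bounds.
    """
    import lmfit

    cold = np.asarray(cold, float)
    cpm = np.asarray(cpm, float)
    if cold.shape != cpm.shape:
        raise ValueError("cold and cpm must have the same shape")
    if np.any(cold < 0) or hot_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(cold)) < 4:
        raise ValueError("need >= 4 distinct competitor concentrations "
                         "for a 3-parameter fit")

    span = float(cpm.max() - cpm.min())
    identifiable = span > 1e-9 * max(abs(cpm).max(), 1.0)

    def model(x, kd, bmax, background):
        return bmax * hot_conc / (hot_conc + x + kd) + background

    m = lmfit.Model(model, independent_vars=["x"])
    params = m.make_params()
    if init == "auto":
        start = {"background": float(cpm.min()), "bmax": span, "kd": float(hot_conc)}
    else:
        start = dict(init)
    params["kd"].set(value=max(start["kd"], 1e-9), min=1e-12)
    params["bmax"].set(value=max(start["bmax"], 1e-9), min=0.0)
    params["background"].set(value=start["background"])
    try:
        fit = m.fit(cpm, params, x=cold,
                    weights=np.asarray(weights, float) if weights is not None else None)
    except Exception as exc:  # lmfit raises on pathological inputs
        return BindingFit(np.nan, np.nan, np.nan, None, None, None, hot_conc,
                          np.full_like(cpm, np.nan), False, False, str(exc))

    kd_err = fit.params["kd"].stderr
    if identifiable and (kd_err is None or not np.isfinite(kd_err)
                         or fit.params["bmax"].value <= 1e-6 * max(span, 1.0)):
        identifiable = False
    return BindingFit(
        kd=float(fit.params["kd"].value),
        bmax=float(fit.params["bmax"].value),
        background=float(fit.params["background"].value),
        kd_stderr=kd_err, bmax_stderr=fit.params["bmax"].stderr,
        background_stderr=fit.params["background"].stderr,
        hot_conc=hot_conc,
        residuals=np.asarray(fit.residual, float),
        success=bool(fit.success), identifiable=identifiable,
        message=str(fit.message))


def labeling_efficiency(st_labeled, st_unlabeled, c_labeled, c_unlabeled):
    """Alkylation labeling efficiency in percent.

    ``efficiency = [St_lab/(St_lab+St_unlab)] / [C_lab/(C_lab+C_unlab)] × 100``
    where St is the sample lane at a timepoint and C the SDS-denatured
    fully-alkylated control.  Accepts scalars or arrays (per timepoint).
    Invariant to uniform rescaling of a lane's intensities.
    """
    st_l = np.asarray(st_labeled, float)
    st_u = np.asarray(st_unlabeled, float)
    c_l = np.asarray(c_labeled, float)
    c_u = np.asarray(c_unlabeled, float)
    if np.any(st_l < 0) or np.any(st_u < 0) or np.any(c_l < 0) or np.any(c_u < 0):
        raise ValueError("band intensities must be non-negative")
    c_total = c_l + c_u
    if np.any(c_total == 0) or np.any(c_l == 0):
        raise ValueError("control labeled fraction is zero; cannot normalise")
    st_total = st_l + st_u
    if np.any(st_total == 0):
        raise ValueError("sample lane has zero total intensity")
    eff = (st_l / st_total) / (c_l / c_total) * 100.0
    return float(eff) if eff.ndim == 0 else eff


@dataclass(frozen=True)
class MeltResult:
    """Melting temperature estimate; ``tm`` is None when no interior
    transition was detected (derivative maximum at a ramp boundary)."""

    tm: float | None
    derivative: np.ndarray
    temperature: np.ndarray
    detected: bool
    message: str = ""


def melt_temperature(temperature, fluorescence, smooth_window: int = 5,
                     smooth_order: int = 2) -> MeltResult:
    """Tm as the interior maximum of the smoothed first derivative.

    The curve is smoothed with a Savitzky–Golay filter (default 5-point
    window, order 2), differentiated by central differences, and the
    maximum refined by parabolic interpolation around the grid peak.
    Temperatures must be strictly increasing with at least 10 points.  A
    maximum at either ramp endpoint means no transition was observed and is
    flagged instead of reported.
    """
    t = np.asarray(temperature, float)
    f = np.asarray(fluorescence, float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("temperature and fluorescence must be matching 1-D arrays")
    if len(t) < 10:
        raise ValueError("need at least 10 points spanning the transition")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    window = min(smooth_window, len(f) if len(f) % 2 else len(f) - 1)
    if window > smooth_order:
        f_s = savgol_filter(f, window, smooth_order)
    else:
        f_s = f
    dfdt = np.gradient(f_s, t)
    i = int(np.argmax(dfdt))
    spread = float(dfdt.max() - dfdt.min())
    scale = max(abs(float(dfdt.max())), abs(float(dfdt.min())), 1e-300)
    if spread < 0.05 * scale:
        return MeltResult(None, dfdt, t, False,
                          "no transition detected (derivative is flat)")
    if i == 0 or i == len(t) - 1:
        return MeltResult(None, dfdt, t, False,
                          "no transition detected (derivative maximum at ramp boundary)")
    # parabolic refinement around the grid maximum
    y0, y1, y2 = dfdt[i - 1], dfdt[i], dfdt[i + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    offset = float(np.clip(offset, -1, 1))
    tm = t[i] + offset * (t[min(i + 1, len(t) - 1)] - t[i - 1]) / 2
    return MeltResult(float(tm), dfdt, t, True)


def dilution_concentration(stock_conc: float, v_sample: float, v_diluent: float) -> float:
    """Concentration after diluting ``v_sample`` of stock into ``v_diluent``
    (same volume units; e.g. 4 µL of 0.675 mg/mL into 56 µL → 0.045 mg/mL)."""
    if v_sample <= 0 or v_diluent < 0:
        raise ValueError("volumes must be positive")
    return stock_conc * v_sample / (v_sample + v_diluent)
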