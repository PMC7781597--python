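"""Reductions of two-electrode voltage-clamp (TEVC) measurements.

Covers the standard oocyte workflow quantities: fold effect of a drug on
the outward current at 0 mV, temperature sensitivity as Q10 (ratio of
currents 10 °C apart), normalized drug time courses, and nonlinear
least-squares fits of dose-response data:

* activation by a ligand, standard Hill form
  ``I = I_min + (I_max - I_min) * c**H / (EC50**H + c**H)``;
* inhibition by external acidification, normalized to the current at
  pH 9.0, fitted with the modified Hill form
  ``I = I_min + (I_max - I_min) / (1 + 10**((pHmid / pH) * H))``
  in which the exponent carries the *ratio* of the midpoint to the
  measured pH.  This ratio form is unusual — the conventional
  parameterization uses the difference ``(pHmid - pH)`` — so both are
  available and every fit records which form it used.

Fits use trust-region reflective least squares with three deterministic
initializations; parameter standard errors come from the Gauss-Newton
approximation (Jacobian at the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "TimeCourse",
    "fold_effect",
    "q10",
    "current_at_0mv",
    "hill_activation",
    "ph_inhibition_printed",
    "ph_inhibition_difference",
    "fit_activation_ec50",
    "fit_ph_inhibition",
    "normalize_timecourse",
]


@dataclass
class DoseResponseCurve:
    """Tabular dose-response data: x (concentration in µM, or pH), response
    (current in µA or a normalized ratio), and a replicate id per row."""

    data: pd.DataFrame  # columns: x, response, replicate
    x_kind: str = "concentration_uM"

    def __post_init__(self) -> None:
        missing = {"x", "response"} - set(self.data.columns)
        if missing:
            raise ValueError(f"dose-response table missing columns {sorted(missing)}")
        if "replicate" not in self.data.columns:
            self.data = self.data.assign(replicate=0)
        if not np.isfinite(self.data[["x", "response"]].to_numpy()).all():
            raise ValueError("dose-response table contains non-finite values")

    @classmethod
    def from_csv(cls, path: str | Path, x_kind: str = "concentration_uM") -> "DoseResponseCurve":
        return cls(pd.read_csv(path), x_kind=x_kind)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)


@dataclass
class HillFit:
    """Fitted Hill-model parameters with Gauss-Newton standard errors."""

    form: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_points: int

    @property
    def midpoint(self) -> float:
        return self.params["midpoint"]

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "n_points": self.n_points,
        }


# ---------------------------------------------------------------------------
# Scalar reductions
# ---------------------------------------------------------------------------

def fold_effect(pre: float, post: float) -> float:
    """Ratio of the 0 mV current after vs before drug application."""
    if pre <= 0:
        raise ValueError("pre-drug current must be positive")
    return post / pre


def q10(i_20c: float, i_30c: float) -> float:
    """Temperature sensitivity: current at 30 °C over current at 20 °C.

    The two temperatures span exactly 10 °C, so the raw ratio is the Q10.
    """
    if i_20c <= 0 or i_30c <= 0:
        raise ValueError("currents must be positive")
    return i_30c / i_20c


def current_at_0mv(voltage_mV: np.ndarray, current_uA: np.ndarray) -> float:
    """Interpolate the current at 0 mV from a voltage-ramp record."""
    v = np.asarray(voltage_mV, dtype=float)
    i = np.asarray(current_uA, dtype=float)
    if v.min() > 0 or v.max() < 0:
        raise ValueError("ramp does not span 0 mV")
    order = np.argsort(v)
    return float(np.interp(0.0, v[order], i[order]))


# ---------------------------------------------------------------------------
# Model forms
# ---------------------------------------------------------------------------

def hill_activation(c, i_min, i_max, ec50, h):
    c = np.asarray(c, dtype=float)
    ch = np.power(c, h)
    return i_min + (i_max - i_min) * ch / (np.power(ec50, h) + ch)


def ph_inhibition_printed(ph, i_min, i_max, midpoint, h):
    """Modified Hill form with the midpoint/pH *ratio* in the exponent."""
    ph = np.asarray(ph, dtype=float)
    return i_min + (i_max - i_min) / (1.0 + np.power(10.0, (midpoint / ph) * h))


def ph_inhibition_difference(ph, i_min, i_max, midpoint, h):
    """Conventional Hill form with the (midpoint - pH) difference."""
    ph = np.asarray(ph, dtype=float)
    return i_min + (i_max - i_min) / (1.0 + np.power(10.0, (midpoint - ph) * h))


_PH_FORMS = {
    "printed-ratio": ph_inhibition_printed,
    "difference": ph_inhibition_difference,
}


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _fit(model, x, y, starts, lower, upper, names, form) -> HillFit:
    """Multi-start trust-region least squares with Jacobian-based errors."""

    def residual(p):
        return model(x, *p) - y

    best = None
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, dtype=float), lower, upper)
        try:
            res = least_squares(
                residual, p0, bounds=(lower, upper), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return HillFit(form=form, params={}, stderr={}, rss=float("nan"),
                       converged=False, n_points=len(y))

    p = best.x
    rss = float(2.0 * best.cost)
    dof = max(len(y) - len(p), 1)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except Exception:
        se = np.full(len(p), np.nan)
    return HillFit(
        form=form,
        params={n: float(v) for n, v in zip(names, p)},
        stderr={n: float(v) for n, v in zip(names, se)},
        rss=rss,
        converged=True,
        n_points=len(y),
    )


def fit_activation_ec50(curve: DoseResponseCurve) -> HillFit:
    """Fit the standard Hill activation model to a concentration curve.

    Requires >= 4 distinct concentrations.  EC50 is constrained positive
    and the Hill coefficient to (0, 10], which also guarantees the fitted
    curve is monotone in concentration.
    """
    x, y = curve.x, curve.response
    if len(np.unique(x)) < 4:
        raise ValueError("activation fit requires >= 4 distinct concentrations")
    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-12)
    qs = np.quantile(np.unique(x[x > 0]), [0.25, 0.5, 0.75])
    starts = [[ymin, ymax, q, 1.0] for q in qs]
    lower = [-np.inf, -np.inf, 1e-9, 1e-6]
    upper = [np.inf, np.inf, np.inf, 10.0]
    names = ["i_min", "i_max", "midpoint", "h"]
    fit = _fit(hill_activation, x, y, starts, lower, upper, names, form="hill-activation")
    if fit.converged:
        fit.params["ec50"] = fit.params["midpoint"]
        fit.stderr["ec50"] = fit.stderr["midpoint"]
    return fit


def fit_ph_inhibition(curve: DoseResponseCurve, form: str = "printed-ratio") -> HillFit:
    """Fit the external-pH inhibition curve (responses normalized to pH 9.0).

    ``form`` selects the exponent parameterization: "printed-ratio"
    (midpoint/pH) or "difference" (midpoint - pH).  Requires >= 4 distinct
    pH values.  Non-convergence is flagged and parameters withheld.
    """
    if form not in _PH_FORMS:
        raise ValueError(f"form must be one of {sorted(_PH_FORMS)}")
    model = _PH_FORMS[form]
    x, y = curve.x, curve.response
    if len(np.unique(x)) < 4:
        raise ValueError("pH fit requires >= 4 distinct pH values")
    ymin, ymax = float(y.min()), float(y.max())
    mids = np.quantile(np.unique(x), [0.25, 0.5, 0.75])
    if form == "difference":
        starts = [[ymin, ymax, m, 1.0] for m in mids]
        upper_mid, upper_h = 14.0, 50.0
    else:
        # In the ratio form the exponent is (midpoint/pH)*H, so midpoint and
        # H are identified only through their product; scan several H
        # magnitudes and let i_max absorb the offset the form induces.
        starts = [
            [ymin, y2, m, h0]
            for m in mids
            for h0 in (5.0, 15.0, 40.0)
            for y2 in (ymax, 2.0 * ymax - ymin)
        ]
        upper_mid, upper_h = 14.0, np.inf
    lower = [-np.inf, -np.inf, 1e-6, 1e-6]
    upper = [np.inf, np.inf, upper_mid, upper_h]
    names = ["i_min", "i_max", "midpoint", "h"]
    return _fit(model, x, y, starts, lower, upper, names, form=f"ph-{form}")


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """A 0 mV current time course with its normalized series.

    ``normalized`` divides by the first sample, so it starts at exactly 1;
    ``effect_size`` is the normalized value at the final time point.
    """

    time_s: np.ndarray
    current: np.ndarray
    normalized: np.ndarray

    @property
    def effect_size(self) -> float:
        return float(self.normalized[-1])


def normalize_timecourse(time_s: np.ndarray, current: np.ndarray) -> TimeCourse:
    """Normalize a current time course to its initial value."""
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current, dtype=float)
    if t.shape != i.shape or t.ndim != 1 or len(t) == 0:
        raise ValueError("time and current must be matching non-empty 1-D arrays")
    if i[0] <= 0:
        raise ValueError("initial current must be positive for normalization")
    return TimeCourse(time_s=t, current=i, normalized=i / i[0])
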