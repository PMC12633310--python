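"""Closed-form pharmacology models.

Estimators follow the scikit-learn convention: construct with
hyperparameters, ``fit`` with data, read fitted attributes with trailing
underscores.  Concentrations are molar throughout; pEC50 = -log10(EC50/M).

Models
------
- three-parameter logistic dose-response,
  R = bottom + (top - bottom) / (1 + 10**(logEC50 - log10 C))
- 1:1 biosensor kinetics, association R(t) = R_eq (1 - exp(-k_obs t)) with
  k_obs = k_on C + k_off, dissociation R(t) = R_0 exp(-k_off t)
- steady-state (Langmuir) affinity, R_eq = R_max C / (K_D + C)
- radioligand saturation with a linear nonspecific component, and one-site
  competition with the Cheng-Prusoff conversion K_i = IC50 / (1 + L / K_d)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .synthetic import logistic3_response

__all__ = [
    "LogisticDoseResponse",
    "BLIKinetics",
    "SteadyStateAffinity",
    "SaturationBinding",
    "CompetitionBinding",
    "double_reference",
    "ensemble_fret_ratio",
]


def double_reference(sample: np.ndarray, blank_injection: np.ndarray,
                     reference_surface: np.ndarray,
                     reference_blank: np.ndarray | float = 0.0) -> np.ndarray:
    """Standard SPR/BLI double-referencing.

    Subtracts the blank-injection response over the active surface (bulk
    refractive index and injection artifacts) and the analyte response over
    the reference surface corrected by its own blank (nonspecific binding).
    """
    sample = np.asarray(sample, dtype=float)
    return (sample - np.asarray(blank_injection, dtype=float)
            - (np.asarray(reference_surface, dtype=float) - reference_blank))


class LogisticDoseResponse(BaseEstimator):
    """Three-parameter logistic fit of response vs. log10 concentration.

    Zero concentrations are excluded from the log-domain fit and used only
    to anchor the bottom initial estimate.  Fits both stimulation
    (increasing) and inhibition (decreasing) curves; top/bottom are free.

    Fitted attributes: ``bottom_``, ``top_``, ``logec50_``, ``pec50_``,
    ``se_`` (dict of asymptotic standard errors), ``extrapolated_``.
    """

    def __init__(self, max_extrapolation: float = 1.5):
        self.max_extrapolation = max_extrapolation

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        zero = conc <= 0
        bottom0 = float(np.mean(y[zero])) if zero.any() else float(np.min(y))
        conc, y = conc[~zero], y[~zero]
        uniq = np.unique(conc)
        if len(uniq) < 4:
            raise ValueError("need >= 4 distinct nonzero concentrations")
        x = np.log10(conc)

        def model(x, bottom, top, logec50):
            return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - x))

        p0 = [bottom0, float(np.max(y)), float(np.median(x))]
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
        self.bottom_, self.top_, self.logec50_ = map(float, popt)
        if self.top_ == self.bottom_:
            raise RuntimeError("degenerate fit: top == bottom")
        self.pec50_ = -self.logec50_
        se = np.sqrt(np.diag(pcov))
        self.se_ = {"bottom": se[0], "top": se[1], "logec50": se[2]}
        self.extrapolated_ = bool(
            self.logec50_ < x.min() - self.max_extrapolation
            or self.logec50_ > x.max() + self.max_extrapolation)
        self.ec50_ = 10.0 ** self.logec50_
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).ravel()
        return logistic3_response(conc, self.bottom_, self.top_, self.logec50_)


class SteadyStateAffinity(BaseEstimator):
    """Langmuir steady-state affinity fit, R_eq = R_max C / (K_D + C).

    Fitted attributes: ``kd_`` (M), ``rmax_``, ``se_``, ``unreliable_``
    (set when the top tested concentration is below K_D / 10).
    """

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if np.allclose(y, 0):
            raise ValueError("all-zero responses: nothing to fit")

        scale = float(np.max(conc))  # fit in normalized concentration units

        def model(c, rmax, kd):
            return rmax * c / (kd + c)

        p0 = [float(np.max(y)) * 2.0, 1.0]
        popt, pcov = optimize.curve_fit(model, conc / scale, y, p0=p0,
                                        bounds=([0, 0], [np.inf, np.inf]),
                                        maxfev=20000)
        self.rmax_, self.kd_ = float(popt[0]), float(popt[1]) * scale
        se = np.sqrt(np.diag(pcov))
        self.se_ = {"rmax": se[0], "kd": se[1] * scale}
        self.unreliable_ = bool(np.max(conc) < self.kd_ / 10.0)
        return self

    def predict(self, X):
        conc = np.asarray(X, dtype=float).ravel()
        return self.rmax_ * conc / (self.kd_ + conc)


class BLIKinetics(BaseEstimator):
    """1:1 biosensor kinetics from per-concentration sensorgrams.

    Each association phase is fit with a single exponential
    R(t) = R_eq (1 - exp(-k_obs t)) and each dissociation phase with
    R(t) = R_0 exp(-k_off t); k_on is the slope of k_obs vs. concentration
    (k_obs = k_on C + k_off) and K_D = k_off / k_on.  Equilibrium responses
    feed a steady-state affinity fit as well (``equilibrium_``).

    ``fit`` takes a tidy table with columns concentration, time, response.

    Fitted attributes: ``kobs_`` (dict conc -> 1/s), ``kon_`` (1/(M s)),
    ``koff_`` (1/s), ``kd_`` (M), ``kobs_r2_`` (linearity diagnostic),
    ``equilibrium_`` (fitted SteadyStateAffinity).
    """

    def __init__(self, t_assoc: float = 180.0):
        self.t_assoc = t_assoc

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        concs = np.sort(df["concentration"].unique())
        if len(concs) < 3:
            raise ValueError("need >= 3 concentrations")
        kobs, koffs, req = {}, [], {}
        for c in concs:
            sub = df[df["concentration"] == c]
            t = sub["time"].to_numpy(dtype=float)
            r = sub["response"].to_numpy(dtype=float)
            am = t <= self.t_assoc
            ta, ra = t[am], r[am]

            def assoc(t, r_eq, k_obs):
                return r_eq * (1.0 - np.exp(-k_obs * t))

            p0 = [max(float(ra.max()), 1e-9), 1.0 / max(self.t_assoc / 5, 1e-9)]
            popt, _ = optimize.curve_fit(assoc, ta, ra, p0=p0, maxfev=20000)
            kobs[float(c)] = float(popt[1])
            req[float(c)] = float(popt[0])

            dm = t > self.t_assoc
            if dm.sum() >= 3:
                td = t[dm] - self.t_assoc
                rd = r[dm]

                def dissoc(t, r0, k_off):
                    return r0 * np.exp(np.clip(-k_off * t, -700, 700))

                p0 = [max(float(rd[0]), 1e-9), kobs[float(c)] / 2]
                popt, _ = optimize.curve_fit(dissoc, td, rd, p0=p0, maxfev=20000)
                koffs.append(float(popt[1]))

        cs = np.array(sorted(kobs))
        ks = np.array([kobs[c] for c in cs])
        lin = stats.linregress(cs, ks)
        self.kobs_ = kobs
        self.req_ = req
        self.kon_ = float(lin.slope)
        self.kobs_intercept_ = float(lin.intercept)
        self.kobs_r2_ = float(lin.rvalue**2)
        self.koff_ = float(np.mean(koffs)) if koffs else self.kobs_intercept_
        if self.kon_ <= 0 or self.koff_ <= 0:
            raise RuntimeError("negative fitted rate; data inconsistent with 1:1 binding")
        self.kd_ = self.koff_ / self.kon_
        self.equilibrium_ = SteadyStateAffinity().fit(cs, np.array([req[c] for c in cs]))
        return self


class SaturationBinding(BaseEstimator):
    """One-site saturation binding with paired nonspecific measurements.

    The nonspecific counts (radioligand bound in the presence of excess
    cold competitor) are fit as NS * L through the origin; specific
    binding total - NS * L is fit to B_max L / (K_d + L).

    Fitted attributes: ``kd_`` (M), ``bmax_``, ``ns_`` (counts per M).
    """

    def fit(self, X, y, nonspecific=None):
        L = np.asarray(X, dtype=float).ravel()
        total = np.asarray(y, dtype=float).ravel()
        if nonspecific is None:
            raise ValueError("saturation fit requires paired nonspecific counts")
        ns_counts = np.asarray(nonspecific, dtype=float).ravel()
        if np.any(ns_counts > total + 1e-9):
            raise ValueError("nonspecific exceeds total at some concentration")
        self.ns_ = float(np.sum(ns_counts * L) / np.sum(L * L))
        specific = total - self.ns_ * L
        scale = float(np.max(L))

        def model(c, bmax, kd):
            return bmax * c / (kd + c)

        p0 = [float(np.max(specific)) * 1.5, float(np.median(L)) / scale]
        popt, _ = optimize.curve_fit(model, L / scale, specific, p0=p0,
                                     bounds=([0, 0], [np.inf, np.inf]),
                                     maxfev=20000)
        self.bmax_, self.kd_ = float(popt[0]), float(popt[1]) * scale
        return self

    def predict(self, X):
        L = np.asarray(X, dtype=float).ravel()
        return self.bmax_ * L / (self.kd_ + L) + self.ns_ * L


class CompetitionBinding(BaseEstimator):
    """One-site competition binding with Cheng-Prusoff K_i conversion.

    A one-site logistic in log dose gives the IC50; the inhibitor constant
    follows as K_i = IC50 / (1 + L / K_d_hot) where L is the tracer
    concentration and K_d_hot its dissociation constant.
    """

    def __init__(self, hot_conc: float = 1e-9, hot_kd: float = 1e-9):
        self.hot_conc = hot_conc
        self.hot_kd = hot_kd

    def fit(self, X, y):
        logistic = LogisticDoseResponse().fit(X, y)
        self.logistic_ = logistic
        self.ic50_ = logistic.ec50_
        self.ki_ = self.ic50_ / (1.0 + self.hot_conc / self.hot_kd)
        return self

    def predict(self, X):
        return self.logistic_.predict(X)


def ensemble_fret_ratio(wavelengths: np.ndarray, spectrum: np.ndarray,
                        donor_window: tuple[float, float],
                        acceptor_window: tuple[float, float]) -> float:
    """Acceptor/donor ratio of an emission spectrum.

    The spectrum is normalized to the donor-window integral, so the ratio
    is invariant to overall intensity scaling.
    """
    wl = np.asarray(wavelengths, dtype=float)
    sp = np.asarray(spectrum, dtype=float)
    dm = (wl >= donor_window[0]) & (wl <= donor_window[1])
    am = (wl >= acceptor_window[0]) & (wl <= acceptor_window[1])
    donor = float(np.trapezoid(sp[dm], wl[dm]))
    if donor == 0:
        raise ZeroDivisionError("zero donor integral: ratio undefined")
    acceptor = float(np.trapezoid(sp[am], wl[am]))
    return acceptor / donor
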