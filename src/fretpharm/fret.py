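"""Single-molecule FRET trace analysis.

The analysis chain implemented here turns background-corrected donor and
acceptor intensity traces into conformational-state populations:

1. subtract donor->acceptor spectral leakage;
2. locate photobleaching steps by penalized least-squares changepoint
   segmentation (PELT with an L2 segment cost);
3. estimate the per-molecule detection-correction factor gamma from the
   intensity exchange across the acceptor bleach;
4. apply five selection criteria (signal-to-noise >= 5, single-step acceptor
   bleach before donor bleach, gamma within [0.5, 2.5], anticorrelated
   donor/acceptor fluctuations, single-step donor bleach if present);
5. compute the gamma-corrected efficiency E = Ia / (Ia + gamma * Id) over
   the both-dyes-active window;
6. bin E into 30 intervals over [-0.25, 1.25], normalize per molecule, and
   average with equal weight per molecule;
7. fit a two-Gaussian model to the averaged histogram and report state
   populations as normalized component areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.base import BaseEstimator

__all__ = [
    "CorrectionParams",
    "StepResult",
    "QCReport",
    "FretTrace",
    "EnsembleHistogram",
    "TwoGaussianModel",
    "correct_leakage",
    "detect_steps",
    "estimate_gamma",
    "qc_select",
    "compute_fret",
    "build_histogram",
    "population_fractions",
    "idealize_two_state",
    "analyze_traces",
]

HIST_RANGE = (-0.25, 1.25)
N_BINS = 30


@dataclass
class CorrectionParams:
    """Correction constants and selection thresholds.

    leakage       : donor->acceptor spectral leakage fraction subtracted
                    from the raw acceptor signal (default 0.07).
    gamma_bounds  : acceptance interval for the per-molecule gamma factor.
    snr_min       : minimum signal-to-noise ratio (mean total intensity over
                    the residual sd after step-wise idealization).
    anticorr_max  : maximum allowed Pearson correlation of the differenced
                    donor/acceptor series (must be <= this, default -0.2).
    gamma_window  : frames on each side of the acceptor bleach used for the
                    gamma estimate.
    bleach_guard  : frames around the bleach excluded from those windows.
    """

    leakage: float = 0.07
    gamma_bounds: tuple[float, float] = (0.5, 2.5)
    snr_min: float = 5.0
    anticorr_max: float = -0.2
    gamma_window: int = 20
    bleach_guard: int = 2
    min_gamma_side: int = 10
    min_window: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.leakage < 0.5:
            raise ValueError("leakage must lie in [0, 0.5)")
        lo, hi = self.gamma_bounds
        if not (0 < lo < hi):
            raise ValueError("gamma_bounds must be positive and ordered")
        if self.snr_min <= 0:
            raise ValueError("snr_min must be positive")


def correct_leakage(donor: np.ndarray, acceptor_raw: np.ndarray,
                    leakage: float) -> np.ndarray:
    """Subtract the donor leakage component from the raw acceptor signal.

    ``Ia = Ia_raw - leakage * Id``; the donor is unchanged.  Linear and
    invertible; negative results are permitted (the histogram range extends
    below zero for exactly this reason).
    """
    return np.asarray(acceptor_raw, dtype=float) - leakage * np.asarray(donor, dtype=float)


# ---------------------------------------------------------------------------
# changepoint / step detection


@dataclass
class StepResult:
    """Piecewise-constant segmentation of one intensity series.

    ``frames[i]`` is the first frame of segment ``i + 1`` (the frame at
    which the step lands); ``levels`` are segment means; ``sizes`` are the
    level differences across each step.
    """

    frames: np.ndarray
    levels: np.ndarray
    sizes: np.ndarray
    noise_sd: float
    segments: np.ndarray  # (n_segments, 2) start/stop frame indices

    @property
    def n_steps(self) -> int:
        return len(self.frames)

    def fitted(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for (a, b), level in zip(self.segments, self.levels):
            out[a:b] = level
        return out


def _robust_noise_sd(x: np.ndarray) -> float:
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _pelt(x: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized least-squares changepoint search (PELT pruning)."""
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    for t in range(1, n + 1):
        seg = (s2[t] - s2[cand]) - (s1[t] - s1[cand]) ** 2 / (t - cand)
        vals = F[cand] + seg + penalty
        i = int(np.argmin(vals))
        F[t] = vals[i]
        last[t] = cand[i]
        keep = cand[vals - penalty <= F[t]]
        cand = np.append(keep, t)
    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def detect_steps(series: np.ndarray, penalty: float | None = None,
                 beta: float = 10.0) -> StepResult:
    """Segment an intensity series into piecewise-constant levels.

    The segmentation minimizes the within-segment sum of squares plus a
    per-changepoint penalty (default ``beta * sigma^2 * ln n`` with sigma
    the robust noise estimate from first differences).  Exact: placements
    agree with exhaustive least-squares enumeration for the chosen number
    of steps.  A constant series yields zero steps.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return StepResult(np.array([], int), np.array([x.mean() if n else 0.0]),
                          np.array([]), 0.0, np.array([[0, n]]))
    sd = _robust_noise_sd(x)
    if penalty is None:
        scale = float(np.max(x) - np.min(x))
        penalty = beta * sd * sd * np.log(max(n, 2))
        # floor keeps the noiseless case well-posed (ties broken toward
        # fewer steps) without ever masking a real step
        penalty = max(penalty, 1e-12 * scale * scale + 1e-300)
    cps = _pelt(x, penalty)
    bounds = [0] + cps + [n]
    segments = np.array([[bounds[i], bounds[i + 1]] for i in range(len(bounds) - 1)])
    levels = np.array([x[a:b].mean() for a, b in segments])
    frames = np.array(cps, dtype=int)
    sizes = np.diff(levels)
    return StepResult(frames=frames, levels=levels, sizes=sizes,
                      noise_sd=sd, segments=segments)


@dataclass
class BleachCall:
    """Interpretation of a segmentation as a photobleaching event."""

    bleached: bool
    frame: int  # first dark frame; -1 if never bleached
    single_step: bool  # one entry into background, no recovery


def classify_bleach(result: StepResult, background: float = 0.0,
                    z: float = 4.0) -> BleachCall:
    """Decide whether/where a channel bleaches.

    A segment counts as background when its mean is within ``z`` standard
    errors of the background level (dynamic FRET levels are therefore not
    mistaken for background on any reasonably long segment).  Bleaching
    requires a final run of background segments; a single-step verdict
    additionally requires that no earlier segment touched background
    (no blinking/recovery).
    """
    sd = max(result.noise_sd, 1e-300)
    at_bg = []
    for (a, b), level in zip(result.segments, result.levels):
        se = sd / np.sqrt(max(b - a, 1))
        at_bg.append(abs(level - background) <= z * se + 1e-9)
    at_bg = np.asarray(at_bg)
    if not at_bg.any() or not at_bg[-1]:
        return BleachCall(False, -1, False)
    # first index of the trailing background run
    i = len(at_bg)
    while i > 0 and at_bg[i - 1]:
        i -= 1
    if i == 0:
        # whole trace at background: dark from the start, not a bleach
        return BleachCall(False, -1, False)
    frame = int(result.segments[i][0])
    single = not at_bg[:i].any()
    return BleachCall(True, frame, single)


# ---------------------------------------------------------------------------
# gamma


def estimate_gamma(donor: np.ndarray, acceptor: np.ndarray,
                   acceptor_bleach_frame: int,
                   donor_bleach_frame: int | None = None,
                   window: int = 20, guard: int = 2,
                   min_side: int = 10) -> float:
    """Estimate gamma from the intensity exchange at the acceptor bleach.

    gamma = (mean Ia before - mean Ia after) / (mean Id after - mean Id before)
    over up to ``window`` frames flanking the bleach, excluding the bleach
    frame +- ``guard``.  Both windows draw on the same underlying photon
    budget, so the ratio is exact even when the molecule changes state
    within the window.  Returns NaN when the windows are too short or the
    denominator is non-positive.
    """
    n = len(donor)
    f = acceptor_bleach_frame
    pre_hi = f - guard
    pre_lo = max(pre_hi - window, 0)
    post_lo = f + guard + 1
    post_hi = min(post_lo + window, n)
    if donor_bleach_frame is not None and donor_bleach_frame >= 0:
        post_hi = min(post_hi, donor_bleach_frame)
    if pre_hi - pre_lo < min_side or post_hi - post_lo < min_side:
        return float("nan")
    ia_pre = acceptor[pre_lo:pre_hi].mean()
    ia_post = acceptor[post_lo:post_hi].mean()
    id_pre = donor[pre_lo:pre_hi].mean()
    id_post = donor[post_lo:post_hi].mean()
    denom = id_post - id_pre
    if denom <= 0:
        return float("nan")
    return float((ia_pre - ia_post) / denom)


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCReport:
    molecule_id: int
    snr: float = float("nan")
    acceptor_steps: int = 0
    acceptor_bleach_frame: int = -1
    donor_steps: int = 0
    donor_bleach_frame: int = -1
    bleach_order_ok: bool = False
    single_acceptor_bleach: bool = False
    single_donor_bleach: bool = True
    gamma: float = float("nan")
    anticorrelation: float = float("nan")
    criteria: dict = field(default_factory=dict)
    failure_reasons: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return len(self.failure_reasons) == 0

    def to_dict(self) -> dict:
        d = {
            "molecule_id": self.molecule_id,
            "snr": self.snr,
            "acceptor_bleach_frame": self.acceptor_bleach_frame,
            "donor_bleach_frame": self.donor_bleach_frame,
            "gamma": self.gamma,
            "anticorrelation": self.anticorrelation,
            "pass": self.passed,
            "failure_reasons": ";".join(self.failure_reasons),
        }
        d.update({f"criterion_{k}": v for k, v in self.criteria.items()})
        return d


@dataclass
class FretTrace:
    """Gamma-corrected efficiency series over the both-dyes-active window."""

    molecule_id: int
    E: np.ndarray
    gamma_used: float
    window: tuple[int, int]


def compute_fret(donor: np.ndarray, acceptor: np.ndarray, gamma: float,
                 window: tuple[int, int]) -> FretTrace:
    """E_t = Ia_t / (Ia_t + gamma * Id_t) over the analysis window.

    Frames where the denominator is zero are marked missing (NaN).  Values
    may fall outside [0, 1] because of noise; the histogram range
    [-0.25, 1.25] accommodates them.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a, b = window
    ia = np.asarray(acceptor, dtype=float)[a:b]
    idn = np.asarray(donor, dtype=float)[a:b]
    denom = ia + gamma * idn
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(denom != 0, ia / denom, np.nan)
    return FretTrace(molecule_id=-1, E=E, gamma_used=gamma, window=(a, b))


def _qc_one(mid: int, donor: np.ndarray, acceptor: np.ndarray,
            params: CorrectionParams) -> tuple[QCReport, FretTrace | None]:
    rep = QCReport(molecule_id=mid)
    n = len(donor)

    a_steps = detect_steps(acceptor)
    d_steps = detect_steps(donor)
    rep.acceptor_steps = a_steps.n_steps
    rep.donor_steps = d_steps.n_steps
    a_call = classify_bleach(a_steps)
    d_call = classify_bleach(d_steps)
    rep.acceptor_bleach_frame = a_call.frame
    rep.donor_bleach_frame = d_call.frame
    rep.single_acceptor_bleach = a_call.single_step
    rep.single_donor_bleach = (not d_call.bleached) or d_call.single_step

    f_a = a_call.frame
    f_d = d_call.frame if d_call.bleached else n
    rep.bleach_order_ok = a_call.bleached and f_a < f_d

    window = (0, f_a) if a_call.bleached else (0, 0)
    win_len = window[1] - window[0]

    # criterion 2: single-step acceptor bleach prior to donor bleach
    c2 = a_call.bleached and a_call.single_step and rep.bleach_order_ok
    # criterion 5: single-step donor bleach, if present (vacuous otherwise)
    c5 = rep.single_donor_bleach

    # criterion 1: SNR over the analysis window
    if win_len >= params.min_window:
        total = donor[:f_a] + acceptor[:f_a]
        t_steps = detect_steps(total)
        resid = total - t_steps.fitted(len(total))
        sd = float(np.std(resid))
        rep.snr = float(np.mean(total)) / sd if sd > 0 else float("inf")
    c1 = np.isfinite(rep.snr) and rep.snr >= params.snr_min

    # criterion 3: gamma within the acceptance band
    if a_call.bleached:
        rep.gamma = estimate_gamma(
            donor, acceptor, f_a,
            donor_bleach_frame=d_call.frame if d_call.bleached else None,
            window=params.gamma_window, guard=params.bleach_guard,
            min_side=params.min_gamma_side)
    lo, hi = params.gamma_bounds
    c3 = np.isfinite(rep.gamma) and lo <= rep.gamma <= hi

    # criterion 4: anticorrelated donor/acceptor fluctuations.  The
    # correlation window extends through the acceptor bleach step (the
    # canonical anticorrelated event) so that static single-state molecules
    # are not rejected for lacking conformational transitions.
    if a_call.bleached:
        end = min(f_a + params.gamma_window, f_d, n)
        dd = np.diff(donor[:end])
        da = np.diff(acceptor[:end])
        if len(dd) > 2 and np.std(dd) > 0 and np.std(da) > 0:
            rep.anticorrelation = float(np.corrcoef(dd, da)[0, 1])
    c4 = np.isfinite(rep.anticorrelation) and rep.anticorrelation <= params.anticorr_max

    rep.criteria = {"snr": bool(c1), "bleach_order": bool(c2),
                    "gamma": bool(c3), "anticorrelation": bool(c4),
                    "donor_single_step": bool(c5)}
    rep.failure_reasons = [k for k, ok in rep.criteria.items() if not ok]

    trace = None
    if rep.passed:
        trace = compute_fret(donor, acceptor, rep.gamma, window)
        trace.molecule_id = mid
    return rep, trace


def qc_select(donor: np.ndarray, acceptor: np.ndarray,
              params: CorrectionParams | None = None,
              leakage_corrected: bool = False):
    """Run corrections and the five selection criteria on a trace set.

    ``donor``/``acceptor`` are (n_molecules, n_frames) background-corrected
    arrays.  Returns (accepted FretTrace list, QCReport list).  Every trace
    yields a report; acceptance is the conjunction of the five criteria,
    each recorded individually.
    """
    params = params or CorrectionParams()
    donor = np.atleast_2d(np.asarray(donor, dtype=float))
    acceptor = np.atleast_2d(np.asarray(acceptor, dtype=float))
    if not leakage_corrected:
        acceptor = correct_leakage(donor, acceptor, params.leakage)
    traces, reports = [], []
    for m in range(donor.shape[0]):
        rep, tr = _qc_one(m, donor[m], acceptor[m], params)
        reports.append(rep)
        if tr is not None:
            traces.append(tr)
    return traces, reports


# ---------------------------------------------------------------------------
# histogram


@dataclass
class EnsembleHistogram:
    """Molecule-averaged binned FRET distribution.

    Each per-molecule vector is normalized by that molecule's total number
    of efficiency values (so it sums to <= 1, and to 1 when every value
    falls inside the histogram range); the ensemble histogram is the
    arithmetic mean over molecules, giving every molecule equal weight
    regardless of trace length.
    """

    bin_edges: np.ndarray
    per_molecule: np.ndarray
    averaged: np.ndarray
    n_molecules: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "frequency": self.averaged})


def build_histogram(fret_traces) -> EnsembleHistogram:
    """Bin per-molecule E values into 30 intervals over [-0.25, 1.25].

    Out-of-range values are dropped from the numerator but still count in
    each molecule's normalization; NaN frames are excluded entirely.
    """
    if len(fret_traces) == 0:
        raise ValueError("no accepted traces to histogram")
    edges = np.linspace(HIST_RANGE[0], HIST_RANGE[1], N_BINS + 1)
    vectors = []
    for tr in fret_traces:
        E = tr.E if isinstance(tr, FretTrace) else np.asarray(tr, dtype=float)
        E = E[np.isfinite(E)]
        if len(E) == 0:
            continue
        counts, _ = np.histogram(E, bins=edges)
        vectors.append(counts / len(E))
    if not vectors:
        raise ValueError("no finite efficiency values to histogram")
    per_mol = np.asarray(vectors)
    return EnsembleHistogram(bin_edges=edges, per_molecule=per_mol,
                             averaged=per_mol.mean(axis=0),
                             n_molecules=per_mol.shape[0])


# ---------------------------------------------------------------------------
# two-Gaussian population fit


def _two_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def _one_gauss(x, a, mu, s):
    return a * np.exp(-0.5 * ((x - mu) / s) ** 2)


class TwoGaussianModel(BaseEstimator):
    """Two-Gaussian mixture fit to a binned FRET distribution.

    Nonlinear least squares of a sum of two Gaussians to bin centers vs.
    averaged frequencies.  State populations are normalized component
    areas.  When one component collapses (weight below ``degenerate_frac``
    or width at the floor), the fit is flagged degenerate and a
    single-Gaussian fallback is recorded.

    Fitted attributes (components sorted by mean, ascending):
    ``means_``, ``sigmas_``, ``amplitudes_``, ``weights_`` (areas in units
    of total histogram mass), ``fractions_``, ``dominant_mean_``,
    ``degenerate_``, ``rss_``.
    """

    def __init__(self, init_means=None, sigma_init: float = 0.1,
                 mu_bounds: tuple[float, float] = HIST_RANGE,
                 sigma_bounds: tuple[float, float] = (0.02, 0.5),
                 degenerate_frac: float = 0.03):
        self.init_means = init_means
        self.sigma_init = sigma_init
        self.mu_bounds = mu_bounds
        self.sigma_bounds = sigma_bounds
        self.degenerate_frac = degenerate_frac

    # -- initialization -----------------------------------------------------
    def _guess_means(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if self.init_means is not None:
            return tuple(self.init_means)
        k = np.ones(3) / 3.0
        ys = np.convolve(y, k, mode="same")
        peaks = [i for i in range(1, len(ys) - 1)
                 if ys[i] >= ys[i - 1] and ys[i] >= ys[i + 1] and ys[i] > 0]
        peaks.sort(key=lambda i: -ys[i])
        sep = 3 * (x[1] - x[0]) if len(x) > 1 else 0.1
        chosen: list[int] = []
        for i in peaks:
            if all(abs(x[i] - x[j]) >= sep for j in chosen):
                chosen.append(i)
            if len(chosen) == 2:
                break
        if len(chosen) == 2:
            return float(x[min(chosen)]), float(x[max(chosen)])
        return 0.35, 0.75

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if np.count_nonzero(y) < 2:
            raise ValueError("histogram needs at least 2 non-empty bins")
        self.bin_width_ = float(np.median(np.diff(np.sort(x)))) if len(x) > 1 else 1.0
        m1, m2 = self._guess_means(x, y)
        a0 = max(float(y.max()), 1e-12)
        p0 = [a0, m1, self.sigma_init, a0, m2, self.sigma_init]
        lo = [0.0, self.mu_bounds[0], self.sigma_bounds[0]] * 2
        hi = [np.inf, self.mu_bounds[1], self.sigma_bounds[1]] * 2
        try:
            popt, pcov = optimize.curve_fit(_two_gauss, x, y, p0=p0,
                                            bounds=(lo, hi), maxfev=20000)
            self.converged_ = True
        except RuntimeError:
            popt = np.asarray(p0, dtype=float)
            pcov = np.full((6, 6), np.nan)
            self.converged_ = False
            warnings.warn("two-Gaussian fit did not converge", RuntimeWarning)
        a = np.array([popt[0], popt[3]])
        mu = np.array([popt[1], popt[4]])
        sg = np.array([popt[2], popt[5]])
        order = np.argsort(mu)
        a, mu, sg = a[order], mu[order], sg[order]
        areas = a * sg * np.sqrt(2.0 * np.pi) / self.bin_width_
        self.amplitudes_, self.means_, self.sigmas_ = a, mu, sg
        self.weights_ = areas
        tot = areas.sum()
        self.fractions_ = areas / tot if tot > 0 else np.array([0.5, 0.5])
        self.covariance_ = pcov
        self.rss_ = float(np.sum((y - _two_gauss(x, *popt)) ** 2))

        sig_floor = max(self.sigma_bounds[0] * 1.05, self.bin_width_ / 4)
        self.degenerate_ = bool(self.fractions_.min() < self.degenerate_frac
                                or (sg <= sig_floor).any())
        if self.degenerate_:
            j = int(np.argmax(self.fractions_))
            p1 = [a[j], mu[j], sg[j]]
            try:
                popt1, _ = optimize.curve_fit(
                    _one_gauss, x, y, p0=p1,
                    bounds=([0.0, self.mu_bounds[0], self.sigma_bounds[0]],
                            [np.inf, self.mu_bounds[1], self.sigma_bounds[1]]),
                    maxfev=20000)
            except RuntimeError:
                popt1 = p1
            self.single_amplitude_ = float(popt1[0])
            self.single_mean_ = float(popt1[1])
            self.single_sigma_ = float(popt1[2])
            self.dominant_mean_ = self.single_mean_
        else:
            self.dominant_mean_ = float(mu[np.argmax(self.fractions_)])
        return self

    def fit_histogram(self, hist: EnsembleHistogram) -> "TwoGaussianModel":
        return self.fit(hist.bin_centers, hist.averaged)

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return _two_gauss(x, self.amplitudes_[0], self.means_[0], self.sigmas_[0],
                          self.amplitudes_[1], self.means_[1], self.sigmas_[1])


def population_fractions(model: TwoGaussianModel, sensor: str = "tm4tm6") -> dict:
    """Map fitted component areas to labelled state populations.

    For the TM4-TM6 activation sensor, increased TM4-TM6 distance (TM6
    outward movement, the activation hallmark) corresponds to the LOW-FRET
    component, so active = low-E.  For inter-protomer dimer sensors (tm5,
    h8) the labels are descriptive (low/high) only.
    """
    if model.degenerate_:
        lowdom = model.single_mean_ <= 0.5 * sum(model.means_)
        f_low, f_high = (1.0, 0.0) if lowdom else (0.0, 1.0)
    else:
        f_low, f_high = float(model.fractions_[0]), float(model.fractions_[1])
    if sensor == "tm4tm6":
        return {"active": f_low, "inactive": f_high}
    return {"low": f_low, "high": f_high}


def idealize_two_state(E: np.ndarray, model: TwoGaussianModel,
                       median_width: int = 5) -> np.ndarray:
    """Assign each frame to a fitted component by posterior odds.

    Components are indexed by ascending mean; ties go to the lower state
    index.  A median filter of ``median_width`` frames suppresses
    single-frame misassignments.  A degenerate fit assigns every frame to
    the single surviving component (index 0).
    """
    E = np.asarray(E, dtype=float)
    if model.degenerate_:
        return np.zeros(len(E), dtype=int)
    w = np.clip(model.fractions_, 1e-12, None)
    logp = np.empty((2, len(E)))
    for i in range(2):
        logp[i] = (np.log(w[i]) - np.log(model.sigmas_[i])
                   - 0.5 * ((E - model.means_[i]) / model.sigmas_[i]) ** 2)
    states = (logp[1] > logp[0]).astype(int)
    if median_width > 1:
        states = ndimage.median_filter(states, size=median_width, mode="nearest")
    return states


# ---------------------------------------------------------------------------
# end-to-end convenience


@dataclass
class AnalysisResult:
    reports: list
    fret_traces: list
    histogram: EnsembleHistogram | None
    model: TwoGaussianModel | None
    fractions: dict | None

    @property
    def n_accepted(self) -> int:
        return len(self.fret_traces)

    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.reports])


def analyze_traces(donor: np.ndarray, acceptor: np.ndarray,
                   params: CorrectionParams | None = None,
                   sensor: str = "tm4tm6") -> AnalysisResult:
    """Full chain: corrections -> QC -> histogram -> two-Gaussian fit."""
    traces, reports = qc_select(donor, acceptor, params)
    if not traces:
        return AnalysisResult(reports, [], None, None, None)
    hist = build_histogram(traces)
    model = TwoGaussianModel().fit_histogram(hist)
    fractions = population_fractions(model, sensor=sensor)
    return AnalysisResult(reports, traces, hist, model, fractions)
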