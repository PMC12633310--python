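"""Synthetic data generators with ground-truth manifests.

Every downstream stage of the package (trace photometry, FRET quality
control, population fitting, binding-curve fits, cluster statistics) is
validated by parameter recovery on data produced here.  Each generator
draws all randomness from a single integer seed via
:class:`numpy.random.SeedSequence` spawning, so identical seeds give
bit-identical outputs.

The single-molecule emitter is a two-state (active/inactive) continuous-time
Markov process observed at the camera frame rate, with state-specific FRET
efficiencies, per-molecule detection-correction factor gamma, donor->acceptor
spectral leakage, and single-step photobleaching of each dye.  Intensities
are reported in the convention in which the gamma-corrected efficiency
``E = Ia / (Ia + gamma * Id)`` recovers the ground-truth state efficiency:
for a molecule with total photon budget ``I`` in state with efficiency ``E``,
the ideal detected donor signal is ``I * (1 - E)`` and the ideal acceptor
signal is ``I * E * gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionConfig",
    "TwoStateTruth",
    "PhotophysicsTruth",
    "CurveTruth",
    "PointPatternTruth",
    "TraceSet",
    "simulate_trace_set",
    "render_movie",
    "simulate_curve_data",
    "simulate_point_pattern",
    "simulate_masses",
]


@dataclass
class AcquisitionConfig:
    """Camera acquisition settings.

    Defaults reproduce a typical surface-immobilized smFRET acquisition:
    100 ms exposure per frame, an 80 s donor-excitation block (800 frames)
    followed by a 1 s direct-acceptor-excitation block used to confirm
    fluorophore identity.
    """

    frame_period: float = 0.1
    n_donor_frames: int = 800
    n_red_frames: int = 10
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame_period) or self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.n_donor_frames < 1:
            raise ValueError("n_donor_frames must be >= 1")
        if self.n_red_frames < 0:
            raise ValueError("n_red_frames must be >= 0")


@dataclass
class TwoStateTruth:
    """Ground truth for the two-state conformational emitter.

    ``E_states`` holds (E_low, E_high).  Rates are per second; the
    stationary occupancy of the high-E state is
    ``k_lo_hi / (k_lo_hi + k_hi_lo)``.
    """

    E_states: tuple[float, float] = (0.4, 0.8)
    k_lo_hi: float = 0.25
    k_hi_lo: float = 0.25
    total_intensity: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.E_states
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("require 0 <= E_low < E_high <= 1")
        for k in (self.k_lo_hi, self.k_hi_lo):
            if not np.isfinite(k) or k < 0:
                raise ValueError("transition rates must be finite and >= 0")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")

    @property
    def occupancy_high(self) -> float:
        denom = self.k_lo_hi + self.k_hi_lo
        if denom == 0:
            return 0.5
        return self.k_lo_hi / denom

    @classmethod
    def single_state(cls, efficiency: float,
                     total_intensity: float = 1000.0) -> "TwoStateTruth":
        """Emitter pinned at one efficiency (static inter-protomer sensor)."""
        return cls(E_states=(max(efficiency - 1e-9, 0.0), efficiency),
                   k_lo_hi=1.0, k_hi_lo=0.0, total_intensity=total_intensity)

    @classmethod
    def from_occupancy(
        cls,
        occupancy_high: float,
        E_states: tuple[float, float] = (0.4, 0.8),
        k_total: float = 0.5,
        total_intensity: float = 1000.0,
    ) -> "TwoStateTruth":
        """Build rates with a given stationary high-E occupancy and total
        exchange rate ``k_total = k_lo_hi + k_hi_lo`` (1/s)."""
        if not 0.0 <= occupancy_high <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        return cls(
            E_states=E_states,
            k_lo_hi=occupancy_high * k_total,
            k_hi_lo=(1.0 - occupancy_high) * k_total,
            total_intensity=total_intensity,
        )


@dataclass
class PhotophysicsTruth:
    """Dye photophysics: single-step bleaching, leakage, gamma heterogeneity.

    ``gamma_sigma`` is the log-normal spread of per-molecule gamma around 1,
    truncated to (0, 5].  ``snr`` sets the per-channel Gaussian noise so that
    total intensity / sd(residual of Ia + Id) is approximately ``snr``.
    ``p_acceptor_present`` is the fraction of molecules that carry an
    acceptor dye at all (the rest are donor-only impurities).
    """

    donor_bleach_rate: float = 1.0 / 60.0
    acceptor_bleach_rate: float = 1.0 / 30.0
    leakage: float = 0.07
    gamma_sigma: float = 0.15
    snr: float = 10.0
    p_acceptor_present: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.donor_bleach_rate, self.acceptor_bleach_rate):
            if not np.isfinite(r) or r < 0:
                raise ValueError("bleach rates must be finite and >= 0")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must lie in [0, 1)")
        if self.gamma_sigma < 0:
            raise ValueError("gamma_sigma must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class TraceSet:
    """Per-molecule raw channel intensities plus the ground-truth manifest.

    ``donor``/``acceptor`` are (n_molecules, n_donor_frames) arrays of raw
    (noisy, leakage-contaminated) counts; ``red_block`` is the
    direct-acceptor-excitation check signal.  ``manifest`` records, per
    molecule, the state path, bleach frames (-1 if never bleached within the
    record), gamma, leakage and acceptor presence.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    red_block: np.ndarray
    manifest: pd.DataFrame
    state_paths: np.ndarray
    acq: AcquisitionConfig
    truth: TwoStateTruth
    photo: PhotophysicsTruth

    @property
    def n_molecules(self) -> int:
        return self.donor.shape[0]

    def ideal_efficiency(self, molecule: int) -> np.ndarray:
        lo, hi = self.truth.E_states
        return np.where(self.state_paths[molecule] == 1, hi, lo)


def _sample_state_path(rng: np.random.Generator, truth: TwoStateTruth,
                       n_frames: int, dt: float) -> np.ndarray:
    """Discrete-time Markov path (0 = low-E, 1 = high-E), stationary start."""
    p_hi = truth.occupancy_high
    p01 = 1.0 - np.exp(-truth.k_lo_hi * dt)
    p10 = 1.0 - np.exp(-truth.k_hi_lo * dt)
    states = np.empty(n_frames, dtype=np.int8)
    u = rng.random(n_frames)
    states[0] = 1 if u[0] < p_hi else 0
    for t in range(1, n_frames):
        if states[t - 1] == 0:
            states[t] = 1 if u[t] < p01 else 0
        else:
            states[t] = 0 if u[t] < p10 else 1
    return states


def simulate_trace_set(
    truth: TwoStateTruth,
    photo: PhotophysicsTruth,
    acq: AcquisitionConfig,
    n_molecules: int,
) -> TraceSet:
    """Simulate a set of two-state smFRET molecules.

    Per molecule: a stationary Markov state path, exponential single-step
    bleach times for each dye, a truncated log-normal gamma, ideal channel
    intensities, leakage of ``photo.leakage * Id`` added to the acceptor
    channel before noise, then additive Gaussian camera noise.  After the
    acceptor bleaches the donor recovers its full photon budget; after the
    donor bleaches both channels drop to zero.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    ss = np.random.SeedSequence(acq.seed)
    children = ss.spawn(n_molecules)
    n = acq.n_donor_frames
    dt = acq.frame_period
    lo, hi = truth.E_states
    I0 = truth.total_intensity
    noise_sd = I0 / (photo.snr * np.sqrt(2.0))

    donor = np.empty((n_molecules, n))
    acceptor = np.empty((n_molecules, n))
    red = np.empty((n_molecules, acq.n_red_frames))
    paths = np.empty((n_molecules, n), dtype=np.int8)
    rows = []

    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        states = _sample_state_path(rng, truth, n, dt)
        paths[m] = states
        # truncated log-normal gamma around 1
        while True:
            gamma = float(np.exp(rng.normal(0.0, photo.gamma_sigma))) \
                if photo.gamma_sigma > 0 else 1.0
            if 0.0 < gamma <= 5.0:
                break
        has_acceptor = bool(rng.random() < photo.p_acceptor_present)
        t_a = rng.exponential(1.0 / photo.acceptor_bleach_rate) \
            if (has_acceptor and photo.acceptor_bleach_rate > 0) else np.inf
        t_d = rng.exponential(1.0 / photo.donor_bleach_rate) \
            if photo.donor_bleach_rate > 0 else np.inf
        f_a = int(t_a / dt) if np.isfinite(t_a) else n + 1
        f_d = int(t_d / dt) if np.isfinite(t_d) else n + 1

        E = np.where(states == 1, hi, lo).astype(float)
        frames = np.arange(n)
        acceptor_alive = has_acceptor & (frames < f_a)
        donor_alive = frames < f_d
        E_eff = np.where(acceptor_alive, E, 0.0)
        Id = np.where(donor_alive, I0 * (1.0 - E_eff), 0.0)
        Ia = np.where(donor_alive & acceptor_alive, I0 * E_eff * gamma, 0.0)
        Ia_obs = Ia + photo.leakage * Id
        donor[m] = Id + rng.normal(0.0, noise_sd, n)
        acceptor[m] = Ia_obs + rng.normal(0.0, noise_sd, n)
        # identity-check block: direct acceptor excitation reveals the
        # acceptor dye; presence (not bleach status) is what is modelled here
        red_level = I0 if has_acceptor else 0.0
        red[m] = red_level + rng.normal(0.0, noise_sd, acq.n_red_frames)

        rows.append({
            "molecule_id": m,
            "gamma": gamma,
            "leakage": photo.leakage,
            "has_acceptor": has_acceptor,
            "acceptor_bleach_frame": f_a if f_a <= n else -1,
            "donor_bleach_frame": f_d if f_d <= n else -1,
            "occupancy_high_empirical": float(states.mean()),
        })

    manifest = pd.DataFrame(rows)
    return TraceSet(donor=donor, acceptor=acceptor, red_block=red,
                    manifest=manifest, state_paths=paths,
                    acq=acq, truth=truth, photo=photo)


# ---------------------------------------------------------------------------
# movie rendering


@dataclass
class DualViewGeometry:
    """Left/right dual-view layout on one camera frame.

    The acceptor channel is the right half; ``shift``/``linear`` inject a
    configurable affine misalignment of the acceptor channel relative to the
    donor channel (for registration testing).
    """

    channel_shape: tuple[int, int] = (128, 128)
    shift: tuple[float, float] = (0.0, 0.0)
    linear: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))

    def map_to_acceptor(self, pos: np.ndarray) -> np.ndarray:
        A = np.asarray(self.linear)
        return pos @ A.T + np.asarray(self.shift)


@dataclass
class DualViewMovie:
    """Rendered frames: (n_frames, rows, 2*cols); left = donor, right = acceptor."""

    frames: np.ndarray
    geometry: DualViewGeometry
    positions: np.ndarray  # donor-channel (row, col) per molecule
    baseline: float
    n_donor_frames: int
    n_red_frames: int

    @property
    def channel_shape(self) -> tuple[int, int]:
        return self.geometry.channel_shape

    def donor_channel(self, frame: int) -> np.ndarray:
        cols = self.channel_shape[1]
        return self.frames[frame][:, :cols]

    def acceptor_channel(self, frame: int) -> np.ndarray:
        cols = self.channel_shape[1]
        return self.frames[frame][:, cols:]


def _gaussian_spot(shape: tuple[int, int], pos: np.ndarray, counts: float,
                   sigma: float) -> np.ndarray:
    """2-D Gaussian with unit-normalized discrete integral times ``counts``."""
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    g = np.exp(-((rr - pos[0]) ** 2 + (cc - pos[1]) ** 2) / (2.0 * sigma**2))
    s = g.sum()
    if s <= 0:
        return np.zeros(shape)
    return counts * g / s


def render_movie(
    trace_set: TraceSet,
    psf_sigma: float = 1.2,
    geometry: DualViewGeometry | None = None,
    baseline: float = 100.0,
    read_noise_sd: float = 0.0,
    shot_noise: bool = False,
    positions: np.ndarray | None = None,
    margin: float = 8.0,
    seed: int | None = None,
) -> DualViewMovie:
    """Render a trace set into a dual-view movie.

    Each molecule contributes a discrete-normalized 2-D Gaussian spot whose
    integrated counts per frame equal its trace value, so total added counts
    per frame are conserved before noise.  Camera noise is Poisson shot
    noise (optional) plus Gaussian read noise on top of a constant baseline
    offset.
    """
    geom = geometry or DualViewGeometry(channel_shape=trace_set.acq.image_shape)
    rows, cols = geom.channel_shape
    if cols * 2 <= cols:
        raise ValueError("invalid channel layout")
    n_mol = trace_set.n_molecules
    rng = np.random.default_rng(
        np.random.SeedSequence([trace_set.acq.seed, 0x5EED]) if seed is None else seed)
    if positions is None:
        positions = np.column_stack([
            rng.uniform(margin, rows - margin, n_mol),
            rng.uniform(margin, cols - margin, n_mol),
        ])
    positions = np.asarray(positions, dtype=float)
    acc_pos = geom.map_to_acceptor(positions)
    for p, q in zip(positions, acc_pos):
        if not (0 <= p[0] < rows and 0 <= p[1] < cols
                and 0 <= q[0] < rows and 0 <= q[1] < cols):
            raise ValueError("molecule position outside channel field")

    n_d = trace_set.acq.n_donor_frames
    n_r = trace_set.acq.n_red_frames
    frames = np.empty((n_d + n_r, rows, cols * 2))
    for t in range(n_d + n_r):
        dch = np.zeros((rows, cols))
        ach = np.zeros((rows, cols))
        for m in range(n_mol):
            if t < n_d:
                dv = trace_set.donor[m, t]
                av = trace_set.acceptor[m, t]
            else:
                dv = 0.0
                av = trace_set.red_block[m, t - n_d]
            if dv != 0:
                dch += _gaussian_spot((rows, cols), positions[m], dv, psf_sigma)
            if av != 0:
                ach += _gaussian_spot((rows, cols), acc_pos[m], av, psf_sigma)
        frame = np.concatenate([dch, ach], axis=1) + baseline
        if shot_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if read_noise_sd > 0:
            frame = frame + rng.normal(0.0, read_noise_sd, frame.shape)
        frames[t] = frame
    return DualViewMovie(frames=frames, geometry=geom, positions=positions,
                         baseline=baseline, n_donor_frames=n_d, n_red_frames=n_r)


# ---------------------------------------------------------------------------
# binding / dose-response curve data


_CURVE_MODELS = ("logistic3", "bli_1to1", "steady_state", "saturation", "competition")


@dataclass
class CurveTruth:
    """Ground truth for one of the closed-form pharmacology models.

    ``parameters`` is model-specific:
      logistic3   : bottom, top, logEC50 (log10 molar)
      bli_1to1    : k_on (1/(M s)), k_off (1/s), r_max, t_assoc (s), t_dissoc (s), dt (s)
      steady_state: K_D (M), r_max
      saturation  : K_d (M), B_max, ns_slope (counts per M)
      competition : ic50 (M), top, bottom
    """

    model_tag: str
    parameters: dict
    concentrations: Sequence[float]
    noise_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.model_tag not in _CURVE_MODELS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        conc = np.asarray(self.concentrations, dtype=float)
        if self.model_tag in ("logistic3", "competition") and np.any(conc <= 0):
            raise ValueError("log-domain models require positive concentrations")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def logistic3_response(conc: np.ndarray, bottom: float, top: float,
                       logec50: float) -> np.ndarray:
    x = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - x))


def bli_response(t: np.ndarray, conc: float, k_on: float, k_off: float,
                 r_max: float, t_assoc: float) -> np.ndarray:
    """Noise-free 1:1 sensorgram: single-exponential association then decay."""
    k_obs = k_on * conc + k_off
    r_eq = r_max * conc / (conc + k_off / k_on)
    assoc = r_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_assoc)))
    r0 = r_eq * (1.0 - np.exp(-k_obs * t_assoc))
    out = np.where(t <= t_assoc, assoc, r0 * np.exp(-k_off * (t - t_assoc)))
    return out


def simulate_curve_data(truth: CurveTruth, seed: int = 0) -> pd.DataFrame:
    """Evaluate the model deterministically, add Gaussian noise, replicate.

    Returns a tidy table.  For ``bli_1to1`` the columns are
    (concentration, replicate, time, response); for the equilibrium/dose
    models (concentration, replicate, response).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    conc = np.asarray(truth.concentrations, dtype=float)
    p = truth.parameters
    rows = []
    if truth.model_tag == "bli_1to1":
        dt = p.get("dt", 1.0)
        t = np.arange(0.0, p["t_assoc"] + p["t_dissoc"] + dt / 2, dt)
        for c in conc:
            r = bli_response(t, c, p["k_on"], p["k_off"], p["r_max"], p["t_assoc"])
            for rep in range(truth.n_replicates):
                noisy = r + rng.normal(0.0, truth.noise_sd, r.shape)
                for ti, ri in zip(t, noisy):
                    rows.append({"concentration": c, "replicate": rep,
                                 "time": ti, "response": ri})
        return pd.DataFrame(rows)

    if truth.model_tag == "logistic3":
        mean = logistic3_response(conc, p["bottom"], p["top"], p["logec50"])
    elif truth.model_tag == "steady_state":
        mean = p["r_max"] * conc / (p["K_D"] + conc)
    elif truth.model_tag == "saturation":
        mean = p["B_max"] * conc / (p["K_d"] + conc)
    elif truth.model_tag == "competition":
        mean = logistic3_response(conc, p["top"], p["bottom"],
                                  np.log10(p["ic50"]))
    for c, mu in zip(conc, mean):
        for rep in range(truth.n_replicates):
            rows.append({
                "concentration": c,
                "replicate": rep,
                "response": mu + (rng.normal(0.0, truth.noise_sd)
                                  if truth.noise_sd > 0 else 0.0),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial point patterns and mass events


@dataclass
class PointPatternTruth:
    """Clustered point pattern on a square field (nm units)."""

    n_clusters: int = 20
    mean_size: float = 4.0
    spread: float = 15.0
    field_size: float = 2000.0
    background_rate: float = 0.0  # stray particles per nm^2

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.mean_size < 0:
            raise ValueError("counts must be >= 0")
        if self.spread <= 0:
            raise ValueError("spread must be positive")


def simulate_point_pattern(truth: PointPatternTruth, seed: int = 0,
                           min_size: int = 1):
    """Thomas-style clustered pattern.

    Cluster sizes are 1 + Poisson(mean_size - 1) (so every cluster has at
    least one particle); members are isotropic Gaussian around the cluster
    center with sd ``spread``.  Returns (coords, labels) where stray
    background points carry label -1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA0]))
    coords = []
    labels = []
    L = truth.field_size
    for k in range(truth.n_clusters):
        size = min_size + rng.poisson(max(truth.mean_size - min_size, 0.0))
        center = rng.uniform(0, L, 2)
        pts = center + rng.normal(0.0, truth.spread, (size, 2))
        coords.append(np.clip(pts, 0, L))
        labels.extend([k] * size)
    n_bg = rng.poisson(truth.background_rate * L * L)
    if n_bg:
        coords.append(rng.uniform(0, L, (n_bg, 2)))
        labels.extend([-1] * n_bg)
    if coords:
        xy = np.concatenate(coords, axis=0)
    else:
        xy = np.empty((0, 2))
    return xy, np.asarray(labels, dtype=int)


def simulate_masses(components: Sequence[tuple[float, float, float]],
                    n_events: int, seed: int = 0):
    """Draw mass-photometry events from a Gaussian mixture.

    ``components`` is a list of (mean_kDa, weight, sd_kDa); weights must sum
    to 1.  Returns (masses, component_labels).
    """
    comps = [(float(m), float(w), float(s)) for m, w, s in components]
    weights = np.array([w for _, w, _ in comps])
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must be >= 0 and sum to 1")
    if any(s <= 0 or m <= 0 for m, _, s in comps):
        raise ValueError("component means and sds must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1]))
    labels = rng.choice(len(comps), size=n_events, p=weights)
    means = np.array([m for m, _, _ in comps])
    sds = np.array([s for _, _, s in comps])
    masses = rng.normal(means[labels], sds[labels])
    return masses, labels
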