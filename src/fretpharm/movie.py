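"""Dual-view movie processing: registration, spot detection, photometry.

Turns two-channel TIRF movies (donor-excitation block followed by a short
direct-acceptor-excitation block) into per-molecule raw intensity traces.
Coordinates are 0-based (row, col) with pixel centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import DualViewMovie

__all__ = [
    "AffineMap",
    "Spot",
    "TraceRaw",
    "register_channels",
    "detect_spots",
    "exclude_donor_only",
    "extract_traces",
]


@dataclass
class AffineMap:
    """Affine map from donor-channel to acceptor-channel pixel coordinates."""

    linear: np.ndarray  # 2x2
    offset: np.ndarray  # 2-vector
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part must be invertible")

    def apply(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        out = pos @ self.linear.T + self.offset
        return out[0] if out.shape[0] == 1 else out

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        return AffineMap(linear=inv, offset=-inv @ self.offset,
                         rms_residual=self.rms_residual)

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(linear=np.eye(2), offset=np.zeros(2))


@dataclass
class Spot:
    position: tuple[float, float]
    peak_intensity: float
    channel: str = "donor"
    has_acceptor_id: bool = False


@dataclass
class TraceRaw:
    """Per-molecule raw channel intensities with local background estimates.

    Background is stored separately (per frame, scaled to aperture area) so
    the correction is reversible.
    """

    molecule_id: int
    donor_raw: np.ndarray
    acceptor_raw: np.ndarray
    background_donor: np.ndarray
    background_acceptor: np.ndarray
    red_block_acceptor: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def donor_corrected(self) -> np.ndarray:
        return self.donor_raw - self.background_donor

    @property
    def acceptor_corrected(self) -> np.ndarray:
        return self.acceptor_raw - self.background_acceptor


# ---------------------------------------------------------------------------
# spot detection


def detect_spots(image: np.ndarray, neighborhood: int = 5,
                 intensity_threshold: float | None = None) -> list[Spot]:
    """Find local intensity maxima within a square neighborhood.

    A pixel is a detection when it is a strict maximum over the
    ``neighborhood x neighborhood`` window and exceeds the threshold
    (default: median + 5 robust SDs of the image).  Sub-pixel position by
    intensity centroid over the window after subtracting the local minimum.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if neighborhood % 2 == 0:
        raise ValueError("neighborhood size must be odd")
    if intensity_threshold is None:
        med = np.median(image)
        mad = 1.4826 * np.median(np.abs(image - med))
        intensity_threshold = med + 5.0 * max(mad, 1e-12)
    foot = np.ones((neighborhood, neighborhood), dtype=bool)
    foot[neighborhood // 2, neighborhood // 2] = False
    neigh_max = ndimage.maximum_filter(image, footprint=foot, mode="nearest")
    peaks = (image > neigh_max) & (image > intensity_threshold)
    half = neighborhood // 2
    spots = []
    for r, c in zip(*np.nonzero(peaks)):
        r0, r1 = max(r - half, 0), min(r + half + 1, image.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, image.shape[1])
        win = image[r0:r1, c0:c1] - image[r0:r1, c0:c1].min()
        tot = win.sum()
        if tot <= 0:
            pos = (float(r), float(c))
        else:
            rr = np.arange(r0, r1)[:, None]
            cc = np.arange(c0, c1)[None, :]
            pos = (float((win * rr).sum() / tot), float((win * cc).sum() / tot))
        spots.append(Spot(position=pos, peak_intensity=float(image[r, c])))
    return spots


# ---------------------------------------------------------------------------
# channel registration


def _coarse_shift(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Integer-pixel shift of b relative to a by FFT cross-correlation."""
    fa = np.fft.rfft2(a - a.mean())
    fb = np.fft.rfft2(b - b.mean())
    xc = np.fft.irfft2(fa.conj() * fb, s=a.shape)
    idx = np.unravel_index(np.argmax(xc), xc.shape)
    shift = np.array(idx, dtype=float)
    for k in range(2):
        if shift[k] > a.shape[k] / 2:
            shift[k] -= a.shape[k]
    return shift


def register_channels(donor_image: np.ndarray, acceptor_image: np.ndarray,
                      neighborhood: int = 5,
                      intensity_threshold: float | None = None,
                      match_radius: float = 5.0) -> AffineMap:
    """Least-squares affine registration from matched fiducial spots.

    Fiducials are detected independently in each channel, matched by mutual
    nearest neighbor within ``match_radius`` px after a coarse FFT
    cross-correlation shift, and the donor->acceptor affine map is fit by
    linear least squares.  Requires >= 3 non-collinear matches.
    """
    d_spots = detect_spots(donor_image, neighborhood, intensity_threshold)
    a_spots = detect_spots(acceptor_image, neighborhood, intensity_threshold)
    if len(d_spots) < 3 or len(a_spots) < 3:
        raise ValueError("registration requires >= 3 fiducials per channel")
    P = np.array([s.position for s in d_spots])
    Q = np.array([s.position for s in a_spots])
    shift = _coarse_shift(donor_image, acceptor_image)
    Ps = P + shift
    # mutual nearest neighbors
    d2 = ((Ps[:, None, :] - Q[None, :, :]) ** 2).sum(axis=2)
    fwd = np.argmin(d2, axis=1)
    bwd = np.argmin(d2, axis=0)
    pairs = [(i, fwd[i]) for i in range(len(P))
             if bwd[fwd[i]] == i and d2[i, fwd[i]] <= match_radius**2]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched fiducials")
    Pm = np.array([P[i] for i, _ in pairs])
    Qm = np.array([Q[j] for _, j in pairs])
    # collinearity check via singular values of centered donor positions
    sv = np.linalg.svd(Pm - Pm.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("matched fiducials are collinear")
    A = np.column_stack([Pm, np.ones(len(Pm))])
    coef, *_ = np.linalg.lstsq(A, Qm, rcond=None)
    linear = coef[:2].T
    offset = coef[2]
    resid = Qm - (Pm @ linear.T + offset)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AffineMap(linear=linear, offset=offset, rms_residual=rms)


# ---------------------------------------------------------------------------
# donor-only exclusion


def exclude_donor_only(donor_spots: list[Spot], red_block_images: np.ndarray,
                       affine: AffineMap, threshold: float | None = None,
                       search_radius: int = 2) -> list[Spot]:
    """Retain donor spots whose mapped acceptor position lights up under
    direct acceptor excitation.

    The red-block frames are averaged; a spot is retained when the maximum
    background-subtracted intensity within ``search_radius`` px of the
    mapped position exceeds the threshold (default: median + 5 robust SDs).
    """
    red = np.asarray(red_block_images, dtype=float)
    if red.ndim == 2:
        red = red[None]
    if red.shape[0] == 0:
        raise ValueError("red-block images are required")
    avg = red.mean(axis=0)
    med = np.median(avg)
    if threshold is None:
        # robust noise floor, plus a dynamic-range floor so near-noiseless
        # backgrounds do not let sub-signal fluctuations through
        mad = 1.4826 * np.median(np.abs(avg - med))
        threshold = med + max(5.0 * mad, 0.1 * (float(avg.max()) - med), 1e-12)
    retained = []
    for spot in donor_spots:
        q = affine.apply(np.asarray(spot.position))
        r, c = int(round(q[0])), int(round(q[1]))
        r0, r1 = max(r - search_radius, 0), min(r + search_radius + 1, avg.shape[0])
        c0, c1 = max(c - search_radius, 0), min(c + search_radius + 1, avg.shape[1])
        ok = r1 > r0 and c1 > c0 and float(avg[r0:r1, c0:c1].max()) > threshold
        spot.has_acceptor_id = bool(ok)
        if ok:
            retained.append(spot)
    return retained


# ---------------------------------------------------------------------------
# aperture photometry


def _disc_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def extract_traces(movie: DualViewMovie, spots: list[Spot],
                   affine: AffineMap | None = None,
                   aperture_radius: float = 3.0,
                   background_diameter: float = 35.0) -> list[TraceRaw]:
    """Aperture photometry with local background correction.

    Per frame: raw intensity is the sum of counts in a circular aperture;
    background is the median pixel value in the local circular region
    (``background_diameter`` px across, aperture excluded), scaled to the
    aperture area.  Background is stored separately so the correction is
    reversible.  Spots whose background region extends past the channel
    border are flagged, not dropped.
    """
    affine = affine or AffineMap.identity()
    rows, cols = movie.channel_shape
    n_d, n_r = movie.n_donor_frames, movie.n_red_frames
    donor_stack = movie.frames[:, :, :cols]
    acc_stack = movie.frames[:, :, cols:]
    out = []
    for mid, spot in enumerate(spots):
        p = np.asarray(spot.position, dtype=float)
        q = affine.apply(p)
        flags = []
        for pos, name in ((p, "donor"), (q, "acceptor")):
            if not (aperture_radius <= pos[0] <= rows - 1 - aperture_radius
                    and aperture_radius <= pos[1] <= cols - 1 - aperture_radius):
                raise ValueError(f"aperture for spot {mid} outside {name} channel")
            r_bg = background_diameter / 2.0
            if not (r_bg <= pos[0] <= rows - 1 - r_bg
                    and r_bg <= pos[1] <= cols - 1 - r_bg):
                flags.append(f"{name}_background_truncated")

        def photometry(stack: np.ndarray, pos: np.ndarray):
            ap = _disc_mask((rows, cols), pos, aperture_radius)
            bg_region = _disc_mask((rows, cols), pos, background_diameter / 2.0) & ~ap
            n_ap = int(ap.sum())
            raw = stack[:, ap].sum(axis=1)
            bg = np.median(stack[:, bg_region], axis=1) * n_ap
            return raw, bg

        d_raw, d_bg = photometry(donor_stack[:n_d], p)
        a_raw, a_bg = photometry(acc_stack[:n_d], q)
        if n_r > 0:
            red_raw, red_bg = photometry(acc_stack[n_d:], q)
            red = red_raw - red_bg
        else:
            red = np.empty(0)
        out.append(TraceRaw(
            molecule_id=mid, donor_raw=d_raw, acceptor_raw=a_raw,
            background_donor=d_bg, background_acceptor=a_bg,
            red_block_acceptor=red, flags=flags))
    return out


def traces_to_frame(traces: list[TraceRaw]) -> pd.DataFrame:
    """Long-format table: one row per (molecule, frame)."""
    rows = []
    for tr in traces:
        for f in range(len(tr.donor_raw)):
            rows.append({
                "molecule_id": tr.molecule_id, "frame": f,
                "donor_raw": tr.donor_raw[f], "acceptor_raw": tr.acceptor_raw[f],
                "background_donor": tr.background_donor[f],
                "background_acceptor": tr.background_acceptor[f]})
    return pd.DataFrame(rows)
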