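"""Plain-text readers and writers for the pipeline's interchange formats.

Traces travel as TSV (one row per molecule and frame) with a sidecar JSON
ground-truth or processing manifest; movies as multi-frame TIFF; curve data
as CSV; fit reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import DualViewMovie, TraceSet


def write_trace_tsv(path, trace_set: TraceSet) -> None:
    """One row per (molecule, frame): donor/acceptor raw counts; red block
    appended with frame indices continuing past the donor block."""
    n_mol, n = trace_set.donor.shape
    n_red = trace_set.red_block.shape[1]
    mol = np.repeat(np.arange(n_mol), n + n_red)
    frame = np.tile(np.concatenate([np.arange(n), np.arange(n, n + n_red)]), n_mol)
    donor = np.concatenate([
        np.concatenate([trace_set.donor[m], np.zeros(n_red)]) for m in range(n_mol)])
    acc = np.concatenate([
        np.concatenate([trace_set.acceptor[m], trace_set.red_block[m]])
        for m in range(n_mol)])
    block = np.tile(np.concatenate([np.repeat("donor", n), np.repeat("red", n_red)]), n_mol)
    pd.DataFrame({"molecule_id": mol, "frame": frame, "block": block,
                  "donor_raw": donor, "acceptor_raw": acc}).to_csv(
        path, sep="\t", index=False)


def read_trace_tsv(path):
    """Inverse of :func:`write_trace_tsv`: returns (donor, acceptor,
    red_block) arrays of shape (n_molecules, n_frames)."""
    df = pd.read_csv(path, sep="\t")
    donor_blk = df[df["block"] == "donor"]
    red_blk = df[df["block"] == "red"]
    donor = donor_blk.pivot(index="molecule_id", columns="frame",
                            values="donor_raw").to_numpy()
    acceptor = donor_blk.pivot(index="molecule_id", columns="frame",
                               values="acceptor_raw").to_numpy()
    if len(red_blk):
        red = red_blk.pivot(index="molecule_id", columns="frame",
                            values="acceptor_raw").to_numpy()
    else:
        red = np.empty((donor.shape[0], 0))
    return donor, acceptor, red


def write_manifest_json(path, trace_set: TraceSet) -> None:
    payload = {
        "n_molecules": int(trace_set.n_molecules),
        "frame_period": trace_set.acq.frame_period,
        "E_states": list(trace_set.truth.E_states),
        "occupancy_high": trace_set.truth.occupancy_high,
        "leakage": trace_set.photo.leakage,
        "molecules": trace_set.manifest.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_movie_tiff(path, movie: DualViewMovie) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32))


def read_movie_tiff(path, channel_shape=None, n_red_frames: int = 0) -> DualViewMovie:
    from .synthetic import DualViewGeometry

    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    rows, width = frames.shape[1], frames.shape[2]
    shape = channel_shape or (rows, width // 2)
    return DualViewMovie(frames=frames, geometry=DualViewGeometry(channel_shape=shape),
                         positions=np.empty((0, 2)), baseline=0.0,
                         n_donor_frames=frames.shape[0] - n_red_frames,
                         n_red_frames=n_red_frames)


def write_fit_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_json_default))
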