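"""On-disk trial layout: TIFF frames, force CSV and YAML metadata.

A trial directory looks like::

    trial_0001/
      ridge/frame_00000.tif ...    # grazing-light fingerprint channel
      contact/frame_00000.tif ...  # coaxial-light real-contact channel
      force.csv                    # t_s, fx_N, fy_N, fz_N
      meta.yaml                    # alpha_um, mu, pixel_resolution, frame_times

Round-tripping a generated trial through this layout is lossless up to
the stored dtype (float32 images).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError
from .images import ContactFrame, TrialRecord

__all__ = ["write_trial", "read_trial"]


def write_trial(trial: TrialRecord, path: str | Path) -> Path:
    """Write a trial to the standard directory layout; returns the path."""
    root = Path(path)
    (root / "ridge").mkdir(parents=True, exist_ok=True)
    (root / "contact").mkdir(parents=True, exist_ok=True)
    frame_times = []
    for i, frame in enumerate(trial.frames):
        tifffile.imwrite(
            root / "ridge" / f"frame_{i:05d}.tif",
            np.asarray(frame.ridge_image, dtype=np.float32),
        )
        tifffile.imwrite(
            root / "contact" / f"frame_{i:05d}.tif",
            np.asarray(frame.contact_image, dtype=np.float32),
        )
        frame_times.append(float(frame.timestamp))
    t = trial.meta.get("force_t")
    fz = trial.meta.get("force_noisy")
    if t is None or fz is None:  # fall back to the per-frame samples
        t = trial.times
        fz = trial.force
    pd.DataFrame(
        {
            "t_s": np.asarray(t, dtype=float),
            "fx_N": 0.0,
            "fy_N": 0.0,
            "fz_N": np.asarray(fz, dtype=float),
        }
    ).to_csv(root / "force.csv", index=False)
    meta = {
        "alpha_um": float(trial.alpha_um),
        "mu": None if trial.mu is None else float(trial.mu),
        "pixel_resolution": float(trial.pixel_resolution),
        "frame_times": frame_times,
    }
    with open(root / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return root


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial directory back into a :class:`TrialRecord`."""
    root = Path(path)
    meta_path = root / "meta.yaml"
    if not meta_path.exists():
        raise DataError(f"{root} is not a trial directory (missing meta.yaml)")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    force = pd.read_csv(root / "force.csv")
    ridge_files = sorted((root / "ridge").glob("frame_*.tif"))
    contact_files = sorted((root / "contact").glob("frame_*.tif"))
    if len(ridge_files) != len(contact_files) or not ridge_files:
        raise DataError(f"{root}: ridge/contact frame counts differ or are empty")
    frame_times = meta["frame_times"]
    if len(frame_times) != len(ridge_files):
        raise DataError(f"{root}: frame_times does not match the frame count")
    t = force["t_s"].to_numpy()
    fz = force["fz_N"].to_numpy()
    frames = []
    for rf, cf, ti in zip(ridge_files, contact_files, frame_times):
        frames.append(
            ContactFrame(
                ridge_image=tifffile.imread(rf),
                contact_image=tifffile.imread(cf),
                timestamp=float(ti),
                normal_force=float(np.interp(ti, t, fz)),
                pixel_resolution=float(meta["pixel_resolution"]),
            )
        )
    return TrialRecord(
        frames=frames,
        alpha_um=float(meta["alpha_um"]),
        mu=meta.get("mu"),
        meta={"force_t": t, "force_noisy": fz},
    )
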