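"""HDF5 container and CSV mirrors for traces, stimulus and results.

One hierarchical container per recording:

    /traces/raw, /traces/neuropil            (n_cells, n_frames)
    /traces/corrected, /traces/spikes, ...   (after preprocessing)
    /cells/{x_um, y_um, depth_um, roi_area_um2, ...}
    /stimulus/{onset_s, kx, ky}              + screen/update-rate attrs
    /running                                 per-frame indicator
    /kernels/{w, v}                          (after fitting)

CSV mirrors of the cells table and stimulus log keep the container
inspectable without HDF5 tooling.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import TraceSet
from .stimulus import ScreenGeometry, StimulusSequence

SCHEMA_VERSION = 1

_REQUIRED = ("traces/raw", "traces/neuropil", "cells/x_um", "cells/y_um",
             "cells/depth_um", "cells/roi_area_um2", "running")

_OPTIONAL_SERIES = ("corrected", "spikes", "drift")
_OPTIONAL_PER_CELL = ("noise_sigma", "kurtosis", "neuropil_beta")


def write_traces(
    path,
    traces: TraceSet,
    stimulus: StimulusSequence | None = None,
    running: np.ndarray | None = None,
    seed: int | None = None,
) -> None:
    """Write a TraceSet (and optionally stimulus/running) to the container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["imaging_rate_hz"] = traces.imaging_rate_hz
        if seed is not None:
            f.attrs["seed"] = int(seed)
        g = f.create_group("traces")
        g.create_dataset("raw", data=traces.raw)
        g.create_dataset("neuropil", data=traces.neuropil)
        for name, arr in (("corrected", traces.corrected),
                          ("spikes", traces.inferred_spikes),
                          ("drift", traces.drift_estimate)):
            if arr is not None:
                g.create_dataset(name, data=arr)
        c = f.create_group("cells")
        c.create_dataset("x_um", data=traces.centroid_um[:, 0])
        c.create_dataset("y_um", data=traces.centroid_um[:, 1])
        c.create_dataset("depth_um", data=traces.depth_um)
        c.create_dataset("roi_area_um2", data=traces.roi_area_um2)
        for name in _OPTIONAL_PER_CELL:
            arr = getattr(traces, name)
            if arr is not None:
                c.create_dataset(name, data=arr)
        if running is not None:
            f.create_dataset("running", data=np.asarray(running, dtype=float))
        else:
            f.create_dataset("running", data=np.zeros(traces.n_frames))
        if stimulus is not None:
            s = f.create_group("stimulus")
            s.create_dataset("onset_s", data=stimulus.onset_times_s)
            s.create_dataset("kx", data=stimulus.kx)
            s.create_dataset("ky", data=stimulus.ky)
            s.attrs["update_rate_hz"] = stimulus.update_rate_hz
            s.attrs["sf_max_cpd"] = stimulus.sf_max_cpd
            s.attrs["screen_width_cm"] = stimulus.screen.width_cm
            s.attrs["screen_height_cm"] = stimulus.screen.height_cm
            s.attrs["screen_distance_cm"] = stimulus.screen.distance_cm


def read_traces(path) -> tuple[TraceSet, StimulusSequence | None, np.ndarray]:
    """Read a container back into (TraceSet, stimulus, running).

    Raises a clean error naming any missing required group/dataset, and on
    truncated or non-HDF5 files, without returning a partial object.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise OSError(f"not a readable HDF5 container: {path}: {e}") from None
    with f:
        missing = [k for k in _REQUIRED if k not in f]
        if missing:
            raise KeyError(f"container {path} is missing: {', '.join(missing)}")
        traces = TraceSet(
            raw=f["traces/raw"][()],
            neuropil=f["traces/neuropil"][()],
            imaging_rate_hz=float(f.attrs["imaging_rate_hz"]),
            centroid_um=np.column_stack([f["cells/x_um"][()], f["cells/y_um"][()]]),
            depth_um=f["cells/depth_um"][()],
            roi_area_um2=f["cells/roi_area_um2"][()],
        )
        if "traces/corrected" in f:
            traces.corrected = f["traces/corrected"][()]
        if "traces/spikes" in f:
            traces.inferred_spikes = f["traces/spikes"][()]
        if "traces/drift" in f:
            traces.drift_estimate = f["traces/drift"][()]
        for name in _OPTIONAL_PER_CELL:
            if f"cells/{name}" in f:
                setattr(traces, name, f[f"cells/{name}"][()])
        running = f["running"][()]
        stimulus = None
        if "stimulus" in f:
            s = f["stimulus"]
            screen = ScreenGeometry(
                width_cm=float(s.attrs["screen_width_cm"]),
                height_cm=float(s.attrs["screen_height_cm"]),
                distance_cm=float(s.attrs["screen_distance_cm"]),
            )
            stimulus = StimulusSequence(
                kx=s["kx"][()], ky=s["ky"][()], onset_times_s=s["onset_s"][()],
                update_rate_hz=float(s.attrs["update_rate_hz"]),
                screen=screen, sf_max_cpd=float(s.attrs["sf_max_cpd"]),
            )
    return traces, stimulus, running


def write_kernels(path, w: np.ndarray, v: np.ndarray) -> None:
    """Append fitted kernels to an existing container."""
    with h5py.File(path, "a") as f:
        if "kernels" in f:
            del f["kernels"]
        g = f.create_group("kernels")
        g.create_dataset("w", data=w)
        g.create_dataset("v", data=v)


def write_cells_csv(path, traces: TraceSet) -> None:
    traces.qc_table().to_csv(path, index=False)


def fits_table(fits) -> pd.DataFrame:
    """Per-cell fit summary (r_L, penalty, preferences, significance)."""
    return pd.DataFrame(
        {
            "cell": np.arange(len(fits)),
            "r_L": [f.r_L for f in fits],
            "penalty": [f.penalty for f in fits],
            "pref_orientation_deg": [f.pref_orientation_deg for f in fits],
            "pref_sf_cpd": [f.pref_sf_cpd for f in fits],
            "significant": [f.significant for f in fits],
            "b": [f.b for f in fits],
            "a": [f.a for f in fits],
        }
    )
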