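"""Readers and writers for stacks, sweep sets and analysis results.

On-disk schema (shared with any real acquisition that follows it):

* imaging stack — multi-page TIFF or an HDF5 ``frames`` dataset, plus a JSON
  sidecar ``{frame_rate_hz, stim_freq_hz, eye, direction_deg}`` (for HDF5 the
  same fields may live in dataset attributes);
* current sweep set — HDF5 ``sweeps`` (n_sweeps x n_samples, pA) with
  attributes ``sampling_rate_hz``, ``stim_onset_s``, ``test_pulse_start_s``,
  ``test_pulse_end_s``;
* EPSP sweeps — HDF5 ``voltage`` (n_sweeps x n_samples, mV) with
  ``sampling_rate_hz``, ``stim_time_s`` and a per-sweep
  ``acquisition_time_s`` dataset;
* tables — plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .imaging import IntrinsicStack, OdiResult, ResponseMap
from .quantal import SweepSet
from .stdp import EpspSweep


# -- imaging stacks ---------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(stack: IntrinsicStack, path: str | Path) -> Path:
    """Write a stack as TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5) + JSON sidecar."""
    path = Path(path)
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "stim_freq_hz": stack.stim_freq,
        "eye": stack.eye,
        "direction_deg": stack.direction,
    }
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, stack.frames.astype(np.float32), photometric="minisblack"
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=stack.frames, compression="gzip")
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported stack extension {path.suffix!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def load_stack(path: str | Path) -> IntrinsicStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    if path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if meta is None:
            raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["frames"]
            frames = ds[...]
            if meta is None:
                meta = {
                    "frame_rate_hz": float(ds.attrs["frame_rate_hz"]),
                    "stim_freq_hz": float(ds.attrs["stim_freq_hz"]),
                    "eye": str(ds.attrs["eye"]),
                    "direction_deg": float(ds.attrs["direction_deg"]),
                }
    else:
        raise ValueError(f"unsupported stack extension {path.suffix!r}")
    return IntrinsicStack(
        frames=np.asarray(frames),
        frame_rate=float(meta["frame_rate_hz"]),
        stim_freq=float(meta["stim_freq_hz"]),
        eye=str(meta["eye"]),
        direction=float(meta["direction_deg"]),
    )


# -- current sweep sets -----------------------------------------------------

def save_sweepset(sweeps: SweepSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sweeps", data=sweeps.sweeps, compression="gzip")
        ds.attrs["sampling_rate_hz"] = sweeps.sampling_rate
        ds.attrs["stim_onset_s"] = sweeps.stim_onset
        ds.attrs["test_pulse_start_s"] = sweeps.test_pulse_window[0]
        ds.attrs["test_pulse_end_s"] = sweeps.test_pulse_window[1]
        ds.attrs["units"] = "pA"
    return path


def load_sweepset(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        ds = f["sweeps"]
        return SweepSet(
            sweeps=ds[...],
            sampling_rate=float(ds.attrs["sampling_rate_hz"]),
            stim_onset=float(ds.attrs["stim_onset_s"]),
            test_pulse_window=(
                float(ds.attrs["test_pulse_start_s"]),
                float(ds.attrs["test_pulse_end_s"]),
            ),
        )


# -- EPSP sweeps ------------------------------------------------------------

def save_epsp_sweeps(sweeps: list[EpspSweep], path: str | Path) -> Path:
    path = Path(path)
    volt = np.stack([s.voltage for s in sweeps])
    acq = np.array([s.acquisition_time for s in sweeps])
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage", data=volt, compression="gzip")
        ds.attrs["sampling_rate_hz"] = sweeps[0].sampling_rate
        ds.attrs["stim_time_s"] = sweeps[0].stim_time
        ds.attrs["units"] = "mV"
        f.create_dataset("acquisition_time_s", data=acq)
    return path


def load_epsp_sweeps(path: str | Path) -> list[EpspSweep]:
    with h5py.File(path, "r") as f:
        ds = f["voltage"]
        volt = ds[...]
        fs = float(ds.attrs["sampling_rate_hz"])
        stim = float(ds.attrs["stim_time_s"])
        acq = f["acquisition_time_s"][...]
    return [
        EpspSweep(voltage=v, sampling_rate=fs, stim_time=stim, acquisition_time=float(a))
        for v, a in zip(volt, acq)
    ]


# -- maps and results -------------------------------------------------------

def save_response_map(rmap: ResponseMap, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("magnitude", data=rmap.magnitude)
        ds.attrs["eye"] = rmap.eye
        ds.attrs["smoothed"] = rmap.smoothed
        ds.attrs["units"] = "fractional reflectance change x1e4"
        if rmap.phase is not None:
            f.create_dataset("phase", data=rmap.phase)
    return path


def load_response_map(path: str | Path) -> ResponseMap:
    with h5py.File(path, "r") as f:
        ds = f["magnitude"]
        return ResponseMap(
            magnitude=ds[...],
            eye=str(ds.attrs["eye"]),
            phase=f["phase"][...] if "phase" in f else None,
            smoothed=bool(ds.attrs["smoothed"]),
        )


def odi_summary_row(result: OdiResult, label: str = "") -> dict:
    """Flat summary of an :class:`OdiResult` for CSV reporting."""
    return {
        "label": label,
        "amp_contra": result.amp_contra,
        "amp_ipsi": result.amp_ipsi,
        "odi": result.odi,
        "n_pixels": result.n_pixels,
        "roi_fraction": result.threshold_fraction,
    }
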