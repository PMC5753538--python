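"""Serialization: NIfTI-1 volumes for image frames, masks and maps; JSON
sidecars for per-frame metadata, phantom/protocol specs and gradient
waveforms; CSV for study summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import AcquisitionProtocol, DiffusionImageSeries, LVPhantomSpec
from .gradients import GradientWaveform

__all__ = [
    "save_series",
    "load_series",
    "save_maps",
    "save_spec",
    "load_spec",
    "save_protocol",
    "load_protocol",
    "save_waveform",
    "load_waveform",
]


def _nifti(arr: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine=np.eye(4))


def save_series(series: DiffusionImageSeries, out_dir: str | Path) -> Path:
    """Write frames as one rows x cols x frames NIfTI plus a JSON sidecar of
    per-frame metadata and NIfTI masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(series.frames, 0, -1)
    nib.save(_nifti(vol), out / "frames.nii")
    nib.save(_nifti(series.myocardium.astype(float)), out / "myocardium.nii")
    if series.blood_pool is not None:
        nib.save(_nifti(series.blood_pool.astype(float)), out / "blood_pool.nii")
    sidecar = {
        "tag": series.tag,
        "frames": [
            {"b": float(series.bvals[i]),
             "dir": [float(v) for v in series.bvecs[i]],
             "rr_ms": float(series.rr_ms[i]),
             "corrupted": bool(series.corrupted[i])}
            for i in range(series.n_frames)
        ],
    }
    (out / "series.json").write_text(json.dumps(sidecar, indent=1))
    return out


def load_series(in_dir: str | Path) -> DiffusionImageSeries:
    d = Path(in_dir)
    vol = np.asarray(nib.load(d / "frames.nii").dataobj)
    frames = np.moveaxis(vol, -1, 0)
    meta = json.loads((d / "series.json").read_text())
    myo = np.asarray(nib.load(d / "myocardium.nii").dataobj) > 0.5
    blood_path = d / "blood_pool.nii"
    blood = (np.asarray(nib.load(blood_path).dataobj) > 0.5
             if blood_path.exists() else None)
    fr = meta["frames"]
    return DiffusionImageSeries(
        frames=frames,
        bvals=np.array([f["b"] for f in fr]),
        bvecs=np.array([f["dir"] for f in fr]),
        rr_ms=np.array([f["rr_ms"] for f in fr]),
        tag=meta["tag"],
        myocardium=myo,
        blood_pool=blood,
        corrupted=np.array([f.get("corrupted", False) for f in fr]),
    )


def save_maps(maps, out_dir: str | Path) -> Path:
    """Write each scalar map as its own NIfTI volume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("md", "fa", "mode", "ha", "ta", "e2a"):
        nib.save(_nifti(getattr(maps, name)), out / f"{name}.nii")
    return out


def save_spec(spec: LVPhantomSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(spec), indent=1))


def load_spec(path: str | Path) -> LVPhantomSpec:
    d = json.loads(Path(path).read_text())
    d["centre"] = tuple(d["centre"])
    d["eigenvalues"] = tuple(d["eigenvalues"])
    return LVPhantomSpec(**d)


def save_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    d = dataclasses.asdict(protocol)
    d["directions"] = np.asarray(protocol.directions).tolist()
    Path(path).write_text(json.dumps(d, indent=1))


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    d = json.loads(Path(path).read_text())
    d["directions"] = np.array(d["directions"])
    return AcquisitionProtocol(**d)


def save_waveform(w: GradientWaveform, path: str | Path) -> None:
    d = {"breakpoints": [[float(t), float(g)]
                         for t, g in zip(w.times_ms, w.amps_mt_m)],
         "refocus": [float(t) for t in w.refocus_ms],
         "gmax": w.gmax_mt_m, "slew": w.slew_t_m_s}
    Path(path).write_text(json.dumps(d, indent=1))


def load_waveform(path: str | Path) -> GradientWaveform:
    d = json.loads(Path(path).read_text())
    bp = np.array(d["breakpoints"], dtype=float)
    return GradientWaveform(times_ms=bp[:, 0], amps_mt_m=bp[:, 1],
                            refocus_ms=tuple(d.get("refocus", ())),
                            gmax_mt_m=d.get("gmax", 43.0),
                            slew_t_m_s=d.get("slew", 180.0))
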