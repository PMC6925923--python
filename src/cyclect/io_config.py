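"""Slice I/O (DICOM, TIFF/PNG, HDF5), configuration loading, run manifests."""

from __future__ import annotations

import difflib
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import h5py
import imageio.v3 as iio
import numpy as np
import yaml

from .datatypes import CT_RANGE, CTSlice
from .losses import LossWeights
from .training import TrainConfig

__version__ = "0.1.0"

_FORMATS = ("hdf5", "png", "tiff", "dicom")


def write_slices(slices: Sequence[CTSlice], path: str | Path,
                 format: str = "hdf5") -> Path:
    """Persist a slice collection; 16-bit integer formats store rounded
    intensities (the canonical CT scale fits comfortably in uint16)."""
    path = Path(path)
    if format == "hdf5":
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("pixels", data=np.stack([s.pixels for s in slices]))
            f.create_dataset("ids", data=np.array([s.id for s in slices]))
            f.create_dataset("dose_fraction",
                             data=np.array([s.dose_fraction for s in slices]))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for s in slices:
        pix = np.clip(np.rint(s.pixels), 0, 65535).astype(np.uint16)
        if format == "png":
            iio.imwrite(path / f"slice_{s.id:05d}.png", pix)
        elif format == "tiff":
            import tifffile
            tifffile.imwrite(path / f"slice_{s.id:05d}.tif", pix)
        elif format == "dicom":
            _write_dicom(path / f"slice_{s.id:05d}.dcm", pix, s)
        else:
            raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    manifest = [{"id": s.id, "dose_fraction": s.dose_fraction,
                 "provenance": s.provenance} for s in slices]
    (path / "slices.json").write_text(json.dumps(manifest, indent=1))
    return path


def _write_dicom(fname: Path, pix: np.ndarray, s: CTSlice) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(str(fname), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.InstanceNumber = s.id + 1
    ds.Rows, ds.Columns = pix.shape
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleIntercept, ds.RescaleSlope = 0, 1
    ds.PixelData = pix.tobytes()
    ds.save_as(fname, enforce_file_format=True)


def read_slices(path: str | Path, format: str = "hdf5",
                dose_fraction: float = 1.0) -> list[CTSlice]:
    """Load a slice collection, sorted by stable id; all slices in a
    collection must share one size."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[CTSlice] = []
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            pix, ids = f["pixels"][...], f["ids"][...]
            doses = f["dose_fraction"][...]
        for p, i, d in zip(pix, ids, doses):
            out.append(CTSlice(pixels=p, dose_fraction=float(d),
                               provenance="loaded", id=int(i)))
    else:
        pats = {"png": "*.png", "tiff": "*.tif*", "dicom": "*.dcm"}
        if format not in pats:
            raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
        files = sorted(path.glob(pats[format]))
        if not files:
            raise FileNotFoundError(f"no {format} slices found in {path}")
        for i, f in enumerate(files):
            if format == "dicom":
                import pydicom
                arr = pydicom.dcmread(f).pixel_array
            else:
                arr = iio.imread(f)
            out.append(CTSlice(pixels=np.asarray(arr, np.float64),
                               dose_fraction=dose_fraction,
                               provenance="loaded", id=i))
    sizes = {s.side for s in out}
    if len(sizes) > 1:
        raise ValueError(f"mixed slice sizes in one collection: {sorted(sizes)}")
    return sorted(out, key=lambda s: s.id)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: keys accepted in a YAML config file, mapped onto TrainConfig plus pipeline
#: settings used by the CLI.
CONFIG_KEYS = {
    "lr0", "total_epochs", "decay_start_epoch", "batch_size", "lambda_cyc",
    "alpha_prior", "seed", "adam_beta1", "adam_beta2", "channels", "width",
    "n_res_blocks", "use_prior", "checkpoint_every", "max_steps",
    # pipeline settings
    "n_slices", "size", "dose_fraction", "n_angles", "patch_size",
    "prior_method", "max_val",
}

PIPELINE_DEFAULTS = {"n_slices": 16, "size": 64, "dose_fraction": 0.05,
                     "n_angles": 180, "patch_size": 128,
                     "prior_method": "bm3d", "max_val": CT_RANGE[1]}


def load_config(path: str | Path) -> tuple[TrainConfig, dict]:
    """Parse and validate a YAML config; unknown keys are rejected with a
    closest-match suggestion; defaults are filled in and echoed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    for key in raw:
        if key not in CONFIG_KEYS:
            hint = difflib.get_close_matches(key, CONFIG_KEYS, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suffix}")
    weights = LossWeights(float(raw.pop("lambda_cyc", 10.0)),
                          float(raw.pop("alpha_prior", 10.0)))
    pipeline = dict(PIPELINE_DEFAULTS)
    for k in list(raw):
        if k in PIPELINE_DEFAULTS:
            pipeline[k] = raw.pop(k)
    cfg = TrainConfig(weights=weights, **raw)
    return cfg, pipeline


def config_echo(cfg: TrainConfig, pipeline: dict) -> dict:
    d = asdict(cfg)
    d["weights"] = {"lambda_cyc": cfg.weights.lambda_cyc,
                    "alpha_prior": cfg.weights.alpha_prior}
    d.update(pipeline)
    return d


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, command: str, config: dict,
                   seeds: dict, inputs: Sequence[str | Path] = ()) -> Path:
    """Write the single run manifest of an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).is_file()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "software_version": __version__,
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1, default=str))
    return p
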