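"""Readers/writers: 4-D NIfTI-1 image stacks with JSON sidecars, ROI
masks, JSON configs and run manifests.

A tagged sequence is stored as one ``<base>.nii.gz`` of shape
(nx, nz, 1, nt) plus ``<base>.json``; a PC sequence as
``<base>_velocity.nii.gz`` and ``<base>_magnitude.nii.gz`` plus
``<base>.json``.  All metadata keys carry explicit units (mm, s, cm/s).
Image data round-trip losslessly at float32.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import DCMGeometry, WallMotionProgram
from .synth import PCAcquisition, PCSequence, TagAcquisition, TaggedSequence
from .tagging import ROI

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_roi",
    "read_roi",
    "load_config",
    "validate_config",
    "RunManifest",
]

SCHEMA_VERSION = 1

_TAG_KEYS = {
    "tag_spacing": "tag_spacing_mm",
    "tag_width": "tag_width_mm",
    "tag_delay": "tag_delay_s",
    "tag_depth": "tag_depth",
    "voxel_size": "voxel_size_mm",
    "frame_interval": "frame_interval_s",
    "n_frames": "n_frames",
    "noise_sigma": "noise_sigma",
    "seed": "seed",
    "x_margin": "x_margin_mm",
    "advect": "advect",
}
_PC_KEYS = {
    "voxel_size": "voxel_size_mm",
    "matrix": "matrix",
    "slice_thickness": "slice_thickness_mm",
    "frame_interval": "frame_interval_s",
    "n_frames": "n_frames",
    "venc": "venc_cms",
    "slice_x_position": "slice_x_position_mm",
    "velocity_noise_sigma": "velocity_noise_sigma_cms",
    "magnitude_noise_sigma": "magnitude_noise_sigma",
    "seed": "seed",
}


def _acq_to_meta(acq, keymap):
    d = dataclasses.asdict(acq)
    d.pop("nominal_tag_positions", None)
    return {keymap[k]: v for k, v in d.items()}


def _meta_to_acq(meta, keymap, cls, kind):
    kwargs = {}
    for field, key in keymap.items():
        if key not in meta:
            raise ValueError(
                f"sidecar for a {kind} sequence is missing required field {key!r}"
            )
        kwargs[field] = meta[key]
    return cls(**kwargs)


def _save_nifti(array_xz_t, voxel_size, path):
    img = nib.Nifti1Image(
        np.asarray(array_xz_t, dtype=np.float32)[:, :, None, :],
        affine=np.diag([voxel_size, voxel_size, 1.0, 1.0]),
    )
    nib.save(img, str(path))


def _load_nifti(path):
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.float32)[:, :, 0, :]


def write_sequence(seq, base_path) -> Path:
    """Write a Tagged/PC sequence as NIfTI-1 plus a JSON sidecar.

    Returns the sidecar path.
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(seq, TaggedSequence):
        _save_nifti(np.moveaxis(seq.frames, 0, -1), seq.acquisition.voxel_size,
                    base.with_suffix(".nii.gz"))
        meta = {
            "schema_version": SCHEMA_VERSION,
            "kind": "tagged",
            "acquisition": _acq_to_meta(seq.acquisition, _TAG_KEYS),
            "frame_times_s": [float(t) for t in seq.frame_times],
            "nominal_tag_positions_mm": [float(p) for p in seq.nominal_tag_positions],
            "x0_mm": float(seq.x_coords[0]),
            "z0_mm": float(seq.z_coords[0]),
        }
    elif isinstance(seq, PCSequence):
        vs = seq.acquisition.voxel_size
        _save_nifti(np.moveaxis(seq.velocity_frames, 0, -1), vs,
                    base.parent / (base.name + "_velocity.nii.gz"))
        _save_nifti(np.moveaxis(seq.magnitude_frames, 0, -1), vs,
                    base.parent / (base.name + "_magnitude.nii.gz"))
        meta = {
            "schema_version": SCHEMA_VERSION,
            "kind": "pc",
            "acquisition": _acq_to_meta(seq.acquisition, _PC_KEYS),
            "frame_times_s": [float(t) for t in seq.frame_times],
            "y0_mm": float(seq.y_coords[0]),
            "z0_mm": float(seq.z_coords[0]),
        }
    else:
        raise TypeError(f"cannot write object of type {type(seq).__name__}")
    sidecar = base.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def read_sequence(base_path):
    """Read a sequence written by :func:`write_sequence` (base or sidecar path)."""
    base = Path(base_path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} not found; a sequence needs both the NIfTI "
            "file(s) and its JSON metadata"
        )
    meta = json.loads(sidecar.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported sidecar schema_version {meta.get('schema_version')!r}"
        )
    times = np.asarray(meta["frame_times_s"], dtype=float)
    if meta["kind"] == "tagged":
        acq = _meta_to_acq(meta["acquisition"], _TAG_KEYS, TagAcquisition, "tagged")
        data = _load_nifti(base.with_suffix(".nii.gz"))
        nx, nz = data.shape[0], data.shape[1]
        vs = acq.voxel_size
        return TaggedSequence(
            frames=np.moveaxis(data, -1, 0),
            acquisition=acq,
            frame_times=times,
            nominal_tag_positions=np.asarray(meta["nominal_tag_positions_mm"]),
            x_coords=meta["x0_mm"] + vs * np.arange(nx),
            z_coords=meta["z0_mm"] + vs * np.arange(nz),
        )
    if meta["kind"] == "pc":
        acq = _meta_to_acq(meta["acquisition"], _PC_KEYS, PCAcquisition, "pc")
        vel = _load_nifti(base.parent / (base.name + "_velocity.nii.gz"))
        mag = _load_nifti(base.parent / (base.name + "_magnitude.nii.gz"))
        ny, nz = vel.shape[0], vel.shape[1]
        vs = acq.voxel_size
        return PCSequence(
            velocity_frames=np.moveaxis(vel, -1, 0),
            magnitude_frames=np.moveaxis(mag, -1, 0),
            acquisition=acq,
            frame_times=times,
            y_coords=meta["y0_mm"] + vs * np.arange(ny),
            z_coords=meta["z0_mm"] + vs * np.arange(nz),
        )
    raise ValueError(f"unknown sequence kind {meta['kind']!r}")


def write_roi(roi: ROI, path) -> Path:
    """Write an ROI as a NIfTI mask (.nii/.nii.gz) or polygon-free JSON."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {"label": roi.label, "shape": list(roi.mask.shape),
                   "indices": np.argwhere(roi.mask).tolist()}
        path.write_text(json.dumps(payload))
    else:
        img = nib.Nifti1Image(roi.mask.astype(np.uint8), affine=np.eye(4))
        img.header["descrip"] = roi.label.encode()[:79]
        nib.save(img, str(path))
    return path


def read_roi(path) -> ROI:
    """Read an ROI mask from NIfTI or JSON (index list or polygon)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        mask = np.zeros(tuple(payload["shape"]), dtype=bool)
        if "indices" in payload:
            idx = np.asarray(payload["indices"], dtype=int)
            mask[tuple(idx.T)] = True
        elif "polygon" in payload:
            from skimage.draw import polygon as sk_polygon
            poly = np.asarray(payload["polygon"], dtype=float)
            rr, cc = sk_polygon(poly[:, 0], poly[:, 1], shape=mask.shape)
            mask[rr, cc] = True
        else:
            raise ValueError("ROI JSON needs 'indices' or 'polygon'")
        return ROI(mask=mask, label=payload.get("label", ""))
    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj) > 0
    return ROI(mask=mask, label=str(img.header["descrip"].astype(str)))


_CONFIG_SECTIONS = {
    "geometry": DCMGeometry,
    "program": WallMotionProgram,
    "tag_acquisition": TagAcquisition,
    "pc_acquisition": PCAcquisition,
}


def validate_config(config: dict) -> dict:
    """Build the typed objects a config describes, validating invariants.

    Unknown sections or fields, and any violated invariant (e.g.
    tag_width >= tag_spacing), raise ValueError naming the offender.
    """
    out = {}
    for section, payload in config.items():
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        cls = _CONFIG_SECTIONS[section]
        if section == "tag_acquisition" and "nominal_tag_positions" in payload:
            payload = dict(payload)
            payload["nominal_tag_positions"] = tuple(payload["nominal_tag_positions"])
        try:
            out[section] = cls(**payload)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid {section!r} config: {exc}") from exc
    return out


def load_config(path) -> dict:
    """Load and validate a JSON config file."""
    return validate_config(json.loads(Path(path).read_text()))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one experiment run."""

    config: dict
    seeds: dict
    version: str
    checksums: dict

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def for_outputs(cls, config: dict, seeds: dict, version: str, paths) -> "RunManifest":
        return cls(config=config, seeds=seeds, version=version,
                   checksums={str(p): _sha256(p) for p in paths})
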