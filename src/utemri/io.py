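"""File formats: NIfTI volumes with JSON sidecars, YAML run configs.

Multi-echo series are stored as 4D NIfTI (echo along the 4th axis) with
a JSON sidecar carrying the echo times in ms, protocol name, noise sigma
and seed.  The sidecar is authoritative for echo times — NIfTI time-axis
metadata is not portable across tools.  Rates are serialized in s^-1,
times in ms, everywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .forward_model import MultiEchoSeries
from .phantom import Phantom, PhantomConfig, SpioDepot, TissueSpec
from .protocols import PROTOCOLS, Protocol, get_protocol
from .relaxometry import RatioMap, RelaxationMap


class UtemriIOError(Exception):
    """Base class for file/validation errors raised by this package."""


class SidecarMismatchError(UtemriIOError):
    """Sidecar metadata inconsistent with the image it describes."""


class MalformedSidecarError(UtemriIOError):
    """Sidecar JSON missing required fields or unreadable."""


class MissingROIError(UtemriIOError):
    """A phantom file lacks one of the five required ROI codes."""


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size_mm: float, ndim_spatial: int) -> np.ndarray:
    aff = np.eye(4)
    for i in range(min(3, ndim_spatial)):
        aff[i, i] = voxel_size_mm
    return aff


def save_series(series: MultiEchoSeries, path: str | Path, voxel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = series.data
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm, data.ndim - 1))
    nib.save(img, str(path))
    sidecar = {
        "echo_times_ms": list(series.echo_times),
        "protocol": series.protocol.name,
        "mode": series.protocol.mode,
        "tr_ms": series.protocol.tr,
        "flip_angle_deg": series.protocol.flip_angle,
        "noise_sigma": series.noise_sigma,
        "seed": series.seed,
        "voxel_size_mm": voxel_size_mm,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_series(path: str | Path) -> MultiEchoSeries:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise MalformedSidecarError(f"missing sidecar {side_path}")
    try:
        meta = json.loads(side_path.read_text())
    except json.JSONDecodeError as exc:
        raise MalformedSidecarError(f"unreadable sidecar {side_path}: {exc}") from exc
    for key in ("echo_times_ms", "protocol"):
        if key not in meta:
            raise MalformedSidecarError(f"sidecar {side_path} lacks field {key!r}")

    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    echo_times = [float(t) for t in meta["echo_times_ms"]]
    if data.shape[-1] != len(echo_times):
        raise SidecarMismatchError(
            f"sidecar lists {len(echo_times)} echo_times_ms but volume has "
            f"{data.shape[-1]} echoes"
        )
    name = meta["protocol"]
    if name in PROTOCOLS:
        protocol = get_protocol(name)
        if tuple(echo_times) != protocol.echo_times:
            protocol = dataclasses.replace(protocol, echo_times=tuple(echo_times))
    else:
        protocol = Protocol(
            name=name,
            echo_times=tuple(echo_times),
            tr=float(meta.get("tr_ms", echo_times[-1] + 1.0)),
            flip_angle=float(meta.get("flip_angle_deg", 0.0)),
            mode=meta.get("mode", "r2star"),
        )
    return MultiEchoSeries(
        data=np.clip(data, 0.0, None),
        echo_times=tuple(echo_times),
        protocol=protocol,
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
        seed=meta.get("seed"),
    )


def save_map(map_obj: RelaxationMap | RatioMap, path: str | Path, voxel_size_mm: float = 1.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(map_obj, RelaxationMap):
        values = map_obj.rate
        sidecar = {
            "map_type": "relaxation",
            "mode": map_obj.mode,
            "echo_times_used_ms": list(map_obj.echo_times_used),
            "units": "s^-1",
        }
    else:
        values = map_obj.value
        sidecar = {
            "map_type": "ratio",
            "kind": map_obj.kind,
            "echo_pair": list(map_obj.echo_pair),
            "echo_times_ms": list(map_obj.echo_times),
            "units": "dimensionless",
        }
    out = np.where(map_obj.valid_mask, values, np.nan).astype(np.float32)
    nib.save(nib.Nifti1Image(out, _affine(voxel_size_mm, out.ndim)), str(path))
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def load_map(path: str | Path) -> RelaxationMap | RatioMap:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise MalformedSidecarError(f"missing sidecar {side_path}")
    meta = json.loads(side_path.read_text())
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    valid = np.isfinite(values)
    if meta.get("map_type") == "ratio":
        return RatioMap(
            value=values,
            echo_pair=tuple(meta["echo_pair"]),
            kind=meta["kind"],
            valid_mask=valid,
            echo_times=tuple(meta["echo_times_ms"]),
        )
    return RelaxationMap(
        rate=values,
        intercept=np.full(values.shape, np.nan),
        r_squared=np.full(values.shape, np.nan),
        valid_mask=valid,
        mode=meta.get("mode", "r2star"),
        echo_times_used=tuple(meta.get("echo_times_used_ms", ())),
    )


def save_phantom(phantom: Phantom, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(
            phantom.label_map.astype(np.int16),
            _affine(phantom.voxel_size_mm, phantom.label_map.ndim),
        ),
        str(path),
    )
    sidecar = {
        "voxel_size_mm": phantom.voxel_size_mm,
        "roi_codes": phantom.roi_codes,
        "tissues": {
            str(code): dataclasses.asdict(spec) for code, spec in phantom.tissues.items()
        },
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    if phantom.pd_texture is not None:
        tex_path = path.with_name(path.name.replace(".nii", "_texture.nii", 1))
        nib.save(
            nib.Nifti1Image(
                phantom.pd_texture.astype(np.float32),
                _affine(phantom.voxel_size_mm, phantom.pd_texture.ndim),
            ),
            str(tex_path),
        )
    return path


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise MalformedSidecarError(f"missing sidecar {side_path}")
    meta = json.loads(side_path.read_text())
    for key in ("roi_codes", "tissues", "voxel_size_mm"):
        if key not in meta:
            raise MalformedSidecarError(f"phantom sidecar lacks field {key!r}")
    from .phantom import ROI_NAMES

    missing = sorted(set(ROI_NAMES) - set(meta["roi_codes"]))
    if missing:
        raise MissingROIError(f"phantom sidecar missing ROI codes: {missing}")
    label_map = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    tissues = {
        int(code): TissueSpec(**fields) for code, fields in meta["tissues"].items()
    }
    tex_path = path.with_name(path.name.replace(".nii", "_texture.nii", 1))
    pd_texture = (
        np.asarray(nib.load(str(tex_path)).dataobj, dtype=float)
        if tex_path.exists()
        else None
    )
    return Phantom(
        label_map=label_map,
        tissues=tissues,
        voxel_size_mm=float(meta["voxel_size_mm"]),
        roi_codes={k: int(v) for k, v in meta["roi_codes"].items()},
        pd_texture=pd_texture,
    )


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one simulation/analysis run."""

    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    protocol: str = "cones_ute"
    noise_sigma: float = 0.0
    seed: int = 0
    ratios: tuple[str, ...] = ("R12", "R15", "R25")
    subtraction_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    rois: tuple[str, ...] = (
        "joint_space",
        "fat_pad",
        "tibial_bone",
        "dorsal_muscle",
        "defect_region",
    )
    alpha: float = 0.15

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = d.get("phantom") or {}
        if isinstance(ph, dict):
            ph = dict(ph)
            if isinstance(ph.get("spio_depot"), dict):
                ph["spio_depot"] = SpioDepot(**ph["spio_depot"])
            if isinstance(ph.get("tissues"), dict):
                ph["tissues"] = {
                    name: t if isinstance(t, TissueSpec) else TissueSpec(**t)
                    for name, t in ph["tissues"].items()
                }
            if "shape" in ph:
                ph["shape"] = tuple(ph["shape"])
            d["phantom"] = PhantomConfig(**ph)
        if "ratios" in d:
            d["ratios"] = tuple(d["ratios"])
        if "subtraction_pairs" in d:
            d["subtraction_pairs"] = tuple(tuple(p) for p in d["subtraction_pairs"])
        if "rois" in d:
            d["rois"] = tuple(d["rois"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise UtemriIOError(f"run config {path} must be a YAML mapping")
        try:
            return cls.from_dict(data)
        except (TypeError, ValueError) as exc:
            raise UtemriIOError(f"invalid run config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
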