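"""File formats, seeding, and run manifests.

Complex dual-echo images are stored either as a NumPy ``.npz`` archive
with pinned key names (``s1_real``, ``s1_imag``, ``s2_real``,
``s2_imag`` plus scalar metadata ``te1_ms``, ``te2_ms``, ``b0_tesla``,
``fat_shift_ppm``, ``pixel_spacing_mm``) or as two pairs of NIfTI
volumes (real/imag per echo) referenced from a YAML sidecar carrying
the same metadata keys.  Separation results are written as float32
NIfTI maps plus a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionParams, DualEchoImage, WaterFatResult

__all__ = [
    "DataError",
    "read_dual_echo",
    "write_dual_echo",
    "write_dual_echo_nifti",
    "write_result",
    "read_result_water_fat",
    "derive_seed",
    "file_sha256",
    "RunManifest",
]

ARCHIVE_KEYS = ("s1_real", "s1_imag", "s2_real", "s2_imag")
META_KEYS = ("te1_ms", "te2_ms", "b0_tesla", "fat_shift_ppm", "pixel_spacing_mm")


class DataError(ValueError):
    """Raised for malformed or incomplete input files."""


def _params_to_meta(p: AcquisitionParams) -> dict:
    return {
        "te1_ms": float(p.te1_ms),
        "te2_ms": float(p.te2_ms),
        "b0_tesla": float(p.field_strength_t),
        "fat_shift_ppm": float(p.fat_shift_ppm),
        "pixel_spacing_mm": [float(v) for v in p.pixel_spacing_mm],
    }


def _params_from_meta(meta: dict, source: str) -> AcquisitionParams:
    missing = [k for k in META_KEYS if k not in meta]
    if missing:
        raise DataError(f"{source}: missing metadata keys: {', '.join(missing)}")
    return AcquisitionParams(
        te1_ms=float(meta["te1_ms"]),
        te2_ms=float(meta["te2_ms"]),
        field_strength_t=float(meta["b0_tesla"]),
        fat_shift_ppm=float(meta["fat_shift_ppm"]),
        pixel_spacing_mm=tuple(float(v) for v in np.asarray(meta["pixel_spacing_mm"]).ravel()),
    )


def write_dual_echo(img: DualEchoImage, path: str | Path) -> Path:
    """Write a dual-echo image as an ``.npz`` archive (lossless float64)."""
    path = Path(path)
    arrays = {
        "s1_real": img.s1.real,
        "s1_imag": img.s1.imag,
        "s2_real": img.s2.real,
        "s2_imag": img.s2.imag,
    }
    meta = _params_to_meta(img.params)
    np.savez(
        path,
        **arrays,
        te1_ms=meta["te1_ms"],
        te2_ms=meta["te2_ms"],
        b0_tesla=meta["b0_tesla"],
        fat_shift_ppm=meta["fat_shift_ppm"],
        pixel_spacing_mm=np.asarray(meta["pixel_spacing_mm"]),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_dual_echo(path: str | Path) -> DualEchoImage:
    """Read a dual-echo image from an ``.npz`` archive or a YAML NIfTI sidecar."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix in (".yaml", ".yml"):
        return _read_dual_echo_nifti(path)
    with np.load(path) as z:
        missing = [k for k in ARCHIVE_KEYS if k not in z]
        missing += [k for k in META_KEYS if k not in z]
        if missing:
            raise DataError(f"{path}: missing archive keys: {', '.join(missing)}")
        s1 = z["s1_real"] + 1j * z["s1_imag"]
        s2 = z["s2_real"] + 1j * z["s2_imag"]
        meta = {k: z[k] for k in META_KEYS}
    if s1.shape != s2.shape:
        raise DataError(f"{path}: echo shapes differ: {s1.shape} vs {s2.shape}")
    return DualEchoImage(s1, s2, _params_from_meta(meta, str(path)))


def _nifti_of(arr: np.ndarray, dtype=np.float32) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine=np.eye(4))
    img.header.set_data_dtype(dtype)
    return img


def write_dual_echo_nifti(img: DualEchoImage, prefix: str | Path) -> Path:
    """Write an image as four NIfTI files plus a YAML sidecar; returns the sidecar path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    files = {}
    for key, arr in (
        ("s1_real", img.s1.real), ("s1_imag", img.s1.imag),
        ("s2_real", img.s2.real), ("s2_imag", img.s2.imag),
    ):
        fname = f"{prefix.name}_{key}.nii.gz"
        nib.save(_nifti_of(arr, np.float64), str(prefix.parent / fname))
        files[key] = fname
    sidecar = prefix.parent / f"{prefix.name}.yaml"
    doc = {"files": files, **_params_to_meta(img.params)}
    sidecar.write_text(yaml.safe_dump(doc, sort_keys=True))
    return sidecar


def _read_dual_echo_nifti(sidecar: Path) -> DualEchoImage:
    doc = yaml.safe_load(sidecar.read_text())
    if "files" not in doc:
        raise DataError(f"{sidecar}: missing 'files' mapping")
    missing = [k for k in ARCHIVE_KEYS if k not in doc["files"]]
    if missing:
        raise DataError(f"{sidecar}: missing file entries: {', '.join(missing)}")
    arrays = {}
    for key, fname in doc["files"].items():
        fpath = sidecar.parent / fname
        if not fpath.exists():
            raise DataError(f"{sidecar}: referenced file missing: {fname}")
        arrays[key] = np.asanyarray(nib.load(str(fpath)).dataobj).astype(float)
    s1 = arrays["s1_real"] + 1j * arrays["s1_imag"]
    s2 = arrays["s2_real"] + 1j * arrays["s2_imag"]
    if s1.shape != s2.shape:
        raise DataError(f"{sidecar}: echo shapes differ")
    return DualEchoImage(s1, s2, _params_from_meta(doc, str(sidecar)))


def write_result(result: WaterFatResult, prefix: str | Path) -> dict[str, Path]:
    """Write a separation result: water/fat/selection NIfTI, phasor pair, provenance JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr, dtype in (
        ("water", result.water, np.float32),
        ("fat", result.fat, np.float32),
        ("phasor_real", result.phasor.real, np.float32),
        ("phasor_imag", result.phasor.imag, np.float32),
        ("selection", result.selection, np.uint8),
    ):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(_nifti_of(arr, dtype), str(p))
        paths[name] = p
    prov = prefix.parent / f"{prefix.name}_provenance.json"
    prov.write_text(json.dumps(_jsonable(result.meta), indent=2, sort_keys=True))
    paths["provenance"] = prov
    return paths


def read_result_water_fat(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    out = []
    for name in ("water", "fat"):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        if not p.exists():
            raise DataError(f"missing result map: {p}")
        out.append(np.asanyarray(nib.load(str(p)).dataobj).astype(float))
    return out[0], out[1]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed fan-out: stable hash of (master seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance record of a pipeline run: command, config, seeds, hashes, timings."""

    def __init__(self, command: str, config: dict | None = None, seed: int = 0):
        self.doc: dict[str, Any] = {
            "tool": "dixonsep",
            "version": _package_version(),
            "command": command,
            "config": _jsonable(config or {}),
            "seed": int(seed),
            "stages": [],
            "outputs": {},
        }
        self._t0: float | None = None
        self._stage: str | None = None

    def start_stage(self, name: str) -> None:
        self._stage = name
        self._t0 = time.perf_counter()

    def end_stage(self, **info: Any) -> None:
        assert self._stage is not None and self._t0 is not None
        self.doc["stages"].append(
            {"name": self._stage,
             "wall_s": round(time.perf_counter() - self._t0, 6),
             **_jsonable(info)}
        )
        self._stage = None
        self._t0 = None

    def add_output(self, name: str, path: str | Path) -> None:
        self.doc["outputs"][name] = {"path": str(path), "sha256": file_sha256(path)}

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.doc, indent=2, sort_keys=True))
        return path


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("dixonsep")
    except Exception:  # pragma: no cover
        return "unknown"
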