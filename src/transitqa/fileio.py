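"""Portal-image file formats, run configuration and the JSON run report.

A portal image is stored as either a single-channel float TIFF or a
plain-text matrix, always accompanied by a JSON sidecar carrying the beam
geometry:

    {"sad_cm": ..., "sid_cm": ..., "pixel_pitch_iso_cm": ...,
     "rows": ..., "cols": ..., "center_px": [r, c], "label": "..."}

The sidecar lives next to the image with a ``.json`` extension.  Round
trips are lossless for TIFF (float64) and good to float formatting
precision for the text variant.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
from pydantic import BaseModel

from .errors import FormatError
from .raytrace import BeamGeometry
from .transit import PortalImage

__all__ = [
    "read_portal_image",
    "write_portal_image",
    "sidecar_path",
    "read_rtimage",
    "RunReport",
]

_TEXT_SUFFIXES = {".txt", ".csv", ".dat"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def _geom_to_sidecar(img: PortalImage) -> dict[str, Any]:
    g = img.geom
    return {
        "sad_cm": g.sad,
        "sid_cm": g.sid,
        "pixel_pitch_iso_cm": g.pixel_pitch_iso,
        "rows": g.shape[0],
        "cols": g.shape[1],
        "center_px": list(g.center_px),
        "label": img.label,
    }


def write_portal_image(img: PortalImage, path) -> None:
    """Write image values plus JSON geometry sidecar (format from extension)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(path, img.values.astype(np.float64))
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, img.values, fmt="%.10e", delimiter=",")
    else:
        raise FormatError(f"unsupported portal image extension: {path.suffix!r}")
    with open(sidecar_path(path), "w", encoding="utf-8") as f:
        json.dump(_geom_to_sidecar(img), f, indent=2)
        f.write("\n")


def read_portal_image(path) -> PortalImage:
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FormatError(f"missing sidecar {sc}")
    with open(sc, "r", encoding="utf-8") as f:
        meta = json.load(f)
    required = {"sad_cm", "sid_cm", "pixel_pitch_iso_cm", "rows", "cols"}
    if not required <= meta.keys():
        raise FormatError(f"sidecar {sc} is missing keys {sorted(required - meta.keys())}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        vals = np.asarray(tifffile.imread(path), dtype=np.float64)
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        vals = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        raise FormatError(f"unsupported portal image extension: {path.suffix!r}")
    if vals.shape != (int(meta["rows"]), int(meta["cols"])):
        raise FormatError(
            f"pixel grid {vals.shape} does not match sidecar "
            f"({meta['rows']}, {meta['cols']})"
        )
    geom = BeamGeometry(
        sad=float(meta["sad_cm"]),
        sid=float(meta["sid_cm"]),
        pixel_pitch_iso=float(meta["pixel_pitch_iso_cm"]),
        shape=(int(meta["rows"]), int(meta["cols"])),
        center_px=tuple(meta["center_px"]) if "center_px" in meta else None,
    )
    return PortalImage(vals, geom, label=str(meta.get("label", "")))


def read_rtimage(path, label: str = "") -> PortalImage:
    """Optional DICOM RTIMAGE import (requires pydicom).

    Pixel spacing is rescaled from the detector plane to the isocenter
    plane using the RT image SID and the machine SAD.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError("DICOM import requires the optional pydicom dependency") from exc
    ds = pydicom.dcmread(path)
    try:
        sid = float(ds.RTImageSID) / 10.0  # mm -> cm
        sad = float(ds.RadiationMachineSAD) / 10.0
        pitch_det = float(ds.ImagePlanePixelSpacing[0]) / 10.0
        vals = ds.pixel_array.astype(np.float64)
    except AttributeError as exc:
        raise FormatError(f"not a usable RTIMAGE: missing {exc}") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    vals = vals * slope + intercept
    geom = BeamGeometry(
        sad=sad,
        sid=sid,
        pixel_pitch_iso=pitch_det * sad / sid,
        shape=vals.shape,
    )
    return PortalImage(np.clip(vals, 0.0, None), geom, label=label or "RTIMAGE import")


class RunReport(BaseModel):
    """Single-JSON summary of a QA run (validates against the shipped schema)."""

    seed: int
    versions: dict[str, str]
    config: dict[str, Any]
    duty_cycle: float | None = None
    gpr_2mm2pct: float | None = None
    gpr_1mm1pct: float | None = None
    best_window: dict[str, float] | None = None
    outputs: dict[str, str] = {}


def report_schema() -> dict[str, Any]:
    return RunReport.model_json_schema()
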