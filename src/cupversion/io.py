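"""Readers and writers: annotation files, images, configs, reports.

Annotation schema (JSON, one object or a list of objects)::

    {
      "film_id": "f001",
      "side": "left" | "right",
      "apparent_retroversion": false,          # optional
      "landmarks": {
        "symphysis":  [x, y],
        "scj":        [x, y],
        "teardrop_l": [x, y],
        "teardrop_r": [x, y]
      },
      "cup": {
        "rim_points": [[x, y], ...]            # >= 5 points, OR
        "ellipse": {"cx":, "cy":, "a":, "b":, "orientation_deg":}
      }
    }

The CSV equivalent has one row per point with columns
``film_id, side, point_type, x, y`` (point_type in symphysis/scj/
teardrop_l/teardrop_r/rim) and an optional ``apparent_retroversion``
column.  Coordinates are 0-based pixels, y growing downward.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Ellipse2D
from .landmarks import (
    MeasurementRecord,
    MissingLandmarkError,
    PelvicLandmarks,
    StandardizationConfig,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilmAnnotation",
    "measure_annotation",
    "read_annotations",
    "write_annotations",
    "read_image",
    "load_config",
    "records_to_dataframe",
    "write_records",
    "make_provenance",
]

_POINT_TYPES = ("symphysis", "scj", "teardrop_l", "teardrop_r")


@dataclass(frozen=True)
class FilmAnnotation:
    """Parsed annotation of one film: landmarks plus the cup rim."""

    film_id: str
    side: str
    landmarks: PelvicLandmarks
    rim_points: Optional[np.ndarray] = None
    ellipse: Optional[Ellipse2D] = None
    apparent_retroversion: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(
                f"film {self.film_id!r}: side must be 'left' or 'right', got {self.side!r}"
            )
        if self.rim_points is None and self.ellipse is None:
            raise ValueError(
                f"film {self.film_id!r}: cup needs either rim_points or ellipse"
            )


def _annotation_from_dict(obj: dict) -> FilmAnnotation:
    film_id = str(obj.get("film_id", ""))
    try:
        lm_raw = obj["landmarks"]
    except KeyError:
        raise MissingLandmarkError("landmarks") from None
    coords = {}
    for name in _POINT_TYPES:
        if name not in lm_raw or lm_raw[name] is None:
            raise MissingLandmarkError(name)
        p = lm_raw[name]
        if len(p) != 2:
            raise ValueError(f"film {film_id!r}: landmark {name!r} must be [x, y]")
        coords[name] = (float(p[0]), float(p[1]))
    cup = obj.get("cup", {})
    rim = cup.get("rim_points")
    ell = cup.get("ellipse")
    ellipse = None
    if ell is not None:
        ellipse = Ellipse2D(
            center=(float(ell["cx"]), float(ell["cy"])),
            a=float(ell["a"]),
            b=float(ell["b"]),
            orientation_deg=float(ell.get("orientation_deg", 0.0)),
        )
    return FilmAnnotation(
        film_id=film_id,
        side=str(obj.get("side", "")),
        landmarks=PelvicLandmarks(**coords),
        rim_points=None if rim is None else np.asarray(rim, dtype=float),
        ellipse=ellipse,
        apparent_retroversion=bool(obj.get("apparent_retroversion", False)),
    )


def read_annotations(path: str | Path) -> list[FilmAnnotation]:
    """Read annotations from a JSON or CSV file (one or many films)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return _read_annotations_csv(path)
    with open(path) as fh:
        data = json.load(fh)
    items = data if isinstance(data, list) else [data]
    return [_annotation_from_dict(obj) for obj in items]


def _read_annotations_csv(path: Path) -> list[FilmAnnotation]:
    df = pd.read_csv(path)
    required = {"film_id", "side", "point_type", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV is missing columns: {sorted(missing)}")
    out = []
    for film_id, grp in df.groupby("film_id", sort=False):
        lm = {}
        for name in _POINT_TYPES:
            rows = grp[grp["point_type"] == name]
            if rows.empty:
                raise MissingLandmarkError(name)
            lm[name] = (float(rows.iloc[0]["x"]), float(rows.iloc[0]["y"]))
        rim = grp[grp["point_type"] == "rim"][["x", "y"]].to_numpy(float)
        retro = bool(grp["apparent_retroversion"].iloc[0]) \
            if "apparent_retroversion" in grp.columns else False
        out.append(
            FilmAnnotation(
                film_id=str(film_id),
                side=str(grp["side"].iloc[0]),
                landmarks=PelvicLandmarks(**lm),
                rim_points=rim if rim.size else None,
                apparent_retroversion=retro,
            )
        )
    return out


def _annotation_to_dict(ann: FilmAnnotation) -> dict:
    cup: dict = {}
    if ann.rim_points is not None:
        cup["rim_points"] = np.asarray(ann.rim_points, dtype=float).tolist()
    if ann.ellipse is not None:
        e = ann.ellipse
        cup["ellipse"] = {
            "cx": e.center[0], "cy": e.center[1],
            "a": e.a, "b": e.b, "orientation_deg": e.orientation_deg,
        }
    lm = ann.landmarks
    return {
        "film_id": ann.film_id,
        "side": ann.side,
        "apparent_retroversion": bool(ann.apparent_retroversion),
        "landmarks": {
            "symphysis": list(lm.symphysis),
            "scj": list(lm.scj),
            "teardrop_l": list(lm.teardrop_l),
            "teardrop_r": list(lm.teardrop_r),
        },
        "cup": cup,
    }


def write_annotations(annotations: Sequence[FilmAnnotation], path: str | Path) -> None:
    """Write annotations to JSON or CSV, chosen by the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = []
        for ann in annotations:
            lm = ann.landmarks
            pts = [(name, getattr(lm, name)) for name in _POINT_TYPES]
            if ann.rim_points is not None:
                pts += [("rim", p) for p in np.asarray(ann.rim_points, dtype=float)]
            for name, (x, y) in pts:
                rows.append(
                    {
                        "film_id": ann.film_id,
                        "side": ann.side,
                        "point_type": name,
                        "x": x,
                        "y": y,
                        "apparent_retroversion": int(ann.apparent_retroversion),
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    else:
        payload = [_annotation_to_dict(a) for a in annotations]
        with open(path, "w") as fh:
            json.dump(payload if len(payload) != 1 else payload[0], fh, indent=2)
            fh.write("\n")


def measure_annotation(
    ann: FilmAnnotation,
    config: StandardizationConfig = StandardizationConfig(),
    pixel_spacing: float = 1.0,
) -> MeasurementRecord:
    """Measure one annotated film: fit the rim ellipse if needed, then run
    the full landmark/standardization chain."""
    from .ellipse_fit import fit_ellipse
    from .landmarks import measure_film

    if ann.rim_points is not None:
        ellipse, residual = fit_ellipse(ann.rim_points)
    else:
        ellipse, residual = ann.ellipse, float("nan")
    return measure_film(
        ann.landmarks,
        ellipse,
        ann.side,
        config,
        film_id=ann.film_id,
        apparent_retroversion=ann.apparent_retroversion,
        fit_residual_rms=residual,
        pixel_spacing=pixel_spacing,
        provenance=make_provenance(config),
    )


def read_image(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a DICOM or PNG image; return (pixel array, pixel spacing mm/px).

    DICOM PixelSpacing is honoured when present (mean of row/col spacing,
    with a warning if anisotropic); PNG and spacing-less DICOM fall back to
    1.0 px units with a logged warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array
        spacing_attr = getattr(ds, "PixelSpacing", None)
        if spacing_attr is None:
            logger.warning("%s: no PixelSpacing; using unit pixels", path.name)
            return pixels, 1.0
        row, col = float(spacing_attr[0]), float(spacing_attr[1])
        if abs(row - col) > 1e-9:
            logger.warning("%s: anisotropic PixelSpacing %s; using mean", path.name,
                           list(spacing_attr))
        return pixels, (row + col) / 2.0
    if suffix == ".png":
        from PIL import Image

        with Image.open(path) as img:
            pixels = np.asarray(img)
        logger.warning("%s: PNG carries no pixel spacing; using unit pixels", path.name)
        return pixels, 1.0
    raise ValueError(f"unsupported image format: {path.name!r} (expected DICOM or PNG)")


def load_config(path: str | Path) -> StandardizationConfig:
    """Load a standardization config from JSON or TOML."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    known = {"ssd", "neutral_v", "tilt_branch", "units"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StandardizationConfig(**raw)


def make_provenance(config: StandardizationConfig) -> str:
    """Version + config-hash string stamped into every record."""
    payload = json.dumps(
        {"ssd": config.ssd, "neutral_v": config.neutral_v,
         "tilt_branch": config.tilt_branch, "units": config.units},
        sort_keys=True,
    )
    digest = hashlib.sha256(payload.encode()).hexdigest()[:12]
    return f"cupversion-{__version__} config:{digest}"


def records_to_dataframe(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Flatten measurement records into a tidy DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "film_id": r.film_id,
                "side": r.side,
                "radiographic_anteversion_deg": r.radiographic_anteversion,
                "inclination_deg": r.inclination,
                "standardized_anteversion_deg": r.standardized_anteversion,
                "h": r.h,
                "v": r.v,
                "ssd": r.ssd,
                "theta_deg": r.pose.theta,
                "phi_deg": r.pose.phi,
                "ellipse_cx": r.ellipse.center[0],
                "ellipse_cy": r.ellipse.center[1],
                "ellipse_a": r.ellipse.a,
                "ellipse_b": r.ellipse.b,
                "ellipse_orientation_deg": r.ellipse.orientation_deg,
                "fit_residual_rms": r.fit_residual_rms,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows)


def write_records(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write records to CSV with 6-decimal floats (byte-reproducible)."""
    records_to_dataframe(records).to_csv(path, index=False, float_format="%.6f")
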