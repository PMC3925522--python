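"""Landmark container and JSON I/O.

The landmark file carries the anatomical curves and points the pipeline
needs beyond the meshes: the pelvic brim polyline, the obturator foramen rim
polyline, the obturator canal point, the foramen top point, the incision
endpoints, and (optionally) a polygon delimiting the analyzed quadrilateral
region. Coordinates are mm, matching the meshes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputContractError

_REQUIRED = ("brim", "foramen_rim", "obturator_canal", "foramen_top", "incision")


@dataclass
class LandmarkSet:
    brim: np.ndarray                 # (N, 3) ordered polyline
    foramen_rim: np.ndarray          # (M, 3) ordered closed polyline
    obturator_canal: np.ndarray      # (3,)
    foramen_top: np.ndarray          # (3,)
    incision_proximal: np.ndarray    # (3,)
    incision_distal: np.ndarray      # (3,)
    region_polygon: np.ndarray | None = None  # (K, 3) closed polyline
    side: str = "left"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "side": self.side,
            "brim": self.brim.tolist(),
            "foramen_rim": self.foramen_rim.tolist(),
            "obturator_canal": self.obturator_canal.tolist(),
            "foramen_top": self.foramen_top.tolist(),
            "incision": {
                "proximal": self.incision_proximal.tolist(),
                "distal": self.incision_distal.tolist(),
            },
        }
        if self.region_polygon is not None:
            d["region_polygon"] = self.region_polygon.tolist()
        if self.meta:
            d["meta"] = self.meta
        return d

    def mirrored_x(self) -> "LandmarkSet":
        """Reflect across the x = 0 (sagittal) plane; flips side label."""

        def m(a: np.ndarray) -> np.ndarray:
            out = np.array(a, dtype=float, copy=True)
            out[..., 0] *= -1
            return out

        return LandmarkSet(
            brim=m(self.brim),
            foramen_rim=m(self.foramen_rim),
            obturator_canal=m(self.obturator_canal),
            foramen_top=m(self.foramen_top),
            incision_proximal=m(self.incision_proximal),
            incision_distal=m(self.incision_distal),
            region_polygon=None if self.region_polygon is None else m(self.region_polygon),
            side="right" if self.side == "left" else "left",
            meta=dict(self.meta),
        )


def save_landmarks(lm: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(lm.to_dict(), indent=1))
    return path


def load_landmarks(path: str | Path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise InputContractError(f"landmark file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputContractError(f"landmark file {path} is not valid JSON: {exc}") from exc
    for key in _REQUIRED:
        if key not in raw:
            raise InputContractError(f"landmark file {path} missing required key {key!r}")
    for key in ("proximal", "distal"):
        if key not in raw["incision"]:
            raise InputContractError(f"landmark file {path} missing incision.{key}")

    def arr(x, shape_hint):
        a = np.asarray(x, dtype=float)
        if a.ndim == 1:
            a = a.reshape(shape_hint)
        if not np.isfinite(a).all():
            raise InputContractError(f"non-finite coordinates in landmark file {path}")
        return a

    return LandmarkSet(
        brim=arr(raw["brim"], (-1, 3)),
        foramen_rim=arr(raw["foramen_rim"], (-1, 3)),
        obturator_canal=arr(raw["obturator_canal"], (3,)),
        foramen_top=arr(raw["foramen_top"], (3,)),
        incision_proximal=arr(raw["incision"]["proximal"], (3,)),
        incision_distal=arr(raw["incision"]["distal"], (3,)),
        region_polygon=arr(raw["region_polygon"], (-1, 3)) if "region_polygon" in raw else None,
        side=raw.get("side", "left"),
        meta=raw.get("meta", {}),
    )
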