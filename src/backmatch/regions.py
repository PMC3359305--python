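"""Labelled regions of interest (ROIs).

Region classes follow the field protocol for background-matching studies:
``octopus_mantle`` (the reference patch on the animal), ``distinct_object``
(a conspicuous structure — coral head, rock, algal patch), ``general_substrate``
(the surrounding bottom at large) and optionally ``hidden_zone`` (scene area
the animal itself cannot see, excluded from similarity scoring).

A region is a rectangle, a simple polygon (rasterised with
``skimage.draw.polygon2mask``) or an explicit boolean mask.  RegionSets
round-trip through a small JSON format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError

VALID_LABELS = ("octopus_mantle", "distinct_object", "general_substrate", "hidden_zone")


@dataclass
class Region:
    label: str
    rect: tuple[int, int, int, int] | None = None  # (row, col, height, width)
    polygon: np.ndarray | None = None  # (N, 2) array of (row, col) vertices
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.label not in VALID_LABELS:
            raise ConfigError("label", f"{self.label!r} not one of {VALID_LABELS}")
        n_geom = sum(g is not None for g in (self.rect, self.polygon, self.mask))
        if n_geom != 1:
            raise ConfigError(self.label, "exactly one of rect/polygon/mask required")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
                raise ConfigError(self.label, "polygon must be an (N>=3, 2) vertex array")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ConfigError(self.label, "mask shape does not match image")
            return self.mask.astype(bool)
        if self.rect is not None:
            r, c, h, w = self.rect
            m = np.zeros(shape, dtype=bool)
            m[max(r, 0) : r + h, max(c, 0) : c + w] = True
            return m
        from skimage.draw import polygon2mask

        return polygon2mask(shape, self.polygon)


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)
    image_ref: str | None = None

    def labelled(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def mask(self, label: str, shape: tuple[int, int]) -> np.ndarray:
        """Union mask of all regions carrying ``label``."""
        out = np.zeros(shape, dtype=bool)
        for reg in self.labelled(label):
            out |= reg.to_mask(shape)
        return out

    def require(self, labels: Sequence[str]) -> None:
        for lab in labels:
            if not self.labelled(lab):
                raise ConfigError("regions", f"no region labelled {lab!r}")

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {"image_ref": self.image_ref, "regions": []}
        for reg in self.regions:
            if reg.rect is not None:
                geom = {"type": "rect", "rect": list(reg.rect)}
            elif reg.polygon is not None:
                geom = {"type": "polygon", "vertices": reg.polygon.tolist()}
            else:
                geom = {"type": "mask", "true_pixels": np.argwhere(reg.mask).tolist(),
                        "shape": list(reg.mask.shape)}
            payload["regions"].append({"label": reg.label, **geom})
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RegionSet":
        with open(path) as fh:
            payload = json.load(fh)
        regions = []
        for item in payload["regions"]:
            kind = item["type"]
            if kind == "rect":
                regions.append(Region(item["label"], rect=tuple(item["rect"])))
            elif kind == "polygon":
                regions.append(Region(item["label"], polygon=np.asarray(item["vertices"])))
            elif kind == "mask":
                m = np.zeros(tuple(item["shape"]), dtype=bool)
                idx = np.asarray(item["true_pixels"], dtype=int)
                if len(idx):
                    m[idx[:, 0], idx[:, 1]] = True
                regions.append(Region(item["label"], mask=m))
            else:
                raise ConfigError("regions", f"unknown geometry type {kind!r}")
        return cls(regions=regions, image_ref=payload.get("image_ref"))
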