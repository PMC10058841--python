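"""Spatial-spectral point clouds and the four tree-component classes.

A point cloud couples per-point XYZ coordinates (metres) with a per-point
spectrum on the fixed 101-channel grid.  Spectra are either raw echo peak
intensities (arbitrary linear units, awaiting white-reference calibration)
or reflectances.  Ground-truth or predicted component labels ride along as
an optional integer-coded column.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "ComponentLabel",
    "SpectralPointCloud",
    "ColorMap",
    "DEFAULT_COLORMAP",
    "LABEL_NAMES",
]


class ComponentLabel(enum.IntEnum):
    """The four tree organs, coded 1..4 in fixed evaluation order."""

    UNRIPE_FRUIT = 1
    RIPE_FRUIT = 2
    WOOD = 3
    LEAF = 4

    @property
    def display_name(self) -> str:
        return LABEL_NAMES[self]

    @classmethod
    def from_name(cls, name: str) -> "ComponentLabel":
        try:
            return _NAME_TO_LABEL[name.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown component label {name!r}") from None


LABEL_NAMES: Mapping[ComponentLabel, str] = {
    ComponentLabel.UNRIPE_FRUIT: "UnripeFruit",
    ComponentLabel.RIPE_FRUIT: "RipeFruit",
    ComponentLabel.WOOD: "Wood",
    ComponentLabel.LEAF: "Leaf",
}

_NAME_TO_LABEL = {name.lower(): lab for lab, name in LABEL_NAMES.items()}
# tolerate snake/space variants on read
_NAME_TO_LABEL.update(
    {
        "unripe_fruit": ComponentLabel.UNRIPE_FRUIT,
        "unripe fruit": ComponentLabel.UNRIPE_FRUIT,
        "ripe_fruit": ComponentLabel.RIPE_FRUIT,
        "ripe fruit": ComponentLabel.RIPE_FRUIT,
    }
)

ALL_LABELS = tuple(ComponentLabel)


@dataclass
class ColorMap:
    """Mapping from component label to an RGB triple in 0..255."""

    mapping: Mapping[ComponentLabel, tuple[int, int, int]]

    def __post_init__(self) -> None:
        missing = [lab for lab in ComponentLabel if lab not in self.mapping]
        if missing:
            raise ValueError(f"colormap missing labels: {missing}")
        colors = [tuple(self.mapping[lab]) for lab in ComponentLabel]
        if len(set(colors)) != len(colors):
            raise ValueError("colormap colors must be pairwise distinct")
        for c in colors:
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ValueError(f"invalid RGB triple {c}")

    def __getitem__(self, label: ComponentLabel) -> tuple[int, int, int]:
        return tuple(self.mapping[ComponentLabel(label)])

    def as_array(self, labels: np.ndarray) -> np.ndarray:
        """Per-point uint8 RGB array, shape (n, 3)."""
        lut = np.zeros((max(ComponentLabel) + 1, 3), dtype=np.uint8)
        for lab in ComponentLabel:
            lut[lab] = self.mapping[lab]
        return lut[np.asarray(labels, dtype=int)]


#: Green leaves, brown wood, orange ripe fruit, yellow-green unripe fruit.
DEFAULT_COLORMAP = ColorMap(
    {
        ComponentLabel.UNRIPE_FRUIT: (154, 205, 50),
        ComponentLabel.RIPE_FRUIT: (255, 140, 0),
        ComponentLabel.WOOD: (139, 69, 19),
        ComponentLabel.LEAF: (34, 139, 34),
    }
)


@dataclass
class SpectralPointCloud:
    """Point cloud with one spectrum per point on a fixed wavelength grid.

    Attributes
    ----------
    coords : ndarray, shape (n, 3)
        XYZ in metres.  By convention y is the range axis away from the
        scanner (used by background segmentation); this is a convention,
        not an enforced constraint.
    spectra : ndarray, shape (n, n_channels)
        Echo peak intensities or reflectances, one row per point.
    spectra_kind : {"intensity", "reflectance"}
    labels : ndarray of int or None
        Optional per-point component labels (codes 1..4).
    grid : WavelengthGrid
    """

    coords: np.ndarray
    spectra: np.ndarray
    spectra_kind: str = "reflectance"
    labels: np.ndarray | None = None
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.spectra.size == 0:
            self.spectra = self.spectra.reshape(0, self.grid.n_channels)
        if self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.spectra.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"coords ({self.coords.shape[0]}) and spectra "
                f"({self.spectra.shape[0]}) point counts differ"
            )
        if self.spectra.shape[1] != self.grid.n_channels:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} channels, grid expects "
                f"{self.grid.n_channels}"
            )
        if self.spectra_kind not in ("intensity", "reflectance"):
            raise ValueError(f"unknown spectra_kind {self.spectra_kind!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.coords.shape[0],):
                raise ValueError("labels length must equal point count")
        if self.spectra_kind == "reflectance" and self.spectra.size:
            if not np.all(np.isfinite(self.spectra)):
                raise ValueError("reflectance spectra must be finite")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def subset(self, index: np.ndarray) -> "SpectralPointCloud":
        """New cloud containing the selected points (mask or index array)."""
        labels = None if self.labels is None else self.labels[index]
        return replace(
            self,
            coords=self.coords[index].reshape(-1, 3),
            spectra=self.spectra[index].reshape(-1, self.grid.n_channels),
            labels=labels,
        )

    def with_labels(self, labels: np.ndarray) -> "SpectralPointCloud":
        return replace(self, labels=np.asarray(labels, dtype=np.int64))
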