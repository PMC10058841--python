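"""Per-point spectral feature extraction.

Nine features drive the component classifiers: five single-band
reflectances chosen for between-class contrast (700, 730, 780, 850,
900 nm), the mean reflectance over the 760-930 nm near-infrared window
(35 channels, both ends inclusive), and three chlorophyll-sensitive
vegetation indices:

    CI_red_edge = R780 / R710 - 1
    NDVI        = (R800 - R670) / (R800 + R670)
    NDRE        = (R790 - R720) / (R790 + R720)

Indices are ratios, hence invariant to overall spectrum scale (and so to
laser incidence-angle brightness changes); band features scale linearly.
A zero denominator produces a missing value (NaN), never a clipped one;
classifiers reject rows containing missing features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import SpectralPointCloud
from .grid import WavelengthGrid

__all__ = ["FEATURE_NAMES", "FeatureTable", "band_reflectance", "extract_features"]

#: Fixed feature order; trained models are only portable across tables
#: sharing this exact naming and order.
FEATURE_NAMES: tuple[str, ...] = (
    "R700",
    "R730",
    "R780",
    "R850",
    "R900",
    "AVG_R760_R930",
    "CI_red_edge",
    "NDVI",
    "NDRE",
)


@dataclass
class FeatureTable:
    """Per-point feature matrix with a fixed, versioned column order."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.names))
        if self.values.shape[1] != len(self.names):
            raise ValueError(
                f"feature table width {self.values.shape[1]} != "
                f"{len(self.names)} names"
            )

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def missing_rows(self) -> np.ndarray:
        """Indices of rows containing any non-finite feature value."""
        return np.flatnonzero(~np.isfinite(self.values).all(axis=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def band_reflectance(
    spectrum: np.ndarray, wavelength_nm: float, grid: WavelengthGrid
) -> float | np.ndarray:
    """Reflectance at an exact grid wavelength (no interpolation).

    Accepts a single spectrum or a (n, n_channels) stack; off-grid
    wavelengths raise ``KeyError``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    return spectrum[..., grid.index(wavelength_nm)]


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def extract_features(cloud: SpectralPointCloud) -> FeatureTable:
    """Compute the nine classification features for every point."""
    if cloud.spectra_kind != "reflectance":
        raise ValueError("feature extraction requires reflectance spectra; "
                         "calibrate first")
    s, g = cloud.spectra, cloud.grid
    band = lambda wl: s[:, g.index(wl)]

    avg = s[:, g.slice(760, 930)].mean(axis=1) if len(cloud) else np.empty(0)
    ci = _safe_ratio(band(780), band(710)) - 1.0
    ndvi = _safe_ratio(band(800) - band(670), band(800) + band(670))
    ndre = _safe_ratio(band(790) - band(720), band(790) + band(720))

    values = np.column_stack(
        [band(700), band(730), band(780), band(850), band(900), avg, ci, ndvi, ndre]
    ) if len(cloud) else np.empty((0, 9))
    return FeatureTable(values)
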