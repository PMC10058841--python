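"""White-reference reflectance calibration and background segmentation.

Echo peak intensities are converted to reflectance against a scan of a
diffuse reference panel of known reflectivity (a ~99% Spectralon-type
whiteboard placed at the sample distance):

    rho_t(lambda_i) = V_t(lambda_i) / V_b(lambda_i) * rho_b(lambda_i)

per channel, where V_t and V_b are the sample and panel echo peak values
in the same (arbitrary linear) units, which the ratio cancels.

Background removal exploits scan geometry: the sample hangs a fixed
distance in front of a backdrop, so a single coordinate threshold on the
range axis separates the two.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import SpectralPointCloud
from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = ["ReferencePanel", "calibrate_reflectance", "segment_background",
           "CalibrationError"]


class CalibrationError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """White-reference scan: per-channel peak voltages and panel reflectivity.

    Parameters
    ----------
    peak_voltages : ndarray, shape (n_channels,)
        Panel echo peak values V_b per channel; must be strictly positive.
    reflectance : float or ndarray, default 0.99
        Panel reflectivity rho_b, scalar or per channel, in (0, 1].
    """

    peak_voltages: np.ndarray
    reflectance: float | np.ndarray = 0.99
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        self.peak_voltages = np.asarray(self.peak_voltages, dtype=float)
        if self.peak_voltages.shape != (self.grid.n_channels,):
            raise ValueError(
                f"panel needs {self.grid.n_channels} peak voltages, "
                f"got shape {self.peak_voltages.shape}"
            )
        nonpos = np.flatnonzero(~(self.peak_voltages > 0))
        if nonpos.size:
            wl = self.grid.wavelengths[nonpos[0]]
            raise CalibrationError(
                f"panel peak voltage is not positive at {wl:g} nm"
            )
        rho = np.asarray(self.reflectance, dtype=float)
        if rho.ndim == 0:
            rho = np.full(self.grid.n_channels, float(rho))
        if rho.shape != (self.grid.n_channels,):
            raise ValueError("panel reflectance must be scalar or per-channel")
        if np.any((rho <= 0) | (rho > 1)):
            raise ValueError("panel reflectance must lie in (0, 1]")
        self.reflectance = rho

    @classmethod
    def from_csv(
        cls,
        voltages_path: str | Path,
        reflectance_path: str | Path | None = None,
        reflectance: float = 0.99,
        grid: WavelengthGrid = DEFAULT_GRID,
    ) -> "ReferencePanel":
        """Load a panel from 2-column (wavelength_nm, value) CSV files.

        Wavelengths must match the grid exactly; no interpolation is done.
        """
        vb = _read_channel_csv(voltages_path, grid)
        rho: float | np.ndarray = reflectance
        if reflectance_path is not None:
            rho = _read_channel_csv(reflectance_path, grid)
        return cls(peak_voltages=vb, reflectance=rho, grid=grid)


def _read_channel_csv(path: str | Path, grid: WavelengthGrid) -> np.ndarray:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (wavelength_nm, value)")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    out = np.full(grid.n_channels, np.nan)
    for w, v in zip(wl, val):
        out[grid.index(w)] = v  # KeyError for off-grid wavelengths
    missing = np.flatnonzero(np.isnan(out))
    if missing.size:
        raise ValueError(
            f"{path}: no value for {grid.wavelengths[missing[0]]:g} nm"
        )
    return out


def calibrate_reflectance(
    cloud: SpectralPointCloud,
    panel: ReferencePanel,
    clamp_negative: bool = False,
) -> SpectralPointCloud:
    """Convert echo intensities to reflectance against the reference panel.

    Coordinates and labels pass through untouched.  Negative or zero sample
    intensities (noise) yield non-positive reflectances; ``clamp_negative``
    floors them at zero (off by default to keep the ratio faithful).
    """
    if cloud.spectra_kind != "intensity":
        raise ValueError("cloud already holds reflectance spectra")
    if cloud.grid != panel.grid:
        raise ValueError("cloud and panel wavelength grids differ")
    rho = cloud.spectra / panel.peak_voltages * panel.reflectance
    if clamp_negative:
        rho = np.maximum(rho, 0.0)
    return replace(cloud, spectra=rho, spectra_kind="reflectance")


def segment_background(
    cloud: SpectralPointCloud,
    axis: str = "y",
    cut: float = 0.0,
    keep: str = "near",
) -> SpectralPointCloud:
    """Keep points on one side of a coordinate threshold on the range axis.

    ``keep="near"`` retains points with coordinate < ``cut`` (the sample in
    front of the backdrop); ``keep="far"`` retains coordinate >= ``cut``.
    The two choices partition the cloud exactly.
    """
    try:
        ax = {"x": 0, "y": 1, "z": 2}[axis]
    except KeyError:
        raise ValueError(f"axis must be x, y or z, got {axis!r}") from None
    if not np.isfinite(cut):
        raise ValueError("cut must be finite")
    if keep not in ("near", "far"):
        raise ValueError(f"keep must be 'near' or 'far', got {keep!r}")
    coord = cloud.coords[:, ax]
    mask = coord < cut if keep == "near" else coord >= cut
    return cloud.subset(mask)
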