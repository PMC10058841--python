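"""Fixed wavelength grid of the hyperspectral scanner.

The instrument records one echo spectrum per point on a fixed axis of 101
channels from 550 nm to 1050 nm in 5 nm steps.  All spectra in this package
live on this grid; band lookups are exact-match (no interpolation), so an
off-grid wavelength is an error, never a silent round.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavelengthGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis with an exact wavelength -> channel mapping.

    Parameters
    ----------
    start_nm, stop_nm : float
        First and last channel wavelengths, inclusive.
    step_nm : float
        Channel spacing.
    """

    start_nm: float = 550.0
    stop_nm: float = 1050.0
    step_nm: float = 5.0

    def __post_init__(self) -> None:
        span = self.stop_nm - self.start_nm
        if self.step_nm <= 0 or span <= 0:
            raise ValueError("grid must have positive extent and step")
        n, rem = divmod(span, self.step_nm)
        if rem != 0:
            raise ValueError(
                f"grid span {span} nm is not a multiple of step {self.step_nm} nm"
            )

    @property
    def n_channels(self) -> int:
        return int((self.stop_nm - self.start_nm) / self.step_nm) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """All channel wavelengths in ascending order, shape (n_channels,)."""
        return self.start_nm + self.step_nm * np.arange(self.n_channels)

    def index(self, wavelength_nm: float) -> int:
        """Channel index of an on-grid wavelength.

        Raises
        ------
        KeyError
            If the wavelength does not lie exactly on the grid.
        """
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if pos != idx or not 0 <= idx < self.n_channels:
            raise KeyError(
                f"wavelength {wavelength_nm} nm is not on the "
                f"{self.start_nm}-{self.stop_nm}/{self.step_nm} nm grid"
            )
        return idx

    def slice(self, lo_nm: float, hi_nm: float) -> slice:
        """Channel slice covering [lo_nm, hi_nm] inclusive of both ends."""
        return slice(self.index(lo_nm), self.index(hi_nm) + 1)


#: The scanner's native 101-channel grid.
DEFAULT_GRID = WavelengthGrid(550.0, 1050.0, 5.0)
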