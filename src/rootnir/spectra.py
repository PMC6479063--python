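"""Core in-memory container for absorbance spectra on a shared wavelength grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpectraMatrix:
    """Samples x bands absorbance matrix on a common, strictly increasing grid.

    Parameters
    ----------
    ids : list of str
        One identifier per sample (row).
    wavelengths : ndarray of shape (n_bands,)
        Strictly increasing wavelengths in nm.
    values : ndarray of shape (n_samples, n_bands)
        Absorbance values; must be finite.
    meta : dict
        Free-form provenance (e.g. the pre-processing applied).
    """

    ids: list
    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.ids = list(self.ids)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 3:
            raise ValueError("wavelength grid must be 1-D with at least 3 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError(
                "wavelength grid must be strictly increasing "
                "(sort the bands and remove duplicated wavelengths)"
            )
        if self.values.shape != (len(self.ids), self.wavelengths.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} samples x {self.wavelengths.size} bands"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorbance matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            list(self.ids), self.wavelengths.copy(), self.values.copy(), dict(self.meta)
        )

    def subset(self, indices) -> "SpectraMatrix":
        """Row subset (new object; grid shared by copy)."""
        indices = np.asarray(indices, dtype=int)
        return SpectraMatrix(
            [self.ids[i] for i in indices],
            self.wavelengths.copy(),
            self.values[indices],
            dict(self.meta),
        )


def default_grid(n_points: int = 662,
                 wn_start: float = 12489.0,
                 wn_end: float = 3594.0) -> np.ndarray:
    """FT-NIR wavelength grid in nm, uniform in wavenumber.

    The instrument records 662 bands from 12489 to 3594 cm^-1 (about 800 to
    2782 nm).  Points are spaced uniformly in wavenumber and reported as
    wavelengths lambda = 1e7 / nu, returned in increasing nm order.
    """
    wavenumbers = np.linspace(wn_start, wn_end, n_points)
    return 1e7 / wavenumbers


def nm_to_wavenumber(nm: np.ndarray) -> np.ndarray:
    return 1e7 / np.asarray(nm, dtype=float)
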