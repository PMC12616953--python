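"""Wavelength-indexed optical curves and resampling.

A :class:`SpectrumTable` holds one nonnegative curve -- a fluorophore
absorption or emission spectrum, a filter transmissivity, or a light-source
power spectrum -- tabulated on a strictly increasing wavelength grid in
nanometres.  Outside its tabulated support a spectrum is zero.  Absolute
units cancel in every downstream ratio, so curves are accepted in arbitrary
units and never renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectrumTable", "common_grid", "resample_to_grid"]


class SpectrumError(ValueError):
    """Raised for invalid or degenerate spectra."""


@dataclass(frozen=True)
class SpectrumTable:
    """One optical curve: value(wavelength), zero outside the tabulated range."""

    wavelength_nm: np.ndarray
    value: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelength_nm, dtype=float))
        val = np.atleast_1d(np.asarray(self.value, dtype=float))
        if wl.size == 0 or val.size == 0:
            raise SpectrumError(f"empty spectrum {self.name!r}")
        if wl.shape != val.shape or wl.ndim != 1:
            raise SpectrumError(
                f"spectrum {self.name!r}: wavelength and value must be equal-length 1-D arrays"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise SpectrumError(f"spectrum {self.name!r}: wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(val)):
            raise SpectrumError(f"spectrum {self.name!r}: non-finite entries")
        if np.any(val < 0):
            raise SpectrumError(f"spectrum {self.name!r}: values must be nonnegative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation inside the support, zero outside.

        The support test carries a small absolute tolerance so that grid
        points sitting exactly on a boundary (up to float round-off from
        accumulated grid construction) take the tabulated edge value rather
        than flickering to zero.
        """
        grid = np.asarray(grid, dtype=float)
        # clamp to the edge values first, then zero outside the support with a
        # small tolerance band, so boundary points keep their tabulated value
        out = np.interp(grid, self.wavelength_nm, self.value)
        lo, hi = self.support
        tol = 1e-6
        out = np.where((grid < lo - tol) | (grid > hi + tol), 0.0, out)
        return out

    def on_grid(self, grid: np.ndarray) -> "SpectrumTable":
        return SpectrumTable(np.asarray(grid, dtype=float), self.interp(grid), self.name)

    def scaled(self, factor: float) -> "SpectrumTable":
        if factor < 0:
            raise SpectrumError("scale factor must be nonnegative")
        return SpectrumTable(self.wavelength_nm, self.value * float(factor), self.name)

    def __mul__(self, other: "SpectrumTable | float") -> "SpectrumTable":
        if isinstance(other, SpectrumTable):
            if self.wavelength_nm.shape != other.wavelength_nm.shape or not np.array_equal(
                self.wavelength_nm, other.wavelength_nm
            ):
                raise SpectrumError(
                    "pointwise product requires identical grids; resample first"
                )
            name = f"{self.name}*{other.name}" if self.name and other.name else ""
            return SpectrumTable(self.wavelength_nm, self.value * other.value, name)
        return self.scaled(float(other))

    __rmul__ = __mul__

    def integral(self) -> float:
        """Trapezoidal integral over the tabulated grid."""
        if self.wavelength_nm.size < 2:
            return 0.0
        return float(np.trapezoid(self.value, self.wavelength_nm))


def common_grid(spectra: list[SpectrumTable] | tuple[SpectrumTable, ...], step_nm: float) -> np.ndarray:
    """Strictly increasing grid with spacing ``step_nm`` covering the union of supports."""
    if step_nm <= 0:
        raise SpectrumError("step_nm must be positive")
    if not spectra:
        raise SpectrumError("no spectra given")
    lo = min(s.support[0] for s in spectra)
    hi = max(s.support[1] for s in spectra)
    # end at the smallest lo + k*step that reaches hi (allow for float round-off)
    n = max(1, int(np.ceil((hi - lo) / step_nm - 1e-9)))
    return lo + step_nm * np.arange(n + 1)


def resample_to_grid(
    spectra: list[SpectrumTable] | tuple[SpectrumTable, ...], step_nm: float
) -> list[SpectrumTable]:
    """Resample all spectra onto one shared grid spanning the union of supports."""
    grid = common_grid(spectra, step_nm)
    return [s.on_grid(grid) for s in spectra]
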