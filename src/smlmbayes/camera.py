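"""Camera calibration, optical constants and photoelectron conversion.

Raw camera frames arrive as integer ADU (analog-to-digital units).  Every
downstream stage of the pipeline works in photoelectrons, obtained by the
affine camera model

    n(i, j) = (I(i, j) - offset) / gain

where ``offset`` is the camera bias in ADU and ``gain`` the effective
electronic gain in ADU per photoelectron (for an EMCCD this folds in the
electron-multiplication register).

The optics determine two pixel-domain scales used everywhere else:

* the Airy-disk radius ``R_airy = 0.61 λ M / (NA μ)`` (first diffraction
  minimum, in camera pixels), which sets the local-maximum neighborhood and,
  through ``h_f = ceil(R_airy)``, the fitting-window half-size;
* the theoretical Gaussian PSF width ``s0 = 0.21 λ M / (NA μ)`` (pixels),
  the fixed standard deviation of the Gaussian PSF model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraOptics",
    "OpticsDerived",
    "PhotoelectronFrame",
    "to_photoelectrons",
    "derive_optics",
]


class ConfigurationError(ValueError):
    """Raised for physically inconsistent camera/optics parameters."""


class InvalidInputError(ValueError):
    """Raised for non-finite or malformed input data."""


@dataclass(frozen=True)
class CameraOptics:
    """Camera calibration and optical constants of the experiment.

    Parameters
    ----------
    offset : float
        ADU bias offset subtracted before gain division.
    gain : float
        Effective electronic gain, ADU per photoelectron. Must be > 0.
    pixel_size_nm : float
        Physical camera pixel size ``μ`` in nm.
    magnification : float
        Total optical magnification ``M``.
    na : float
        Numerical aperture of the objective.
    wavelength_nm : float
        Emission-maximum wavelength ``λ`` in nm.
    """

    offset: float
    gain: float
    pixel_size_nm: float
    magnification: float
    na: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigurationError("gain must be > 0 ADU per photoelectron")
        for name in ("pixel_size_nm", "magnification", "na", "wavelength_nm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def pixel_size_sample_nm(self) -> float:
        """Effective sample-plane pixel size ``p_eff = μ / M`` in nm."""
        return self.pixel_size_nm / self.magnification


@dataclass(frozen=True)
class OpticsDerived:
    """Pixel-domain quantities derived from :class:`CameraOptics`."""

    r_airy_px: float
    h_f: int
    s0_px: float


@dataclass(frozen=True)
class PhotoelectronFrame:
    """One camera frame converted to photoelectron counts.

    Values are real and may be negative (noise below the bias offset is
    preserved so background estimates stay unbiased).
    """

    values: np.ndarray
    frame_index: int = 0


def to_photoelectrons(frame: np.ndarray, cam: CameraOptics, frame_index: int = 0) -> PhotoelectronFrame:
    """Convert a raw ADU frame to photoelectron counts.

    Applies ``n = (I - offset) / gain`` pixelwise; negative results are kept.
    """
    arr = np.asarray(frame, dtype=np.float64)
    if arr.size == 0:
        raise InvalidInputError("empty frame")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("frame contains non-finite pixel values")
    return PhotoelectronFrame(values=(arr - cam.offset) / cam.gain, frame_index=frame_index)


def derive_optics(cam: CameraOptics) -> OpticsDerived:
    """Derive the Airy radius, fit half-window and PSF width in pixels.

    Raises
    ------
    ConfigurationError
        If the Airy radius comes out below one camera pixel (undersampled
        PSF: the detection neighborhood and fit window would be degenerate).
    """
    p_eff = cam.pixel_size_sample_nm
    r_airy = 0.61 * cam.wavelength_nm / (cam.na * p_eff)
    s0 = 0.21 * cam.wavelength_nm / (cam.na * p_eff)
    if r_airy < 1.0:
        raise ConfigurationError(
            f"Airy radius {r_airy:.3f} px < 1 px: PSF undersampled at this pixel size"
        )
    return OpticsDerived(r_airy_px=r_airy, h_f=int(math.ceil(r_airy)), s0_px=s0)
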