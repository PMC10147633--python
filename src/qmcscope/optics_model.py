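"""Classical and biphoton image formation.

A biphoton pair traversing balanced, symmetric signal/idler paths behaves,
for image formation, like a single photon at half the SPDC wavelength.  The
coincidence image therefore obeys the same incoherent imaging law as the
classical wide-field image, but with the intensity point-spread function
evaluated at lambda/2 and with the illumination envelope replaced by the
squared field-intensity distribution:

    classical:  G1(rho) = [ |t(rho)|^2 * gamma_CI(rho) ]  (x)  |h(lambda)|^2
    QMC:        G2(rho) = [ |t(rho)|^2 * Gamma_QMC(rho) ]  (x)  |h(lambda/2)|^2

where t is the amplitude transmission of the object, (x) denotes 2-D
incoherent convolution on the object plane, and |h|^2 is the (normalized)
intensity PSF of the shared pupil.  Halving the wavelength halves every
lateral length scale of the PSF, which is the factor-2 (Heisenberg-limit)
resolution gain this package quantifies.

Units: lengths in micrometres on the object plane unless a name says
otherwise (wavelengths carry an explicit ``_nm`` suffix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import fftconvolve
from scipy.special import j1

__all__ = [
    "OpticalConfig",
    "ObjectMap",
    "IlluminationEnvelope",
    "SamplingError",
    "intensity_psf",
    "classical_image",
    "qmc_image",
    "airy_fwhm_um",
]

#: FWHM of the Airy *intensity* pattern in units of lambda/NA
#: (dense numeric scan of (2 J1(v)/v)^2; v_HWHM = 1.61633...).
AIRY_FWHM_COEFF = 0.514497


class SamplingError(ValueError):
    """Grid spacing too coarse to resolve the requested PSF."""


@dataclass
class OpticalConfig:
    """Parameters of the image-formation model.

    Parameters
    ----------
    lambda_signal_nm:
        SPDC signal/idler wavelength (532 nm for a 266 nm-pumped source).
    lambda_pump_nm:
        Pump wavelength (266 nm); informational — the QMC equivalent
        wavelength is defined as ``lambda_signal_nm / 2``.
    na_effective:
        Effective numerical aperture of the shared pupil.  May be well below
        the nominal objective NA when the pupil is underfilled; it is the
        free parameter calibrated against a measured classical resolution.
    magnification:
        Object-to-detector magnification M.  The model keeps images on the
        object-plane grid; M only rescales coordinates (no resampling here).
    pixel_pitch_um:
        Object-plane grid spacing in micrometres per pixel.
    defocus_z_um:
        Axial offset from the classical focal plane.
    defocus_zr_um:
        Rayleigh-type axial scale of the defocus model
        ``FWHM(z) = FWHM(0) * sqrt(1 + (z/z_R)^2)``; shared by both arms.
    psf_model:
        ``"airy"`` (circular pupil, default) or ``"gaussian"``
        (sigma = 0.21 lambda/NA, for closed-form checks).
    """

    lambda_signal_nm: float = 532.0
    lambda_pump_nm: float = 266.0
    na_effective: float = 0.25
    magnification: float = 40.0 / 3.0
    pixel_pitch_um: float = 0.1
    defocus_z_um: float = 0.0
    defocus_zr_um: float = 10.0
    psf_model: str = "airy"

    def __post_init__(self) -> None:
        if not (0.0 < self.na_effective <= 1.0):
            raise ValueError(f"na_effective must be in (0, 1], got {self.na_effective}")
        if self.lambda_signal_nm <= 0:
            raise ValueError("lambda_signal_nm must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.defocus_zr_um <= 0:
            raise ValueError("defocus_zr_um must be positive")
        if self.psf_model not in ("airy", "gaussian"):
            raise ValueError(f"unknown psf_model {self.psf_model!r}")

    @property
    def lambda_qmc_nm(self) -> float:
        """Equivalent biphoton wavelength: exactly half the signal wavelength."""
        return self.lambda_signal_nm / 2.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OpticalConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ObjectMap:
    """Amplitude transmission map t(rho) in [0, 1] on a uniform grid."""

    t: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 2:
            raise ValueError("ObjectMap.t must be 2-D")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("transmission map contains non-finite values")
        if self.t.min() < 0.0 or self.t.max() > 1.0:
            raise ValueError("transmission coefficients must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t.shape

    # ---- constructors -------------------------------------------------

    @classmethod
    def knife_edge(
        cls, shape: tuple[int, int], spacing_um: float, edge_col: int | None = None
    ) -> "ObjectMap":
        """Opaque left half / transparent right half, edge at ``edge_col``."""
        rows, cols = shape
        if edge_col is None:
            edge_col = cols // 2
        t = np.zeros((rows, cols))
        t[:, edge_col:] = 1.0
        return cls(t, spacing_um)

    @classmethod
    def two_points(
        cls, shape: tuple[int, int], spacing_um: float, separation_um: float
    ) -> "ObjectMap":
        """Two transparent points straddling the grid centre along columns."""
        rows, cols = shape
        t = np.zeros((rows, cols))
        half = separation_um / (2.0 * spacing_um)
        c0, c1 = int(round(cols / 2 - half)), int(round(cols / 2 + half))
        t[rows // 2, c0] = 1.0
        t[rows // 2, c1] = 1.0
        return cls(t, spacing_um)

    # ---- I/O ----------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Export as 16-bit TIFF (t scaled to the full uint16 range)."""
        import tifffile

        tifffile.imwrite(str(path), np.round(self.t * 65535).astype(np.uint16))

    @classmethod
    def from_tiff(cls, path: str | Path, spacing_um: float) -> "ObjectMap":
        import tifffile

        raw = tifffile.imread(str(path)).astype(float)
        return cls(raw / 65535.0, spacing_um)

    def to_fits(self, path: str | Path) -> None:
        from ._fits import write_image

        write_image(path, np.round(self.t * 65535).astype(np.uint16),
                    {"SPACING": self.spacing_um})

    @classmethod
    def from_fits(cls, path: str | Path, spacing_um: float | None = None) -> "ObjectMap":
        from ._fits import read_image

        data, header = read_image(path)
        if spacing_um is None:
            spacing_um = float(header.get("SPACING", 1.0))
        return cls(np.asarray(data, dtype=float) / 65535.0, spacing_um)


@dataclass
class IlluminationEnvelope:
    """Illumination envelopes on the object plane.

    ``gamma_ci`` is the classical wide-field intensity distribution;
    ``gamma_qmc`` is the squared-intensity distribution seen by coincidence
    imaging.  When built from a single field-intensity envelope the latter is
    the elementwise square of the former, which narrows a Gaussian envelope
    by sqrt(2).
    """

    gamma_ci: np.ndarray
    gamma_qmc: np.ndarray

    def __post_init__(self) -> None:
        self.gamma_ci = np.asarray(self.gamma_ci, dtype=float)
        self.gamma_qmc = np.asarray(self.gamma_qmc, dtype=float)
        if self.gamma_ci.shape != self.gamma_qmc.shape:
            raise ValueError("gamma_ci and gamma_qmc must share a grid")
        if np.any(self.gamma_ci < 0) or np.any(self.gamma_qmc < 0):
            raise ValueError("illumination envelopes must be non-negative")

    @classmethod
    def from_field_intensity(cls, envelope: np.ndarray) -> "IlluminationEnvelope":
        envelope = np.asarray(envelope, dtype=float)
        return cls(gamma_ci=envelope, gamma_qmc=envelope**2)

    @classmethod
    def uniform(cls, shape: tuple[int, int], value: float = 1.0) -> "IlluminationEnvelope":
        env = np.full(shape, float(value))
        return cls.from_field_intensity(env)


# ---------------------------------------------------------------------------
# PSF construction
# ---------------------------------------------------------------------------

def airy_fwhm_um(wavelength_nm: float, na: float) -> float:
    """FWHM of the Airy intensity pattern, ~0.514 lambda/NA, in micrometres."""
    return AIRY_FWHM_COEFF * (wavelength_nm * 1e-3) / na


def _defocus_scale(config: OpticalConfig) -> float:
    return float(np.sqrt(1.0 + (config.defocus_z_um / config.defocus_zr_um) ** 2))


def intensity_psf(
    config: OpticalConfig,
    wavelength_nm: float | None = None,
    *,
    spacing_um: float | None = None,
    radius_um: float | None = None,
) -> np.ndarray:
    """Incoherent intensity PSF |h|^2 on the object-plane grid, sum == 1.

    Parameters
    ----------
    wavelength_nm:
        Wavelength at which to evaluate the pupil; defaults to the signal
        wavelength.  Pass ``config.lambda_qmc_nm`` for the biphoton PSF.
    spacing_um:
        Grid spacing; defaults to ``config.pixel_pitch_um``.  Must satisfy
        ``spacing <= lambda / (4 NA)`` or a :class:`SamplingError` is raised.
    radius_um:
        Half-width of the (square, odd-sized) kernel.  Defaults to 12 PSF
        FWHMs, enough to capture the slowly decaying Airy rings.
    """
    if wavelength_nm is None:
        wavelength_nm = config.lambda_signal_nm
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    spacing = config.pixel_pitch_um if spacing_um is None else spacing_um
    wavelength_um = wavelength_nm * 1e-3
    nyquist = wavelength_um / (4.0 * config.na_effective)
    if spacing > nyquist:
        raise SamplingError(
            f"grid spacing {spacing:.4g} um exceeds lambda/(4 NA) = "
            f"{nyquist:.4g} um; the PSF would be aliased"
        )

    scale = _defocus_scale(config)
    fwhm0 = airy_fwhm_um(wavelength_nm, config.na_effective)
    if radius_um is None:
        radius_um = 12.0 * fwhm0 * scale
    half = max(int(np.ceil(radius_um / spacing)), 3)
    coords = np.arange(-half, half + 1) * spacing
    xx, yy = np.meshgrid(coords, coords)
    # defocus broadens laterally: evaluate the in-focus profile at r / scale
    r = np.hypot(xx, yy) / scale

    if config.psf_model == "gaussian":
        sigma = 0.21 * wavelength_um / config.na_effective
        psf = np.exp(-(r**2) / (2.0 * sigma**2))
    else:
        v = 2.0 * np.pi * config.na_effective * r / wavelength_um
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = np.where(v == 0.0, 1.0, 2.0 * j1(v) / np.where(v == 0.0, 1.0, v))
        psf = amp**2
    return psf / psf.sum()


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------

def _form_image(
    obj: ObjectMap,
    envelope: np.ndarray,
    config: OpticalConfig,
    wavelength_nm: float,
) -> np.ndarray:
    if envelope.shape != obj.shape:
        raise ValueError(
            f"object grid {obj.shape} and illumination grid {envelope.shape} differ"
        )
    base = (obj.t**2) * envelope
    psf = intensity_psf(config, wavelength_nm, spacing_um=obj.spacing_um)
    return fftconvolve(base, psf, mode="same")


def classical_image(
    obj: ObjectMap, illum: IlluminationEnvelope, config: OpticalConfig
) -> np.ndarray:
    """Expected classical wide-field intensity image on the object grid.

    ``|t|^2 * gamma_CI`` blurred by the intensity PSF at the signal
    wavelength; coordinates on the detector are the object coordinates times
    the magnification M (no resampling performed here).
    """
    return _form_image(obj, illum.gamma_ci, config, config.lambda_signal_nm)


def qmc_image(
    obj: ObjectMap, illum: IlluminationEnvelope, config: OpticalConfig
) -> np.ndarray:
    """Expected coincidence (QMC) image: same pipeline at lambda/2 with the
    squared-intensity envelope.  This is what the covariance estimator in
    :mod:`qmcscope.coincidence` recovers from frame stacks."""
    return _form_image(obj, illum.gamma_qmc, config, config.lambda_qmc_nm)
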