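"""Two-beam thin-film interference model for vitreous ice on EM grids.

A free-standing amorphous-ice film of thickness ``t`` illuminated at normal
incidence reflects from its two interfaces. With amplitude reflectances
``r1`` (above/film) and ``r2`` (film/below), the two-beam reflectance is

    R(t, lam) = r1**2 + r2**2 + 2*r1*r2*cos(4*pi*n_film*t/lam)

which is periodic in ``t`` with period ``lam / (2*n_film)``. For the
symmetric air/ice/air stack r1 = -r2, so R(0) = 0 and R peaks at the
quarter-wave thickness. Multiple internal reflections are neglected:
|r| ~ 0.13 for ice, so second-order terms are < 2% of the modulation.

The microscope illuminates through a triple-bandpass filter; each colour
channel is the reflectance band-averaged over the channel's passband.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthSet",
    "FilmStack",
    "fresnel_amplitude",
    "film_reflectance",
    "band_averaged_reflectance",
    "N_ICE",
]

#: Refractive index of low-density amorphous ice in the visible (default).
N_ICE = 1.31

# Gauss-Legendre 5-point nodes/weights on [-1, 1], used for band averaging.
_GL5_NODES, _GL5_WEIGHTS = np.polynomial.legendre.leggauss(5)


def fresnel_amplitude(n_incident: float, n_transmitted: float) -> float:
    """Normal-incidence Fresnel amplitude reflectance between two media.

    Parameters
    ----------
    n_incident, n_transmitted
        Refractive indices on either side of the interface; both must be
        finite and >= 1.

    Returns
    -------
    float
        ``(n_incident - n_transmitted) / (n_incident + n_transmitted)``,
        in (-1, 1). Negative when reflecting off a denser medium.
    """
    for name, n in (("n_incident", n_incident), ("n_transmitted", n_transmitted)):
        if not np.isfinite(n) or n < 1.0:
            raise ValueError(f"{name} must be finite and >= 1, got {n!r}")
    return (n_incident - n_transmitted) / (n_incident + n_transmitted)


@dataclass(frozen=True)
class WavelengthSet:
    """The three illumination bands of the triple-bandpass filter.

    Defaults follow a 433/517/613 nm tripleband filter; the passband FWHM
    is not printed on such filters' datasheets here, so 20 nm per channel
    is assumed (configurable).
    """

    centers: tuple[float, float, float] = (433.0, 517.0, 613.0)
    bandwidths: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self) -> None:
        if len(self.centers) != 3 or len(self.bandwidths) != 3:
            raise ValueError("exactly three channels are required")
        c = np.asarray(self.centers, dtype=float)
        b = np.asarray(self.bandwidths, dtype=float)
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(b))):
            raise ValueError("wavelengths and bandwidths must be finite")
        if np.any(c <= 0) or np.any(b <= 0):
            raise ValueError("wavelengths and bandwidths must be positive")
        if not np.all(np.diff(c) > 0):
            raise ValueError("channel centers must be strictly increasing")


@dataclass(frozen=True)
class FilmStack:
    """Refractive-index stack above/inside/below the ice film.

    The default is the free-standing film (air / ice / air), for which the
    two interface reflectances are equal and opposite and the film is
    perfectly dark at zero thickness.
    """

    n_film: float = N_ICE
    n_above: float = 1.0
    n_below: float = 1.0
    r1: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "r1", fresnel_amplitude(self.n_above, self.n_film))
        object.__setattr__(self, "r2", fresnel_amplitude(self.n_film, self.n_below))

    @property
    def max_reflectance(self) -> float:
        """Upper bound (|r1| + |r2|)**2 of the two-beam reflectance."""
        return (abs(self.r1) + abs(self.r2)) ** 2

    @property
    def period(self) -> float:
        """Thickness period of the fringes at unit wavelength: 1/(2 n)."""
        return 1.0 / (2.0 * self.n_film)


def film_reflectance(t, lam, stack: FilmStack | None = None):
    """Two-beam reflectance of an ice film of thickness ``t`` at wavelength ``lam``.

    Parameters
    ----------
    t : array_like
        Film thickness in nm, >= 0.
    lam : float
        Vacuum wavelength in nm, > 0.
    stack : FilmStack, optional
        Index stack; defaults to free-standing ice in air.

    Returns
    -------
    ndarray or float
        Reflectance in [0, (|r1|+|r2|)**2], periodic in ``t`` with period
        ``lam / (2 * stack.n_film)``.
    """
    if stack is None:
        stack = FilmStack()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("thickness must be non-negative")
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"wavelength must be positive, got {lam!r}")
    phase = 4.0 * np.pi * stack.n_film * t / lam
    r = stack.r1**2 + stack.r2**2 + 2.0 * stack.r1 * stack.r2 * np.cos(phase)
    return r if r.ndim else float(r)


def band_averaged_reflectance(t, wavelengths: WavelengthSet | None = None,
                              stack: FilmStack | None = None):
    """Reflectance in each colour channel, averaged over the filter passband.

    Each channel integrates ``film_reflectance`` over
    [center - FWHM/2, center + FWHM/2] with 5-point Gauss-Legendre
    quadrature, normalised to the band width.

    Returns an array of shape ``t.shape + (3,)``.
    """
    if wavelengths is None:
        wavelengths = WavelengthSet()
    if stack is None:
        stack = FilmStack()
    t = np.asarray(t, dtype=float)
    out = np.empty(t.shape + (3,), dtype=float)
    for c, (center, fwhm) in enumerate(zip(wavelengths.centers, wavelengths.bandwidths)):
        half = fwhm / 2.0
        acc = np.zeros_like(t)
        for node, w in zip(_GL5_NODES, _GL5_WEIGHTS):
            acc += w * film_reflectance(t, center + half * node, stack)
        out[..., c] = acc / 2.0  # GL weights sum to 2 on [-1, 1]
    return out
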