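"""Species basis spectra, Beer-Lambert quantitation, Savitzky-Golay
second derivatives, and spectral unmixing.

Each heme species is modelled as a sum of Gaussian bands (Soret plus Q
bands) at the catalogued centres; the Soret peak extinction of every
globin species is anchored to 150 mM^-1 cm^-1, the coefficient used for
heme quantitation.  Overlapping Soret bands (e.g. the 423 nm low-spin and
435 nm high-spin deoxyferrous forms) are resolved by the second-derivative
minima; time-resolved series are unmixed by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls
from scipy.signal import savgol_filter

__all__ = [
    "Band",
    "BasisSpectrum",
    "Spectrum",
    "SpectrumSeries",
    "SPECIES_CATALOG",
    "default_grid",
    "make_basis",
    "quantify",
    "Quantification",
    "second_derivative",
    "band_minima",
    "unmix_series",
    "UnmixResult",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default wavelength grid: 250-700 nm at 1 nm.
def default_grid() -> np.ndarray:
    return np.arange(250.0, 701.0, 1.0)


@dataclass(frozen=True)
class Band:
    center: float      # nm
    fwhm: float        # nm
    extinction: float  # M^-1 cm^-1 at the peak

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band width must be > 0")
        if self.extinction <= 0:
            raise ValueError("band extinction must be > 0")


# Band positions: ferric and deoxyferrous centres as observed for these
# globins (ferric Soret ~410, Q 532/563; deoxy 6cLS 423, Q 527/556; the
# 5cHS deoxy Soret at 435).  Ligated-state centres (oxyferrous, carboxy,
# nitrosyl) are generic b-type heme values, flagged non-measured below.
# Soret FWHM 10 nm (6cLS) / 14 nm (5cHS); Q bands 14 nm at a 0.1 Soret
# amplitude ratio.  All Sorets anchored at 150 mM^-1 cm^-1.
_SORET = 150_000.0
_Q = 0.1 * _SORET

SPECIES_CATALOG: Dict[str, Tuple[Band, ...]] = {
    "ferric_6cLS": (Band(410, 10, _SORET), Band(532, 14, _Q), Band(563, 14, 0.6 * _Q)),
    "deoxy_6cLS": (Band(423, 10, _SORET), Band(527, 14, _Q), Band(556, 14, _Q)),
    "deoxy_5cHS": (Band(435, 14, _SORET), Band(556, 18, 0.8 * _Q)),
    "oxyferrous": (Band(412, 10, _SORET), Band(541, 14, _Q), Band(577, 14, _Q)),
    "carboxy": (Band(419, 10, _SORET), Band(540, 14, _Q), Band(569, 14, _Q)),
    "ferric_NO": (Band(420, 10, _SORET), Band(533, 14, _Q), Band(565, 14, _Q)),
    "ferrous_NO": (Band(417, 10, _SORET), Band(545, 14, _Q), Band(575, 14, _Q)),
    # NO-donor quantitation band (not a heme species)
    "proli_nonoate": (Band(252, 40, 8_400.0),),
}

#: Species whose band centres were not measured for these proteins and are
#: generic catalogue defaults; echoed in output metadata by the IO layer.
NON_MEASURED_SPECIES = ("oxyferrous", "carboxy", "ferric_NO", "ferrous_NO")


@dataclass
class BasisSpectrum:
    """Extinction spectrum of one species as a sum of Gaussian bands."""

    species: str
    bands: Tuple[Band, ...]

    def extinction(self, wavelengths: np.ndarray | float) -> np.ndarray | float:
        wl = np.asarray(wavelengths, dtype=float)
        eps = np.zeros_like(wl, dtype=float)
        for b in self.bands:
            sigma = b.fwhm * _FWHM_TO_SIGMA
            eps += b.extinction * np.exp(-0.5 * ((wl - b.center) / sigma) ** 2)
        return eps if eps.ndim else float(eps)

    @property
    def peak_band(self) -> Band:
        return max(self.bands, key=lambda b: b.extinction)


@dataclass
class Spectrum:
    """A single absorbance spectrum on a wavelength grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength: float = 1.0  # cm

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance grids differ in shape")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def at(self, wavelength: float) -> float:
        """Absorbance at the grid point nearest to ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.absorbance[i])


@dataclass
class SpectrumSeries:
    """Wavelength x time absorbance matrix."""

    wavelengths: np.ndarray
    times: np.ndarray
    absorbance: np.ndarray  # shape (n_wavelengths, n_times)
    pathlength: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (len(self.wavelengths), len(self.times)):
            raise ValueError("absorbance must be (n_wavelengths, n_times)")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def spectrum_at(self, time_index: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.absorbance[:, time_index],
                        self.pathlength)


def make_basis(species: Iterable[str]) -> List[BasisSpectrum]:
    """Basis spectra for a set of catalogued species.

    Raises ``KeyError`` for unknown labels; enforces identifiability
    (any two requested species differ in at least one band centre by
    >= 2 nm).
    """
    labels = list(species)
    out: List[BasisSpectrum] = []
    for lab in labels:
        if lab not in SPECIES_CATALOG:
            raise KeyError(
                f"unknown species {lab!r}; supported: "
                + ", ".join(sorted(SPECIES_CATALOG))
            )
        out.append(BasisSpectrum(lab, SPECIES_CATALOG[lab]))
    for i, a in enumerate(out):
        for b in out[i + 1:]:
            ca = sorted(x.center for x in a.bands)
            cb = sorted(x.center for x in b.bands)
            n = min(len(ca), len(cb))
            if all(abs(ca[k] - cb[k]) < 2.0 for k in range(n)) and len(ca) == len(cb):
                raise ValueError(
                    f"species {a.species!r} and {b.species!r} are not "
                    "identifiable (all band centres within 2 nm)"
                )
    return out


@dataclass(frozen=True)
class Quantification:
    concentration: float  # M
    wavelength: float     # nm used
    absorbance: float
    saturated: bool


def quantify(
    spectrum: Spectrum, species: str, basis: Optional[BasisSpectrum] = None
) -> Quantification:
    """Beer-Lambert concentration from the species' quantitation band.

    ``c = A_peak / (eps_peak * pathlength)``.  Absorbance above 3.0 sets a
    saturation warning flag on the result.
    """
    if basis is None:
        basis = make_basis([species])[0]
    band = basis.peak_band
    wl_min, wl_max = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if not (wl_min <= band.center <= wl_max):
        raise ValueError(
            f"spectrum ({wl_min:g}-{wl_max:g} nm) does not cover the "
            f"quantitation wavelength {band.center:g} nm of {species!r}"
        )
    a = spectrum.at(band.center)
    c = a / (band.extinction * spectrum.pathlength)
    return Quantification(
        concentration=c, wavelength=band.center, absorbance=a,
        saturated=a > 3.0,
    )


def second_derivative(
    spectrum: Spectrum, window_points: int = 15, poly_order: int = 4
) -> Spectrum:
    """Savitzky-Golay smoothed second derivative (D2) of a spectrum.

    The default 15-point window with a quartic polynomial reproduces the
    band positions of overlapping Sorets; edges are trimmed by half a
    window where the polynomial fit is one-sided.  Minima of D2 locate
    overlapping band centres.
    """
    if window_points % 2 == 0 or window_points <= poly_order or poly_order < 2:
        raise ValueError("require odd window_points > poly_order >= 2")
    n = len(spectrum.wavelengths)
    if window_points > n:
        raise ValueError("window larger than the wavelength grid")
    step = float(np.median(np.diff(spectrum.wavelengths)))
    d2 = savgol_filter(
        spectrum.absorbance, window_length=window_points, polyorder=poly_order,
        deriv=2, delta=step,
    )
    half = window_points // 2
    sl = slice(half, n - half)
    return Spectrum(spectrum.wavelengths[sl], d2[sl], spectrum.pathlength)


def band_minima(d2: Spectrum, prominence_frac: float = 0.05) -> np.ndarray:
    """Wavelengths of local minima of a D2 spectrum (band centres).

    Only minima whose depth exceeds ``prominence_frac`` of the deepest
    minimum are reported, which discards noise wiggles.
    """
    y = d2.absorbance
    interior = (y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])
    idx = np.nonzero(interior)[0] + 1
    if len(idx) == 0:
        return np.array([])
    depth = -y[idx]
    keep = depth > prominence_frac * depth.max()
    return d2.wavelengths[idx[keep]]


@dataclass
class UnmixResult:
    species: List[str]
    times: np.ndarray
    concentrations: np.ndarray  # (n_species, n_times), molar
    residual: np.ndarray        # relative residual norm per time point


def unmix_series(
    series: SpectrumSeries, basis: Sequence[BasisSpectrum]
) -> UnmixResult:
    """Non-negative least-squares projection of each spectrum onto a basis.

    Solves ``min ||E c - a||`` with ``c >= 0`` per time point, where ``E``
    holds the basis extinction spectra scaled by the pathlength.  A
    rank-deficient basis raises a ``ValueError`` listing collinear pairs.
    """
    if len(basis) < 2:
        raise ValueError("need at least 2 basis spectra to unmix")
    E = np.column_stack(
        [b.extinction(series.wavelengths) for b in basis]
    ) * series.pathlength
    # collinearity check on the grid
    norms = np.linalg.norm(E, axis=0)
    if np.any(norms == 0):
        dead = [basis[i].species for i in np.nonzero(norms == 0)[0]]
        raise ValueError(f"basis spectra vanish on the grid: {dead}")
    G = (E / norms).T @ (E / norms)
    pairs = [
        (basis[i].species, basis[j].species)
        for i in range(len(basis))
        for j in range(i + 1, len(basis))
        if abs(G[i, j]) > 1.0 - 1e-10
    ]
    if pairs or np.linalg.matrix_rank(E) < len(basis):
        raise ValueError(
            "basis is rank-deficient on this grid; collinear pairs: "
            f"{pairs if pairs else 'none resolved pairwise'}"
        )
    n_t = len(series.times)
    conc = np.zeros((len(basis), n_t))
    resid = np.zeros(n_t)
    for k in range(n_t):
        a = series.absorbance[:, k]
        c, rnorm = nnls(E, a)
        conc[:, k] = c
        denom = np.linalg.norm(a)
        resid[k] = rnorm / denom if denom > 0 else 0.0
    return UnmixResult(
        species=[b.species for b in basis],
        times=series.times.copy(),
        concentrations=conc,
        residual=resid,
    )
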