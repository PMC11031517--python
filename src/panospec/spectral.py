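"""Spectral physics: tube spectrum, attenuation tables, PAN/PVMI synthesis.

The forward model is two-basis-material Beer-Lambert attenuation.  Given the
projected thickness images t_b (bone) and t_s (soft tissue) in mm, the
polychromatic panoramic radiograph has expected counts

    N(x) = N0 * sum_j w_j * exp(-mu_b(E_j) t_b(x) - mu_s(E_j) t_s(x)),

while a virtual monoenergetic image at energy E0 is the linear combination

    A(x) = mu_b(E0) t_b(x) + mu_s(E0) t_s(x).

Linear attenuation coefficients come from embedded mass-attenuation tables
(ICRU-44 soft tissue and cortical bone compositions, NIST node energies)
multiplied by nominal densities, interpolated log-log.  The tube spectrum is
a Kramers bremsstrahlung shape filtered by aluminium; a CSV loader lets users
substitute a measured spectrum.  The detector is ideal: no noise, scatter or
energy-bin response is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .projector import MaterialThicknessImage
from .volume import BONE, SOFT

# --------------------------------------------------------------------------
# Embedded mass attenuation tables: energy keV -> mu/rho (cm^2/g).
# Node energies 20-150 keV; ICRU-44 tissue compositions, elemental Al.
_NODE_KEV = np.array([20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 150.0])

_MU_RHO = {
    "soft": np.array([0.8205, 0.3783, 0.2698, 0.2264, 0.2048, 0.1823, 0.1693, 0.1492]),
    "bone": np.array([4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1480]),
    "aluminium": np.array([3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378]),
}

_DENSITY_G_CM3 = {"soft": 1.06, "bone": 1.92, "aluminium": 2.699}

_MATERIAL_ALIASES = {
    BONE: "bone",
    SOFT: "soft",
    "bone": "bone",
    "soft": "soft",
    "soft_tissue": "soft",
    "aluminium": "aluminium",
    "aluminum": "aluminium",
    "al": "aluminium",
}

ENERGY_SPAN_KEV = (float(_NODE_KEV[0]), float(_NODE_KEV[-1]))


def attenuation_mu(material, energies_kev) -> np.ndarray:
    """Linear attenuation coefficient mu(E) in mm^-1.

    Log-log interpolation of the embedded mass-attenuation nodes times the
    material density; exact at table nodes.  Energies must lie within the
    table span (20-150 keV).
    """
    key = _MATERIAL_ALIASES.get(material if not isinstance(material, str) else material.lower())
    if key is None:
        raise ValueError(f"unknown material {material!r}")
    e = np.atleast_1d(np.asarray(energies_kev, dtype=float))
    lo, hi = ENERGY_SPAN_KEV
    if e.min() < lo or e.max() > hi:
        raise ValueError(f"energies must be within [{lo}, {hi}] keV, got [{e.min()}, {e.max()}]")
    log_mu = np.interp(np.log(e), np.log(_NODE_KEV), np.log(_MU_RHO[key]))
    mu_cm = np.exp(log_mu) * _DENSITY_G_CM3[key]    # cm^-1
    mu_mm = mu_cm / 10.0
    return mu_mm if np.ndim(energies_kev) else float(mu_mm[0])


@dataclass
class AttenuationTable:
    """mu(E) lookups for the two basis materials (bone, soft tissue)."""

    def mu(self, material, energies_kev):
        return attenuation_mu(material, energies_kev)

    def decomposition_matrix(self, e_a: float, e_b: float) -> np.ndarray:
        """2x2 matrix [[mu_b(Ea), mu_s(Ea)], [mu_b(Eb), mu_s(Eb)]]."""
        return np.array(
            [
                [self.mu(BONE, e_a), self.mu(SOFT, e_a)],
                [self.mu(BONE, e_b), self.mu(SOFT, e_b)],
            ]
        )


# --------------------------------------------------------------------------
# Tube spectrum

@dataclass
class Spectrum:
    """Discrete tube spectrum: bin energies (keV) and normalized weights."""

    energies_kev: np.ndarray
    weights: np.ndarray
    n0: float = 1.0e5          # reference incident photons per pixel

    def __post_init__(self) -> None:
        self.energies_kev = np.atleast_1d(np.asarray(self.energies_kev, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.energies_kev.shape != self.weights.shape:
            raise ValueError("energies and weights must have the same length")
        if np.any(np.diff(self.energies_kev) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("spectrum has no fluence")
        if abs(total - 1.0) > 1e-12:
            self.weights = self.weights / total
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    @property
    def mean_energy_kev(self) -> float:
        return float(np.sum(self.energies_kev * self.weights))

    @classmethod
    def monoenergetic(cls, energy_kev: float, n0: float = 1.0e5) -> "Spectrum":
        return cls(np.array([float(energy_kev)]), np.array([1.0]), n0)

    @classmethod
    def from_csv(cls, path, n0: float = 1.0e5) -> "Spectrum":
        """Load a measured spectrum from a two-column CSV (energy_kev, weight)."""
        arr = np.loadtxt(path, delimiter=",", comments="#")
        arr = np.atleast_2d(arr)
        order = np.argsort(arr[:, 0])
        return cls(arr[order, 0], arr[order, 1], n0)


def tungsten_spectrum(
    kvp: float,
    filtration_mm_al: float = 2.5,
    n_bins: int = 64,
    e_min_kev: float = 20.0,
    n0: float = 1.0e5,
) -> Spectrum:
    """Kramers bremsstrahlung spectrum of a tungsten tube with Al filtration.

    The unfiltered fluence follows the Kramers shape ``(kvp - E) / E``
    evaluated at bin centers on [e_min, kvp], multiplied by the aluminium
    transmission ``exp(-mu_Al(E) * filtration)``, clipped at zero above the
    tube voltage and renormalized to unit weight.  Characteristic tungsten
    lines are not modeled.  ``n_bins = 1`` degenerates to a single bin at the
    band center.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError("kvp must be within [40, 150] keV")
    if filtration_mm_al < 0:
        raise ValueError("filtration cannot be negative")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not ENERGY_SPAN_KEV[0] <= e_min_kev < kvp:
        raise ValueError("e_min must lie within the attenuation table span and below kvp")
    edges = np.linspace(e_min_kev, kvp, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.clip(kvp - centers, 0.0, None) / centers
    if filtration_mm_al > 0:
        mu_al = attenuation_mu("aluminium", centers)
        fluence = fluence * np.exp(-mu_al * filtration_mm_al)
    return Spectrum(centers, fluence, n0)


# --------------------------------------------------------------------------
# Image synthesis

@dataclass
class PanImage:
    """Polychromatic panoramic radiograph: expected counts + attenuation view."""

    counts: np.ndarray             # N(x), expected photons
    n0: float
    geometry_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if np.any(self.counts < 0) or np.any(self.counts > self.n0 * (1 + 1e-12)):
            raise ValueError("counts must lie in [0, N0]")

    @property
    def attenuation(self) -> np.ndarray:
        """-ln(N / N0); the radiograph-like display (dense structures bright)."""
        return -np.log(np.maximum(self.counts, np.finfo(float).tiny) / self.n0)


@dataclass
class MonoImage:
    """Virtual monoenergetic attenuation line-integral image."""

    values: np.ndarray             # A(x), dimensionless
    energy_kev: float
    geometry_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("monoenergetic attenuation must be non-negative")


def _check_pair(t_b: MaterialThicknessImage, t_s: MaterialThicknessImage) -> None:
    if t_b.values.shape != t_s.values.shape:
        raise ValueError("thickness images must have the same shape")
    if t_b.geometry_id != t_s.geometry_id:
        raise ValueError("thickness images come from different geometries")


def synthesize_pan(
    t_b: MaterialThicknessImage,
    t_s: MaterialThicknessImage,
    spectrum: Spectrum,
    tables: AttenuationTable | None = None,
) -> PanImage:
    """Polychromatic Beer-Lambert synthesis of the conventional panoramic image."""
    _check_pair(t_b, t_s)
    tables = tables or AttenuationTable()
    mu_b = tables.mu(BONE, spectrum.energies_kev)
    mu_s = tables.mu(SOFT, spectrum.energies_kev)
    mu_b = np.atleast_1d(mu_b)
    mu_s = np.atleast_1d(mu_s)
    n = np.zeros(t_b.values.shape, dtype=np.float64)
    for w, mb, ms in zip(spectrum.weights, mu_b, mu_s):
        n += w * np.exp(-mb * t_b.values - ms * t_s.values)
    return PanImage(spectrum.n0 * n, spectrum.n0, t_b.geometry_id)


def synthesize_pvmi(
    t_b: MaterialThicknessImage,
    t_s: MaterialThicknessImage,
    energy_kev: float,
    tables: AttenuationTable | None = None,
) -> MonoImage:
    """Virtual monoenergetic image A = mu_b(E0) t_b + mu_s(E0) t_s."""
    _check_pair(t_b, t_s)
    tables = tables or AttenuationTable()
    a = tables.mu(BONE, energy_kev) * t_b.values + tables.mu(SOFT, energy_kev) * t_s.values
    return MonoImage(a, float(energy_kev), t_b.geometry_id)


def recover_thickness(
    mono_a: MonoImage,
    mono_b: MonoImage,
    tables: AttenuationTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert two monoenergetic images back to (t_b, t_s) in mm.

    Solves the per-pixel 2x2 linear system; exact round trip of
    :func:`synthesize_pvmi` up to solver precision.
    """
    if mono_a.values.shape != mono_b.values.shape:
        raise ValueError("mono images must have the same shape")
    if mono_a.energy_kev == mono_b.energy_kev:
        raise ValueError("decomposition needs two distinct energies (singular system)")
    tables = tables or AttenuationTable()
    m = tables.decomposition_matrix(mono_a.energy_kev, mono_b.energy_kev)
    det = np.linalg.det(m)
    if abs(det) < 1e-15:
        raise ValueError("attenuation matrix is singular")
    inv = np.linalg.inv(m)
    t_b = inv[0, 0] * mono_a.values + inv[0, 1] * mono_b.values
    t_s = inv[1, 0] * mono_a.values + inv[1, 1] * mono_b.values
    return t_b, t_s


def window_image(
    img: np.ndarray,
    level: float | None = None,
    width: float | None = None,
) -> np.ndarray:
    """Linear window to an 8-bit display image.

    Maps ``[level - width/2, level + width/2]`` to [0, 255] with clipping.
    Without level/width, the 1st and 99th percentiles set the window; a
    degenerate (constant) image gets a window of width 1 around its value.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if level is None or width is None:
        lo, hi = np.percentile(img, [1.0, 99.0])
        if hi <= lo:
            lo, hi = lo - 0.5, lo + 0.5
        level, width = (lo + hi) / 2.0, hi - lo
    if width <= 0:
        raise ValueError("window width must be positive")
    lo = level - width / 2.0
    scaled = (img - lo) / width * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
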