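"""Microdosimetric post-processing of TEPC pulse-height spectra.

A tissue-equivalent proportional counter (TEPC) records events binned by
lineal energy y (keV/um), emulating energy deposition in a ~1 um tissue
site.  Given per-source-particle count spectra for the neutron and the
secondary gamma-ray fields and their fluences through the target, this
module combines them fluence-weighted, computes the frequency- and
dose-mean lineal energies, the log-binned dose distribution y*d(y), a
dose-weighted mean quality factor, the frequency-mean specific energy
z_F of a spherical site, and Poisson hit statistics N = D / z_F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from ._constants import KEV_IN_J
from .errors import DomainError

__all__ = [
    "PulseHeightSpectrum",
    "FluencePair",
    "MicrodosimetricSummary",
    "HitDistribution",
    "combine_spectra",
    "lineal_energy_means",
    "dose_distribution",
    "mean_quality_factor",
    "icrp60_quality_factor",
    "specific_energy_from_lineal",
    "hit_distribution",
    "summarize_spectrum",
]


@dataclass
class PulseHeightSpectrum:
    """Event counts per source particle, binned in lineal energy.

    ``bin_edges`` (keV/um) are strictly increasing, normally log-spaced;
    ``counts[i]`` belongs to the bin [edges[i], edges[i+1]).  The bin's
    representative lineal energy is the geometric midpoint.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    particle: str = "combined"  # "neutron", "gamma" or "combined"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.bin_edges <= 0):
            raise ValueError("lineal-energy bin edges must be positive")
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.particle not in ("neutron", "gamma", "combined"):
            raise ValueError(f"unknown particle tag {self.particle!r}")

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric midpoints of the (log-spaced) bins."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclass
class FluencePair:
    """Neutron and gamma fluence through the target, per source neutron."""

    phi_n: float
    phi_gamma: float

    def __post_init__(self):
        if self.phi_n < 0 or self.phi_gamma < 0:
            raise ValueError("fluences must be non-negative")
        if self.phi_n == 0 and self.phi_gamma == 0:
            raise ValueError("at least one fluence must be positive")


@dataclass
class MicrodosimetricSummary:
    y_F: float        # frequency-mean lineal energy, keV/um
    y_D: float        # dose-mean lineal energy, keV/um
    q_bar: float      # dose-weighted mean quality factor
    z_F_mGy: float    # frequency-mean specific energy of the site, mGy


@dataclass
class HitDistribution:
    """Poisson hit statistics of a microscopic sub-volume."""

    N: float                 # mean hits, D / z_F
    p: np.ndarray            # p(0..nu_max)
    p_multi: float           # 1 - p(0) - p(1)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def combine_spectra(spec_n: PulseHeightSpectrum, spec_gamma: PulseHeightSpectrum,
                    fluences: FluencePair) -> PulseHeightSpectrum:
    """Fluence-weighted combination of neutron and gamma spectra.

    Per bin: (phi_g / (phi_n + phi_g)) * C_gamma + (phi_n / (phi_n + phi_g)) * C_n.
    Both spectra must share identical binning; no resampling is attempted.
    """
    if spec_n.bin_edges.shape != spec_gamma.bin_edges.shape or not np.allclose(
        spec_n.bin_edges, spec_gamma.bin_edges
    ):
        raise DomainError("mismatched bin edges: spectra cannot be combined")
    total = fluences.phi_n + fluences.phi_gamma
    w_n = fluences.phi_n / total
    w_g = fluences.phi_gamma / total
    return PulseHeightSpectrum(
        bin_edges=spec_n.bin_edges.copy(),
        counts=w_g * spec_gamma.counts + w_n * spec_n.counts,
        particle="combined",
    )


def lineal_energy_means(spec: PulseHeightSpectrum) -> tuple[float, float]:
    """Frequency- and dose-mean lineal energies (y_F, y_D) in keV/um.

    y_F = sum C_i y_i / sum C_i ; y_D = sum C_i y_i^2 / sum C_i y_i,
    with y_i the geometric bin midpoints.  y_D >= y_F always
    (Cauchy-Schwarz).
    """
    if spec.total_counts <= 0:
        raise DomainError("empty spectrum: lineal-energy means undefined")
    y = spec.midpoints
    c = spec.counts
    first = float(np.dot(c, y))
    y_f = first / spec.total_counts
    y_d = float(np.dot(c, y * y)) / first
    return y_f, y_d


def dose_distribution(spec: PulseHeightSpectrum) -> np.ndarray:
    """Per-bin dose fraction normalised to the log10 bin width, y*d(y).

    Each value is (C_i y_i / sum C_j y_j) / dlog10(bin); multiplying back
    by the bin widths and summing returns exactly 1.
    """
    y = spec.midpoints
    weighted = spec.counts * y
    total = weighted.sum()
    if total <= 0:
        raise DomainError("empty spectrum: dose distribution undefined")
    dlog = np.diff(np.log10(spec.bin_edges))
    return (weighted / total) / dlog


def icrp60_quality_factor(y) -> np.ndarray | float:
    """ICRP 60 Q(L) piecewise relation with lineal energy as LET surrogate.

    Q = 1 below 10 keV/um, 0.32*y - 2.2 between 10 and 100, 300/sqrt(y)
    above 100 keV/um.
    """
    y = np.asarray(y, dtype=float)
    q = np.where(
        y < 10.0, 1.0,
        np.where(y <= 100.0, 0.32 * y - 2.2, 300.0 / np.sqrt(np.maximum(y, 1e-300))),
    )
    return q if q.ndim else float(q)


def mean_quality_factor(spec: PulseHeightSpectrum,
                        q_of_y: Optional[Callable] = None) -> float:
    """Dose-weighted mean quality factor over the spectrum.

    q_bar = sum q(y_i) C_i y_i / sum C_i y_i.  The Q(y) relation is
    pluggable; the default is the ICRP 60 piecewise form.
    """
    if q_of_y is None:
        q_of_y = icrp60_quality_factor
    y = spec.midpoints
    weighted = spec.counts * y
    total = weighted.sum()
    if total <= 0:
        raise DomainError("empty spectrum: mean quality factor undefined")
    return float(np.dot(np.asarray(q_of_y(y), dtype=float), weighted)) / total


def specific_energy_from_lineal(y_F: float, diameter_um: float = 1.0,
                                density_g_cm3: float = 1.0) -> float:
    """Frequency-mean specific energy z_F (mGy) of a spherical site.

    For a sphere the Cauchy mean chord length is l = (2/3) d, so the mean
    energy of one event is y_F * l; dividing by the site mass
    rho * (pi/6) d^3 and converting keV -> J, g -> kg gives z_F in mGy.
    Equivalent closed form: z_F ∝ y_F / (rho d^2).
    """
    if y_F <= 0 or diameter_um <= 0 or density_g_cm3 <= 0:
        raise ValueError("inputs must be positive")
    energy_J = y_F * (2.0 / 3.0) * diameter_um * KEV_IN_J
    mass_kg = density_g_cm3 * 1e3 * (math.pi / 6.0) * (diameter_um * 1e-6) ** 3
    return energy_J / mass_kg * 1e3  # Gy -> mGy


def hit_distribution(dose_mGy: float, z_F_mGy: float,
                     nu_max: int = 10) -> HitDistribution:
    """Poisson hit statistics for sub-volumes receiving mean N = D / z_F.

    p(nu) = N^nu exp(-N) / nu!; ``p`` holds nu = 0..nu_max and
    ``p_multi`` = 1 - p(0) - p(1) is the multi-hit probability.
    """
    if z_F_mGy <= 0:
        raise DomainError("z_F must be positive")
    if dose_mGy < 0:
        raise ValueError("dose must be non-negative")
    if nu_max < 1:
        raise ValueError("nu_max must be at least 1")
    n_mean = dose_mGy / z_F_mGy
    p = stats.poisson.pmf(np.arange(nu_max + 1), n_mean)
    return HitDistribution(N=n_mean, p=p, p_multi=float(1.0 - p[0] - p[1]))


def summarize_spectrum(spec: PulseHeightSpectrum, diameter_um: float = 1.0,
                       density_g_cm3: float = 1.0,
                       q_of_y: Optional[Callable] = None) -> MicrodosimetricSummary:
    """One-stop summary: y_F, y_D, q_bar and z_F for a site diameter."""
    y_f, y_d = lineal_energy_means(spec)
    return MicrodosimetricSummary(
        y_F=y_f,
        y_D=y_d,
        q_bar=mean_quality_factor(spec, q_of_y),
        z_F_mGy=specific_energy_from_lineal(y_f, diameter_um, density_g_cm3),
    )
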