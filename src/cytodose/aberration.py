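"""Per-cell aberration multiplicity distributions and Poisson-dispersion tests.

In cytogenetic biodosimetry the raw observable at each dose point is the
number of cells carrying exactly k aberrations (dicentrics + rings for the
dicentric chromosome assay, micronuclei per binucleated cell for the
cytokinesis-block micronucleus assay).  Densely ionising radiation deposits
several DNA double-strand breaks along a single charged-particle track, so
the per-cell counts cluster and the distribution becomes overdispersed
relative to Poisson.  This module computes the standard summary statistics:
yield per cell, the dispersion index sigma^2/y, and Papworth's u-statistic
for departure from Poisson (|u| > 1.96 flags significance at the 5% level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PoolingError, UndefinedStatisticError

__all__ = [
    "AberrationDistribution",
    "DistributionStats",
    "summarize_distribution",
    "papworth_u",
    "pool_distributions",
    "OVERDISPERSION_THRESHOLD",
]

#: two-sided 5% normal critical value used to flag overdispersion
OVERDISPERSION_THRESHOLD = 1.96

#: tolerance (mGy) for the dose-component bookkeeping, matching the
#: rounding of published per-component dose columns
_DOSE_SUM_TOL_MGY = 1.0


@dataclass
class AberrationDistribution:
    """Cell counts by aberration multiplicity at one dose point.

    ``counts[k]`` is the number of cells observed with exactly ``k``
    aberrations; the vector is dense from 0 to k_max (trailing zeros are
    allowed).  Dose components record the high-LET 14N(n,p)14C and the
    low-LET (n,gamma) contributions to the total absorbed dose.
    """

    label: str
    assay: str  # "DCA" or "MN"
    dose_total_mGy: float
    dose_np_mGy: float
    dose_gamma_mGy: float
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("cell counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("at least one cell must be scored")
        if self.assay not in ("DCA", "MN"):
            raise ValueError(f"unknown assay {self.assay!r} (expected 'DCA' or 'MN')")
        if abs(self.dose_np_mGy + self.dose_gamma_mGy - self.dose_total_mGy) > _DOSE_SUM_TOL_MGY:
            raise ValueError(
                "dose components (n,p) + (n,gamma) must sum to the total dose "
                f"within {_DOSE_SUM_TOL_MGY} mGy"
            )

    @property
    def cells(self) -> int:
        return int(self.counts.sum())

    @property
    def multiplicities(self) -> np.ndarray:
        """Expanded per-cell multiplicity vector (one entry per scored cell)."""
        return np.repeat(np.arange(self.counts.size), self.counts)


@dataclass
class DistributionStats:
    """Summary statistics of one multiplicity distribution."""

    cells: int
    total_aberrations: int
    total_sd: int              # Poisson SD of the total, rounded: sqrt(x)
    yield_per_cell: float
    variance: float            # sample variance, denominator (n - 1)
    dispersion_index: float    # sigma^2 / y; NaN when undefined
    u_statistic: float         # Papworth u; NaN when undefined
    overdispersed_flag: bool = field(default=False)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.dispersion_index)


def papworth_u(dispersion: float, cells: int, total: int) -> float:
    """Papworth's u-statistic for departure of the dispersion index from 1.

    u = (d - 1) * sqrt((n - 1) / (2 * (1 - 1/x)))

    with d the (unrounded) dispersion index, n the number of cells and x
    the total aberration count.  Under the Poisson hypothesis u is
    asymptotically standard normal; u > 1.96 indicates significant
    overdispersion.
    """
    if total < 1:
        raise UndefinedStatisticError("u-test undefined with zero aberrations")
    if cells < 2:
        raise UndefinedStatisticError("u-test requires at least two cells")
    if total == 1:
        # 1 - 1/x vanishes; the statistic degenerates
        raise UndefinedStatisticError("u-test undefined with a single aberration")
    return (dispersion - 1.0) * math.sqrt((cells - 1) / (2.0 * (1.0 - 1.0 / total)))


def summarize_distribution(dist: AberrationDistribution) -> DistributionStats:
    """Compute totals, yield, sample variance, dispersion index and u-test.

    The sample variance uses denominator (n - 1).  The SD quoted on the
    aberration total is the Poisson value sqrt(x) rounded to an integer.
    With zero aberrations the dispersion index and u-statistic are
    undefined and returned as NaN with the overdispersion flag off.
    """
    n = dist.cells
    k = np.arange(dist.counts.size, dtype=float)
    x = float(np.dot(k, dist.counts))
    y = x / n
    # closed forms equivalent to np.var(multiplicities, ddof=1)
    sum_k2 = float(np.dot(k * k, dist.counts))
    variance = (sum_k2 - n * y * y) / (n - 1) if n > 1 else 0.0

    total = int(round(x))
    if total == 0 or y == 0.0:
        return DistributionStats(
            cells=n, total_aberrations=total, total_sd=0,
            yield_per_cell=y, variance=variance,
            dispersion_index=float("nan"), u_statistic=float("nan"),
            overdispersed_flag=False,
        )

    dispersion = variance / y
    try:
        u = papworth_u(dispersion, n, total)
    except UndefinedStatisticError:
        u = float("nan")
    return DistributionStats(
        cells=n,
        total_aberrations=total,
        total_sd=int(round(math.sqrt(total))),
        yield_per_cell=y,
        variance=variance,
        dispersion_index=dispersion,
        u_statistic=u,
        overdispersed_flag=(not math.isnan(u)) and u > OVERDISPERSION_THRESHOLD,
    )


def pool_distributions(dists: list[AberrationDistribution]) -> AberrationDistribution:
    """Pool multiplicity distributions scored at the same dose point.

    Counts add component-wise (ragged k_max is densified); the dose fields
    of the first distribution are preserved.  Mixing assays or doses is
    refused: donor pooling is only meaningful within one exposure.
    """
    if not dists:
        raise PoolingError("nothing to pool: empty distribution list")
    first = dists[0]
    for d in dists[1:]:
        if d.assay != first.assay:
            raise PoolingError(
                f"cannot pool assays {first.assay!r} and {d.assay!r}"
            )
        if abs(d.dose_total_mGy - first.dose_total_mGy) > _DOSE_SUM_TOL_MGY:
            raise PoolingError(
                "cannot pool distributions at different doses "
                f"({first.dose_total_mGy} vs {d.dose_total_mGy} mGy)"
            )
    kmax = max(d.counts.size for d in dists)
    counts = np.zeros(kmax, dtype=np.int64)
    for d in dists:
        counts[: d.counts.size] += d.counts
    return AberrationDistribution(
        label="+".join(d.label for d in dists),
        assay=first.assay,
        dose_total_mGy=first.dose_total_mGy,
        dose_np_mGy=first.dose_np_mGy,
        dose_gamma_mGy=first.dose_gamma_mGy,
        counts=counts,
    )
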