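"""Mesh-weighted statistics of finite-element von Mises stress fields.

An FE mesh adapted to surface curvature concentrates small elements in
some regions, so plain per-element summaries over-weight densely meshed
areas.  Weighting every element by its volume corrects this: the
mesh-weighted arithmetic mean (MWAM) and mesh-weighted median (MWM) are
the volume-weighted counterparts of the mean and median, and the
percentage differences between the plain and weighted versions (PEofAM,
PEofM) quantify how far the mesh is from a quasi-ideal mesh (QIM), one
whose unweighted statistics can be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

STANDARD_GRAVITY = 9.81  # m s^-2

__all__ = [
    "StressField",
    "StressSummary",
    "body_weight_force",
    "mwam",
    "weighted_percentile",
    "mwm",
    "stress_summary",
    "is_quasi_ideal",
]


@dataclass
class StressField:
    """Per-element von Mises stress (MPa) and element volume (mm^3)."""

    sigma: np.ndarray
    vol: np.ndarray
    specimen_id: str = ""
    element_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.vol = np.asarray(self.vol, dtype=float)
        if self.sigma.ndim != 1 or self.vol.ndim != 1:
            raise ValueError("sigma and vol must be 1-D")
        if self.sigma.size != self.vol.size:
            raise ValueError("sigma and vol must have equal length")
        if self.sigma.size == 0:
            raise ValueError("stress field must contain at least one element")
        if np.any(self.sigma < 0):
            raise ValueError("von Mises stress must be nonnegative")
        if np.any(self.vol <= 0):
            raise ValueError("element volumes must be strictly positive")
        if self.element_ids is None:
            self.element_ids = np.arange(1, self.sigma.size + 1)
        else:
            self.element_ids = np.asarray(self.element_ids)
            if self.element_ids.size != self.sigma.size:
                raise ValueError("element_ids length mismatch")

    @property
    def n_elements(self) -> int:
        return int(self.sigma.size)

    @property
    def total_volume(self) -> float:
        return float(self.vol.sum())


@dataclass
class StressSummary:
    """Plain and mesh-weighted summaries of one stress field."""

    specimen_id: str
    MWAM: float
    MWM: float
    M25: float
    M50: float
    M75: float
    M95: float
    AM: float
    median: float
    PEofAM: float
    PEofM: float
    total_volume: float
    pe_defined: bool = field(default=True)

    def as_dict(self) -> dict[str, float | str | bool]:
        return {
            "specimen_id": self.specimen_id,
            "MWAM": self.MWAM,
            "MWM": self.MWM,
            "M25": self.M25,
            "M50": self.M50,
            "M75": self.M75,
            "M95": self.M95,
            "AM": self.AM,
            "median": self.median,
            "PEofAM": self.PEofAM,
            "PEofM": self.PEofM,
            "total_volume": self.total_volume,
            "pe_defined": self.pe_defined,
        }


def body_weight_force(body_mass_g: float) -> float:
    """Applied trochlear load in newtons for a quadrupedal stance.

    The hind limbs of most monkeys carry a minority share of body
    weight; the load is 30% of body mass times gravitational
    acceleration.
    """
    if body_mass_g < 0:
        raise ValueError("body mass must be nonnegative")
    return 0.30 * (body_mass_g / 1000.0) * STANDARD_GRAVITY


def mwam(fld: StressField) -> float:
    """Mesh-weighted arithmetic mean: sum(sigma_i v_i) / sum(v_i)."""
    return float(np.dot(fld.sigma, fld.vol) / fld.vol.sum())


def weighted_percentile(fld: StressField, q: float, *, interpolate: bool = False) -> float:
    """Volume-weighted stress percentile.

    Default is the left-continuous inverse-CDF (step) definition: the
    smallest stress at which the volume-weighted cumulative distribution
    reaches a fraction ``q`` of the total volume.  Ties in stress pool
    their volume at one step.  ``interpolate=True`` gives a piecewise
    linear variant instead.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    order = np.argsort(fld.sigma, kind="stable")
    s = fld.sigma[order]
    v = fld.vol[order]
    cum = np.cumsum(v)
    target = q * cum[-1]
    if interpolate:
        # midpoint convention on the cumulative mass of each element
        mid = cum - v / 2.0
        return float(np.interp(target, mid, s))
    idx = int(np.searchsorted(cum, target, side="left"))
    idx = min(idx, s.size - 1)
    return float(s[idx])


def mwm(fld: StressField) -> float:
    """Mesh-weighted median: the volume-weighted 50th percentile."""
    return weighted_percentile(fld, 0.5)


def _plain_median_lower(x: np.ndarray) -> float:
    """Median with the lower-median convention for even counts."""
    s = np.sort(x)
    n = s.size
    if n % 2 == 1:
        return float(s[n // 2])
    return float(s[n // 2 - 1])


def stress_summary(fld: StressField) -> StressSummary:
    """All plain and mesh-weighted summaries, with QIM error percentages.

    PEofAM = |AM - MWAM| / MWAM * 100 and PEofM = |median - MWM| / MWM
    * 100.  If a weighted statistic is zero the percentage is undefined
    and flagged (``pe_defined=False``, values NaN).
    """
    m = mwam(fld)
    med_w = mwm(fld)
    am = float(fld.sigma.mean())
    med = _plain_median_lower(fld.sigma)
    pe_defined = m > 0 and med_w > 0
    if pe_defined:
        pe_am = abs(am - m) / m * 100.0
        pe_m = abs(med - med_w) / med_w * 100.0
    else:
        warnings.warn(
            f"specimen {fld.specimen_id!r}: MWAM or MWM is zero; "
            "PEofAM/PEofM undefined",
            stacklevel=2,
        )
        pe_am = pe_m = float("nan")
    return StressSummary(
        specimen_id=fld.specimen_id,
        MWAM=m,
        MWM=med_w,
        M25=weighted_percentile(fld, 0.25),
        M50=med_w,
        M75=weighted_percentile(fld, 0.75),
        M95=weighted_percentile(fld, 0.95),
        AM=am,
        median=med,
        PEofAM=pe_am,
        PEofM=pe_m,
        total_volume=fld.total_volume,
        pe_defined=pe_defined,
    )


def is_quasi_ideal(summary: StressSummary, threshold_pct: float = 2.0) -> bool:
    """True if both QIM error percentages are at or below the threshold."""
    if not summary.pe_defined:
        warnings.warn(
            f"specimen {summary.specimen_id!r}: PE fields undefined; "
            "mesh treated as not quasi-ideal",
            stacklevel=2,
        )
        return False
    return summary.PEofAM <= threshold_pct and summary.PEofM <= threshold_pct
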