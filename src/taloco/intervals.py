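"""The Intervals' method: fixed-length features from a stress field.

A stress distribution is summarised as the percentages of total model
volume whose von Mises stress falls into N equal-width bins between 0
and an upper fixed threshold FT_upper.  The resulting N-vector is a
mesh-independent, fixed-length multivariate representation of the
field, comparable across specimens, suitable for ordination and
classification.  A convergence procedure picks the smallest N at which
the between-specimen distance structure has stabilised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fea import StressField, stress_summary

__all__ = [
    "IntervalProfile",
    "FeatureMatrix",
    "interval_profile",
    "default_ft_upper",
    "choose_intervals",
    "boxcox_center_scale",
    "profiles_to_frame",
]

DEFAULT_N = 10
DEFAULT_CANDIDATE_NS = (5, 10, 15, 25, 50)


@dataclass
class IntervalProfile:
    """Percent of total element volume per stress interval."""

    values: np.ndarray
    N: int
    FT_upper: float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.FT_upper <= 0:
            raise ValueError("FT_upper must be positive")
        if self.values.size != self.N:
            raise ValueError("values length must equal N")


def interval_profile(
    fld: StressField,
    FT_upper: float,
    N: int = DEFAULT_N,
    *,
    discard_above: bool = False,
) -> IntervalProfile:
    """Bin element volume into N equal stress intervals on [0, FT_upper).

    Interval k (1-based) spans [(k-1)*FT_upper/N, k*FT_upper/N).  By
    default, elements at or above FT_upper are accumulated into the top
    interval so the profile always sums to 100% of volume; with
    ``discard_above`` they are dropped (the profile then sums to the
    retained volume share scaled to the full total).
    """
    if FT_upper <= 0:
        raise ValueError("FT_upper must be positive")
    if N < 2:
        raise ValueError("N must be at least 2")
    idx = np.minimum(np.floor(fld.sigma / FT_upper * N).astype(int), N - 1)
    if discard_above:
        keep = fld.sigma < FT_upper
        vols = np.bincount(idx[keep], weights=fld.vol[keep], minlength=N)
    else:
        vols = np.bincount(idx, weights=fld.vol, minlength=N)
    values = 100.0 * vols / fld.vol.sum()
    return IntervalProfile(values=values, N=N, FT_upper=FT_upper, specimen_id=fld.specimen_id)


def default_ft_upper(fields: list[StressField]) -> float:
    """Upper threshold rule: max over specimens of M95, rounded up."""
    m95 = max(stress_summary(f).M95 for f in fields)
    return float(math.ceil(m95))


def _profile_distance_corr(fields: list[StressField], FT_upper: float, n1: int, n2: int) -> float:
    """Mantel-style Pearson correlation of between-specimen distance
    matrices (upper triangles) at two interval counts."""
    from scipy.spatial.distance import pdist

    p1 = np.array([interval_profile(f, FT_upper, n1).values for f in fields])
    p2 = np.array([interval_profile(f, FT_upper, n2).values for f in fields])
    d1 = pdist(p1)
    d2 = pdist(p2)
    if np.allclose(d1, d1[0]) or np.allclose(d2, d2[0]):
        # no distance structure to destabilise: treat as converged
        return 1.0
    return float(np.corrcoef(d1, d2)[0, 1])


def choose_intervals(
    fields: list[StressField],
    FT_upper: float,
    candidate_Ns: tuple[int, ...] = DEFAULT_CANDIDATE_NS,
    tol: float = 0.01,
) -> int:
    """Smallest candidate N whose distance structure matches the next
    larger candidate's with correlation above 1 - tol.

    Falls back to the largest candidate with a warning if the ladder
    never converges.
    """
    if len(candidate_Ns) < 2:
        raise ValueError("need at least two candidate interval counts")
    if len(fields) < 3:
        raise ValueError("need at least three stress fields")
    if list(candidate_Ns) != sorted(candidate_Ns):
        raise ValueError("candidate_Ns must be increasing")
    for n1, n2 in zip(candidate_Ns[:-1], candidate_Ns[1:]):
        if _profile_distance_corr(fields, FT_upper, n1, n2) > 1.0 - tol:
            return int(n1)
    warnings.warn(
        "interval-count ladder did not converge; using largest candidate",
        stacklevel=2,
    )
    return int(candidate_Ns[-1])


@dataclass
class FeatureMatrix:
    """Feature table plus the transform metadata needed to re-apply the
    training-time Box-Cox/centre/scale to new (fossil) rows."""

    data: pd.DataFrame
    lambdas: dict[str, float | None] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def transform_new(self, new: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored per-column transform to held-out rows."""
        if not self.lambdas:
            raise ValueError("no stored transform; run boxcox_center_scale first")
        out = {}
        for col in self.data.columns:
            x = new[col].to_numpy(dtype=float)
            lam = self.lambdas[col]
            if lam is not None:
                x = x + self.offsets[col]
                x = np.log(x) if lam == 0 else (x**lam - 1.0) / lam
            out[col] = (x - self.means[col]) / self.sds[col]
        return pd.DataFrame(out, index=new.index)


def boxcox_center_scale(matrix: FeatureMatrix | pd.DataFrame) -> FeatureMatrix:
    """Per column: Box-Cox (ML lambda) then centre to mean 0, scale to sd 1.

    Interval percentages can be exactly zero, and Box-Cox needs strictly
    positive input, so each column is shifted by half its smallest
    positive value before the transform.  Constant columns skip Box-Cox
    and are centred only (sd recorded as 1), with a warning.  The fitted
    lambda, offset, mean and sd per column are stored so fossil rows can
    be pushed through the identical transform.
    """
    df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("all entries must be nonnegative")
    out = {}
    lambdas: dict[str, float | None] = {}
    offsets: dict[str, float] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"column {col!r} is constant; Box-Cox skipped", stacklevel=2)
            lambdas[col] = None
            offsets[col] = 0.0
            means[col] = float(x.mean())
            sds[col] = 1.0
            out[col] = x - x.mean()
            continue
        positive = x[x > 0]
        eps = positive.min() / 2.0 if (x == 0).any() else 0.0
        shifted = x + eps
        transformed, lam = stats.boxcox(shifted)
        mu = float(transformed.mean())
        sd = float(transformed.std(ddof=0))
        lambdas[col] = float(lam)
        offsets[col] = float(eps)
        means[col] = mu
        sds[col] = sd
        out[col] = (transformed - mu) / sd
    return FeatureMatrix(
        data=pd.DataFrame(out, index=df.index),
        lambdas=lambdas,
        offsets=offsets,
        means=means,
        sds=sds,
    )


def profiles_to_frame(profiles: list[IntervalProfile]) -> pd.DataFrame:
    """One row per specimen, columns I1..IN."""
    n = profiles[0].N
    if any(p.N != n for p in profiles):
        raise ValueError("profiles have differing interval counts")
    return pd.DataFrame(
        [p.values for p in profiles],
        index=[p.specimen_id for p in profiles],
        columns=[f"I{k}" for k in range(1, n + 1)],
    )
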