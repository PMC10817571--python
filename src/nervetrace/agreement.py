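"""Method-comparison statistics between two measurement sources.

Three tools, as used when comparing manual nerve morphometry against an
automated method:

* Spearman rank correlation (midranks for ties; two-sided p from the
  t-approximation with n-2 degrees of freedom) with the conventional
  interpretation bands |rs| in [0.2, 0.39] weak, [0.4, 0.59] moderate,
  [0.6, 0.79] strong.
* Student's t-test: unpaired pooled-variance by default, paired optional.
* Bland-Altman agreement: differences are reference minus test, so a
  positive mean difference means the test method underestimates; limits
  of agreement are mean difference +/- 1.96 times the sample S.D. of the
  differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ConstantInputError, GeometryError

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "correlation_band",
    "spearman",
    "two_sample_t",
    "bland_altman",
]


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p: float
    n: int
    band: str


@dataclass(frozen=True)
class AgreementResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    coverage: float
    n: int
    diffs: np.ndarray = field(repr=False)
    pair_means: np.ndarray = field(repr=False)


def correlation_band(rs: float) -> str:
    """Interpretation band of |rs|: weak / moderate / strong / other."""
    r = abs(rs)
    if 0.2 <= r <= 0.39:
        return "weak"
    if 0.4 <= r <= 0.59:
        return "moderate"
    if 0.6 <= r <= 0.79:
        return "strong"
    return "other"


def _vec(x, name, min_n):
    v = np.asarray(x, dtype=float).ravel()
    if v.size < min_n:
        raise ConfigurationError(f"{name} needs at least {min_n} values")
    return v


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks and t-approximation p-value."""
    xv = _vec(x, "x", 3)
    yv = _vec(y, "y", 3)
    if xv.size != yv.size:
        raise GeometryError("x and y must have equal length")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ConstantInputError("rank correlation undefined for constant input")
    rs, p = stats.spearmanr(xv, yv)
    return CorrelationResult(rs=float(rs), p=float(p), n=xv.size,
                             band=correlation_band(float(rs)))


def two_sample_t(a, b, paired: bool = False) -> tuple[float, float]:
    """Student's t-test (pooled-variance unpaired by default, or paired).

    Degenerate zero-variance samples: equal means give (0, 1), unequal
    means give (+/-inf, 0).
    """
    av = _vec(a, "a", 2)
    bv = _vec(b, "b", 2)
    if paired:
        if av.size != bv.size:
            raise GeometryError("paired test needs equal sizes")
        d = av - bv
        if np.ptp(d) == 0:
            if d[0] == 0:
                return 0.0, 1.0
            return float(np.sign(d[0]) * np.inf), 0.0
        t, p = stats.ttest_rel(av, bv)
        return float(t), float(p)
    if np.ptp(av) == 0 and np.ptp(bv) == 0:
        if av[0] == bv[0]:
            return 0.0, 1.0
        return float(np.sign(av[0] - bv[0]) * np.inf), 0.0
    t, p = stats.ttest_ind(av, bv, equal_var=True)
    return float(t), float(p)


def bland_altman(reference, test) -> AgreementResult:
    """Bland-Altman agreement of a test method against a reference.

    Differences are ``reference - test`` (positive mean difference: the
    test method underestimates).  Limits of agreement are the mean
    difference +/- 1.96 sample standard deviations (n-1); coverage is the
    inclusive fraction of pairs inside the limits.  Per-pair means are
    retained for plotting.
    """
    r = _vec(reference, "reference", 3)
    t = _vec(test, "test", 3)
    if r.size != t.size:
        raise GeometryError("reference and test must have equal length")
    d = r - t
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    coverage = float(np.mean((d >= lo) & (d <= hi)))
    return AgreementResult(mean_diff=mean_diff, sd_diff=sd, loa_low=lo,
                           loa_high=hi, coverage=coverage, n=r.size,
                           diffs=d, pair_means=(r + t) / 2.0)
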