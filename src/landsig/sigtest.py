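"""Statistical decisions on landscapes and individual activity cliffs.

Two questions are answered here.  First, is the landscape *valid* — is the
observed SALI distribution distinguishable from the accumulated null of
scrambled landscapes?  A two-sample Kolmogorov-Smirnov test decides, with
the landscape declared valid when p < alpha.  Second, which individual
pairs are statistically significant activity cliffs?  A pair must exceed
the magnitude threshold (a quantile of the observed SALI values) and its
empirical p-value — the fraction of iterations in which the random SALI
value at the same pair position strictly exceeds the observed one — must
fall below alpha.

F_magnitude is the fraction of defined pairs above the magnitude threshold;
F_significant the fraction that also passes the permutation test.  When the
landscape itself is not valid, per-pair significance is not meaningful and
F_significant is reported as NA (None).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SALIVector, TestConfig
from .randomize import RandomSALIPool

logger = logging.getLogger("landsig")

__all__ = [
    "LandscapeTestResult",
    "CliffSignificanceResult",
    "ks_two_sample",
    "landscape_validity_test",
    "cliff_significance",
    "quantile_interval_test",
    "per_iteration_check",
]


@dataclass(frozen=True)
class LandscapeTestResult:
    """Outcome of the KS landscape-validity test for one representation."""

    ks_statistic: float
    p_value: float
    alpha: float
    valid: bool
    n_observed: int
    n_random: int
    representation_name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.ks_statistic <= 1.0:
            raise ValueError("KS statistic must lie in [0, 1]")
        if self.valid != (self.p_value < self.alpha):
            raise ValueError("valid flag must equal (p_value < alpha)")


@dataclass(frozen=True)
class CliffSignificanceResult:
    """Per-pair activity-cliff significance plus the summary fractions.

    ``pairs`` columns: i, j, sali, above_threshold, n_greater, empirical_p,
    significant.  ``f_significant`` is None (NA) when the landscape test
    did not report a valid landscape.
    """

    pairs: pd.DataFrame
    threshold_value: float
    threshold_quantile: float
    f_magnitude: float | None
    f_significant: float | None
    n_iterations: int
    representation_name: str = ""

    @property
    def n_significant(self) -> int:
        return int(self.pairs["significant"].sum())

    @property
    def n_above_threshold(self) -> int:
        return int(self.pairs["above_threshold"].sum())


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS test: exact sup-distance D, asymptotic two-sided p.

    The accumulated null pools reach N·m(m-1)/2 values (millions at
    N = 1000), where only the asymptotic p-value is tractable; it also
    matches R's large-sample default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def landscape_validity_test(observed: SALIVector, pool: RandomSALIPool,
                            cfg: TestConfig, representation_name: str = "") -> LandscapeTestResult:
    """KS comparison of observed SALI values against the accumulated null."""
    obs = observed.defined_values
    if obs.size == 0:
        raise ValueError("all observed pairs are undefined; nothing to test")
    D, p = ks_two_sample(obs, pool.accumulated)
    return LandscapeTestResult(ks_statistic=D, p_value=p, alpha=cfg.alpha,
                               valid=bool(p < cfg.alpha),
                               n_observed=obs.size, n_random=pool.accumulated.size,
                               representation_name=representation_name)


def cliff_significance(observed: SALIVector, pool: RandomSALIPool,
                       landscape: LandscapeTestResult, cfg: TestConfig,
                       representation_name: str = "") -> CliffSignificanceResult:
    """Per-pair empirical p-values and the F_magnitude / F_significant summary.

    The magnitude threshold is the type-7 quantile (numpy/R default linear
    interpolation) of the defined observed SALI values at
    ``cfg.threshold_quantile``; pairs at or above it are magnitude cliffs.
    ``n_greater`` counts iterations whose random value at the same pair
    position is strictly greater than the observed value; empirical_p is
    exactly n_greater / N.
    """
    if pool.per_iteration.shape[1] != observed.n_pairs:
        raise ValueError("pool per-iteration storage does not match the observed pair layout")
    obs = observed.defined_values
    if obs.size == 0:
        raise ValueError("all observed pairs are undefined")
    threshold = float(np.quantile(obs, cfg.threshold_quantile))  # type 7
    N = pool.n_iterations

    vals = observed.values
    defined = observed.defined_mask
    above = defined & (vals >= threshold)
    with np.errstate(invalid="ignore"):
        greater = pool.per_iteration > vals[None, :]
    greater &= pool.per_iteration_mask  # undefined random entries never count
    n_greater = greater.sum(axis=0)
    emp_p = np.where(defined, n_greater / N, np.nan)
    significant = above & (emp_p < cfg.alpha)

    pairs = pd.DataFrame({
        "i": observed.pair_index[:, 0],
        "j": observed.pair_index[:, 1],
        "sali": vals,
        "defined": defined,
        "above_threshold": above,
        "n_greater": n_greater,
        "empirical_p": emp_p,
        "significant": significant,
    })
    n_def = int(defined.sum())
    f_mag = float(above.sum()) / n_def
    f_sig = float(significant.sum()) / n_def if landscape.valid else None
    if not landscape.valid:
        logger.info("landscape not valid (p=%.3g >= alpha=%.3g): F_significant = NA",
                    landscape.p_value, landscape.alpha)
    return CliffSignificanceResult(pairs=pairs, threshold_value=threshold,
                                   threshold_quantile=cfg.threshold_quantile,
                                   f_magnitude=f_mag, f_significant=f_sig,
                                   n_iterations=N,
                                   representation_name=representation_name)


def quantile_interval_test(observed_value: float, pair_pool, lo: float = 0.05,
                           hi: float = 0.95) -> bool:
    """Alternative per-pair formulation: significant iff the observed value
    falls outside the (lo, hi) type-7 quantile interval of the random SALI
    values for that pair."""
    pool = np.asarray(pair_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("pair_pool must be nonempty")
    if lo >= hi:
        raise ValueError("lo must be strictly less than hi")
    qlo, qhi = np.quantile(pool, [lo, hi])
    return bool(observed_value < qlo or observed_value > qhi)


def per_iteration_check(pool: RandomSALIPool, cfg: TestConfig) -> int:
    """Count iterations whose SALI values are KS-distinguishable (p < alpha)
    from the accumulated null distribution.

    Each iteration is compared against the full accumulated pool (itself
    included).  A pool of random landscapes should mostly be
    indistinguishable from its own accumulation; a high count signals that
    single scramblings are unrepresentative.
    """
    if pool.n_iterations == 0:
        raise ValueError("pool has no iterations")
    count = 0
    acc = pool.accumulated
    for k in range(pool.n_iterations):
        vals = pool.iteration_values(k)
        if vals.size == 0:
            continue
        if np.ptp(vals) == 0 and np.ptp(acc) == 0 and vals[0] == acc[0]:
            continue  # identical degenerate distributions: indistinguishable
        _, p = ks_two_sample(vals, acc)
        if p < cfg.alpha:
            count += 1
    return count
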