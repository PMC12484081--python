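"""Parametric blood-lead-level (BLL) distributions and summary-statistic fits.

A country's BLL distribution among 0-19-year-olds is represented by one of
three families:

degenerate
    point mass at the country mean — "everyone at the mean" baseline;
normal
    location/scale in µg/dL, truncated at 0 and renormalized wherever the
    distribution is integrated (BLL is non-negative);
lognormal
    parameters ``(mu, sigma)`` of log-BLL, the standard right-skewed model
    for biomarker concentrations.

Country input tables report only summaries (mean, exceedance shares above
5 and 10 µg/dL), so the log-normal family is fitted from those summaries in
closed form.  With ``z_k = Phi^{-1}(1 - p_k)``:

* mean + one exceedance: sigma solves ``sigma^2/2 - z*sigma + ln(t/m) = 0``
  and ``mu = ln(t) - sigma*z``.  When the mean lies below the threshold the
  quadratic has two admissible roots; a ``root_policy`` selects one.
* two exceedances: ``sigma = (ln t2 - ln t1)/(z2 - z1)``,
  ``mu = ln t1 - sigma*z1`` — exact two-quantile inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.special import ndtr, ndtri

from .errors import FeasibilityError

Family = Literal["degenerate", "normal", "lognormal"]

ROOT_POLICIES = ("smaller_sigma", "larger_sigma", "match_second_exceedance")


@dataclass(frozen=True)
class ExposureDistribution:
    """A parametric BLL distribution.

    ``params`` is ``(point,)`` for degenerate, ``(loc, scale)`` for normal
    and ``(mu, sigma)`` for lognormal.
    """

    family: Family
    params: tuple[float, ...]

    def __post_init__(self):
        if self.family == "degenerate":
            (point,) = self.params
            if point < 0:
                raise ValueError("degenerate point mass must be non-negative")
        elif self.family == "normal":
            loc, scale = self.params
            if loc < 0:
                raise ValueError("normal location must be non-negative")
            if scale <= 0:
                raise ValueError("normal scale must be positive")
        elif self.family == "lognormal":
            _, sigma = self.params
            if sigma <= 0:
                raise ValueError("lognormal sigma must be positive")
        else:
            raise ValueError(f"unknown family {self.family!r}")


def make_degenerate(mean: float) -> ExposureDistribution:
    """Point mass at ``mean`` µg/dL (the baseline exposure model)."""
    if mean < 0:
        raise ValueError(f"mean BLL must be non-negative, got {mean}")
    return ExposureDistribution("degenerate", (float(mean),))


def make_normal(loc: float, scale: float) -> ExposureDistribution:
    return ExposureDistribution("normal", (float(loc), float(scale)))


def make_lognormal(mu: float, sigma: float) -> ExposureDistribution:
    return ExposureDistribution("lognormal", (float(mu), float(sigma)))


def exceedance(dist: ExposureDistribution, threshold: float) -> float:
    """P(BLL > threshold) under ``dist``.

    For the normal family the distribution is truncated at 0 and
    renormalized, consistent with how it is integrated elsewhere.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if dist.family == "degenerate":
        return 1.0 if dist.params[0] > threshold else 0.0
    if dist.family == "normal":
        loc, scale = dist.params
        upper = ndtr((loc - threshold) / scale)  # P(X > t), untruncated
        mass_pos = ndtr(loc / scale)  # P(X > 0)
        return float(upper / mass_pos)
    mu, sigma = dist.params
    return float(ndtr(-(math.log(threshold) - mu) / sigma))


def distribution_mean(dist: ExposureDistribution) -> float:
    """Analytic mean of the family in µg/dL.

    The normal family returns its location (pre-truncation), matching the
    summary statistic it was constructed from.
    """
    if dist.family == "degenerate":
        return dist.params[0]
    if dist.family == "normal":
        return dist.params[0]
    mu, sigma = dist.params
    return math.exp(mu + sigma * sigma / 2.0)


def fit_lognormal_mean_exceedance(
    mean: float,
    p: float,
    threshold: float = 5.0,
    root_policy: str = "smaller_sigma",
    second_p: float | None = None,
    second_threshold: float = 10.0,
) -> ExposureDistribution:
    """Fit a log-normal matching a population mean and one exceedance share.

    Parameters
    ----------
    mean
        Population mean BLL in µg/dL.
    p
        Fraction with BLL above ``threshold``, strictly in (0, 1).
    threshold
        Exceedance threshold in µg/dL (5 by default, the US level of
        concern over 2012-2021).
    root_policy
        When ``mean < threshold`` the defining quadratic has two positive
        roots.  ``smaller_sigma`` (default) picks the less dispersed
        solution; ``larger_sigma`` the other; ``match_second_exceedance``
        picks the root whose implied exceedance at ``second_threshold`` is
        closest to ``second_p`` (falling back to ``smaller_sigma`` when no
        second share is available).

    Raises
    ------
    FeasibilityError
        If no log-normal satisfies both constraints; the message reports
        the admissible range of ``p`` for the given mean.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"exceedance p must be strictly in (0, 1), got {p}")
    if root_policy not in ROOT_POLICIES:
        raise ValueError(f"unknown root_policy {root_policy!r}")

    z = float(ndtri(1.0 - p))
    log_ratio = math.log(mean / threshold)
    disc = z * z + 2.0 * log_ratio
    if -1e-10 < disc < 0.0:
        disc = 0.0  # double root at the feasibility boundary: sigma = z
    if disc < 0:
        # Feasible iff z >= sqrt(2 ln(t/m)), i.e. p <= Phi(-sqrt(2 ln(t/m))).
        p_max = float(ndtr(-math.sqrt(-2.0 * log_ratio)))
        raise FeasibilityError(
            f"no log-normal with mean {mean} µg/dL has exceedance {p} above "
            f"{threshold} µg/dL; admissible p range is (0, {p_max:.6g}]"
        )
    sqrt_disc = math.sqrt(disc)
    roots = [z - sqrt_disc, z + sqrt_disc]
    positive = [s for s in roots if s > 0]
    if not positive:
        p_max = float(ndtr(-math.sqrt(max(-2.0 * log_ratio, 0.0))))
        raise FeasibilityError(
            f"constraints (mean={mean}, p={p}, threshold={threshold}) admit "
            f"no positive dispersion; admissible p range is (0, {p_max:.6g}]"
        )
    if len(positive) == 1:
        sigma = positive[0]
    elif root_policy == "smaller_sigma":
        sigma = min(positive)
    elif root_policy == "larger_sigma":
        sigma = max(positive)
    else:  # match_second_exceedance
        if second_p is None:
            sigma = min(positive)
        else:
            candidates = [
                ExposureDistribution("lognormal", (math.log(threshold) - s * z, s))
                for s in positive
            ]
            errs = [
                (exceedance(c, second_threshold) - second_p) ** 2 for c in candidates
            ]
            sigma = positive[errs.index(min(errs))]
    mu = math.log(threshold) - sigma * z
    return ExposureDistribution("lognormal", (mu, sigma))


def fit_lognormal_two_exceedances(
    p5: float,
    p10: float,
    t1: float = 5.0,
    t2: float = 10.0,
) -> ExposureDistribution:
    """Fit a log-normal from exceedance shares at two thresholds.

    Exact two-quantile inversion; reproduces both input shares to within
    the accuracy of the inverse-normal evaluation (~1e-15).
    """
    if not (t2 > t1 > 0):
        raise ValueError(f"need t2 > t1 > 0, got t1={t1}, t2={t2}")
    for label, val in (("p5", p5), ("p10", p10)):
        if not 0.0 < val < 1.0:
            raise ValueError(f"{label} must be strictly in (0, 1), got {val}")
    if p10 >= p5:
        raise ValueError(
            f"exceedance must decrease with threshold: p_gt{t2:g}={p10} "
            f">= p_gt{t1:g}={p5}"
        )
    z1 = float(ndtri(1.0 - p5))
    z2 = float(ndtri(1.0 - p10))
    sigma = (math.log(t2) - math.log(t1)) / (z2 - z1)
    mu = math.log(t1) - sigma * z1
    return ExposureDistribution("lognormal", (mu, sigma))
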