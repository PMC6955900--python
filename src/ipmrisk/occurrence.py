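"""Occurrence scores to operating-condition distributions.

An occurrence score maps to the standard deviation of a normal
distribution centered at the setpoint and truncated to the judged range:
sd = (occurrence / occurrence_max) * judged_width / 2.  The maximum score
therefore puts one standard deviation at the judged bounds; the minimum
concentrates the mass tightly around the setpoint.

RNG contract: every PP draws from its own substream derived
deterministically from (root seed, uo_id, pp_name), so leave-one-out
re-simulations can reuse identical draws (common random numbers).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .ra_model import ProcessParameterAssessment, ScoreScale

__all__ = ["OperatingDistribution", "occurrence_std", "operating_distribution",
           "sample", "expected_abs_deviation", "substream"]


@dataclass(frozen=True)
class OperatingDistribution:
    """Truncated normal over a PP's judged range (all values in PP units).

    ``uniform`` switches to a uniform distribution over the judged range —
    an alternative reading of the maximum-occurrence case; the truncated
    normal is the default model.
    """

    mean: float
    sd: float
    lower: float
    upper: float
    uniform: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"bounds [{self.lower}, {self.upper}] are not an interval")
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(f"mean {self.mean} outside [{self.lower}, {self.upper}]")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def pdf(self, x):
        if self.uniform:
            x = np.asarray(x, dtype=float)
            inside = (x >= self.lower) & (x <= self.upper)
            return np.where(inside, 1.0 / (self.upper - self.lower), 0.0)
        return self._frozen().pdf(x)

    def cdf(self, x):
        if self.uniform:
            return np.clip((np.asarray(x, dtype=float) - self.lower)
                           / (self.upper - self.lower), 0.0, 1.0)
        return self._frozen().cdf(x)


def occurrence_std(occurrence: int, o_max: int, judged_width: float) -> float:
    """Standard deviation implied by an occurrence score."""
    if not 1 <= occurrence <= o_max:
        raise ValueError(f"occurrence {occurrence} outside [1, {o_max}]")
    if judged_width <= 0:
        raise ValueError(f"judged_width must be > 0, got {judged_width}")
    return (occurrence / o_max) * judged_width / 2.0


def operating_distribution(
    pp: ProcessParameterAssessment,
    scale: ScoreScale,
    *,
    occurrence_reference: int | None = None,
    uniform_at_max: bool = False,
) -> OperatingDistribution:
    """Distribution of a PP's operating condition implied by its occurrence score."""
    o_ref = scale.o_max if occurrence_reference is None else occurrence_reference
    sd = occurrence_std(pp.occurrence, o_ref, pp.judged_width)
    uniform = uniform_at_max and pp.occurrence == o_ref
    return OperatingDistribution(mean=pp.setpoint, sd=sd,
                                 lower=pp.judged_lower, upper=pp.judged_upper,
                                 uniform=uniform)


def sample(dist: OperatingDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n operating conditions; every value lies within the judged range."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    if dist.uniform:
        return rng.uniform(dist.lower, dist.upper, size=n)
    a = (dist.lower - dist.mean) / dist.sd
    b = (dist.upper - dist.mean) / dist.sd
    return stats.truncnorm.rvs(a, b, loc=dist.mean, scale=dist.sd,
                               size=n, random_state=rng)


def expected_abs_deviation(dist: OperatingDistribution) -> float:
    """E|x - mean| under the operating distribution, by adaptive quadrature.

    Splitting the integral at the mean avoids the kink of |x - mean|.
    Serves as the analytic oracle for Monte Carlo means and as the fast
    ranking mode's expectation.
    """
    if dist.uniform:
        w = dist.upper - dist.lower
        lo, up = dist.mean - dist.lower, dist.upper - dist.mean
        return (lo * lo + up * up) / (2.0 * w)
    pdf = dist.pdf
    left, _ = integrate.quad(lambda x: (dist.mean - x) * pdf(x),
                             dist.lower, dist.mean, epsabs=1e-12, limit=200)
    right, _ = integrate.quad(lambda x: (x - dist.mean) * pdf(x),
                              dist.mean, dist.upper, epsabs=1e-12, limit=200)
    return left + right


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic child generator for a labelled entity (e.g. one PP).

    The stream depends only on the root seed and the labels, so removing
    other entities from a simulation leaves this stream unchanged.
    """
    keys = [zlib.crc32(str(lbl).encode("utf-8")) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))
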