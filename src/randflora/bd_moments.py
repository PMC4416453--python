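"""Closed-form birth-death quantities and method-of-moments rate estimators.

Under a constant-rate birth-death process with speciation rate lambda and
extinction rate mu (net diversification r = lambda - mu, extinction fraction
epsilon = mu / lambda), the number of extant descendants of a single lineage
that survives to time t is geometric with parameter

    beta = (e^{r t} - 1) / (e^{r t} - epsilon),

and the probability that the lineage has died out by t is alpha = epsilon *
beta.  Everything in this module derives from that law:

* ``stem_rate`` / ``crown_rate`` invert the survival-conditioned expected
  clade size to estimate r from an observed (clade size, clade age) pair at a
  fixed epsilon -- the "method-of-moments" estimators used throughout the
  Rand Flora meta-analysis, evaluated at epsilon in {0, 0.5, 0.9}.
* ``prob_geq_stem`` / ``prob_geq_crown`` give the tail probability of
  observing a clade at least as large as the one seen, given a background
  rate -- the clade-size probability test.
* ``diversity_limits`` inverts those tails to produce confidence envelopes of
  expected diversity through time, against which observed clades are mapped.

Rates are natural-log based, in events per lineage per Myr; ages in Myr.
The critical process (epsilon = 1) and declining diversity (r < 0) are
rejected explicitly rather than clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "BDParams",
    "GeometricLaw",
    "RateEstimate",
    "DiversityEnvelope",
    "two_taxon_adjustment",
    "stem_rate",
    "crown_rate",
    "geometric_law",
    "expected_stem_diversity",
    "expected_crown_diversity",
    "stem_tail",
    "crown_tail",
    "crown_pmf",
    "prob_geq_stem",
    "prob_geq_crown",
    "diversity_limits",
]

Basis = Literal["crown", "stem"]

#: clade sizes below which r*t is treated as zero in series expansions
_RT_TINY = 1e-12


def _check_epsilon(epsilon: float) -> float:
    epsilon = float(epsilon)
    if not 0.0 <= epsilon < 1.0:
        raise DomainError(
            f"epsilon={epsilon!r} outside [0, 1); the critical process "
            "(epsilon = 1) is not supported"
        )
    return epsilon


def _check_age(t: float, name: str = "t") -> float:
    t = float(t)
    if not t > 0.0 or not math.isfinite(t):
        raise DomainError(f"{name}={t!r} must be a positive, finite age in Myr")
    return t


@dataclass(frozen=True)
class BDParams:
    """Birth-death process parameters.

    ``lambda_`` and ``mu`` are per-lineage rates (events / lineage / Myr);
    ``r = lambda_ - mu`` and ``epsilon = mu / lambda_`` are derived and kept
    consistent by construction.
    """

    lambda_: float
    mu: float

    def __post_init__(self) -> None:
        if not self.lambda_ > 0.0:
            raise DomainError(f"lambda_={self.lambda_!r} must be > 0")
        if self.mu < 0.0:
            raise DomainError(f"mu={self.mu!r} must be >= 0")
        if self.mu >= self.lambda_:
            # epsilon = 1 excluded for all estimator uses
            _check_epsilon(self.mu / self.lambda_)

    @property
    def r(self) -> float:
        return self.lambda_ - self.mu

    @property
    def epsilon(self) -> float:
        return self.mu / self.lambda_

    @classmethod
    def from_net(cls, r: float, epsilon: float) -> "BDParams":
        """Build from net rate and extinction fraction: lambda = r/(1-eps)."""
        epsilon = _check_epsilon(epsilon)
        if not r > 0.0:
            raise DomainError(f"r={r!r} must be > 0 to recover (lambda, mu)")
        lam = r / (1.0 - epsilon)
        return cls(lambda_=lam, mu=lam * epsilon)


@dataclass(frozen=True)
class GeometricLaw:
    """Survival-conditioned clade-size law at horizon ``t``.

    ``beta`` is the geometric parameter of the size of a surviving lineage's
    descendance; ``alpha = epsilon * beta`` is the probability the lineage has
    gone extinct by ``t``.
    """

    beta: float
    alpha: float
    t: float


@dataclass(frozen=True)
class RateEstimate:
    """A method-of-moments net diversification rate, with its inputs."""

    r_hat: float
    basis: Basis
    epsilon: float
    n: float
    t: float


@dataclass(frozen=True)
class DiversityEnvelope:
    """Confidence bounds on clade size through time at a reference rate."""

    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    conf: float
    epsilon: float
    r_ref: float
    basis: Basis
    reference: str | None = field(default=None)

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise DomainError("envelope lower bound exceeds upper bound")


def two_taxon_adjustment(n: float) -> float:
    """Return 2.01 for a two-taxon clade, ``n`` unchanged otherwise.

    The crown estimator is identically zero at n = 2 for every epsilon, so
    two-taxon clades are assigned a diversity of 2.01 to obtain a nonzero
    (if tiny) rate.  Idempotent: 2.01 passes through.
    """
    if n < 1:
        raise DomainError(f"n={n!r} must be >= 1")
    return 2.01 if n == 2 else n


def stem_rate(n: float, t: float, epsilon: float) -> RateEstimate:
    """Method-of-moments net rate from clade size and stem age.

    Inverts the survival-conditioned expected size of a single stem lineage,
    n = (e^{r t} - epsilon)/(1 - epsilon), giving

        r_hat = ln(n (1 - epsilon) + epsilon) / t.
    """
    epsilon = _check_epsilon(epsilon)
    t = _check_age(t)
    n = float(n)
    if n < 1.0:
        raise DomainError(f"n={n!r} must be >= 1 for a surviving stem lineage")
    r_hat = math.log(n * (1.0 - epsilon) + epsilon) / t
    return RateEstimate(r_hat=r_hat, basis="stem", epsilon=epsilon, n=n, t=t)


def _crown_bracket(n: float, epsilon: float) -> float:
    """The bracketed term of the crown estimator (equals n when epsilon=0)."""
    disc = n * (n * epsilon**2 - 8.0 * epsilon + 2.0 * n * epsilon + n)
    if disc < 0.0:  # cannot occur for n >= 2, eps in [0,1); guard roundoff
        disc = 0.0
    return (
        0.5 * n * (1.0 - epsilon**2)
        + 2.0 * epsilon
        + 0.5 * (1.0 - epsilon) * math.sqrt(disc)
    )


def crown_rate(n: float, t: float, epsilon: float) -> RateEstimate:
    """Method-of-moments net rate from clade size and crown age.

    With no extinction this is (ln n - ln 2)/t; for epsilon > 0 the
    extinction-corrected form

        r_hat = (1/t) * [ln( n(1-eps^2)/2 + 2 eps
                             + (1-eps)/2 * sqrt(n (n eps^2 - 8 eps + 2 n eps + n)) )
                          - ln 2]

    is used, which reduces to the simple form as eps -> 0 and is identically
    zero at n = 2 (use :func:`two_taxon_adjustment` first for such clades).
    """
    epsilon = _check_epsilon(epsilon)
    t = _check_age(t)
    n = float(n)
    if n < 2.0:
        raise DomainError(
            f"n={n!r} must be >= 2 for a crown clade (two-taxon clades: "
            "apply two_taxon_adjustment first)"
        )
    if epsilon == 0.0:
        r_hat = (math.log(n) - math.log(2.0)) / t
    else:
        r_hat = (math.log(_crown_bracket(n, epsilon)) - math.log(2.0)) / t
    return RateEstimate(r_hat=r_hat, basis="crown", epsilon=epsilon, n=n, t=t)


def geometric_law(r: float, epsilon: float, t: float) -> GeometricLaw:
    """Survival-conditioned geometric size parameters at horizon ``t``."""
    epsilon = _check_epsilon(epsilon)
    r = float(r)
    t = float(t)
    if r < 0.0:
        raise DomainError(
            f"r={r!r} < 0: declining-diversity regime unsupported"
        )
    if t < 0.0:
        raise DomainError(f"t={t!r} must be >= 0")
    rt = r * t
    if rt < _RT_TINY:
        beta = rt / (1.0 - epsilon)  # series limit: (e^x-1)/(e^x-eps) ~ x/(1-eps)
    else:
        em1 = math.expm1(rt)
        beta = em1 / (em1 + 1.0 - epsilon)
    return GeometricLaw(beta=beta, alpha=epsilon * beta, t=t)


def expected_stem_diversity(r: float, epsilon: float, t: float) -> float:
    """Expected size of a surviving stem lineage: (e^{rt} - eps)/(1 - eps)."""
    law = geometric_law(r, epsilon, t)  # argument validation
    rt = float(r) * float(t)
    del law
    return math.expm1(rt) / (1.0 - epsilon) + 1.0


def expected_crown_diversity(r: float, epsilon: float, t: float) -> float:
    """Clade size whose crown-basis rate estimate equals ``r``.

    The exact functional inverse of :func:`crown_rate` in n: for epsilon = 0
    this is 2 e^{rt} in closed form; for epsilon > 0 it is recovered by
    monotone root-finding on [2, +inf).
    """
    geometric_law(r, epsilon, t)  # argument validation
    r = float(r)
    t = float(t)
    rt = r * t
    if rt < _RT_TINY:
        return 2.0
    if epsilon == 0.0:
        return 2.0 * math.exp(rt)

    def f(n: float) -> float:
        return crown_rate(n, t, epsilon).r_hat - r

    lo = 2.0
    hi = 20.0 * math.exp(rt) + 10.0
    while f(hi) < 0.0:  # expand bracket; r_hat is increasing in n
        hi *= 4.0
        if hi > 1e300:
            raise DomainError("expected_crown_diversity bracket expansion failed")
    if f(lo) > 0.0:
        return 2.0  # r below the two-founder floor; zero-growth limit
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def _check_size_integer(n: float, minimum: int) -> int:
    if isinstance(n, float) and not n.is_integer():
        raise DomainError(
            f"n={n!r} must be an integer: tail probabilities are defined on "
            "integer clade sizes"
        )
    n_int = int(n)
    if n_int < minimum:
        raise DomainError(f"n={n!r} must be >= {minimum}")
    return n_int


def stem_tail(n: int, beta: float) -> float:
    """P(N >= n | one founder survives) = beta^(n-1)."""
    n = _check_size_integer(n, 1)
    if not 0.0 <= beta < 1.0:
        raise DomainError(f"beta={beta!r} outside [0, 1)")
    return beta ** (n - 1)


def crown_tail(n: int, beta: float) -> float:
    """P(N >= n | both crown founders survive).

    The clade size is the sum of two independent survival-conditioned
    geometric sizes, with tail beta^(n-2) * [(n-1) - (n-2) beta].
    """
    n = _check_size_integer(n, 2)
    if not 0.0 <= beta < 1.0:
        raise DomainError(f"beta={beta!r} outside [0, 1)")
    return beta ** (n - 2) * ((n - 1) - (n - 2) * beta)


def crown_pmf(k: int, beta: float) -> float:
    """P(N = k | both crown founders survive) = (k-1)(1-beta)^2 beta^(k-2)."""
    k = _check_size_integer(k, 2)
    return (k - 1) * (1.0 - beta) ** 2 * beta ** (k - 2)


def prob_geq_stem(n: int, r: float, epsilon: float, t: float) -> float:
    """Probability of a clade of size >= n from a surviving stem lineage."""
    law = geometric_law(r, epsilon, t)
    return stem_tail(n, law.beta)


def prob_geq_crown(n: int, r: float, epsilon: float, t: float) -> float:
    """Probability of a clade of size >= n given both crown founders survive."""
    law = geometric_law(r, epsilon, t)
    return crown_tail(n, law.beta)


def _invert_stem_tail(q: float, beta: float) -> float:
    # continuous n >= 1 solving beta^(n-1) = q
    if beta <= 0.0:
        return 1.0
    return 1.0 + math.log(q) / math.log(beta)


def _invert_crown_tail(q: float, beta: float) -> float:
    # continuous n >= 2 solving beta^(n-2) ((n-1) - (n-2) beta) = q
    if beta <= 0.0:
        return 2.0

    def g(x: float) -> float:
        return beta ** (x - 2.0) * ((x - 1.0) - (x - 2.0) * beta) - q

    lo = 2.0
    if g(lo) <= 0.0:  # q >= 1: the tail never exceeds 1, bound is the floor
        return 2.0
    hi = 4.0
    while g(hi) > 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise DomainError("crown tail inversion failed to bracket")
    return float(brentq(g, lo, hi, xtol=1e-10, rtol=1e-12))


def diversity_limits(
    r_ref: float,
    epsilon: float,
    times: Sequence[float],
    conf: float = 0.95,
    basis: Basis = "crown",
) -> DiversityEnvelope:
    """Confidence envelope of expected diversity through time.

    At each time point the lower bound solves tail(n) = (1 + conf)/2 and the
    upper bound solves tail(n) = (1 - conf)/2 in the continuous relaxation of
    the basis-appropriate tail law, so the envelope contains the expectation
    everywhere.  Bounds are real-valued (>= 2 crown, >= 1 stem); observed
    integer clade sizes are compared against them directly.
    """
    if basis not in ("crown", "stem"):
        raise DomainError(f"basis={basis!r} must be 'crown' or 'stem'")
    if not 0.0 < conf < 1.0:
        raise DomainError(f"conf={conf!r} outside (0, 1)")
    times_arr = np.asarray(times, dtype=float)
    if times_arr.size == 0:
        raise DomainError("times grid is empty")
    if np.any(np.diff(times_arr) <= 0.0):
        raise DomainError("times grid must be strictly increasing")
    if times_arr[0] < 0.0:
        raise DomainError("times must be >= 0")

    q_lo = (1.0 + conf) / 2.0
    q_hi = (1.0 - conf) / 2.0
    invert = _invert_crown_tail if basis == "crown" else _invert_stem_tail
    lower = np.empty_like(times_arr)
    upper = np.empty_like(times_arr)
    for i, t in enumerate(times_arr):
        beta = geometric_law(r_ref, epsilon, t).beta if t > 0 else 0.0
        lower[i] = invert(q_lo, beta)
        upper[i] = invert(q_hi, beta)
    return DiversityEnvelope(
        times=times_arr,
        lower=lower,
        upper=upper,
        conf=conf,
        epsilon=epsilon,
        r_ref=float(r_ref),
        basis=basis,
    )
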