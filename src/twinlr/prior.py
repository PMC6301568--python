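"""Branching-process model of the pre-twinning de novo mutation frequency.

The zygote carries two identical alleles at an autosomal site.  Each of the
first ``m`` post-fertilization cell division cycles doubles the number of
homologous chromosomes, and cycle ``k`` synthesises ``2**(k+1)`` nascent
chromosomes, each an equally likely mutation target.  A mutation struck in
cycle ``k`` therefore segregates at frequency ``1/2**(k+1)`` among the
chromosomes present after cycle ``m``.  Conditioning on a single mutational
event somewhere in the first ``m`` cycles yields a discrete frequency
distribution with closed-form mean and variance; matching those two moments
to a beta distribution gives the prior that is later updated with somatic
NGS read counts.

The casework default is ``m = 5.5``: monozygotic twinning happens within the
first week of pregnancy at roughly one division per day, with about a quarter
of splits preceding blastocyst formation at day 5.  The moment formulas are
smooth in ``m`` and are evaluated at this non-integer value; the pmf itself
counts discrete cycles and requires integer ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencyPMF",
    "PriorSpec",
    "pretwinning_pmf",
    "expected_frequency",
    "frequency_variance",
    "beta_from_moments",
    "default_prior",
    "average_pretwinning_divisions",
]


def _check_m(m: float) -> float:
    m = float(m)
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"number of pre-twinning divisions must be > 0, got {m}")
    return m


@dataclass(frozen=True)
class FrequencyPMF:
    """Distribution of a pre-twinning variant's chromosome frequency.

    Entry ``k`` (1-based) is the event that the mutation arose in division
    cycle ``k``: frequency ``1/2**(k+1)`` with probability
    ``2**(k-1) / (2**m - 1)``.
    """

    m: int
    frequencies: np.ndarray
    probabilities: np.ndarray

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.frequencies.tolist(), self.probabilities.tolist()))

    def mean(self) -> float:
        return float(np.dot(self.frequencies, self.probabilities))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.dot(self.frequencies**2, self.probabilities) - mu**2)


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior (alpha, beta) for the pre-twinning variant frequency.

    ``m`` records the division count the prior was derived from and
    ``rounded`` whether the casework rounding (0.5, 15) was applied.
    """

    alpha: float
    beta: float
    m: float = 5.5
    rounded: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"beta prior requires alpha > 0 and beta > 0, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def pretwinning_pmf(m: int) -> FrequencyPMF:
    """Exact frequency distribution of a single pre-twinning mutation.

    Parameters
    ----------
    m : int
        Number of completed pre-twinning division cycles.  Must be a positive
        integer: the pmf enumerates discrete cycles (use
        :func:`expected_frequency` / :func:`frequency_variance` for real m).
    """
    _check_m(m)
    if float(m) != int(m):
        raise ValueError(
            f"the pre-twinning pmf is defined for integer division counts only, got m={m}; "
            "the moment formulas accept real m"
        )
    m = int(m)
    k = np.arange(1, m + 1)
    freqs = 0.5 ** (k + 1)
    probs = 2.0 ** (k - 1) / (2.0**m - 1.0)
    return FrequencyPMF(m=m, frequencies=freqs, probabilities=probs)


def expected_frequency(m: float) -> float:
    """Mean pre-twinning variant frequency, ``m / (2**(m+2) - 4)``."""
    m = _check_m(m)
    return m / (2.0 ** (m + 2) - 4.0)


def frequency_variance(m: float) -> float:
    """Variance of the pre-twinning variant frequency.

    ``[ (2**m - 1)/2**(m-1) - m**2/(2**m - 1) ] / (16 * (2**m - 1))``;
    for integer ``m`` this equals the variance of :func:`pretwinning_pmf`.
    """
    m = _check_m(m)
    pow_m = 2.0**m
    return ((pow_m - 1.0) / 2.0 ** (m - 1.0) - m**2 / (pow_m - 1.0)) / (16.0 * (pow_m - 1.0))


def beta_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters matching a given mean and variance.

    Solves ``mean = a/(a+b)`` and ``variance = ab / ((1+a+b)(a+b)^2)``:
    ``a + b = mean(1-mean)/variance - 1``, then ``a = mean*(a+b)``.

    Raises ``ValueError`` when ``variance >= mean*(1-mean)`` (no beta
    distribution has that much spread for the given mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if variance <= 0.0:
        raise ValueError(f"variance must be > 0, got {variance}")
    if variance >= mean * (1.0 - mean):
        raise ValueError(
            f"no beta distribution has mean {mean} and variance {variance}: "
            "variance must be < mean*(1-mean)"
        )
    total = mean * (1.0 - mean) / variance - 1.0
    return mean * total, (1.0 - mean) * total


def default_prior(exact: bool = False, m: float = 5.5) -> PriorSpec:
    """Casework beta prior for the pre-twinning variant frequency.

    With ``exact=False`` (default) returns the rounded prior (0.5, 15) used
    throughout the reference casework tables; with ``exact=True`` returns the
    full-precision moment match for the given ``m`` (alpha=0.4895,
    beta=15.2652 at m=5.5).
    """
    if not exact and m == 5.5:
        return PriorSpec(alpha=0.5, beta=15.0, m=5.5, rounded=True)
    alpha, beta = beta_from_moments(expected_frequency(m), frequency_variance(m))
    return PriorSpec(alpha=alpha, beta=beta, m=m, rounded=False)


def average_pretwinning_divisions() -> float:
    """Weighted average of division counts over reported twinning times.

    A quarter of monozygotic splits precede blastocyst formation (days 1-5),
    the rest occur on days 6-7, at roughly one division cycle per day:
    ``0.25*mean(1..5) + 0.75*mean(6,7)``.  Note this evaluates to 5.625; the
    casework convention rounds it to 5.5, which is what :func:`default_prior`
    uses.
    """
    return 0.25 * (1 + 2 + 3 + 4 + 5) / 5 + 0.75 * (6 + 7) / 2
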