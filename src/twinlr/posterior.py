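"""Beta-binomial updating of the variant-frequency prior with NGS read counts.

Conjugacy makes the update trivial: observing ``v`` variant and ``w``
wild-type reads in a twin's somatic sample turns the Beta(alpha, beta) prior
on the germline variant frequency into Beta(alpha + v, beta + w).  The two
summaries the casework needs are the posterior mean (paternity scenario) and
the upper-tail probability beyond the Sanger detection limit (sperm-donor
scenario).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import beta as _beta_dist

from .prior import PriorSpec

__all__ = ["ReadCount", "PosteriorBeta", "update", "posterior_mean", "exceedance_probability"]


@dataclass(frozen=True)
class ReadCount:
    """Variant (v) and wild-type (w) read counts at one site in one sample.

    ``v = w = 0`` is permitted and leaves the prior unchanged.  A single
    variant read in the non-alleged twin is treated as real pre-twinning
    signal, never filtered as sequencing error: that choice is conservative
    towards the alleged carrier.
    """

    v: int
    w: int

    def __post_init__(self) -> None:
        if self.v != int(self.v) or self.w != int(self.w):
            raise ValueError(f"read counts must be integers, got v={self.v}, w={self.w}")
        if self.v < 0 or self.w < 0:
            raise ValueError(f"read counts must be non-negative, got v={self.v}, w={self.w}")

    def __add__(self, other: "ReadCount") -> "ReadCount":
        return ReadCount(self.v + other.v, self.w + other.w)

    @property
    def depth(self) -> int:
        return self.v + self.w


@dataclass(frozen=True)
class PosteriorBeta:
    """Updated beta parameters for one variant's frequency in one twin."""

    alpha: float
    beta: float
    twin_label: str = ""
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"posterior beta requires alpha > 0 and beta > 0, got ({self.alpha}, {self.beta})"
            )


def update(prior: PriorSpec, reads: ReadCount, twin_label: str = "", variant_id: str = "") -> PosteriorBeta:
    """Conjugate update: Beta(alpha, beta) -> Beta(alpha + v, beta + w)."""
    return PosteriorBeta(
        alpha=prior.alpha + reads.v,
        beta=prior.beta + reads.w,
        twin_label=twin_label,
        variant_id=variant_id,
    )


def posterior_mean(post: PosteriorBeta) -> float:
    """E(p) = alpha / (alpha + beta)."""
    return post.alpha / (post.alpha + post.beta)


def exceedance_probability(post: PosteriorBeta, threshold: float) -> float:
    """P(p >= threshold) under Beta(alpha, beta).

    One minus the regularized incomplete beta function I_threshold(alpha,
    beta), computed by ``scipy.stats.beta.sf``.  The distribution is
    continuous, so P(p >= t) and P(p > t) coincide.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return float(_beta_dist.sf(threshold, post.alpha, post.beta))
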