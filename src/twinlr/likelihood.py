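"""Per-variant likelihoods, likelihood ratios and posterior odds for a case.

A case weighs two mutually exclusive, exhaustive hypotheses: the
germline-derived cells (a sperm sample, or the paternal complement of a
child) came from twin A, or from twin B.  Third-party donors are assumed to
have been excluded beforehand (e.g. by STR profiling) and are not modelled.

For each discriminating variant k the germline frequency in twin X follows
the updated beta posterior.  The scenario fixes the likelihood:

* sperm sample — the variant was called by Sanger sequencing in the sample,
  whose detection limit is about a 5% allele fraction, so
  ``lik_k(X) = P(p_X,k >= threshold)`` (conservative: detection is certain
  once the frequency clears the limit);
* paternity — inheritance of the variant is a single draw from the father's
  germline, so ``lik_k(X) = E(p_X,k)``.

Variants on different chromosomes are treated as independent and their LRs
multiplied; same-chromosome pairs are still multiplied but flagged with a
warning, since no joint model is available.  Variants not observed in the
germline-derived sample are uninformative and excluded by default; setting
``use_absence=True`` instead scores them with the complement likelihood
(1 - detection likelihood), a principled extension that departs from the
reference casework behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .posterior import PosteriorBeta, ReadCount, exceedance_probability, posterior_mean, update
from .prior import PriorSpec, default_prior

__all__ = [
    "VariantObservation",
    "ScenarioConfig",
    "VariantResult",
    "CaseResult",
    "variant_likelihood",
    "variant_lr",
    "combine_case",
    "is_discriminating",
]

SCENARIOS = ("sperm", "paternity")


@dataclass(frozen=True)
class VariantObservation:
    """One discriminating variant: read counts in both twins + germline call.

    ``germline_detected`` is the Sanger call in the sperm sample (sperm
    scenario) or the inherited/not-inherited flag for the child (paternity
    scenario).
    """

    variant_id: str
    chromosome: str
    reads_A: ReadCount
    reads_B: ReadCount
    germline_detected: bool

    def __post_init__(self) -> None:
        if not str(self.chromosome):
            raise ValueError(f"variant {self.variant_id!r}: chromosome label must be non-empty")

    def swapped(self) -> "VariantObservation":
        """The same observation with the twin labels exchanged."""
        return VariantObservation(
            variant_id=self.variant_id,
            chromosome=self.chromosome,
            reads_A=self.reads_B,
            reads_B=self.reads_A,
            germline_detected=self.germline_detected,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "sperm"
    detection_threshold: float = 0.05
    prior: PriorSpec = field(default_factory=default_prior)
    prior_odds: float = 1.0
    use_absence: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError(f"detection threshold must lie in (0, 1), got {self.detection_threshold}")
        if self.prior_odds <= 0:
            raise ValueError(f"prior odds must be > 0, got {self.prior_odds}")


@dataclass(frozen=True)
class VariantResult:
    variant_id: str
    lik_A: float
    lik_B: float
    lr: float
    informative: bool = True


@dataclass(frozen=True)
class CaseResult:
    per_variant: list[VariantResult]
    combined_lr: float
    posterior_odds: float
    warnings: list[str]


def is_discriminating(obs: VariantObservation, max_trace_reads: int = 1) -> bool:
    """Whether a variant is discriminating in the casework sense.

    Called in the germline-derived sample, and present at no more than trace
    level (default: at most one variant read) in the somatic tissue of one of
    the twins.  Variants at similar frequency in both twins carry little
    evidence either way.
    """
    return obs.germline_detected and min(obs.reads_A.v, obs.reads_B.v) <= max_trace_reads


def variant_likelihood(post: PosteriorBeta, config: ScenarioConfig, detected: bool) -> float:
    """Likelihood of one germline observation under one twin's posterior."""
    if config.scenario == "sperm":
        lik = exceedance_probability(post, config.detection_threshold)
    else:
        lik = posterior_mean(post)
    return lik if detected else 1.0 - lik


def variant_lr(lik_A: float, lik_B: float) -> float:
    """Likelihood ratio lik_A / lik_B for one variant."""
    if lik_B == 0.0:
        raise ValueError(
            "likelihood under hypothesis B is exactly zero; the beta model never yields 0 "
            "for thresholds < 1 — check the posterior parameters"
        )
    return lik_A / lik_B


def combine_case(observations: list[VariantObservation], config: ScenarioConfig) -> CaseResult:
    """Per-variant likelihoods and LRs, their product, and posterior odds.

    The combined LR is the product of the informative per-variant LRs
    (independence across chromosomes); posterior odds = prior odds x
    combined LR.  Warnings flag same-chromosome variant pairs and, under the
    default configuration, variants excluded for absence from the
    germline-derived sample.
    """
    if not observations:
        raise ValueError("a case needs at least one variant observation")

    warnings: list[str] = []
    seen: dict[str, str] = {}
    for obs in observations:
        if obs.chromosome in seen:
            warnings.append(
                f"variants {seen[obs.chromosome]!r} and {obs.variant_id!r} share chromosome "
                f"{obs.chromosome}; their independence is assumed but not modelled — "
                "the combined LR may overstate the evidence"
            )
        else:
            seen[obs.chromosome] = obs.variant_id

    per_variant: list[VariantResult] = []
    combined_lr = 1.0
    for obs in observations:
        if not obs.germline_detected and not config.use_absence:
            warnings.append(
                f"variant {obs.variant_id!r} not detected in the germline-derived sample; "
                "not informative under the default model and excluded from the LR"
            )
            per_variant.append(
                VariantResult(obs.variant_id, math.nan, math.nan, 1.0, informative=False)
            )
            continue
        post_A = update(config.prior, obs.reads_A, "A", obs.variant_id)
        post_B = update(config.prior, obs.reads_B, "B", obs.variant_id)
        lik_A = variant_likelihood(post_A, config, obs.germline_detected)
        lik_B = variant_likelihood(post_B, config, obs.germline_detected)
        lr = variant_lr(lik_A, lik_B)
        per_variant.append(VariantResult(obs.variant_id, lik_A, lik_B, lr))
        combined_lr *= lr

    return CaseResult(
        per_variant=per_variant,
        combined_lr=combined_lr,
        posterior_odds=config.prior_odds * combined_lr,
        warnings=warnings,
    )
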