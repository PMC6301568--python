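"""Forward simulation of early embryonic mutation, twinning and sequencing.

This module is both the synthetic-case generator and the brute-force oracle
for the closed-form branching-process model:

1. a de novo mutation is placed in one of the first ``m_pre`` division
   cycles by picking a nascent chromosome uniformly (cycle k contributes
   ``2**(k+1)`` targets), so a cycle-k mutation leaves ``2**(m_pre - k)``
   carrier cells among the ``2**m_pre`` pre-twinning cells;
2. the twinning split allocates the cells to the two embryos by sampling
   *without* replacement (half/half hypergeometric) — the minimal model
   consistent with a physical partition of a finite cell mass;
3. each twin then grows ``m_post`` further divisions with carriers breeding
   true and no new mutations, which leaves carrier fractions unchanged
   (the LR model being validated assumes all discriminating variants are
   pre-twinning, and the simulator matches that model);
4. sequencing draws variant reads binomially at the configured depth with
   success probability half the carrier-cell fraction (heterozygous
   autosomal site: one of the two homologous chromosomes per carrier cell);
5. the germline-derived sample is read out from the donor twin's lineage,
   and the variant is called detected when its chromosome fraction clears
   the Sanger limit.

A Polya-urn simulator is included as the independent route to the beta
limit law that motivates the prior family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import VariantObservation
from .posterior import ReadCount
from .prior import pretwinning_pmf

__all__ = [
    "SimulationConfig",
    "SimulatedCase",
    "simulate_pretwinning_frequency",
    "simulate_polya_urn",
    "simulate_twin_case",
    "simulate_cases",
]

_CHROMOSOMES = [str(i) for i in range(1, 23)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated case.

    Defaults mirror the casework setting: five completed pre-twinning
    divisions (the integer pmf closest to the 5.5-division average), ten
    post-twinning divisions (within the <=15-division window before germline
    segregation), 100x coverage (middle of the reported 75-125x range), the
    5% Sanger detection limit, and two candidate discriminating variants per
    case.
    """

    m_pre: int = 5
    m_post: int = 10
    coverage_mean: int = 100
    threshold: float = 0.05
    n_variants: int = 2
    seed: int = 0
    error_rate: float = 0.0
    poisson_depth: bool = False

    def __post_init__(self) -> None:
        if self.m_pre < 1:
            raise ValueError(f"m_pre must be >= 1, got {self.m_pre}")
        if self.m_post < 0:
            raise ValueError(f"m_post must be >= 0, got {self.m_post}")
        if self.coverage_mean < 1:
            raise ValueError(f"coverage_mean must be >= 1, got {self.coverage_mean}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.n_variants < 1:
            raise ValueError(f"n_variants must be >= 1, got {self.n_variants}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must lie in [0, 1), got {self.error_rate}")


@dataclass(frozen=True)
class SimulatedCase:
    """A synthetic twin case with full ground truth.

    ``true_freqs_A`` / ``true_freqs_B`` are the germline variant-chromosome
    fractions per twin (half the carrier-cell fraction); ``mutation_cycles``
    records each variant's origin cycle, which conditions the cross-twin
    frequency correlation.
    """

    observations: list[VariantObservation]
    true_donor: str
    true_freqs_A: list[float]
    true_freqs_B: list[float]
    mutation_cycles: list[int] = field(default_factory=list)
    carriers_presplit: list[int] = field(default_factory=list)
    carriers_A: list[int] = field(default_factory=list)


def simulate_pretwinning_frequency(m: int, n_reps: int, seed: int) -> np.ndarray:
    """Empirical pre-twinning frequency distribution (brute-force oracle).

    Each replicate picks one nascent chromosome uniformly among the
    ``sum(2**(k+1) for k in 1..m)`` synthesised in the first ``m`` cycles and
    returns the frequency ``1/2**(k+1)`` of the cycle it belongs to.
    Returns the array of sampled frequencies.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(seed)
    targets = 2.0 ** (np.arange(1, m + 1) + 1)  # mutation targets per cycle
    cycles = rng.choice(np.arange(1, m + 1), size=n_reps, p=targets / targets.sum())
    return 0.5 ** (cycles + 1)


def simulate_polya_urn(
    black: int, white: int, n_draws: int, seed: int, n_reps: int = 1
) -> float | np.ndarray:
    """Final black-ball fraction after Polya draw-and-reinforce sampling.

    Each draw returns the ball plus one more of the same colour, the scheme
    whose limiting composition is Beta(black, white).  With ``n_reps > 1``
    the replicates run vectorised and an array is returned.
    """
    if black < 1 or white < 1:
        raise ValueError(f"urn must start with >= 1 ball of each colour, got ({black}, {white})")
    if n_draws < 0:
        raise ValueError(f"n_draws must be >= 0, got {n_draws}")
    rng = np.random.default_rng(seed)
    b = np.full(n_reps, black, dtype=np.int64)
    total = black + white
    for step in range(n_draws):
        drew_black = rng.random(n_reps) < b / (total + step)
        b += drew_black
    frac = b / (total + n_draws)
    return float(frac[0]) if n_reps == 1 else frac


def _sequence(rng: np.random.Generator, allele_freq: float, config: SimulationConfig) -> ReadCount:
    depth = (
        int(rng.poisson(config.coverage_mean)) if config.poisson_depth else config.coverage_mean
    )
    e = config.error_rate
    p_read = allele_freq * (1.0 - e) + (1.0 - allele_freq) * e
    v = int(rng.binomial(depth, p_read)) if depth > 0 else 0
    return ReadCount(v=v, w=depth - v)


def simulate_twin_case(
    config: SimulationConfig, true_donor: str = "A", rng: np.random.Generator | None = None
) -> SimulatedCase:
    """Simulate one twin case; deterministic given the config's seed."""
    if true_donor not in ("A", "B"):
        raise ValueError(f"true_donor must be 'A' or 'B', got {true_donor!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    pmf = pretwinning_pmf(config.m_pre)
    n_cells = 2**config.m_pre
    half = n_cells // 2

    observations: list[VariantObservation] = []
    freqs_A: list[float] = []
    freqs_B: list[float] = []
    cycles: list[int] = []
    carriers_pre: list[int] = []
    carriers_A_list: list[int] = []
    for i in range(config.n_variants):
        k = int(rng.choice(np.arange(1, config.m_pre + 1), p=pmf.probabilities))
        carriers = 2 ** (config.m_pre - k)
        carriers_A = int(rng.hypergeometric(carriers, n_cells - carriers, half))
        carriers_B = carriers - carriers_A
        # post-twinning growth is deterministic doubling: fractions persist
        frac_A = carriers_A / half
        frac_B = carriers_B / half
        allele_A = frac_A / 2.0  # heterozygous site: variant on 1 of 2 homologues
        allele_B = frac_B / 2.0

        reads_A = _sequence(rng, allele_A, config)
        reads_B = _sequence(rng, allele_B, config)
        donor_allele = allele_A if true_donor == "A" else allele_B
        detected = donor_allele >= config.threshold

        observations.append(
            VariantObservation(
                variant_id=f"var{i + 1}",
                chromosome=_CHROMOSOMES[i % len(_CHROMOSOMES)],
                reads_A=reads_A,
                reads_B=reads_B,
                germline_detected=detected,
            )
        )
        freqs_A.append(allele_A)
        freqs_B.append(allele_B)
        cycles.append(k)
        carriers_pre.append(carriers)
        carriers_A_list.append(carriers_A)

    return SimulatedCase(
        observations=observations,
        true_donor=true_donor,
        true_freqs_A=freqs_A,
        true_freqs_B=freqs_B,
        mutation_cycles=cycles,
        carriers_presplit=carriers_pre,
        carriers_A=carriers_A_list,
    )


def simulate_cases(
    config: SimulationConfig, n_cases: int, true_donor: str = "A"
) -> list[SimulatedCase]:
    """Simulate a batch of cases from a single seeded stream."""
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    rng = np.random.default_rng(config.seed)
    return [simulate_twin_case(config, true_donor=true_donor, rng=rng) for _ in range(n_cases)]
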