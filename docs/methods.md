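# Methods

## The statistical problem

Two monozygotic twins, A and B, are the only candidate donors of a sample of
germline-derived cells (a sperm sample, or the paternal genomic complement
of a child); third parties are assumed excluded beforehand, e.g. by STR
profiling, so the two hypotheses are exhaustive. The data per discriminating
variant k are (i) NGS read counts (v, w) of the variant and wild-type
alleles in each twin's somatic tissue and (ii) a presence/absence call for
the variant in the germline-derived sample. The deliverable is the
likelihood ratio LR = Π_k lik_k(A)/lik_k(B) and the posterior odds.

## Prior on the germline variant frequency

The frequency trajectory of a mutant cell lineage under repeated division is
a reinforcement process of the Polya-urn type, whose limiting composition is
beta-distributed; this motivates a beta family for the frequency p of a
pre-twinning variant. The prior's two parameters come from the branching
process of early cleavage: cycle k of the first m divisions synthesises
2^(k+1) nascent chromosomes, each an equally likely mutation target, and a
cycle-k mutation ends at frequency 1/2^(k+1). Conditioning on a single
mutational event in the first m cycles,

    P(p = 1/2^(k+1)) = 2^(k−1) / (2^m − 1),   k = 1..m,

with closed-form mean m/(2^(m+2) − 4) and variance
[(2^m − 1)/2^(m−1) − m²/(2^m − 1)] / (16(2^m − 1)). The pmf requires
integer m; the moment formulas are smooth and are evaluated at the casework
value m = 5.5. That value reflects twinning times: about a quarter of MZ
splits precede blastocyst formation (days 1–5), the rest occur on days 6–7,
at roughly one division per day. The arithmetic weighted average of those
division counts is 5.625 (`average_pretwinning_divisions` exposes it); the
casework convention rounds to 5.5, and the default follows the convention so
that every downstream constant matches the published casework tables.

Moment matching at m = 5.5 gives α = 0.4895, β = 15.2652 at full precision.
Rounding the moments to three significant figures first gives β = 15.2510;
both are within the rounding slack of the casework values α ≈ 0.5, β ≈ 15,
which `default_prior()` returns (the full-precision match via
`default_prior(exact=True)`). The rounded prior is the default because all
published casework numbers use it.

## Updating and scenario likelihoods

Beta-binomial conjugacy: reads (v, w) in twin X give p ~ Beta(α + v, β + w).
A single variant read in the non-alleged twin is deliberately treated as
real pre-twinning signal rather than sequencing error — conservative toward
the alleged carrier. Two scenario likelihoods:

* **Sperm sample.** Sanger sequencing detects alleles down to about a 5%
  fraction, so a confirmed call is scored as lik_k(X) = P(p_X,k ≥ 0.05),
  the upper tail of the regularized incomplete beta function
  (`scipy.stats.beta.sf`; the distribution is continuous so ≥ and >
  coincide). Accuracy contract: 1e-6 relative, verified against adaptive
  quadrature of an independently coded beta density.
* **Paternity.** Inheritance of the variant is one draw from the father's
  germline, so lik_k(X) = E(p_X,k) = α_X,k/(α_X,k + β_X,k).

Variants absent from the germline-derived sample are uninformative under
this conditioning and are excluded (LR factor 1) with a warning. The
complement score 1 − lik is available behind `use_absence=True`
(`--use-absence`), a principled extension that is off by default so default
output matches the published casework behaviour. Variants sharing a
chromosome are still multiplied — no joint model exists for them — but a
prominent warning flags the independence caveat. LRs are reported at full
precision alongside a 3-significant-figure rendering (scientific below
0.01, else four decimals) and nearest-integer LRs, mirroring the casework
presentation.

A known boundary of the model: likelihoods built from updated beta priors
alone drive the LR to infinity as coverage grows, because recurrent
germline mutation in the non-alleged twin is not modelled. At current
casework coverage (75–125×) the beta likelihoods dominate the germline
mutation rate by orders of magnitude, so the simplification is harmless;
it is out of scope here, as are sequencing-error models, mixture samples
and three-hypothesis cases.

## The forward simulator

`simulate_twin_case` emulates the generative story the closed forms
describe, and only that story:

1. the mutation cycle is drawn from the pmf above (`m_pre` integer
   divisions, default 5 — the integer pmf nearest the 5.5 casework
   average), leaving 2^(m_pre−k) carrier cells among 2^m_pre;
2. the twinning split allocates cells half/half by sampling **without**
   replacement (hypergeometric carrier allocation) — the minimal model
   consistent with a physical partition of the cell mass;
3. each twin grows `m_post` further divisions (default 10, within the
   ≤15-division window before germline segregation) with carriers breeding
   true and no new mutations, so fractions persist;
4. sequencing draws variant reads Binomial(depth, f/2) at fixed depth
   (default 100×, mid-range of casework coverage), where f is the
   carrier-cell fraction — a heterozygous autosomal site carries the
   variant on one of two homologues, matching the observed 3:1 to 1:1
   wild-type:variant read ratios; a Poisson-depth option and a per-read
   error rate exist for robustness studies, both off by default so output
   is deterministic given the seed;
5. the germline call is detected iff the donor twin's variant-chromosome
   fraction reaches the Sanger threshold (default 0.05). Default
   `n_variants=2` per case, the casework-typical count.

What it does **not** emulate: post-twinning mutation, the primordial-germ-
cell bottleneck and germline/soma divergence (the germline is read from the
same post-split lineage as the soma), spatial clustering of carrier cells,
recurrent mutation, and sequencing error by default. Passing tests
therefore validate the internal consistency of the model and code under
the model's own assumptions; they do not show that real germline/soma
pairs behave this way.

### Correlation across the split

Conditional on the mutation's origin cycle, the carrier total is fixed and
the without-replacement split makes the twins' carrier fractions exactly
anti-correlated — "high in one twin implies low in the other". Marginally,
over random origin cycles, the correlation is strongly *positive*, because
an early mutation is frequent in both twins while a late one is rare in
both. The simulator records the origin cycle, and the anti-correlation
invariant is tested per cycle; stating it marginally would be false.

## Numerical and design choices

* Exceedance probabilities: `scipy.stats.beta.sf`; independent test oracle
  via `scipy.integrate.quad` on a `math.lgamma`-based density.
* Combined LR: plain float product of per-variant LRs (cases have few
  variants; no underflow risk), which keeps permutation and label-swap
  identities tight.
* Degenerate inputs: v = w = 0 returns the prior; thresholds 0 and 1 give
  tails 1 and 0; `beta_from_moments` rejects variance ≥ mean(1−mean);
  the pmf rejects non-integer m with a message pointing to the moment
  formulas; large m underflows E(p) gracefully to 0.
* The reference casework table contains two internal inconsistencies: the
  (α=25.5, β=80) row prints a posterior mean of 0.2537, which equals
  α/(α+w) rather than α/(α+β) ≈ 0.2417, and the w=75 rows print β = 80
  although the stated rule gives 15 + 75 = 90 (the printed likelihood
  columns are consistent with β = 80). The implementation follows the
  stated formulas exactly; tests verify the likelihood columns from the
  printed (α, β) and document the anomalous mean as irreproducible.
* Study sizes in the stochastic tests — 2×10⁵ replicates for the pmf
  oracle, 10⁴ urn replicates of 2000 draws, 1000 simulated cases at 100×
  coverage — were chosen to put Monte-Carlo error well inside the asserted
  bounds while keeping the suite fast; all stochastic tests run under the
  fixed seed 20180756, and the end-to-end donor-recovery rate observed
  under that seed (134/134 eligible cases favouring the true donor) is
  recorded in the test docstring.
* Input is a flat TSV, not VCF: the casework datum is a pair of read counts
  per twin plus an external germline flag, which VCF does not naturally
  carry; a VCF importer is out of scope for v1.
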