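# Methods

This note records the models behind each module, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Pedigree model and kinship

A pedigree is a validated DAG: referenced parents must exist, no
individual may be its own ancestor, no id may serve as both father and
mother, and children must be born strictly after their parents when both
years are known. Cycle detection runs before birth-year validation so a
self-parent is reported as the structural error it is.

Kinship uses the standard recursion — founders unrelated,
φ(i,i) = (1 + φ(father_i, mother_i))/2,
φ(i,j) = (φ(father_i, j) + φ(mother_i, j))/2 recursing on whichever
individual lies deeper in the pedigree (so it cannot be an ancestor of
the other), with memoization. The test suite checks it against a
gene-dropping Monte-Carlo oracle (unique founder alleles dropped
100,000 times) and verifies symmetry and positive semidefiniteness of
the kinship matrix.

Nuclear-unit decomposition assigns every individual exactly one unit as
child (trio, duo, or singleton by how many of its parents are
available) and replicates parents across the units of their children;
`replicate_index` counts the replications. Under the `sequenced_only`
flag an unsequenced parent is treated as absent, which is also how
excluded samples are handled late in the pipeline: the cohort is
re-decomposed with exclusions marked unsequenced so trios degrade to
duos or singletons instead of disappearing.

## Gene-dropping simulator

Founder haplotype alleles are i.i.d. Bernoulli(founder alt frequency)
per site; each meiosis recombines between adjacent sites with the
Haldane (no-interference) fraction r = (1 − e^(−2d/100))/2 for an
inter-site distance of d cM, with r = 1/2 across chromosome boundaries.
Haldane was chosen as the simplest defensible map function; nothing
downstream is sensitive to interference. Genetic positions come from
piecewise-linear interpolation of STR-style anchor tables (terminal
slopes extended outward, floored at 0 cM, monotonicity enforced).

Sequencing is modeled at the allele-count level: per sample per site,
depth ~ Poisson(planned coverage) — matching the observed continuum of
achieved depths rather than fixed tiers — and each read reports the
allele of a uniformly chosen haplotype, flipped with the per-base error
probability (default 0.005; the down-sampling experiments use 0.0075,
inside the 0.5–1 % band typical of short-read platforms). Reads are
exchangeable counts; alignment, indels, multi-allelic variation and sex
chromosomes are not modeled. Multi-allelic/multi-nucleotide records
exist only as literal decoy rows injected for the first QC filter to
remove.

An individual with an unknown single parent receives that gamete as a
fresh draw from the founder pool. Gene-drop output is
Mendelian-consistent by construction, which is what makes downstream
inconsistency rates interpretable as calling error.

What passing tests on this generator do *not* show: robustness to
alignment artifacts, reference bias, batch effects, or real LD
structure — the simulator's LD comes entirely from pedigree descent and
the map, not from population history.

## Coverage design

The greedy ranker works on the sequenced subgraph. It keeps a growing
offspring-set of unique child ids; the first pick is the individual
with the most sequenced direct (one-generation) children, and each
later pick maximizes the number of *new* ids added. Ties go to the
older individual (unknown birth year after known), then to the smaller
id — a total, deterministic order. Rank 1 is sequenced deepest;
`assign_tiers` cuts the ranking into high/medium/low at the requested
sizes (defaults 30×/5×/1×).

"Direct descendants" is read as immediate children: adding a ranked
individual's children (not all descendants) to the offspring-set is the
only reading under which later marginal gains change the ranking, and
the candidate-set/offspring-set bookkeeping is treated as one set.

Down-sampling thins one sample's reads to a target mean depth: new
depth ~ Binomial(dp, target/achieved), new alt count hypergeometric
given the retained depth — jointly equivalent to retaining each read
independently. `evaluate_scheme` thins a trio per role, re-calls
genotypes, and reports the trio Mendelian-inconsistency rate (over
sites where all three calls are non-missing) and per-role concordance
with the full-depth calls, averaged over replicates (default 3).

Two metric subtleties are deliberate:

* The metrics use the *single-sample* maximum-posterior calls, not the
  trio-refined calls: the joint refiner assigns zero probability to
  illegal configurations, so refined calls would make the
  Mendelian-inconsistency comparison identically zero.
* The inconsistency rate conditions on sites where all three members
  are called, so thinning a parent also shifts the conditioning set
  toward well-covered sites. This makes the one-deep-parent scheme
  *systematically slightly better* than parents-medium (a selection
  effect of the metric, reproducible across independent trios). The
  scheme-equivalence test is therefore one-sided — intermediate is not
  worse than parents-medium, and its gap is small relative to the
  parents-low penalty — which is also the substantive claim.

## Genotype calling and refinement

Single-sample calling: genotype likelihoods are Binomial(depth, p) with
p ∈ {e, 1/2, 1−e} for base error e, a Hardy–Weinberg prior at a
supplied allele frequency, maximum-posterior call, missing at zero
depth. Trio refinement maximizes the joint posterior over the 27
configurations (9 for duos, with the untransmitted allele drawn from
the population frequency); members missing at a site are marginalized
with flat likelihoods. Child phase is taken from transmitted alleles
where determinable; unresolvable phase puts the alt allele in the
paternal slot, a fixed tie rule that keeps output deterministic.
Population-scale LD phasing/imputation (haplotype reference panels) is
intentionally out of scope; the trio joint posterior is the defined
stand-in.

Zero-depth sites of family-connected individuals are *imputed* by the
joint model — this is what the refinement step exists to do, and
without it any cohort with a 1× tier (~37 % zero-depth sites per
sample) would lose essentially every site to the final 5 % missingness
ceiling. Individuals with no trio/duo membership keep missing calls at
zero depth: there is no information to impute from.

Consensus haplotypes: an individual refined in k units contributes 2k
haplotypes; they are split into two clusters (one haplotype per pair
per cluster) minimizing total within-cluster Hamming distance — exact
enumeration of the 2^(k−1) orientations for k ≤ 6, greedy seeded by the
first pair beyond — and each cluster collapses by per-locus majority,
ties becoming missing. At the panel level a vote tie falls back to the
individual's own child-unit call: with k = 2 (one child-unit, one
parent-unit) every disagreement is a 2-vs-2 tie, and without the
fallback low-coverage samples would be ~37 % missing after refinement.

## QC cascades

Filter order is frozen and matters (the 5-bp proximity filter sees only
sites alive when it runs); cascades are deterministic and idempotent,
and each ledger asserts conservation on construction. Numerical
conventions, chosen where the rules leave room and held fixed:

* "twofold range of the global median" is the closed interval
  [m/2, 2m] of per-site cumulative depth; boundary values are retained.
* "within 5 bp" means |Δpos| ≤ 5 on the same chromosome; both members
  of a close pair are removed.
* MAF is computed from called genotypes (allele counts over non-missing
  calls), never dosages; the sample set for the Stage-2 MAF filter is
  configurable and defaults to all samples present.
* Heterozygote excess is strict (> 0.6), the Mendelian budget inclusive
  (≥ 5 error units), missingness strict (> 50 %, > 5 %).
* The alignment-caller row of the Stage-2 ledger is a structural
  pass-through (removed = 0): no alignment layer exists here.

Stage 4 masks the child call of each remaining sporadic
Mendelian-error unit before applying the missingness ceiling, so the
masking feeds the final filter exactly as ordered.

## Relatedness and parentage

IBD uses the method-of-moments IBS decomposition with sample allele
frequencies from the LD-pruned panel (small-sample bias corrections
omitted). Estimates are clamped to the simplex; at desk-scale panel
sizes this leaves real noise — empirically π̂ has sd ≈ 0.03 for
unrelated pairs at ~1,500 pruned SNPs even with perfect genotypes, with
a small upward clamp bias. Three consequences are handled explicitly:

* Pairs sharing fewer than 100 usable sites are flagged unreliable.
* Sample *exclusion* demands stronger evidence: pairs with fewer than
  500 shared sites are ignored by `flag_sample_issues`
  (σ(π̂) ≈ 0.03·√(1500/n), so ~500 sites keep 3σ inside the default
  0.15 discordance threshold). At realistic marker counts the floor
  never binds.
* A few samples can still trip the ≥ 10-discordant-pairs default by
  chance; the guaranteed property is a false-positive rate below 5 % of
  samples on a clean colony, not zero flags.

Parentage requires all applicable rules jointly: π̂ within [0.35, 0.65]
and Z0 < 0.1 (artifact defaults standing in for "parent-offspring-level
sharing"), a behavioral record match for mothers and a housing record
match for fathers (skipped, and the call marked provisional, when the
tables are absent), and a 4–15-year age gap — a candidate younger than
the child can never be assigned. Two surviving same-sex candidates
leave the slot unresolved. Record tables are plain (child, candidate)
compatibility TSVs; the original behavioral semantics reduce to boolean
compatibility because no richer records exist for synthetic colonies.

## Mapping panels

Thinning uses the same sliding-window pruner as sample QC (windows and
shifts counted in SNPs: 50/20). r² is the squared Pearson correlation
of genotype dosages (composite LD) over pairwise-complete observations;
monomorphic sites have undefined correlation and are never pruned. The
linkage set is obtained by thinning the *association* set at r² ≤ 0.4,
which guarantees the nesting linkage ⊆ association; one-shot pruning at
two thresholds does not (removals at the stricter threshold can rescue
sites the looser run discarded). A retained set is always re-verified
by an exhaustive within-window pair scan.

Panel summaries report per chromosome: SNP count, density per Mb over
the retained span (last minus first retained position), max and mean
inter-SNP gap, mean pairwise r² within consecutive five-marker windows,
and mean heterozygosity; single-SNP chromosomes report gaps as
unavailable.

## Pipeline and problem sizes

`run_pipeline` executes the stages in study order from one YAML config,
derives every stage seed deterministically from the master seed, and
writes a manifest of output hashes; same config ⇒ byte-identical
outputs. All thresholds default to the printed study values (25 %,
10 %, 50 %, 5 bp, ≥ 5 Mendel errors, 0.6 heterozygosity, 5 % missing,
r² 0.1/0.4/0.9, window 50, shift 20).

Default problem sizes are desk-scale choices: a 30-founder,
3-generation colony (~100–140 members) on 29 autosomes of 125 sites and
115 cM each. Twenty-nine chromosomes at primate-scale map length give
the relatedness stage enough independent markers for stable π̂; the
generator's own default genome (4 × 5,000 sites, 100 cM) remains
available for dense-LD work such as the thinning experiments. The
down-sampling experiment simulates 20 independent trios of ~2,200 sites
at 30× with 0.75 % base error. These sizes keep a full run within tens
of seconds while leaving every qualitative contrast resolvable.

## Known limitations

* Refinement ignores LD between sites (per-site joint posterior); no
  reference-panel imputation or recombination-aware phasing.
* The method-of-moments IBD estimator is noisy and upward-biased at
  small panel sizes (quantified above); likelihood-based relationship
  inference is out of scope.
* Composite (dosage) r² is used throughout; haplotype-phase r² is not
  computed.
* The simulator's missingness arises only from zero depth; real
  missingness from alignment masking or liftover is not modeled, and
  regional chunking of the refinement is not reproduced.
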