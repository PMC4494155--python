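# pedpanel

Pedigree-aware sequencing design and SNP-panel construction for large
breeding colonies, with a gene-dropping simulator that makes every stage
testable end to end.

## The problem

Genotyping a deep multigenerational pedigree (hundreds of related
animals descended from a few dozen founders) by whole-genome sequencing
is cheapest when coverage is spent unevenly: a few ancestors sequenced
deep anchor the haplotypes, and Mendelian transmission lets shallow
(~1×) descendants be called accurately. Turning raw depth-skewed calls
into analysis-ready association and linkage marker panels then takes a
chain of bespoke steps:

1. **Coverage design** — rank colony members by how many sequenced
   direct descendants their genotypes would constrain (greedy set-cover
   on the offspring-set), and cut the ranking into high (~30×), medium
   (~4–6×), and low (~1×) tiers. A down-sampling harness quantifies the
   design intuition: thinning *both parents* of a trio to 1× inflates
   the trio Mendelian-inconsistency rate far more than thinning the
   child.
2. **Genotype refinement** — break the pedigree into trio/duo units
   (replicating shared parents), maximize the joint posterior over the
   27 trio genotype configurations per site (Hardy–Weinberg founder
   priors × Mendelian transmission × binomial read likelihoods), then
   reconcile each individual's replicated haplotypes into two consensus
   haplotypes by Hamming-distance bipartition and per-locus majority
   vote.
3. **Variant QC cascades** — ordered filter ledgers: a discovery screen
   in the high-coverage samples (biallelic SNVs, cumulative-depth
   window, MAF ≥ 25 %, zero missingness, 5-bp proximity), a
   pedigree-wide screen (MAF ≥ 10 %, ≤ 50 % missing, per-site Mendelian
   error budget, heterozygote excess), and a final screen (error
   masking, 5 % missingness ceiling). Every cascade returns a
   conservation-checked ledger (start − Σ removed = end).
4. **Sample QC and parentage** — LD-prune to near-independence
   (r² ≤ 0.1, 50-SNP windows, shift 20), estimate pairwise IBD by the
   method-of-moments IBS decomposition (Z0, Z1, Z2, π̂ = Z1/2 + Z2),
   flag samples whose π̂ contradicts the pedigree kinship 2φ, and assign
   parentage to individuals of unknown ancestry by four joint rules
   (parent-offspring-level sharing with a unique same-sex candidate,
   behavioral record for mothers, housing record for fathers, 4–15-year
   age gap).
5. **Mapping panels** — LD-thin the QC'd panel at r² ≤ 0.9
   (association-scale) and r² ≤ 0.4 (linkage-scale, nested inside the
   association set), drop sites failing a pedigree-wide Mendelian check,
   interpolate genetic positions from STR anchor markers, and summarize
   density, gaps, windowed r², and heterozygosity per chromosome.

No real colony data is required: the `simulate` module gene-drops
founder haplotypes through a simulated pedigree with Haldane
recombination on a genetic map, then models sequencing as Poisson depth
and error-prone binomial allele counts, so the truth behind every
downstream number is known.

## Worked example

```python
from pedpanel import simulate, coverage
from pedpanel.pedigree import Individual, Pedigree

ped = Pedigree([
    Individual("F1", "M", 1980),
    Individual("M1", "F", 1981),
    Individual("C1", "U", 1990, father="F1", mother="M1"),
])
unit = ped.decompose_units()[0]      # trio (F1, M1) -> C1
print(ped.kinship("F1", "C1"))       # 0.25

sites = simulate.default_sites(n_chromosomes=2, sites_per_chromosome=1000, seed=1)
gmap = simulate.default_genetic_map(sites)
truth = simulate.gene_drop(ped, sites, gmap, seed=2)
reads = simulate.simulate_reads(truth, mean_depth=30.0, base_error=0.0075, seed=3)

for label, scheme in [
    ("parents 1x / child 4x", {"father": 1, "mother": 1, "child": 4}),
    ("parents 4x / child 1x", {"father": 4, "mother": 4, "child": 1}),
    ("father 4x / others 1x", {"father": 4, "mother": 1, "child": 1}),
]:
    m = coverage.evaluate_scheme(unit, reads, scheme, replicates=3, seed=4,
                                 base_error=0.0075)
    print(f"{label}: Mendelian inconsistency rate "
          f"{m.mendelian_inconsistency_rate:.3f}")
```

prints

```
0.25
parents 1x / child 4x: Mendelian inconsistency rate 0.120
parents 4x / child 1x: Mendelian inconsistency rate 0.081
father 4x / others 1x: Mendelian inconsistency rate 0.077
```

Reading: with deep parents, the child can be thinned to 1× at modest
cost, and deep-sequencing only the father performs about as well as
deep-sequencing both parents — the observation that justifies a
parents-first hierarchical coverage budget.

The full pipeline (simulate → rank → call → refine → filter → IBD →
thin → summarize) runs from one config:

```bash
pedpanel run --config run.yaml        # or: python -m pedpanel.cli ...
pedpanel rank --ped ped.tsv --n-high 16 --n-medium 407 -o plan.tsv
pedpanel thin --vcf stage2.vcf --r2 0.4 -o linkage_sites.tsv
```

Each run writes per-stage VCFs, filter ledgers, an all-pairs IBD table,
panel summaries, and a `manifest.json` of output hashes; reruns with the
same seed are byte-identical.

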