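# episwarm

Swarm-search detection of SNP–SNP interactions (epistasis) in case-control
genotype data.

Complex-disease risk is often driven by *joint*, non-additive effects of
several single nucleotide polymorphisms (SNPs) — pairs of loci that are nearly
uninformative individually but strongly associated with disease together.
Exhaustively testing all C(M, K) combinations of M SNPs is infeasible at GWAS
scale, so `episwarm` searches the space of K-subsets of SNP indices with a
discrete particle swarm optimizer augmented by three devices:

- **opposition-based learning (OBL)** — every candidate position
  (SNP₁, …, SNP_K) is evaluated together with its mirror image
  (1 + M − SNP₁, …, 1 + M − SNP_K), widening exploration and resisting
  premature convergence;
- **a dynamic inertia weight** — per dimension,
  W = (max *count* − *count*[pSNP]) / (max *count* − min *count*), where
  *count* tallies how often each SNP has appeared in the particles' personal
  bests; rarely chosen SNPs keep exploring (W → 1), repeatedly chosen ones
  exploit (W → 0);
- **a post-procedure** — after the last iteration, all K-subsets of the
  `top_n` most frequently selected SNPs are scanned exhaustively and the
  answer is upgraded if any beats the swarm's best.

The fitness of a SNP set X against the binary phenotype Y is the plug-in
mutual information in bits,

    MI(X; Y) = H(X) + H(Y) − H(X, Y),

computed from the 3^K × 2 genotype/phenotype contingency table; for a binary
phenotype 0 ≤ MI ≤ 1 bit. Association strength is additionally reported as a
likelihood-ratio (G) test p-value, G = 2n·MI (nats), with the degrees of
freedom reduced for empty genotype cells — the natural test companion of an
MI fitness.

The package also ships a penetrance-model case-control **simulator**
(Hardy-Weinberg genotypes, retrospective sampling of the causal loci from
P(g|case) ∝ f(g)·P(g) and P(g|control) ∝ (1−f(g))·P(g), null SNPs with MAF ~
U[0.05, 0.5]) covering the classic two-locus benchmark archetypes — a
both-minor-allele threshold model, an inverse-marginal model, and
zero-marginal xor/zz heterozygosity-parity models — plus a **power
benchmark** (Power 1: exact recovery with no false positives; Power 2:
average fraction of causal SNPs in the reported set) comparing the
opposition-based variant against a plain PSO baseline at matched settings.

## Worked example

Simulate one dataset with a planted pair (both-minor-allele threshold model,
MAF 0.4, prevalence 0.10; 1000 cases, 1000 controls, 100 SNPs), then search
it:

```sh
episwarm simulate --model threshold_both_minor --alpha 1 --theta 8 \
    --maf 0.4 --prevalence 0.1 --n-cases 1000 --n-controls 1000 \
    --snps 100 --seed 11 --out demo
cat demo/dataset.tsv.truth     # SNP37  SNP39  <- planted causal pair
episwarm detect demo/dataset.tsv --particles 100 --iterations 100 \
    --seed 42 --out demo
```

which prints

```
variant        : ioblpso
SNP set        : SNP37, SNP39 (indices 37, 39)
MI interaction : 0.2013 bits
MI SNP37       : 0.0912 bits
MI SNP39       : 0.1046 bits
G-test p-value : 2.321e-115
```

The search recovered exactly the planted pair. The interaction MI (0.20 bits)
well exceeds either single-SNP MI (0.09–0.10 bits) — the joint signal is what
makes the pair detectable — and the G-test rejects independence decisively.
`--runs 20` aggregates repeated seeded searches into a table of distinct
answers with detection counts and Bonferroni-corrected p-values;
`episwarm evaluate spec.yaml` runs a full power study from a YAML experiment
spec.

The same functionality is available as a library:

```python
from episwarm import PenetranceModel, SwarmConfig, run, simulate

model = PenetranceModel.from_json("tests/fixtures/strong_effect_model.json")
dataset, truth = simulate(model, n_cases=1000, n_controls=1000, n_snps=100, seed=11)
result = run(dataset, SwarmConfig(p=100, t=100, seed=42))
print(result.summary())
```

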