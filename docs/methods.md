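# Methods

## Search problem and fitness

Given a case-control dataset of M SNPs coded {0,1,2} (minor-allele count
class) and a binary phenotype Y, the task is to find the K-subset of SNP
indices whose joint genotype is most associated with Y. The objective is the
plug-in mutual information in bits,

    MI(X; Y) = H(X) + H(Y) − H(X, Y),

estimated from the empirical 3^K × 2 contingency table with the convention
0·log 0 = 0. Bits are a declared convention (the estimator is base-agnostic);
they make the binary-phenotype bound exactly H(Y) ≤ 1. Two useful exact
properties of the plug-in estimator are relied on throughout the tests: MI is
non-negative, and it can only grow when a SNP is added to the set
(monotonicity of empirical MI), so an interaction's MI always dominates its
members' single-SNP MI. The estimator is biased upward on small samples; no
bias correction or shrinkage is applied, since the optimizer only compares
combinations within one dataset at a fixed K, where the bias is comparable
across candidates.

MI order invariance is made *exact* (not merely up to float round-off) by
canonically sorting the indices before tallying; the swarm caches fitness per
sorted index set for the same reason.

The reported p-value is the likelihood-ratio G-test of independence between
genotype cells and phenotype: G = 2n·MI (nats), df = (non-empty genotype
rows − 1) × (non-empty phenotype columns − 1). A table whose individuals all
share one genotype cell (df = 0) carries no evidence and returns p = 1. The
multi-run report adds a Bonferroni factor C(M, K), the number of tests an
exhaustive scan would perform. The G-test is a design choice: it is the
likelihood-ratio twin of the MI fitness, so the statistic and the fitness are
two scalings of the same quantity; no claim is made that it reproduces
p-values computed by other software with other tests.

## Optimizer

A particle is an ordered K-tuple of distinct SNP indices (a position in
{1,…,M}^K) plus a real velocity per dimension in [1−M, M−1]. One iteration
of the opposition-based variant (`ioblpso`):

1. **Inertia.** Per dimension k, W = (max c − c[pSNP_k]) / (max c − min c)
   from the counter vector c, which accumulates the contents of all P
   personal bests once per iteration (initialization counts as the first
   increment, so Σ_m c_m = t·P·K after t increments). When all counters are
   equal the ratio is 0/0 and the static weight (0.65) is used — this happens
   at most in the earliest iterations.
2. **Velocity.** v′ = W·v + C1·r1·(pbest − pos) + C2·r2·(gbest − pos), with
   r1, r2 ~ U(0,1) drawn independently per particle, dimension and iteration
   (standard PSO practice). A component leaving [1−M, M−1] is replaced by a
   uniform draw from that interval rather than clamped, preserving search
   diversity at the boundary.
3. **Position.** pos′ = int(pos + v′) if the real-valued sum lies in [1, M],
   else a uniform random integer in [1, M]; `int` truncates toward zero.
   Since a SNP combination is a set, a dimension that duplicates an earlier
   one is resampled uniformly from the indices not already present.
4. **Personal best with opposition.** The position, its mirror
   1 + M − pos (an involution on {1,…,M}, duplicate-free because it is a
   bijection), and the previous personal best are compared by fitness. Exact
   ties keep the previous personal best, then prefer the position over its
   mirror — a stability rule; the optimum is unaffected.
5. **Global best.** Replaced only on *strict* improvement by the best
   personal best (ties keep the incumbent; equal personal bests resolve to
   the lowest particle index). Opposite positions that were not adopted as a
   personal best do not feed the counters — only pbest contents do.
6. **Post-procedure** (after the last iteration): SNPs are ranked by counter
   (descending, ties by ascending index), the top `top_n` are scanned
   exhaustively over all C(top_n, K) subsets, and the answer is upgraded on
   strict improvement. The reported fitness therefore never falls below the
   final global best, and with top_n = M the answer is the global optimum by
   construction.

The plain baseline (`pso`) is the same loop with a fixed inertia weight, no
opposition step in the personal-best comparison, and no post-procedure.

Every particle's position *and* opposite position are evaluated every
iteration (2·P·T fitness calls per run, plus C(top_n, K) at the end); the
memoized cache makes revisits free. A single seeded NumPy generator drives
all draws in a fixed documented order, so runs are bit-reproducible; repeated
runs and experiment batches use `SeedSequence.spawn` child streams.

### Defaults

| parameter | default | meaning |
|---|---|---|
| P | 100 | particles |
| T | 100 | iterations |
| K | 2 | interaction order |
| C1, C2 | 2.0 | cognitive / social acceleration |
| static inertia | 0.65 | baseline PSO weight; dynamic-weight fallback |
| top_n | 10 | post-procedure candidate-set size |

P = T = 100, C1 = C2 = 2 and W = 0.65 are the standard benchmark settings for
this family of methods; top_n = 10 keeps the final exhaustive scan at
C(10,2) = 45 evaluations.

## Simulator

A disease model is a penetrance table f(g) over the 3^K causal genotypes,
causal MAFs, and a prevalence. Tables are built by scaling a non-negative
*shape* so that Σ_g f(g)·P_HWE(g) equals the target prevalence exactly
(checked to 1e-9; infeasible if any scaled penetrance would exceed 1).
Sampling is retrospective: causal genotype tuples for cases come from
P(g|case) = f(g)·P(g)/prevalence and for controls from
P(g|control) = (1−f(g))·P(g)/(1−prevalence), whose prevalence-weighted
mixture recovers the HWE distribution identically. Null SNPs are i.i.d. HWE
with per-SNP MAF ~ U[0.05, 0.5], identical in both classes; all loci are in
linkage equilibrium. Default dimensions per dataset are 2000 cases, 2000
controls, 100 SNPs.

Archetypes: `threshold_both_minor` (risk raised iff both SNPs carry a minor
allele — marginal + interactive effects), `inverse_marginal` (one SNP's
marginal effect flips sign when the partner also carries a minor allele),
and the pure-interaction pair `xor` / `zz` (risk raised iff exactly one /
neither-or-both SNP(s) heterozygous). The parity models have *exactly*
constant single-SNP marginal penetrance at MAF 0.5, the setting the tests
use; away from 0.5 small marginals appear. Published models that exist only
as numeric 3×3 tables are passed in directly (`ref39_m3` / `ref39_m4`).

What the simulator does **not** emulate: linkage disequilibrium between loci,
genotyping error and missingness, covariates and population structure,
quantitative traits, and multiple simultaneous interactions. Passing power
tests therefore demonstrate the optimizer's search behaviour under clean,
independent-locus conditions, not performance on real GWAS data.

## Power benchmark

Power 1 is the fraction of datasets whose reported K-set equals the planted
truth exactly (any false positive scores 0); Power 2 is Σ y_i / (K·N) with
y_i the number of causal SNPs among the K reported — so Power 2 ≥ Power 1
identically. The "reported set" is the method's final answer (the
post-processed global best for `ioblpso`); our methods always return exactly
K SNPs, so no ranked-list truncation is involved. The harness simulates the
N datasets once per model and runs every method/(P,T) cell on the same
datasets, making comparisons paired.

The committed power study runs at a desk scale chosen to keep the full suite
fast while leaving the conclusions stable across seeds: N = 20 datasets,
M = 50 SNPs, 1000 cases / 1000 controls, P = T = 50, on a calibrated
both-minor-threshold model (shape 1 vs 9, MAF 0.4, prevalence 0.10) whose
causal-pair MI exceeds every null pair's by a wide margin (verified
exhaustively in the tests). N = 50, M = 100, 2000/2000 and P = T = 100
remain the reference settings and are plain configuration changes.

## Degenerate inputs and tie-breaks (summary)

- all-equal counters → static inertia weight (0.65);
- all-zero count vectors are rejected by the entropy estimator;
- df = 0 tables → p = 1;
- pbest ties → keep previous, then position over opposite; gbest ties → keep
  incumbent; counter-ranking ties → ascending SNP index;
- duplicate indices after a position update → resample excluding present
  indices;
- missing genotypes are rejected at load time (no missing-data rule exists
  for the method).

## Limitations

- The swarm is sensitive to SNPs with strong main effects: the counters and
  hence the dynamic inertia and post-procedure favour them, which is the
  intended behaviour for threshold-type models but can distract from pure
  interactions among many strong marginals.
- A single best interaction is returned per run; multiple distinct
  interactions in one dataset are only surfaced through repeated seeded runs
  (`multi_run`).
- The plug-in MI bias grows with 3^K/n; K > 3 at typical sample sizes is not
  recommended and higher-order use is untested beyond the unit level.
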