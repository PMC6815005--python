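# Methods

## Problem setting

Given a curated bipartite network of known disease–metabolite associations
(adjacency `M`, diseases × metabolites) and, per disease, a DAG of ancestor
terms, the package ranks all unobserved pairs by a KATZ path-counting score
on a heterogeneous graph that augments `M` with within-type similarities.
The premise is transitivity: a metabolite linked to diseases similar to `D`,
or similar to metabolites already linked to `D`, is a plausible candidate
for `D`.

## Similarity construction

**GIP kernels.** Interaction profiles are the binary rows (diseases) and
columns (metabolites) of `M`. The kernel is
`K(u,v) = exp(−ω‖IP(u)−IP(v)‖²)` with `ω = ω′ / mean‖IP‖²` over all nodes of
that type, `ω′ = 1`. Normalizing by the mean squared profile norm makes the
bandwidth scale-free in the network density; scaling `ω′` by `c` scales `ω`
by `c` exactly. The kernel is a valid RBF kernel (positive semidefinite)
with exact unit diagonal. An all-zero `M` leaves the bandwidth undefined
and is rejected. Metabolite similarity `SM` is exactly the metabolite GIP
kernel; no logistic transform is applied on the metabolite side.

**Logistic sharpening (diseases only).**
`GDL = 1/(1 + exp(a·GD + b))`, `a = −15`, `b = log 9999`. The intercept
forces `GD = 0 ↦ 1/(1+9999) = 10⁻⁴` exactly, so unrelated diseases keep a
small but nonzero similarity, while `GD = 1 ↦ ≈ 0.99695`. With `a < 0` the
map is strictly increasing, so it preserves the ordering of similarities.
The exponent is clipped at ±700 before `exp` to guard overflow for
out-of-range inputs.

**Semantic similarity.** Contributions within a disease's DAG follow the
decay recursion `D_D(d) = max{Δ·D_D(d′)}` over children of `d` inside
`T(D)`, `D_D(D) = 1`, evaluated by memoized recursion (equivalent to a
max-over-paths of `Δ^length`, which is the independent oracle used in
tests). `Δ` defaults to 0.5 — the source method never fixes it and 0.5 is
the convention of the Wang lineage this construction follows; it is exposed
as `semantic_delta`. Terms present in a DAG file but not ancestors of the
disease are excluded from `T(D)` with a warning. `DSS(i,i) = 1` follows
identically from the formula. Diseases with no DAG on file get an all-zero
DSS row/column **including the diagonal**: this deliberately routes every
entry involving them into the fallback branch below.

**Integration.** `SD(i,j) = GDL(i,j)` where `DSS(i,j) = 0`, else
`(1−γ)·DSS + γ·G`. The printed source formula uses the raw `GD` in the
blend while its surrounding argument motivates the sharpened `GDL`; we read
that as a typo and default to `G = GDL`, with `integration_kernel="gd"`
reproducing the formula as printed. `γ = 0.1` by default (the tuned
optimum). The diagonal is computed like any entry (DSS diagonal is 1, so
the blended branch applies); it is not forced to 1.

## KATZ scoring

`M* = [[SM, M′],[M′ᵀ, SD]]` with `M′ = Mᵀ` (metabolite rows). Scores are
the metabolite × disease block of the attenuated walk sum, `δ = 0.1`,
`k = 2` by default (the tuned optimum; performance degrades for k = 3, 4
because long similarity-weighted walks flood the signal). The printed
closed expansions for k = 3, 4 in the source are dimensionally inconsistent
(terms like `SM²·SD` cannot enter an n_m × n_d block); we therefore compute
k = 3, 4 as the exact block of the matrix-power sum, which reproduces the
k = 2 expansion verbatim and the evidently intended corrected higher-order
expansions (a unit test pins the k = 3 block to
`δ³(SM²M′ + SM·M′·SD + M′·SD² + M′M′ᵀM′)` plus the k = 2 terms).

The closed form `(I − δM*)⁻¹ − I` is computed by a symmetric linear solve,
never an explicit inverse, and requires `δ·ρ(M*) < 1` — the true
convergence condition. The source's rule "δ < 1/‖M‖²" does not specify the
norm or the matrix; `delta_bound` reports both `1/ρ(M*)` (enforced for the
closed form) and the literal `1/‖M‖₂²` on the bipartite `M` (warned about
only). The truncated series is a finite sum and accepts any `δ > 0`; note
the default `δ = 0.1` typically exceeds both bounds on realistic networks,
exactly as in the source protocol, which always truncates at small `k`.

Candidate rankings per disease exclude already-known metabolites and break
score ties lexicographically on the metabolite id, so output is fully
deterministic.

## Evaluation protocol

**LOOCV** masks each known pair in turn; **k-fold CV** (5 or 10, repeated)
masks a shuffled k-th of the pairs jointly. In both protocols the GIP
kernels and `SD` are recomputed from the *masked* matrix — the information
a real prospective prediction would have — while `DSS` is computed once
(DAGs do not depend on associations). The leaking alternative (similarities
from the full matrix) is available behind `static_similarity` for
comparison. Held-out positives are ranked against all unknown pairs of the
full dataset; the rank is the mid-rank (strictly-greater count + half the
tied count + 1), so the AUC `mean((n − rank)/(n − 1))` equals the exhaustive
Mann–Whitney statistic with ties counted half, which is how tests verify
it. The ROC curve is a rank-threshold sweep. An optional
`balance_negatives` flag subsamples the negative candidates (seeded) to the
number of positives, mirroring a balanced-sampling variant of the protocol;
the default keeps all negatives.

**Baselines.** RWR iterates `p ← (1−r)Wp + re` (restart `r = 0.7`,
tol 1e-10, max 1000 iterations; the source cites but does not print its
baseline parameters) and personalized PageRank iterates
`p ← dWp + (1−d)v` (`d = 0.85`), both on the column-normalized `M*`, seeded
per disease, scoring metabolites by stationary mass. Both error on
non-convergence and report per-seed column mass so probability conservation
is checkable.

## Synthetic data

The generator plants the one structure KATZ provably exploits: diseases and
metabolites are split into balanced clusters; a pair is associated with
probability 0.5 within a cluster and 0.02 across (defaults: 30 diseases,
90 metabolites, 3 clusters, seed 7). Each cluster shares a chain of DAG
ancestor terms under a common root, so same-cluster diseases have high
semantic similarity and cross-cluster diseases share only the root. Every
node is guaranteed at least one association by a seeded repair step. All
randomness flows through one `numpy.random.Generator` with a documented
draw order (grid Bernoulli draws row-major, then repair draws), so a seed
determines the dataset byte-for-byte.

What a green planted-signal test establishes: the pipeline recovers
block-structured association signal well above a label-permuted null. What
it does not establish: performance on real HMDB-scale data, whose degree
distribution is heavy-tailed and whose MeSH topology is far richer than the
generated chains — the printed AUCs of the original study depend on a
specific HMDB snapshot and are explicitly out of scope.

## Numerical choices and limitations

* Dense linear algebra throughout: the intended scale (≈2.5k nodes) is
  desk-sized; scoring plus a 5-fold CV at 216 × 2262 with ~4500 pairs runs
  in seconds on one CPU.
* Squared distances are formed by the norm/Gram identity and clipped at 0
  against rounding; kernels are re-symmetrized and the diagonal set to 1
  exactly. Similarity blocks asymmetric beyond 1e-8 are rejected at network
  assembly.
* Ties: lexicographic in rankings, mid-rank in AUC — both documented and
  deterministic.
* Degenerate inputs rejected with specific errors: empty association sets,
  all-zero `M`, cyclic DAGs (naming the disease), divergent `δ` for the
  closed form, non-convergent diffusion.
* The DAG file dialect is a deliberately minimal edge list; real MeSH/DO
  parsing (OBO/XML) is out of scope, as is HMDB extraction — DAG and
  association provision are input contracts.
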