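# Methods

## Diffusion model

The screen propagates "heat" from validated disease genes over a weighted
PPI network. With integer STRING-style confidence scores as edge weights,
the adjacency matrix is normalized column-wise, A′ᵢⱼ = Aᵢⱼ / Σₖ Aₖⱼ, making
each column a probability distribution over the neighbors of node *j*. Heat
then follows the graph heat equation dH/dt = −L·H with L = I − A′ and the
uniform seed configuration H₀ = 1/|S| on seeds, 0 elsewhere.

Two modeling points deserve emphasis:

* **Which eigenvalues.** The eigen-solution of the heat equation has the
  componentwise form Hₜ = Σᵢ e^(−λᵢt)⟨vᵢ, H₀⟩vᵢ *in the eigenbasis of L*. A
  reading that applies exponential factors directly to the per-node entries
  of H₀ with eigenvalues of A′ would neither mix heat between nodes nor
  decay it (A′ has spectral radius 1 and eigenvalues of either sign); it is
  not a diffusion. We therefore implement the standard Laplacian semantics,
  which is also what the widely used R diffusion packages compute.
* **Isolated nodes.** A zero column would break column-stochasticity and
  leak heat. Isolated nodes receive a unit self-loop in A′ (they keep their
  own heat), so Σ Hₜ = Σ H₀ holds network-wide. This is a deliberate,
  documented deviation from a literal zero column.

Conservation (to 1e−9) and elementwise nonnegativity are enforced as tested
invariants for every network and every *t*; nonnegativity is protected
against floating-point jitter by clamping only values in (−1e−10, 0).

## Solvers

* `expm` (default): matrix-exponential action `expm_multiply(−tL, H₀)`
  (sparse, scaling-and-squaring/Krylov). Works at full-network scale
  (~19k nodes, ~4M edges) without forming exp(−tL).
* `spectral`: dense eigendecomposition of L. A′ is non-symmetric, so this is
  restricted to ≤ 2000 nodes and falls back to `expm` with a logged warning
  when the eigenvector matrix is ill-conditioned (condition number > 1e8)
  or the reconstruction has a non-negligible imaginary part.
* `iterative`: advances time in fixed steps until two consecutive heat
  vectors differ by less than `eps` in the ∞-norm (cap 10,000 steps). This
  mirrors the "run until the change is below a threshold" description of
  diffusion tools; it converges to the stationary distribution rather than
  a fixed time point.
* **Oracle**: a dense Taylor series Σ (−tL)ᵏH₀/k! (default 30–40 terms)
  implemented with plain dense arithmetic, independent of scipy's
  exponential code path. Tests require |expm − oracle| < 1e−8 on random
  networks up to 200 nodes; the measured discrepancy is at machine epsilon.

Diffusion time defaults to *t* = 0.5 — the default of the reference R
diffusion implementation — since the method description otherwise leaves
*t* unspecified. Node indexing is fixed by first appearance in the input
file, which together with mandatory RNG seeds makes runs byte-identical.

## Permutation null and Z-score

For each gene, `n_perm` (default 1000) random seed sets of the true seed
count are drawn uniformly from **all** network nodes (the minimal reading:
nothing excludes the true seeds), heat is diffused from each, and the
gene's real heat is standardized: Z = (h − h̄)/sd with the sample (n−1)
standard deviation, which is the conservative choice for an unqualified
"sd". Genes whose null sd is exactly 0 get Z ∈ {+∞, 0, −∞} by the sign of
h − h̄ and are flagged. Moments are streamed (Welford), so the full-scale
run never stores an n_perm × n_genes matrix; a `store_heats` option keeps
it for verification, and streamed moments match two-pass arithmetic to
1e−10. Null sets are not degree-matched — plain uniform draws are part of
the method's definition, and degree-aware nulls are out of scope.

## MIS and MFS

* **MIS(g)** = max over seeds g′ of the confidence score I(g, g′); 0 when no
  seed is adjacent. The cutoff (default 900, the highest-confidence band) is
  compared strictly (>) by default; both the value and strictness are
  configurable.
* **MFS(g)** = max over seeds of the cosine Q(g, g′) between annotation
  vectors. The encoding is **binary term membership** over the union of GO
  and KEGG terms carried in one GMT file: weight 1 on each term containing
  the gene. Cosine then measures pure annotation overlap. A per-term
  weighting hook (e.g. inverse-frequency weights) is provided for users who
  want a richer enrichment encoding; membership is the default because it is
  the only construction fully determined by the method's description.
  Ancestor propagation over the GO graph is intentionally not performed —
  if wanted it must be pre-baked into the GMT.

## The staged screen

heat > 1e−10 → Z > 1.96 → MIS > 900 → MFS > 0.9, applied in that order with
later scores computed only for survivors (the filters are independent per
gene, so short-circuiting cannot change the result; it only saves work).
The heat cutoff "e−10" is read as the scientific-notation shorthand 1e−10:
reported per-gene heats at full scale are ~1e−4, and a tiny positive cutoff
is the only reading under which some nodes are actually removed. Seed genes
are excluded from the candidate output by default (the screen reports
*novel* genes); a flag disables this. Output ordering (MFS desc, Z desc,
identifier) is declared by this package, not inherited from the method
description, which never states a sort key.

## Synthetic fixtures

The generator emulates the study's three inputs at desk scale with three
node classes — 20 seeds, 5 planted candidates, 200 background genes by
default — and plants the two mechanisms the screen is designed to detect:

* topology: seed–seed edges with probability 0.30 and planted–seed edges
  with probability 0.40, both scored in STRING's high-confidence band
  (700–999), with one guaranteed planted–seed edge above 900 per planted
  node (so the MIS stage has positive cases at any scale — a bias of the
  truth model, stated openly, not of the method under test); all other
  pairs with probability 0.05 at low scores (150–400, mean degree ≈ 11);
* function: 30 annotation terms all containing every seed; planted genes
  join each term with probability 0.95, background with 0.05, giving
  planted MFS ≈ √(0.95) ≈ 0.97 and background MFS ≈ 0.3.

These rates were chosen once as a caricature of a coherent disease module
(dense high-confidence wiring, shared annotations) against a sparse
unrelated background. What passing tests show is that the implementation
recovers structure *of this planted kind*; the fixtures do not reproduce
the scale-free degree distribution, annotation-size heterogeneity or
evidence-channel correlations of real STRING/GO data, so recovery rates
here do not predict discovery performance on real networks.

### Fixture-scale Z calibration

On a 225-node fixture a size-20 null seed set contains the scored gene
itself with probability ≈ 9%; the retained self-heat makes each gene's null
distribution bimodal and inflates its sd, compressing all Z-scores (planted
genes land near Z ≈ 0.1–1.6). At full scale (19k nodes, 37 seeds) the
self-inclusion rate is 0.2% and the 1.96 cutoff is meaningful. A one-off
calibration run on ten held-out generator seeds (1000–1009, never used by
the test suite) showed every background gene below Z = −0.1 and every
planted gene above Z = 0, so the fixture-scale configuration
(`netheat.simulate.fixture_pipeline_config`) cuts at Z > 0 and keeps every
other cutoff at its full-scale default. The same self-inclusion effect means
the per-gene null is far from Gaussian at this scale: the only calibration
property asserted is one-sided (non-seed genes exceed Z = 1.96 no more than
1.5× the Gaussian tail expectation), a false-positive control rather than a
two-sided tail match.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated inputs:
random networks of 10–200 nodes for solver checks, the 225-node default
fixture with 200 permutations for pipeline checks, 20 fixture replicates
for recovery, 50 for the label-blindness null check. Tolerances: 1e−8
solver-vs-oracle, 1e−10 closed form and streaming moments, 1e−9
conservation. Ties in the candidate ordering break by Z then identifier;
degenerate inputs (empty seed list, empty GMT term, score out of band,
conflicting duplicate edges, mixed taxon prefixes, self-loops) raise typed
validation errors rather than being silently repaired.

## Known limitations

* The enrichment encoding behind MFS is declared (binary membership), not
  recovered from the cited enrichment literature; the weighting hook exists
  for alternatives.
* The full-scale headline numbers of the original study depend on a
  multi-gigabyte STRING v10 download plus GO/KEGG snapshots and are not
  reproduced here; the package reads that dialect directly and the staged
  contract is exercised end-to-end at fixture scale.
* Whether the original permutation null excluded the true seeds is
  unstated in the method description; this implementation samples from all
  nodes and documents the choice.
* The spectral solver is a small-graph diagnostic, not a production path.
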