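# Methods

`duphic` reconstructs, on synthetic data, the analysis chain needed to
place a topologically associating domain (TAD) boundary inside a tandem
segmental duplication — a region that standard Hi-C pipelines blank out
because reads mapping to it are ambiguous among the repeat copies.

## The synthetic duplicated locus

The generator emulates a ~1 Mb gene cluster modelled on the
regulators-of-complement-activation locus: seven genes, with an 18 kb
duplication unit repeated in tandem (two copies by default) inside the
central gene. The planted TAD boundary sits at the midpoint of the
second copy; every copy carries a reverse-orientation CTCF site at the
same within-copy offset, and the outer TAD anchors are convergent
('+' at the left edge, '−' at the right edge of each domain).

Contacts are cis-only (the analysis concerns a single locus) and
sampled at bin resolution: pair (i, j), i < j, has probability
proportional to

```
P(i, j) ∝ (d + 1)^(−α) · s^(#planted boundaries straddled),   d = j − i
```

with decay exponent α = 1 (the canonical power-law decay of contact
frequency with genomic distance at the sub-Mb scale) and insulation
s = 0.2 by default. Self-pairs (d = 0) are excluded, mirroring standard
short-range Hi-C filtering. A base-pair position is then drawn
uniformly within each end's bin; an end falling inside the duplicated
block acquires a candidate at the homologous position of every copy, so
the read becomes multi-mapping. Copies are exact — the worst case for
mappability; sequence divergence between copies is out of scope.
Randomness uses NumPy's `default_rng` (PCG64), so a seed fixes the
output byte-for-byte across platforms.

The insulation default of 0.2 is a free parameter (the real insulation
strength of the modelled boundary is not quantified anywhere we could
anchor it); 0.2 produces a clearly visible but noisy boundary, which is
the regime in which a caller is worth testing.

What the generator does **not** emulate: restriction-fragment
structure, trans contacts, copy-number differences between homologues,
distance-dependent noise beyond multinomial sampling, and mapping
errors other than exact-repeat ambiguity. Passing tests therefore show
that the rescue-and-call machinery is correct under the stated
statistical model, not that it is robust to every artefact of real
Hi-C libraries.

## Multiread rescue

1. **Distance-decay prior.** The mean contact count per admissible bin
   pair at each distance d ≥ `min_d` (default 2 bins) is smoothed by a
   cubic least-squares spline in log d – log(mean) space
   (`spline_df` = 8 degrees of freedom, interior knots at quantiles of
   log d), exponentiated, floored at ε = 10⁻¹² and normalised over the
   distance grid. The prior is fitted **once**, on uniquely mapping
   reads only; it is not refit after multireads are incorporated (the
   iterative step below already feeds rescued mass back through the
   local counts, and refitting would couple the prior to the quantity
   being estimated).
2. **Posterior allocation.** For a multiread with candidates k at
   distances d_k, each sweep sets

   ```
   posterior_k ∝ P(d_k) · (L_k + pseudocount)
   ```

   where L_k is the summed current count — unique reads plus the
   previous sweep's fractional multiread mass — in the
   (2w+1) × (2w+1) bin-pair square centred on candidate k, clipped to
   the matrix. The product form (prior times local evidence,
   renormalised per read) is this package's interpretation of
   "prior updated by local counts"; it is the natural
   posterior-of-origin under a locally homogeneous contact intensity.
   Sweeps are synchronous (Jacobi-style): all posteriors of a sweep
   are computed from the previous sweep's matrix and the fractional
   layer is rebuilt afterwards, so results are independent of read
   order. The first sweep sees unique-read counts only. Iteration
   stops when the largest per-read posterior change falls below
   `tol` = 10⁻⁴ or after `max_iter` = 50 sweeps.
3. **Accumulation.** *Fractional* mode adds each multiread's posterior
   mass at its candidates (total mass is conserved exactly: #uni +
   #multi). *Stringent* mode assigns a multiread wholly to its best
   candidate iff that posterior is ≥ 0.99 (ties at the threshold kept,
   per the "greater or equal" convention) and discards it otherwise.

Numerical choices: w = 2 bins (a 25 kb square at 5 kb bins) balances
locality against sparsity; pseudocount 0.5 keeps zero-coverage
candidates alive through the prior; distances below `min_d` evaluate to
the prior's ε floor rather than being removed from candidate support —
hard removal could orphan a read whose candidates are all short-range
and would break exact count conservation, which we treat as
non-negotiable. If every candidate of a read has zero weight (possible
only with pseudocount 0), the read falls back to prior-only weights.

## Spectral TAD calling

The caller is an independent re-implementation in the spirit of
spectral-clustering TAD callers, not a port of any specific tool. The
matrix is sum-pooled 5 kb → 25 kb (mass preserved exactly; a trailing
partial coarse bin is absorbed into the last full one). Each sliding
window (40 coarse bins, stride half a window) is first normalised
observed/expected — every entry divided by the mean contact at its
distance — because the decay band otherwise dominates the spectrum and
fragments the diagonal into spurious segments; genuine domains survive
as enrichment over the decay expectation, and the transform makes the
caller invariant to global count rescaling. The window graph is then
embedded with the leading eigenvectors of the degree-normalised
adjacency D^(−1/2) W D^(−1/2) (dense symmetric solver; eigenvector
signs fixed first-nonzero-positive; columns scaled by their
eigenvalues so structureless directions with λ ≈ 0 contribute nothing
— a constant matrix cannot manufacture a split). Contiguous
segmentations into k = 2 … k_max = 5 groups of at least
min_tad = 4 coarse bins (100 kb) are found by exact dynamic
programming on within-segment variance; the k with the best silhouette
wins, and no cut is emitted unless the silhouette reaches 0.15.
Window-level cuts are consolidated by voting (a cut must be proposed
by at least half the windows covering it), and contacts beyond 200
coarse bins are ignored when building window graphs. Only first-level
(non-nested) domains are called.

## Virtual 4C

The profile at bin j is the summed contact of j with the viewpoint
bins — the matrix row(s) at the viewpoint — optionally smoothed by a
centred moving average (default 3 bins) with truncated edges.
Viewpoint self-bins are flagged, not zeroed, and raw fractional counts
are used without further normalisation. The strongly-constrained
viewpoint scenario (a viewpoint one bin downstream of the planted
boundary keeping ≥ 90 % of its mass on its own side) is simulated at
insulation 0.05 rather than the generator default 0.2: the phenomenon
being emulated is a profile that essentially does not cross the
boundary, and the analytic expectation under α = 1 decay shows the
same-side fraction is ~82 % at s = 0.2 versus ~95 % at s = 0.05, so
only a strongly insulated boundary reproduces it.

## CTCF motifs and anchor orientation

Scanning is plain log₂-odds PWM scoring against a uniform background
on both strands (reverse strand scored on the reverse complement,
positions always reported on forward coordinates); windows containing
N are skipped, overlapping hits are all kept — repeat copies
legitimately produce periodic hits. A 19 bp CTCF position-frequency
matrix ships with the package so the synthetic pipeline is
self-contained; any JASPAR-style table can be substituted (counts get
a 0.25 pseudocount per cell). Default threshold 8 bits; at that level
a 1 Mb random background yields a realistic sprinkling of weak hits,
while planted consensus sites score the model maximum (~26 bits) and
are separable at a 20-bit threshold. A TAD is *convergent* when a '+'
hit lies within the anchor window (default 50 kb, two coarse bins) of
its left boundary and a '−' hit within the window of its right
boundary; *tandem* and *divergent* are defined analogously, with
convergent taking precedence.

## Assay arithmetic

Comparative Ct, percent input, ChART accessibility, MNase occupancy,
dual-luciferase normalisation and the pooled-variance unpaired t-test
are implemented as pure formulas (see the module docstrings for the
exact expressions). Replicates are averaged on the Ct scale before
exponentiation, with SEM propagated to the transformed scale by the
delta method. The ChART/MNase forms — retained fraction
2^(−(Ct_dig − Ct_undig)) at the target, divided by the same at a
protected control locus, subtracted from 1 (accessibility) or reported
directly (occupancy, 1.0 = fully compacted), clipped to [0, 1] — are
parameterised interpretations of the stated normalisation conventions,
not assertions about any particular instrument's software. The ChIP
input fraction defaults to 1 % but is an explicit parameter. The
t-test is Student's (pooled), two-sided, df = n_a + n_b − 2; zero
pooled variance returns t = 0, p = 1 when means agree and an explicit
error otherwise.

## Problem sizes and determinism

The shipped analyses and checks use 200 000 reads over 200 bins
(1 Mb / 5 kb), 40 coarse bins at 25 kb, and 5–20 simulation seeds per
property — sizes at which every stage's statistical behaviour (decay
slope recovery, boundary recovery, rescue coverage) is stable while a
full run of the test suite and the acceptance script completes in a
few minutes on one core. All stages are deterministic given the seed;
the TAD caller and rescue iteration contain no randomness at all.

## Known limitations

* Exact-copy ambiguity only; divergent repeats would need alignment
  scores in the candidate model.
* The rescue posterior assumes candidate-local contact intensity is
  well estimated by a small square neighbourhood; very sparse matrices
  push the posteriors toward the prior.
* The spectral caller targets the two-to-few-domain regime of a ~1 Mb
  locus; genome-wide calling would need windowed streaming and was not
  a goal.
* Stringent (≥ 0.99) allocation keeps few reads when repeat copies are
  exactly symmetric — by design it only resolves reads for which the
  local context is decisive.
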