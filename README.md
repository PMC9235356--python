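# duphic

Repeat-aware chromatin-architecture analysis of a duplicated locus.

Segmental duplications are blind spots of standard Hi-C processing:
reads mapping inside a tandem repeat align equally well to every copy
and are discarded, so a TAD boundary lying *inside* the repeat cannot
be localised. `duphic` implements the full chain needed to resolve such
a boundary and exercises it end-to-end on a synthetic ~1 Mb locus
carrying an 18 kb tandem duplication, so nothing needs downloading:

1. **Multiread rescue** — fit a distance-decay prior P(d) by a
   univariate spline to uniquely mapping reads, then iteratively
   compute per-read posteriors over candidate bin pairs,
   `posterior_k ∝ P(d_k) · (L_k + pseudocount)` with L_k the local
   contact count around candidate k, and accumulate posteriors as
   fractional contact counts (or assign whole reads at a ≥ 0.99
   posterior in stringent mode). Total count mass is conserved exactly.
2. **Spectral TAD calling** at 25 kb: sliding-window spectral
   segmentation of the observed/expected contact graph
   (degree-normalised Laplacian, eigenvalue-scaled embedding, exact
   contiguous dynamic programming, silhouette model selection).
3. **Virtual 4C** — viewpoint profiles (matrix rows) exported as
   bedGraph tracks.
4. **CTCF motif scanning** — log-odds PWM hits on both strands and
   TAD-anchor orientation labels (convergent / tandem / divergent).
5. **Assay arithmetic** — comparative Ct, ChIP percent input, ChART
   accessibility, MNase occupancy, dual-luciferase normalisation,
   pooled t-test.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic locus (1 Mb, 5 kb bins, 18 kb × 2 duplication,
boundary planted at 587 kb inside copy 2, 200 000 reads, seed 7):

```bash
python analysis/01_simulate_region.py
python analysis/02_rescue_multireads.py
python analysis/03_call_tads.py
python analysis/04_virtual_4c.py
python analysis/05_scan_ctcf.py
python analysis/06_assay_quant.py
```

Representative output:

```
reads: 200,000 total, 10,421 multi-mapping (5.2%)

fractional mass 200,000.000 vs #uni+#multi 200,000 (error 2.62e-10)
duplication-interior coverage: unique-only max 0, fractional min 1437

boundary at 575,000 bp (CR1;dup_copy_1;dup_copy_2); planted truth
587,000 bp, offset 0.02 coarse bins

   viewpoint   upstream  downstream  side
       CR2         2071          55  mostly upstream
       CR1L         116        1779  mostly downstream

TAD [0, 575,000) -> convergent; 2 reverse-orientation hits at the
right anchor
```

Reading: the duplication's interior bins receive **zero** coverage
from uniquely mapping reads but ~1 400 fractional contacts after
rescue; the spectral caller then places the inter-TAD boundary within
a fraction of a 25 kb bin of the planted truth, inside the repeat;
virtual-4C profiles of genes on either side of the boundary are
constrained to their own TAD; and the upstream TAD is flanked by a
convergent anchor pair whose reverse-orientation side repeats once per
duplication copy. The same workflow is available as a single command,
`dup-hic run --seed 7 --out results/run` (see `dup-hic --help` for the
individual stages).

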