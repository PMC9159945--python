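# Methods

This note documents the statistical model, the conventions, and the design
decisions behind `dpimap`, in the order the pipeline runs.

## Site universe and coordinates

DddA deaminates cytosines almost exclusively in the 5´-TC-3´ dinucleotide
context, so only those positions are scored: on the forward strand the C of
a `TC`, and on the reverse strand the (forward-coordinate) G of a `GA`. A
site is anchored at the deaminated base's forward-strand coordinate, giving
one coordinate per scored base and unambiguous joins with count tables.
Coordinates are 0-based in memory; TSV outputs are 1-based (pileup
convention), while BED/bedGraph keep their native 0-based half-open
convention. Contexts containing `N` are excluded (the transition state is
undefined), and chromosomes are treated as linear — a circular chromosome
loses at most one wrap-around dinucleotide at the origin.

The mean TC spacing (genome length / both-strand site count) bounds the
method's spatial resolution. The both-strands convention is used
throughout; densities quoted for one strand only would be twice as sparse.

## Filtering cascade

Defaults (all overridable in `FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 15 | minimum quality-filtered depth, required in *every* replicate |
| `max_freq` | 0.95 | per-replicate transition-frequency cap (removes fixed variants and hypervariable positions) |
| `consensus_k/n` | 3 of 4 | replicates that must carry ≥1 mutant read for a site to be reported |
| `window_bp` | 75 | centered moving-average window |

Semantics worth noting:

* The depth and frequency filters drop a site from **all** replicates if
  any replicate violates them; under these all-or-nothing semantics the
  order of depth filter, cap and mask is irrelevant.
* "Depth" is the per-base quality-filtered call count at the site (one unit
  per read); pair-aware deduplication is upstream of this package.
* A site absent from one replicate's table is treated as depth 0 there and
  is therefore removed by the depth filter — absence of evidence is not
  evidence of no mutation.
* The consensus rule is an integer test (alt count ≥ 1), not a frequency
  test, and the reported mean frequency averages alt/depth over **all**
  replicates, zeros included. With `consensus_k = 0` it reduces to the
  plain per-site mean.
* The moving average is centered and inclusive with half-width
  ⌊75/2⌋ = 37 bp and is computed **over surviving TC sites only**, so
  positions removed by filtering do not contribute zeros. The alternative
  convention — dividing the window sum by the full window width so every
  genomic base pair implicitly contributes zero — is available via
  `moving_average(..., denominator="genome")`; it shrinks values in
  site-sparse regions and is not the default.
* Frequencies are carried at full floating precision; rounding (6
  significant digits) happens only at TSV export.

## Emission model and peak shape

At surviving site *i* (position *x_i*), replicate *r* contributes an
independent binomial observation

    c_ir ~ Binomial(n_ir, p_i),
    p_i  = clip(b + Σ_j A_j exp(-(x_i - μ_j)² / (2 σ_j²)), ε, 1-ε)

with background rate *b*, peak centers μ_j (bp), amplitudes A_j (probability
units) and widths σ_j (bp, bounded to [10, 500] by default), and ε = 1e-9.
The binomial on (depth, alt) is the minimal faithful model of the count
data; the Gaussian bump is the conventional minimal shape for a smooth
unimodal footprint. Both choices are isolated behind `PeakModelParams` /
`loglik`, the single place to swap in alternatives (e.g. an overdispersed
emission or a flat-top profile). Since all replicates share p_i, the
likelihood depends on the data only through per-site totals, which the
implementation exploits.

## Detection procedure

1. Fit the background-only null: b̂ = Σc/Σn (closed form).
2. Challenge: seed one extra peak at the maximum of the 75 bp-smoothed
   residual (observed pooled frequency minus current model; ties go to the
   leftmost position), and maximize the likelihood over (b, μ, A, σ) with
   L-BFGS-B using analytic gradients, restarted from σ ∈ {25, 75, 200} bp
   (the σ landscape is multimodal). Existing peaks stay fixed during a
   challenge; convergence tolerance is ~1e-8 on the log-likelihood, and a
   non-converged fit is flagged, not raised.
3. Compute Λ = 2(logL₁ − logL₀) (clamped at 0 — the models are nested) and
   its p-value under the null calibration (below). If p ≤ α (default 0.05),
   absorb the peak, jointly re-optimize all parameters, and repeat;
   otherwise stop. `max_peaks` (50) is a safety cap. The first
   non-rejection terminates the sequence; no additional multiple-testing
   correction is applied across peaks, matching the sequential scheme, and
   per-peak p-values are reported as-is.

**Null calibration.** Because μ is chosen by scanning and A sits on a
boundary under the null, Wilks' χ² asymptotics are invalid. The default is
a parametric bootstrap: B = 199 background-only datasets are simulated on
the observed depth skeleton at rate b̂, the *full* scan-and-fit is re-run
on each, and the observed Λ is referred to the resulting max-Λ
distribution with the +1-corrected p-value p = (1 + #{Λ_b ≥ Λ})/(B + 1);
the rejection threshold is the ⌈(1−α)(B+1)⌉-th order statistic (the 190th
of 199 at α = 0.05), giving exact α control under the bootstrap null. The
calibration is computed once per contig (at b̂) and reused across
iterations; re-simulating from each intermediate fitted model would be
slightly more faithful for second and later peaks but is far more
expensive, and the first test — which controls whether any peak is called —
is exact. A `chi2_df3` mode (threshold χ²₃;1−α) is available and documented
as anti-conservative. Type-I control of the default mode is itself a tested
property (the 400-dataset experiment in the acceptance suite and
`scripts/acceptance.py`).

**Degenerate inputs.** Fewer than 10 sites, or no mutant reads at all,
yields an empty peak list with a warning, never a crash.

**Determinism.** One integer seed in `DetectionConfig` drives all bootstrap
draws; identical inputs and seed reproduce identical peak tables
byte-for-byte.

## Single-cell test

Per-clone fixed TC→TT SNP counts inside a user-supplied window (there is no
default window — it is the sequenced amplicon) are compared against
Poisson(λ̂), λ̂ = sample mean, via the K–S sup distance evaluated over the
integer support (both CDFs are step functions jumping at integers, so the
supremum over ℝ is attained there). Adjacent SNPs count individually. With
λ estimated and a discrete distribution, the classical K–S p-value is only
approximate, so the default is a Lilliefors-style parametric bootstrap
(B = 999) with λ re-estimated in every bootstrap sample; `plugin` mode
reports the classical p-value for compatibility. All-zero counts return
D = 0, p = 1 with a warning. Calls that are not TC-context transitions are
ignored and counted; clones without coverage over the window are flagged
and excluded.

## Benchmarking conventions

Peak-to-motif distance is reported under two conventions: distance to the
nearest motif center, and distance to the midpoint of the span
(min start … max end) of the peak's motif group, where groups represent
promoters with multiple adjacent motifs. A peak is assigned to the group
whose span midpoint is nearest (the assignment rule is otherwise
under-determined). Peaks with no candidate within 1,000 bp (configurable)
are reported unmatched rather than inflating averages with genome-scale
distances. The two conventions coincide exactly for singleton groups; no
general inequality between them holds, and none is asserted.

## Simulator

The generator emulates the experiment's data-generating process end to end:
i.i.d. genomes at a chosen GC fraction (default 0.66, a high-GC bacterium;
expected both-strand TC density gc(1−gc)/2), per-site-per-replicate depths
drawn Poisson(mean 100) — a negative-binomial option adds overdispersion —
and alt counts Binomial(depth, p_i) with the same background + Gaussian
peak rate model the detector fits. Default study conditions: 10 kb genome,
background 0.005, 4 replicates. Clones draw an exposure e (constant, gamma,
or finite mixture); each window site mutates independently with probability
1 − e^(−e), so homogeneous exposure yields approximately Poisson totals —
exactly the null the single-cell test assumes — while mixtures produce the
heavy-tailed alternative.

What the simulator deliberately does **not** reproduce: real dinucleotide
composition (an i.i.d. genome has no TpC depletion, so absolute site
densities differ from real chromosomes), correlated depth along the genome
(library/GC bias), strand-specific deamination asymmetries, within-site
overdispersion across replicates beyond binomial, and read-level artifacts
(the package starts from counts by design). Passing recovery and
calibration tests therefore demonstrates correctness of the statistical
machinery under its stated model, not robustness to every real-data
pathology; the filtering cascade is the line of defense against the most
important ones (coverage dropouts, fixed variants, hypervariable regions).

## Problem sizes used in validation

The null-calibration experiment uses 400 independent 10 kb datasets
(≈1,100 sites each) with B = 199 bootstrap scans per dataset; recovery uses
20 seeded single-peak datasets and 5 two-peak datasets; the single-cell
calibration uses 200 trials of 369 clones with B = 999. These sizes give
3-binomial-SE acceptance bands of ±3.3 percentage points (n = 400) and
±4.6 points (n = 200) around the nominal 5% level.

## Known limitations

* Contigs are modelled independently; no peak sharing across contigs.
* The bootstrap threshold reuse across iterations (above) makes p-values
  for second and later peaks approximate.
* Amplitudes are additive in probability space and clipped at 1 − ε;
  overlapping strong peaks near saturation are not identifiable.
* The single-cell test assumes a fixed, shared site universe per clone;
  partial window coverage must be handled by excluding the clone.
* No FDR control across conditions or regulons — interpretation is left to
  the user.
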