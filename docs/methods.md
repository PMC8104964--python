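# Methods

This document records the models the package implements, the defaults it
ships, and the reasoning behind every place where the procedure admits more
than one reading. Conventions: coordinates are 0-based and half-open; cut
site `i` denotes the blunt cut between reference positions `i-1` and `i`;
all fold-changes are log2.

## 1. Genotyping

### Alignment

Each merged read is aligned to the expected wild-type amplicon with affine
gap scores: match +1, mismatch −1, gap open −5 (the first gapped position),
gap extend −1. End gaps on the read are free — a read may begin or end
inside the reference without penalty — so truncated fragments align where
they belong and the unaligned reference ends become *boundary offsets*.
Read bases overhanging the aligned region are reported as insertions at the
boundary. Biopython's `PairwiseAligner` provides the dynamic program; an
independent brute-force three-state DP in the test suite cross-checks
optimality on small instances.

**Anchored rescue pass.** Under these scores a large internal deletion
(open −5, extend −1) costs about 1 point per deleted bp, which is the same
rate at which a misaligned flank loses score. For deletions of roughly
100 bp and up — precisely the spanning deletions a multi-guide RNP is
designed to produce — the *optimal* free-end alignment can therefore shift
a flank into an unrelated reference region via a free end gap plus
scattered mismatches, outscoring the true single-deletion alignment.
Whenever the free-end alignment is non-flush or falls below the quality
floor, the read is realigned with both ends anchored (end gaps penalized
like internal gaps), the anchored alignment's end gaps are reinterpreted
as boundary offsets, and the candidate with the higher *quality* wins,
ties going to the free-end pass. Quality is the alignment score with
internal deletion penalties forgiven: a read whose bases all match the
reference is fully explained no matter how much reference was cut out
between them. Clean full-length reads never trigger the second pass, so
the common case costs one alignment.

**Unaligned floor.** A read is `unaligned` when its best quality is below
0.6 × read length. Applying the floor to quality rather than the raw score
keeps it meaningful for deletion-carrying reads; random off-target
sequence still scores ≤ 0.1 per base under this measure, so rejection
power is unchanged.

**Canonicalization.** Indels are shifted to their leftmost equivalent
placement (a deletion moves left while the base entering its window equals
the base leaving it; an insertion rotates its sequence analogously), so
identical biological outcomes share one `outcome_key` regardless of which
optimal alignment the DP reported. Because a deletion in repetitive
context has several equivalent placements, cut-site coverage (for the
spanning-deletion call) is judged over the whole shift-equivalence range,
not just the canonical placement.

### Classification

The malformed-layout rule is applied first: if one alignment boundary is
more than 40 bp from every cut site, or both boundaries are more than
20 bp away, the read is `malformed_layout` (these are typically amplified
off-target fragments, not editing outcomes). A boundary flush with the
reference end counts as distance 0 — a full-length read carries no layout
evidence at its ends. Otherwise: no indels and flush boundaries →
`wildtype` (point mismatches tolerated: sequencing errors and SNPs are not
editing evidence); no indels but truncated boundaries near a cut site →
`malformed_layout`; a single deletion covering two or more cut sites →
`spanning_deletion`; exactly one indel → `deletion` or `insertion`; two or
more indels → `multiple_indels`.

### Efficiency

Per-outcome raw counts are corrected with the size-bias model (section 2)
using each outcome's implied amplicon length. Editing efficiency is
100 × (corrected non-wild-type on-target) / (corrected on-target), where
on-target excludes `malformed_layout` and `unaligned` (configurable).
Samples pass the depth filter when corrected on-target reads exceed 100.

## 2. Amplicon size bias

Fragment `i` of a spike-in pool with starting molar fraction `s_i` is
observed with efficiency `e_i`, so its read fraction is
`m_i = e_i s_i / Σ_j e_j s_j`. Fixing the reference fragment (447 bp,
present in every pool) at `e = 1` makes the system identifiable; the
remaining `n−1` unknowns solve the linear system
`(m_i − 1) e_i s_i + m_i Σ_{j≠i,ref} e_j s_j = −m_i s_ref`
exactly (dense solve), with a 1e-9 self-consistency check against the
forward model. Fragments with zero reads make the system singular and
raise a diagnostic error; non-positive solved efficiencies are reported as
invalid pools rather than clipped, so bad measurements stay visible.

`log2 e` is regressed on fragment length by unweighted ordinary least
squares pooled across pools (reference points contribute their pinned
`log2 e = 0`). The slope, in log2 units per bp, drives the correction

    count_corr = count × 2^(slope × (l_WT − l_read))

which is the identity at Δlength = 0 or slope 0 and down-weights shortened
amplicons for negative slopes. The shipped default slope, −0.014356,
corresponds to a two-round PCR MiSeq library preparation over 146–539 bp
fragments; with it, a 100 bp shorter product is over-observed ≈2.7× and
1000 of its reads correct to ≈369.7. The correction assumes a single
exponential length effect; composition-dependent bias is not modeled (the
fit's R² and per-pool residuals are reported instead).

## 3. Screen scoring

Per donor: four 96-well plates, each with 74 gene wells, 9 neutral
controls (targeting genes not expressed in the assayed cells — they define
the null), 2 non-targeting controls, 1 positive control (TNF for the
TNF-α readout), 2 essential-gene controls, and column 12 reserved for 4
no-pulse and 4 media-only wells. Steps:

1. **Background correction.** Subtract the per-plate (per-assay) mean of
   the media-only absorbances from every sample replicate. Non-positive
   results are floored to the smallest strictly positive corrected value
   — by default across the donor's whole dataset (`floor_scope=
   "dataset"`; per-plate available) — so log-ratios stay defined.
2. **Cell-count normalization.** Divide by the well's mean luminescence
   (two reads, media-only-background-subtracted by default).
3. **Plate normalization.** Within each (plate, assay, replicate), divide
   by the median over the plate's nine neutral-control wells and take
   log2. Normalization is strictly per plate, absorbing plate effects;
   with an odd neutral count the median neutral well sits at exactly 0.
4. **Replicate aggregation.** Arithmetic mean of the replicate log2
   fold-changes (log2FCs are approximately normal, so the mean on the log
   scale is the natural summary).
5. **Hit calling.** `neutral_sd` is the sample standard deviation (ddof 1)
   of the 36 pooled neutral well means; the threshold is 2 × that, applied
   inclusively to |mean log2FC| about 0 (`sd_center="zero"`; banding about
   the neutral mean available). Deviations must also exceed 1e-9 — a
   guard against calling hits on floating-point residue in noise-free or
   degenerate data. Genes occupying several wells are summarised by the
   mean of their well means; per-well calls are also reported.

### The effective null tail of the 2-SD rule

The 2-SD rule does **not** have the Gaussian ≈4.6% (or t-corrected ≈5.3%)
false-positive rate. Each neutral well is normalized by a median it
helped form, which cancels part of its own deviation; each gene well has
the median's sampling noise *added*. With 9 neutral wells per plate the
neutral variance is deflated to ≈0.83 σ² while the gene-well variance is
inflated to ≈1.18 σ², so a threshold of 2 neutral SDs sits at ≈1.7
gene-well SDs — an expected null gene-well hit rate of ≈8% (reduced-model
Monte Carlo: 0.080; full simulator: ≈0.09, the remainder from
luminescence and background noise). This is a property of the published
normalization scheme itself; the acceptance suite checks the simulator
against the correctly derived tail, not the naive one.

## 4. ELISA calibration

Standard curves (twofold dilutions, 31.25–2000 pg/mL in duplicate) are
fitted with the four-parameter logistic `f(x) = d + (a − d)/(1 + (x/c)^b)`
by Levenberg–Marquardt least squares; the fit requires at least five
distinct positive concentrations and a monotone fitted curve. The inverse
`concentration(absorbance)` is defined strictly between the asymptotes and
returns an in-range flag. Within the screen itself, scoring operates on
background-corrected absorbances; conversion to pg/mL is provided for
dose–response style readouts outside the screen path.

## 5. Synthetic data

Generator defaults mirror the study design they emulate and are not tuned
to any test:

- Loci: 200–500 bp random sequence, 1–3 cut sites, each ≥50 bp from the
  amplicon ends, multi-site spans ≤200 bp.
- Single-guide spectra: at efficiency `e`, 50%/30%/12%/8% of `e` go to a
  1 bp deletion, 2 bp deletion, 1 bp insertion and 4 bp deletion (editing
  dominated by 1–2 bp deletions); multi-guide spectra put 45% of `e` into
  the outermost spanning deletion and the rest into small per-site
  deletions.
- Reads: template `i` with length `l_i` is drawn with probability
  ∝ `p_i × 2^(slope × (l_i − l_WT))`, so `correct_count` inverts the bias
  in expectation. Sequencing error is substitution-only (indel errors
  would confound classification; a documented limitation).
- Calibration pools: Dirichlet starting fractions, multinomial reads at a
  chosen depth (or the infinite-depth limit), default 11 pools of the five
  standard lengths.
- Screens: absorbance = plate effect × baseline × 2^(true effect) ×
  lognormal noise + media background; luminescence is an independent
  lognormal cell-count proxy. `noise_sd_log2 = 0.3` per replicate puts the
  neutral-well SD of well means at ≈0.21–0.23, the tight-null regime of a
  well-behaved screen; plate effects default to 0.8–1.25×. Ground truth
  (true effects, plate multipliers, all noise parameters) is exported.

## 6. Limitations and scale

- The aligner is exact DP, not seed-and-extend: loci up to ~1 kb and
  ~10⁵ reads per sample are comfortable; it is not a general-purpose
  aligner for long references.
- One global bias slope per library preparation; no per-locus or
  composition-dependent bias.
- Paired-end merging is upstream; the included overlap merger exists only
  to exercise the simulator's output.
- Cross-donor variation is not modeled statistically; donors are scored
  independently and compared descriptively.
- The hit threshold inherits the ≈8% effective null tail described above;
  users wanting calibrated error rates should prefer the reduced-model
  tail (or a permutation null) over the nominal "2 SD" reading.
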