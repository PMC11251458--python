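# Methods

## The generative model

The simulator produces ground-truth data for a cell in which a single-strand
endoribonuclease has been activated. It is deliberately mechanistic but
minimal; each stage is the simplest model that reproduces the qualitative
signatures the analysis pipeline is built to measure.

### Transcriptome

Random transcripts over {A,C,G,U} with three regions in 0-based half-open
transcript coordinates: 5′UTR `[0, cds_start)`, main ORF `[cds_start,
cds_end)` (length divisible by 3, forced AUG start and UAA stop), 3′UTR
`[cds_end, len)`. Defaults: 5′UTR 30–100 nt, CDS 60–200 codons, 3′UTR 60–200
nt. A configurable fraction of genes (default 0.3) carries one 2–8-codon
AUG…UAA uORF planted wholly inside the 5′UTR; the annotation records the
planted interval. Random sequence naturally contains AUGs and stop codons in
all frames, which is what gives cleavage fragments their "first available
ORF".

### Cleavage

A nuclease is a map from motifs to relative weights. Presets: RNase L
{UU:1, UA:1}, RNase A {U:1, C:1}, IRE1 {UGC:1}. **Cut-position convention:**
cleavage occurs 3′ of the motif's last base — a cut at p splits `[0,p)` /
`[p,len)`. The convention is a package choice (the underlying chemistry maps
motifs, not phosphodiester positions, onto our coordinates); it is
configurable in the sense that any motif map can be supplied, and no
downstream statistic depends on which side of the motif the cut falls.

Per transcript copy:

- survival of baseline loss is Bernoulli with
  p = min(1, (1 − baseline_loss) × resistance). The linear resistance form
  makes "an n-fold survival advantage" literal; spike-in-calibrated studies
  put realistic baseline loss at 0.6–0.99, and the fixture regime uses 0.7
  (read-level) or 0.9 (count-level experiments).
- the number of cuts is Poisson with rate intensity × Σ(site weights) /
  resistance — the simplest memoryless kinetics; cut positions are drawn
  from the motif sites proportionally to weight, without replacement.

Fragments keep provenance (intact / 5′ / internal / 3′). With intensity 0
and loss 0 the pool is exactly the intact transcriptome (tested).

### Translation

- **Intact copies:** P-sites uniform over the main ORF at `density`
  footprints per ORF nt per copy (default 0.2 in the fixture regime, chosen
  so a typical gene receives a few hundred ORF reads — enough that region
  ratios are measurable per transcript at desk scale). Optional uORF
  occupancy via `uorf_density` (default 0: uORF translation is an input for
  the region metrics, not a claim of the simulator).
- **Uncapped fragments (internal and 3′):** with probability `reinit_prob` a
  fragment is translated from the first AUG-initiated ORF at or downstream
  of its 5′ end, any frame, minimum 5 codons (shorter candidate ORFs are
  skipped in favour of the next AUG; near-cognate starts are not modelled).
  Internal fragments are treated like 3′ fragments because the mechanism —
  a cap-independent 5′ end — is identical.
- **5′ fragments:** elongating ribosomes cover the retained ORF portion; if
  the cut truncated the ORF (fragment end < cds_end) an extra
  Poisson(density × stall_weight × abundance) of P-site mass lands on the
  fragment's last nucleotide — ribosomes reaching a 3′ end with no stop
  codon stall there. Fragments that retain the stop codon terminate
  normally and place no stall mass.

Reads get uniform lengths in [25, 34] nt, uniform random 7-nt UMIs, and a 5′
end back-computed from the P-site by the configured offset (+12 nt). Reads
whose 5′ end would be negative, or which cannot fit at ≥25 nt before the
transcript end, are discarded.

### RNA-seq arm

Gene counts are negative binomial (Var = μ + αμ²) with mean proportional to
surviving fragment mass overlapping the CDS, scaled to the requested depth.
`simulate_count_tables` is a faster count-level variant for the differential
stages: lognormal baselines, per-gene survival (1 − loss) × resistance, and
footprint means = RNA means × per-gene ribosome loading, where a TE shift
multiplies loading under treatment. Replicate dispersion defaults to 0.02, a
typical cell-line replicate value; the null-calibration check deliberately
uses a harsher 0.1.

In the TE-recovery experiment the TE-shifted genes are drawn among cleavage
responders (RNA log2FC ≈ ±2.5). This mirrors the genes the consideration
filter is designed for: a 4× TE shift on an RNA-flat gene puts the footprint
log2FC exactly at the |log2FC| > 2 threshold, where any method detects it
half the time by construction.

## The measurement pipeline

- **Footprint processing:** length filter [25, 34]; UMI deduplication on the
  key (transcript, 5′ position, length, UMI) — the conservative
  position-indexed reading; a global per-UMI collapse would merge distinct
  molecules. Fixed +12 nt P-site offset for all lengths (a per-length table
  is a config hook via the `offset` argument). P-sites falling off the
  transcript are dropped and counted, never clamped. rpm normalization
  scales the library to 1e6 and is flag-guarded idempotent.
- **Region metrics:** the three regions partition every position exactly
  (half-open intervals; the position at cds_start is ORF). Default ratio
  mode is per-nt density — invariant to region length and library scaling;
  the total-rpm ratio is available via `mode="total"` since both readings
  are defensible. Transcripts need ≥ 16 raw ORF reads (rescaled if the
  profile is rpm-normalized) to enter cohort summaries; below that a ratio
  is noise. The uORF rule assigns mass in uORF∩ORF overlap to the UTR side
  of the ratio, as appropriate for stress-responsive genes whose last uORF
  overlaps the CDS.
- **Boxplot summaries:** quartiles by linear interpolation; whiskers at the
  most extreme data point within 1.5 × IQR of the quartiles (so bounds stay
  inside the data range); notch half-width 1.58 × IQR/√N. A verbatim /N
  variant exists because both conventions circulate; √N is the standard
  notch formula and the default.
- **Metagene:** anchor conventions are recorded in the output — start:
  offset 0 = first CDS nt; stop: offset 0 = first nt of the stop codon
  (cds_end − 3). Note that offsets +1 and +2 after the stop anchor are still
  inside the ORF, so even an intact-only library shows a small nonzero mean
  over (0, +60]. Default windows −50/+150 (start) and −150/+150 (stop).
  Default normalization divides each gene by its mean ORF occupancy (equal
  gene weighting, scale-invariant); pooled averaging reproduces
  depth-weighted profiles. Offsets a transcript cannot cover contribute
  nothing (no zero-padding).
- **Differential stage:** two-group only, by design — the package's claims
  are property-based (calibration, power, recovery), not parity with any
  external DE tool, and multi-factor/batch designs are out of scope.
  Median-of-ratios size factors (scale-free: a global depth change leaves
  factors unchanged). Per-gene dispersion by method of moments on
  normalized counts (pooled within-group variance), shrunk in log space
  toward a fitted α(μ) = a0 + a1/μ trend with prior weight 20 effective df;
  genes whose moment estimate is non-positive carry no dispersion
  information and take the trend value outright. Wald statistic from the
  delta-method SE of log2 of an NB replicate mean, referred to a
  moderated-t with df = residual + prior df; BH adjustment. The pseudocount
  0.5 guards log2 fold changes of zero means. Constants (prior df 20,
  dispersion clip [1e-8, 10], trend clip at the 2.5/97.5 percentiles) are
  fixed in `diffexpr.py`.
- **TE classification:** te_change = footprint log2FC − RNA log2FC (the
  off-diagonal distance in a footprint-vs-RNA fold-change plane, up to √2).
  A gene is considered when *either* assay is significant (|log2FC| > 2,
  padj < 0.01) and that assay's baseMean > 50; considered genes are
  te-up/te-down at |te_change| > log2(2). Exclusions carry machine-readable
  reasons.
- **Gene sets:** response subsets are base-list ∩ DE calls; paired t-tests
  pair by gene (the natural pairing unit when comparing per-gene fold
  changes between conditions). No cross-panel multiple-testing correction
  is applied; each panel reports its own test. The packaged lists are
  synthetic placeholders wired to the simulator's gene ids — real analyses
  supply curated lists as plain text.

## Fixture scale and what the tests show

The read-level fixture regime is 60 genes × 60 copies at density 0.2, 20
seeds for across-seed claims; count-level experiments use 2000 genes, depth
2e6, n = 3. These sizes give stable statistics in seconds while exercising
every code path; they are stated here as the package's chosen study
conditions.

Passing tests show that the pipeline *recovers what the simulator encodes*:
motif-specific cuts, re-initiation-driven 3′UTR occupancy, 3′-end stalling,
resistance-driven relative upregulation, TE shifts. They do not show that
real libraries behave like the simulator: the generator has no sequence
bias, no codon-level pause structure, no rRNA/tRNA contamination, no
alignment ambiguity (multimapper weights are supported in processing but not
generated), uniform rather than peaked footprint lengths, and fragment ends
exactly at motif cuts with no exonucleolytic trimming. Conclusions about
real data rest on the correctness of the measurements, not on the realism of
the generator.

## Numerical and degenerate-input choices

- All simulation is seeded (`numpy.random.default_rng`); every simulate_*
  call is bit-reproducible given (inputs, seed).
- Empty cohorts, zero libraries, all-zero genes, missing UMIs, unknown
  transcript ids, zero-variance paired differences and infeasible
  transcriptome configurations raise typed errors with context; undefined
  ratios carry reasons instead of NaN surprises.
- Wig export writes one fixedStep block per contiguous nonzero run
  (1-based, step 1); zeros are implicit, so round trips are lossless and
  the file stays sparse.
- Ties in `call_de` thresholds are strict inequalities, matching the
  "greater than" phrasing of the filters.

## Known limitations

- No multi-factor designs, batch terms or shrinkage of fold changes; the
  differential stage is a calibrated stand-in, not a DESeq2 replacement.
- uORF calling from data is out of scope; uORFs come from the annotation.
- The simulator's re-initiation model is all-or-nothing per fragment and
  ignores 40S scanning distance, Kozak context and near-cognate starts.
- UMI collisions (uniform over 4^7) slightly under-deduplicate at very high
  per-position depth; negligible at fixture scale.
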