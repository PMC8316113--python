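# Methods

## The ambigrammatic model

A segment is modelled as a forward ORF plus a reverse ORF in the −0 frame:
reverse codon *k* occupies the reverse complement of forward codon *k*, so
the two reading frames share codon boundaries and the reverse amino acid at
*k* is `translate(revcomp(codon_k))`. Three forward codons (TTA, CTA, TCA)
have stop reverse complements (TAA, TAG, TGA); a genome is ambigrammatic
over a region exactly when that region's forward frame contains neither a
forward stop nor one of these three reverse-stop generators. All internal
coordinates are 0-based half-open on the forward sequence; reverse-strand
features are projected onto forward coordinates for interval arithmetic;
RNA input is normalized to the DNA alphabet on read.

The six-frame scanner reports, per frame and strand, the ORF running from
the first ATG of each stop-free codon stretch to the stretch end. Because
start annotation for reverse ORFs of ambigrammatic viruses is partly
schematic, stop-free stretches without an ATG are also reported, flagged
`has_start=False`; they are never used for mutation design.

## Opposing-frame mutant design

Three modes, each verified internally by translating both frames before and
after applying the plan:

* **stop_reverse (stR)** — single-base substitutions synonymous in the
  forward frame that convert a codon into a reverse-stop generator. The
  donor set is derived from the codon table at run time; candidate sites
  are further restricted to codons that also admit a forward-synonymous
  *non-stop* alternative at the same nucleotide position (in practice the
  CTN/TCN Leu/Ser codons; TTG→TTA is excluded because position 3 of TTG
  has no such alternative). This restriction guarantees that a matched
  nonsynonymous control can always be placed at identical positions.
* **nonsyn_reverse (ns)** — at exactly the stR plan's nucleotide
  positions, the forward-synonymous substitution that changes the reverse
  amino acid without creating a stop.
* **stop_forward (stF)** — reverse-synonymous substitutions creating
  forward stops, with eligibility starting at forward codon 14.

Site selection is deterministic, 5′-most first within the requested region
(default: the dual-coding overlap). The genome generator places a
forward-stop donor codon (CAA) at codon 14 so stF designs are always
feasible on generated genomes.

## Synthetic data: what it emulates and what it does not

All generators draw from named substreams of a single root seed
(`numpy` `SeedSequence`), so outputs are bit-reproducible given
(config, seed). Defaults are the study conditions:

* **Genomes** — 5′-GGGG head, codon body drawn uniformly from the 58
  codons legal in the dual-coding overlap (first codon ATG, last codon CAT
  to give the reverse strand its ATG), and a 21-nt inverted-repeat tail
  ending CCCC-3′. A 3.2-kb genome is ~99% dual-coding.
* **mNGS reads** — uniform start positions, 100-nt reads; per-segment
  expected read count ∝ copy number × length; strand drawn at the
  configured +:− ratio (defaults 70 for the RdRp-like segment, 145 for
  the Robin-like segment; copy ratio 3.8 small:large). No fragmentation
  model beyond uniform starts: adequate for the ratio estimators, which
  depend only on counts.
* **SNVs** — host mode assigns each read wholly to one of two haplotypes,
  with the minor-haplotype fraction drawn once from U[0.45, 0.50] (the
  frequency range typical of diploid biallelic variation); viral mode
  draws per-site frequencies independently from U[0.02, 0.32], makes one
  site tri-allelic, and gives reads independent variant draws (no
  linkage). Sites are placed in pairs within half a read length so that
  spanning reads exist and phasing is testable — mirroring the fact that
  short-read phasing is only informative for nearby variants.
* **Footprints** — host-like: 5′ ends on codon boundaries (3-nt phase
  lock), lengths peaked at 33 nt (support 31–35). Viral plateau-like: 4–6
  stall sites per genome, queue positions spaced by U{30..40} nt upstream
  of each stall (queue depth 8), lengths uniform on 27–37 nt, no phase
  lock. Random 5-nt UMIs on every footprint. Stall count, queue depth and
  plateau heights are free parameters with these documented defaults.
* **Small RNAs** — both strands, length distribution with mode 21 nt.

Not emulated: sequencing errors, quality scores, adapter chemistry, GC or
position-dependent amplification bias, rRNA contamination. Passing
recovery tests therefore demonstrates estimator correctness under the
stated statistical structure, not robustness to real-library artifacts.

## Estimators and numerical choices

* **Strand ratio** count(+)/count(−), flagged infinite at zero negative
  reads, refused below 100 total reads (the reanalysis filter for
  segments with too few mapped pairs).
* **Copy ratio** (reads_a/len_a)/(reads_b/len_b); unbiased under uniform
  sampling.
* **SNV classification** — host_biallelic requires all non-reference
  frequencies inside the biallelic band (default [0.40, 0.60]), ≤2 alleles
  per site, and phase-consistency; quasispecies requires any frequency
  below the band, a >2-allele site, or phase inconsistency. Phasing is
  operationalized on reads spanning ≥2 sites: a pair is consistent when
  ≥90% of spanning reads carry one of the two complementary combinations
  (both-reference or both-major-alternate). Sites without spanning
  evidence are phase-uninformative and neither support nor veto either
  verdict.
* **Coverage conventions** — center mapping spreads 1/L over the L covered
  positions (unnormalized vectors sum exactly to the read count);
  fiveprime puts 1 at the 5′ end. Footprints outside 27–39 nt are
  excluded; normalization is ×10⁶/mapped reads.
* **Welch periodicity** — the padded CDS (25 nt each side) of a 5′-end
  profile is scaled to unit sum within the reference (the scaling choice
  when profiles must be comparable across libraries; the exact formula is
  otherwise unconstrained), then `scipy.signal.welch` with Hann window,
  nperseg=500, noverlap=250, density scaling, median averaging. The peak
  frequency is the argmax over strictly positive frequencies; off-zero
  power below machine-noise scale (possible because scipy detrends each
  segment) is reported as `flat`. The 3-nt period appears at 0.333
  cycles/nt, judged at ±1 frequency bin (1/nperseg).
* **Plateau concentration** — Gini coefficient of the per-position density
  plus the smallest fraction of positions holding 90% of the mass. Both
  are reproducible surrogates for the visually defined plateau pattern;
  neither is claimed to be a canonical definition (none exists).
* **Length-distribution comparison** — two-sample Kolmogorov–Smirnov on
  integer lengths via scipy (exact/asymptotic p as scipy selects);
  indeterminate below 50 reads per sample.

## MNase cut-bias null model

MNase cleaves preferentially 5′ of A/T, so footprint boundaries carry
sequence bias. The model records, for each cut, enrichment weights
(observed base frequency ÷ reference background) at one position on either
side of the cut ("either side" is read minimally as a 2-base context;
window width configurable) plus the empirical length distribution. 5′ and
3′ biases are treated independently, matching the generator's two-step
sampling: draw a 5′ cut ∝ position weights, then a length from the length
distribution re-weighted by the 3′-cut base preference. Default protocol:
10,000 footprints × 10 runs on the actual and on a scrambled (seeded
uniform permutation) sequence.

Weights are identifiable only up to a per-offset scale; `canonical_bias`
anchors them so the background-weighted mean is 1, the form the estimator
returns. Round-trip recovery is within ~5% at 50,000 footprints with a
broad (11-length) distribution; with very few distinct lengths the 3′
weights attenuate, because the 3′ preference can express itself only
through the limited length choice — an intrinsic property of the two-step
model, not an estimator defect.

Run-level Pearson correlations (actual vs observed; scrambled vs observed)
are compared by Welch's t-test on Fisher-z values. "bias-insufficient"
requires no significant difference *and* both mean correlations below 0.3.
The bias model should be fitted on ordinary (host-like) footprints, not on
the anomalous profile under test; fitting on the test profile leaks its
positional base composition into the model and biases the comparison.

## Sequence context

The default folding engine is a simplified stacking scorer: maximum-weight
nested pairing (Nussinov recursion) over pair pseudo-energies GC −3,
AU −2, GU −1 with minimum loop 3. It preserves relative structure (an
inverted repeat scores below its shuffle; homopolymers score 0) but does
**not** reproduce thermodynamic MFE values; the `vienna` engine (ViennaRNA
at 28 °C, the insect-culture temperature) is used when the bindings are
available. Sliding-window defaults are window 50 nt, step 1 nt.

`local_mfe_peak(x) = MFE_x − mean(MFE_{x−w/2}, MFE_{x+w/2})` is exactly
linear and zero on constant and linear profiles; edges are NaN. Footprint
boundaries are `numpy.gradient` of the coverage profile.

Amino-acid context: anchor codon containing the nucleotide at ⌊2L/3⌋ from
the footprint 5′ end (approximate P-site), window of ≤20 residues upstream
(the exit-tunnel region), net charge with K/R = +1, D/E = −1 and histidine
neutral (conventional at cytoplasmic pH), Kyte–Doolittle hydrophobicity.
Cohort enrichment against the ORF background uses a permutation null
(uniform re-anchoring, 1,000 permutations, Bonferroni across the 20 amino
acids + charge + hydrophobicity).

## Pipeline

`run_pipeline` executes genomes → mNGS → SNV → footprints → small-RNA →
MNase-null in dependency order; a disabled upstream stage raises a named
error. Reports are versioned (schema 1), carry the seed and a config hash,
and are byte-identical across runs with the same config. Default sizes
(50,000 mNGS reads, 10,000 footprints, 10,000 small RNAs, 10 × 10,000
null footprints) complete in a few seconds on one CPU; the full default
pipeline is far inside a 10-minute budget.

## Known limitations

* The generator's plateau heights, stall counts and queue depths are
  plausible defaults, not fitted quantities.
* SNV calling consumes the simulator's truth variant lists (or tables);
  the package does not pileup-call from raw base alignments.
* The bundled folding engine is ordinal, not thermodynamic.
* A/P/E-site offset calling and codon-level occupancy are deliberately out
  of scope: MNase end imprecision makes offset assignment unreliable.
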