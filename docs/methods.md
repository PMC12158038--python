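# Methods

## The detection protocol as implemented

Genotyping of the sorghum dwarfing loci follows the standard wet-lab
protocol — PCR of a locus-specific fragment, Sanger sequencing, comparison
to the wild-type gene — translated into deterministic software stages:

1. **In-silico PCR.** The forward primer is searched on the stored strand of
   the gene template (templates are stored gene-5′→3′ with position 1 at the
   ATG, so only one orientation is meaningful); the reverse complement of
   the reverse primer is searched downstream. The product spans both primer
   footprints, which matches the size a gel would show. With
   `max_mismatch > 0`, matches must be exact in the three 3′-terminal bases
   of each primer — a cheap surrogate for extension specificity that avoids
   any thermodynamic model. Zero or multiple candidate products raise
   explicit errors (`NoSite`, `AmbiguousPriming`) rather than guessing.
2. **Size prescreen (Dw3 only).** The large-insertion allele *dw3-ref*
   yields a product ~0.9 kb longer than every other allele, so products of
   ≥ 1800 bp (inclusive, configurable) are classed as insertion-carrying
   before any alignment. 1800 sits midway between the ~1280-bp and ~2160-bp
   product classes and tolerates several hundred bp of drift either way.
3. **Alignment.** The product is aligned globally to the wild-type amplicon
   with Biopython's `PairwiseAligner` under affine scoring: match +2,
   mismatch −3, gap open −6, gap extend −1 (a gap of length L scores
   −6 − (L−1)). These values make each catalog indel align as one gap event
   instead of a cloud of mismatches; any scoring with gap-open ≫ extend and
   mismatch < 0 behaves equivalently on this data.
4. **Variant extraction and normalization.** Alignment columns are scanned
   once; adjacent gap columns merge into a single indel, and every indel is
   then explicitly left-normalized against the reference (shifted to its
   leftmost equivalent placement). Canonical coordinates therefore do not
   depend on the aligner's tie-breaking. Consecutive mismatch columns are
   emitted as separate single-base substitutions; the catalog contains only
   1-bp substitutions, so nothing downstream distinguishes an MNP encoding.
5. **Signature matching.** A substitution signature requires the exact
   alternate base at the exact position (the wild-type base at the *dw1*
   site is not part of the signature — any non-T is wild type there); a
   deletion requires position and length; the *dw3-ref* insertion requires
   position and length within ±10 bp (its inserted content is not publicly
   printed, so content is never compared); the *dw3-sd4* duplication is
   interpreted as a tandem copy of reference bases 5820–5825 inserted after
   5825, which left-normalizes to an insertion starting at 5820. A call is
   wild type when no variant coincides with any signature interval; it is
   the unique satisfied allele when exactly one signature is matched (stray
   variants elsewhere — sequencing noise — never veto a match); it is
   `unknown` when variants coincide with signature intervals but satisfy no
   signature, or when two signatures are satisfied at once.
6. **Diploid composition.** Input is one or two haplotype sequences per
   locus; one sequence means homozygous. Sanger trace deconvolution of
   heterozygotes is out of scope, and haplotype pairs express every
   zygosity the nomenclature can encode. Genotype strings render homozygous
   loci as a single token (`dw1`, `Dw2`, `dw3-ref`) in the style used for
   inbred panels, heterozygotes as `Dw1dw1`, and compound heterozygotes as
   `dw3-a/dw3-b` (an invented but parseable rendering; compound
   heterozygotes do not occur in the published tables). The parser accepts
   both single-token and doubled homozygous forms.

## Population statistics

- **Survey summary.** A carrier is an accession homozygous mutant at ≥ 1
  locus; per-locus counts count accessions (a *dw1 dw3* double carrier
  increments both loci). Carrier percentage is taken over the full panel
  size, not only the genotyped subset. Heights are binned into eight 50-cm
  classes ((k−1)·50, k·50]; out-of-range values are reported, never
  silently dropped.
- **t-tests.** Group comparisons default to the Welch unequal-variance
  t-test with Welch–Satterthwaite degrees of freedom (via
  `scipy.stats.ttest_ind(equal_var=False)`); the pooled Student form is
  available behind a flag. Welch is the safer default because the published
  class standard deviations differ visibly between groups. Constant groups
  are detected by exact range (`np.ptp == 0`) because floating-point
  variance of a constant array can come out at ~1e−28. No multiple-testing
  correction is applied by default; a Bonferroni flag covers the three
  pairwise-class comparisons.
- **F2 grouping.** Default mode is *exclusive*: a single-recessive class
  excludes individuals that are also homozygous recessive elsewhere, and a
  pairwise class excludes triple recessives, so the six groups are disjoint
  and each isolates one genetic contrast. *Inclusive* mode (no exclusion)
  is provided for sensitivity analysis. Heterozygotes never count as
  mutant.
- **Broad-sense heritability.** H² = V_G/V_P from balanced one-way
  random-effects ANOVA: V_E = MS_within, V_G = (MS_between − MS_within)/r
  clipped at zero, V_P = V_G + V_E. Unbalanced designs are rejected rather
  than approximated (a REML fit would be the right tool there and is out of
  scope). The published panel-level H² of 93% is used only as one of the
  recovery-test calibration points, since the underlying replicate-level
  data are not available.

## The synthetic data generator

The generator exists so that every pipeline stage is testable without any
sequence download; it emulates the *structure* of the study's data, not its
biology.

- **References.** Seeded random DNA per locus (Dw1 1.9 kb, Dw2 1.6 kb,
  Dw3 7.3 kb — long enough to contain every signature coordinate), with the
  packaged primers embedded exactly once so wild-type amplicons are exactly
  427 / 997 / 1280 bp and every signature lies inside its amplicon. The
  wild-type base at the *dw1* site is set to C (the published protocol only
  says "non-T"); the *dw3* substitution sites are set to the published
  reference base A; the GA at 549–550 is set literally. Bases flanking each
  indel signature are constrained so that the leftmost placement of the
  indel is its catalog coordinate — left-normalization is then exact at
  tolerance 0. Real Phytozome gene sequences can be dropped in as a
  reference FASTA; nothing in the caller assumes the fabricated layout.
- **Allele application** edits a template per its signature; the *dw3-ref*
  insertion content is seeded random 882-mer whose terminal bases are pinned
  so the insertion cannot shift during normalization.
- **Noise** is substitution-only at a configurable rate (< 5%), outside
  caller-critical intervals: primer footprints plus each signature interval
  with a 1-bp flank (the flank preserves normalization anchors). Indel
  noise is deliberately never generated — Sanger-quality indel error would
  confound signature matching and no error model is published.
- **Landrace panels** are fully homozygous (inbred assumption), with a
  mutant allele drawn independently per locus per accession. Default
  frequencies are the carrier counts of the packaged survey table over the
  241-accession panel (dw1 4/241, dw2 2/241, dw3-ref 11/241, dw3-c 4/241,
  dw3-b 1/241). Real panels are not independent across loci (the published
  *dw1* carriers all also carry *dw3-ref*); the independence simplification
  affects only multi-locus co-occurrence, which no test relies on.
- **F2 populations** draw the recessive-allele dose per locus as
  Binomial(2, ½) — three unlinked loci (they sit on chromosomes 9, 6, 7),
  so no recombination map is needed. Height is
  `baseline − Σ single_effects − Σ pairwise epistasis + N(0, σ)`.
  The packaged effect model is **calibration, not inference**: baseline
  265.0 cm (the tall parent's class), single effects 25.5 / 28.5 / 53.2 cm
  and pairwise epistasis 38.4 / 40.6 / 28.1 cm chosen so the noise-free
  class means equal the published single- and double-recessive class means
  (239.5 / 236.5 / 211.8 and 172.6 / 155.2 / 145.7 cm), residual SD 22 cm
  (typical of the published within-class SDs). True per-locus effect sizes
  cannot be estimated from published summaries alone. Consequently the
  pipeline-recovery tests validate the *software* (simulation → calling →
  grouping → statistics round trip), not the biology.

## What passing tests do and do not show

Synthetic templates are clean: no heterozygous trace ambiguity, no indel
sequencing error, no structural variation beyond the catalog, primers always
match perfectly. Passing the round-trip suites shows the protocol logic,
coordinate arithmetic, and statistics are correct under the documented
conventions; it does not certify performance on real chromatograms or on
alleles outside the catalog. The `unknown` call class is the designed
behaviour for anything novel at a signature site.

## Problem sizes and determinism

Test and acceptance runs use the study-scale sizes: 241-accession panels,
608-plant F2 populations (20 seeds for segregation and class-mean checks),
100 seeded panels per heritability truth. Every random quantity flows from
an explicit integer seed through one `numpy` Generator per run; identical
seeds give byte-identical FASTA/CSV outputs.

## Known limitations and open points

- The published methods name two accessions (8R428, 8R431) as
  double-recessive carriers while the published genotype table lists them as
  `Dw1Dw2dw3-c` and `Dw1Dw2Dw3`; the packaged transcription follows the
  table and the discrepancy is left documented, not resolved.
- The printed ~2165-bp *dw3-ref* product size differs by 3 bp from
  1280 + 882; printed sizes carry a tilde and are treated as approximate —
  the code asserts 2162 on its own fabricated references and never 2165.
- Whether the published ± values are SD or SE is not stated; they are
  treated as SD throughout.
- The *dw3-sd4* "6-bp repeat" is read as a tandem duplication of 5820–5825;
  an unrelated 6-bp insertion at the same position would satisfy the same
  matcher. Likewise any ~882-bp insertion at 6204 passes as *dw3-ref*
  because the inserted sequence is not printed.
- Landrace allele draws are independent across loci; heritability supports
  balanced designs only; no linkage, selection, or field-spatial effects
  are modelled.
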