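# Methods

`limbscreen` implements the analysis of a multiplex CRISPR/Cas9
negative-selection screen in regenerating mosaic haploid axolotl limbs,
together with a generative simulator of the whole experiment. This note
records the models, the parameter choices, and the numerical conventions,
and states what the synthetic data can and cannot establish about real
screens.

## The screen and its readout

A mosaic F0 limb carries many clonal cell lineages, each labeled by a
distinct Cas9-induced indel allele at a targeted locus; in a haploid limb
one allele per locus suffices for loss of function. The limb is amputated,
regenerates, and both limbs are deep-sequenced at each target with
UMI-tagged amplicons. After UMI deduplication, each sample's unique
molecule counts are rescaled to reads per ten thousand (RP10K; the
denominator approximates the number of template cells) and log-transformed
with a pseudocount, `log2(RP10K + 1)`, so that an allele absent from a
limb maps to 0.

For each gene, every mutant allele detected in the primary limb is paired
with its abundance in the regenerate. Neutral lineages re-occur at similar
frequencies, so the regression of regenerate on primary log scores has a
slope near the control slope; negatively selected lineages are depleted or
lost, which flattens the slope and raises the fraction of alleles with
zero regenerate reads. The screen tests both signatures:

* **Homogeneity-of-slopes ANCOVA.** For gene *g* versus a comparison pool,
  the pooled model `y = b0 + b1 x + b2 G + b3 (x G)` (G the group
  indicator) is compared with the common-slope reduction by the
  extra-sum-of-squares F test, `F = (RSS_red − RSS_full) / (RSS_full /
  (n − 4))` on (1, n − 4) df. For two groups this equals the squared-t
  slope-difference test (verified as a property test).
* **Allele-dropout chi-square.** Pearson's chi-square on the 2×2
  lost/preserved table, df = 1, **no** continuity correction — the
  uncorrected statistic is the one that reproduces the published values
  from the published counts. The statistic is computed directly from
  expected counts; the p-value comes from the chi-square distribution.

A gene is **flagged** when its ANCOVA against the pooled controls is
significant at α (default 0.05) *and* its slope is below the control
slope; a gene with fewer than 3 paired alleles is reported as
"insufficient alleles" and not tested. Genes significant against controls
are treated as candidate outliers, and every gene is additionally compared
against the pooled other targets with those outliers removed, so one
strongly selected gene cannot mask another. No multiple-testing correction
is applied; raw p-values are reported so users can apply their own.

Lost alleles (regenerate log score 0) are included in the regressions —
they carry the dropout signal that makes the slope sensitive to selection.

## Simulator

One gene-limb is drawn as follows:

1. **Clone sizes.** `n_lineages` clone sizes are a symmetric
   Dirichlet(`lineage_concentration`) draw scaled to `mutant_fraction`;
   the remainder is wild-type. Each clone gets a distinct random indel:
   deletions (4:1 odds over insertions) with geometric(p = 0.3) length
   truncated to [1, 30] spanning the cut site, or insertions of 1–10
   random bases at the cut.
2. **Regeneration.** `blastema_founders` (B) cells are drawn multinomially
   from the limb; each mutant founder of the targeted gene survives
   independently with probability 1 − s (selection acts once, at blastema
   founding); survivors renormalize to the regenerate's frequencies. If no
   founder survives the regenerate is all wild-type (logged warning).
3. **Sequencing.** `umi_depth` template molecules are drawn multinomially
   from the limb's allele frequencies; each molecule receives a distinct
   10-nt UMI (collisions re-drawn) and a 1 + Poisson(`pcr_duplication_mean`
   − 1) read count; each read is `index + universal adapter + UMI +
   gene-specific insert` with uniform per-base substitution errors and a
   constant quality string.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `n_lineages` | 10 | matches the observed ~5–8 detected alleles per gene-limb after sampling |
| `lineage_concentration` | 0.2 | produces the observed many-rare/few-common spectrum |
| `mutant_fraction` | 0.277 | mean detected-allele frequency ≈ 3.5%, matching the empirical 3.46% |
| `blastema_founders` (B) | 900 | calibrated so the neutral screen brackets the empirical fidelity benchmarks (below) |
| `umi_depth` (D) | 10,000 | the template represents ≈10,000 cells per target per limb |
| `pcr_duplication_mean` | 1.5 | modest sequencing-depth-to-UMI ratio |
| `sequencing_error_rate` | 0.002 | typical short-read substitution rate |
| `read_length` | 250 | covers the full 180-bp default amplicon plus layout |

The bottleneck size and clone-size law were calibrated **jointly and
once**, before any acceptance test was written, against the neutral
(control-locus) fidelity of real screens: ~24% of primary-detected alleles
lost overall and ~29% of low-frequency (<1.6%) alleles lost. With the
defaults the simulator gives ≈18–19% overall and ≈33% low-frequency loss —
inside the ±10-point bands the tests assert. A much larger bottleneck
(tens of thousands of founders) cannot reproduce the observed loss under
any Dirichlet clone law, because sequencing 10,000 molecules alone loses
almost nothing; the observed dropout requires a founder population of
order 10³. B is exposed as a tunable for users who want a different
fidelity regime.

### What the simulator does not model

Grafting chimerism, haploid developmental delay, PCR chimeras, index
hopping, base-quality variation (qualities are constant; no analysis stage
uses them), paired-end read merging (single reads span the amplicon), and
cross-locus linkage (each gene's mosaic is drawn independently; real
multiplex injections can place two targets' mutations in one lineage).
Passing tests therefore show the statistics behave correctly under the
stated generative model, not that the caller is robust to artifact classes
the simulator never produces.

## Read processing

* **Demultiplexing** is exact matching of the 4–6 nt sample index at the
  read start; indexes must be mutually non-prefixing.
* **UMI extraction** finds the universal adapter (≤1 mismatch) after the
  index, takes the next 10 nt as the UMI, and requires the gene primer
  (≤1 mismatch) immediately after; the insert used for calling starts at
  the primer.
* **Allele calling** globally aligns the insert to the reference from the
  primer anchor onward (match +2, mismatch −3, gap open −8, extend −1,
  free 3' end gap, via Biopython's PairwiseAligner). Indels within ±20 bp
  of the cut site define the allele; substitutions are ignored as
  sequencing error; alignment identity <80% outside indels or any indel
  entirely outside the window makes the read unassigned (with a reason
  code). Events are left-aligned (VCF-style) so equivalent placements in
  repeats collapse to one canonical descriptor — the simulator
  canonicalizes the same way, which is what makes exact zero-error
  recovery testable.
* **Performance.** Identical inserts are called once, and a new insert
  first goes through a vectorized single-indel search: the net length
  difference fixes the indel size and the mismatch-minimizing split point
  fixes its position. The result is accepted only when ≤3 substitutions
  remain and the optimum is unambiguous; in that regime it provably equals
  the affine alignment's call (any alternative gap structure costs more
  than the substitutions it could absorb), and a seeded property test
  asserts the equivalence read-by-read. Everything else falls back to the
  full aligner. An earlier design that assigned reads to the
  nearest catalogued allele by Hamming distance was rejected: two real
  alleles can be a single substitution apart (adjacent same-length
  deletions), and nearest-neighbor assignment silently merges them.
* **UMI deduplication** gives each UMI one unique molecule, assigned to
  the strict-majority allele among its reads; tied UMIs are dropped and
  counted. Deduplication happens after calling (call-then-dedup and
  dedup-then-call give the same unique counts; calling first streams
  better).
* **Artifact filtering** removes any non-WT allele whose count in the
  matched non-mutant control sample exceeds max(2 UMIs, 0.05% of the
  control total); a missing control passes the sample through with a
  warning.

Known edge case: a substitution that lands exactly on the base
distinguishing two adjacent same-length deletions genuinely converts one
allele's read into the other's exact sequence; no caller can separate
them, and the substitution-invariance property test excludes that boundary
region. An error inside an insertion allele's inserted bases likewise
creates a (rare, low-count) variant allele.

## Quantification conventions

* RP10K coefficient = 10,000 / total assigned unique molecules, computed
  **per gene per limb sample** (each limb is sequenced separately).
* Allele universe = non-WT alleles detected in the primary limb;
  regenerate-only alleles are reported in a side list but never paired.
* `lost` ⇔ zero unique molecules in the regenerate.
* Fold change is computed on pseudocounted RP10K,
  `max(r1+1, r2+1) / min(r1+1, r2+1)`, so it is defined (and ≥1) for lost
  alleles; the classification buckets split at fold < 2 vs ≥ 2.
  Consequently a lost allele falls in the <2 bucket only when its primary
  RP10K is below 1 (possible only when total assigned > 10,000), and a
  high-frequency lost allele can never fall there — the (high, lost, <2)
  cell is structurally empty.
* The low/high frequency boundary is a strict `<` at 1.6% of the primary
  limb's assigned reads.

## Numerical choices

* Interaction F below 1e-10 is reported as exactly 0 with p = 1
  (identical groups up to floating-point noise).
* A 2×2 table with a zero margin returns statistic 0, p = 1, flagged
  degenerate rather than dividing by zero.
* Regressions require ≥3 pairs and a non-constant predictor; violations
  raise typed errors that the report assembly converts into the
  "insufficient alleles" verdict or a skipped comparison.
* Samples with zero assigned reads raise and are excluded from pairing
  (logged).
* All simulation randomness flows through one `numpy.random.Generator`;
  a fixed seed makes every output file byte-identical.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own verification budget: the end-to-end study uses
12 animals × 6 genes (two controls; one gene at s = 0.8) at 10,000
UMIs/target and 0.2% error, 20 seeded replicates through the full FASTQ
pipeline; the type-I (all-neutral) study uses 20 replicates at the
unique-molecule level (80 gene tests); the neutral-fidelity calibration
uses 240 simulated gene-limb pairs (~1,700 alleles). At these sizes the
detection rate is expected near 100%, the null flag rate near α, and the
loss fractions have Monte-Carlo error ≈1 percentage point.

## Limitations

* The slope statistic responds weakly to moderate selection (s ≤ 0.5):
  a uniform survival penalty mostly shifts the log-scale intercept, and
  the slope reacts mainly through allele dropout. The dropout chi-square
  carries much of the power in that regime; the monotonicity of both
  statistics in s holds for ensemble means, not per-replicate.
* ANCOVA assumes homoscedastic normal residuals; log scores with a point
  mass at zero violate this, which is tolerated (the simulated type-I
  rate calibrates at ≈α) but worth knowing for small gene sets.
* One-way ANCOVA across >2 groups is out of scope; every comparison is a
  two-group slope test against a pooled reference set, and each reported
  statistic names the exact pool it was computed against.
* Per-animal random effects are not modeled; alleles are pooled across
  animals within a gene.
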