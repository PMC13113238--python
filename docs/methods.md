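# Methods

`mutacc` re-implements, as a tested library, the analysis pipeline of a
*Daphnia pulex* mutation–accumulation (MA) experiment: replicate sublines
are propagated through single-progeny bottlenecks so that new germline
mutations accumulate nearly free of selection, and deep short-read
sequencing of each subline is used to count de novo mutations, estimate
per-generation rates and spectra, detect de novo copy-number variants, and
characterize cadmium biokinetics of adapted versus non-adapted animals.
This note documents the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic-data validation does and
does not demonstrate.

## SNM calling (consensus / putation logic)

Input is a pileup-derived table of per-subline, per-site read evidence:
allele counts split by read orientation, total depth, and the number of
multimapped reads. Screening per subline follows the MA-caller criteria:

* multimapped reads are removed first (in this format, allele counts
  already exclude them and `depth = Σ counts + multimap_reads`, so removal
  is subtraction of `multimap_reads` from depth);
* sites within ±20 bp (inclusive) of an indel-mask position are excluded;
* residual depth must lie in the 12–45× band (the stated maximum is read
  as an exclusion rule for >45×);
* a site is called homozygous when the top allele carries ≥ 0.9 of reads,
  heterozygous when exactly two alleles each carry a fraction in the
  closed interval [0.3, 0.7]; fractions in (0.7, 0.9) or (0, 0.3) yield
  no call;
* each allele of a call needs ≥ 2 reads in both orientations (PCR-artifact
  guard). A three-alleles-in-band configuration (impossible under the band
  but guarded) yields no call.

Across the sublines of one condition, a site is *analyzable* only when
every subline produces a call. If all calls agree, the shared genotype is
the consensus (ancestral) genotype. If all but exactly one subline agree
and the odd subline is callable and different, the site yields a candidate
de novo mutation ("putation") in the odd subline. Any other configuration
(two or more discordant sublines, or any uncallable subline) removes the
site from both the mutation count and the analyzed-site denominator —
this symmetric removal is what keeps the rate estimator consistent.
Putations whose derived genotype differs from the consensus by more than
one allele (e.g. hom→hom changes, which would require two hits) are
counted and dropped; single-allele changes — including loss-of-
heterozygosity calls — become SNM records with a class, a reference-strand
triplet context (5′ flank, ancestral allele, 3′ flank) and a region label.

### Analyzed-site accounting

n_i (analyzed diploid sites of subline i) and n_{b,i} (per ancestral base
b) come from the consensus. In census mode every analyzable site is
counted directly. In sampled mode — evidence emitted only for a random
subset of sites, the simulator's default — n_i is the analytic site total
carried in metadata multiplied by the observed analyzable fraction of the
evaluated sites, partitioned by the observed consensus base composition.
Heterozygous consensus sites contribute 0.5 to each allele's tally. A
large disagreement (>0.1 in A+T share) between sampled and analytic
composition raises a warning.

## Rate estimators

Genome-wide per-subline rate and its standard error use the canonical MA
forms: μ_bs = m_i / (2 n_i T_i), SE = √(μ_bs / (2 n_i T_i)), with T_i the
generations propagated. The condition-level rate is the unweighted mean
across sublines with SE = s/√N (s the across-subline SD) — the
mean-of-lines estimator standard in MA studies. Conditional (class-
specific) rates replace n_i with the count of sites of the class's
ancestral pair (n_A + n_T for A:T-origin classes), and their SE is
√(μ_cond / (L · 2 n̄_b · T̄)) with L sublines, n̄_b the mean eligible-site
count and T̄ the mean generations; n_b here counts *sites*, so the diploid
factor 2 appears explicitly, keeping units consistent with μ = m/(2nT).

Spectrum summaries: Ts/Tv is transitions (A:T→G:C, G:C→A:T) over the four
transversion classes, pooled per condition; the GC→AT mutation bias is
AT-gaining (G:C→A:T, G:C→T:A) over GC-gaining (A:T→G:C, A:T→C:G) counts
by default, with a conditional-rate-ratio variant behind a flag (printed
condition-level values are single numbers, so pooled counts are the
default reading). MNM clusters chain same-subline SNMs whose consecutive
gaps are ≤ 50 bp; clusters of ≥ 2 are flagged (the threshold is
configurable; ≥ 2 is the standard MNM definition). Heterozygosity π_t is
the heterozygous fraction of analyzable consensus sites. The life-table
reproductive rate r sums daily offspring over a 30-day window (three
broods for these genotypes).

## Regional and context analyses

Expected regional proportions are analyzable-site shares per region label.
Precedence for overlapping annotation is splice_junction > exon > 3′UTR >
intron > promoter > intergenic (most specific label wins; promoter = 1 kb
upstream, splice junction = first/last 10 bp of an intron, both
configurable). Observed-vs-expected uses the two-sided exact binomial test
in the minimum-likelihood sense (sum of all outcome probabilities not
exceeding the observed outcome's); condition-vs-condition comparisons use
the two-sided Fisher exact test (sum of hypergeometric tables at most as
probable as the observed). No multiple-testing correction is applied by
default, matching per-test reporting; Benjamini–Hochberg is available.

Trinucleotide context tables count all overlapping reference-strand
triplets of the genome ("Tot. Trips"), the mutated triplet of each SNM
("Mut Trips", 5′ flank–ancestral–3′ flank; scaffold-edge SNMs dropped and
reported), and the expected count = total SNMs × triplet abundance /
total triplets. Each context gets a 1-df chi-square (obs−exp)²/exp with no
continuity correction; a global test was considered but per-context 1-df
matches per-cell reporting. Strand collapsing and a pooled CpG row
(C/G-origin SNMs flanked by C or G on either or both sides) are optional.
The A+T% profile stacks ±200 nt windows around SNMs into a 401-column
alignment and slides a 4-nt window in 1-nt steps, giving 398 offsets.

## CNV detection

Per-subline 1-kb window depths are normalized twice: by the subline's
median window depth (library size) and then by the cross-subline median of
the same window (local mappability). Runs of ≥ 3 consecutive windows with
ratio ≥ 1.4 (gain; 3 copies ≈ ratio 1.5) or ≤ 0.6 (loss; 1 copy ≈ 0.5),
merged across single-window gaps, become calls when they span ≥ 3000 bp.
A call overlapping a same-direction call in another subline of the
condition is discarded: a de novo CNV is confined to one subline
(paralleling the putation rule); shared events predate the MA lines. The
window size, thresholds, run length and gap tolerance are parameters of
`CnvParams`; the defaults are this package's own declared operating point
for a windowed median-ratio detector, not inherited from any prior tool.
CNV statistics report count/Σ generations, bp per generation, per-subline
concentration, and a two-sided Mann–Whitney U comparison of length
distributions (exact for small samples without ties, normal approximation
with tie correction otherwise).

## Cadmium biokinetics

One-compartment model with first-order uptake and elimination,
d[Cd]/dt = k_u − k_e·[Cd], initial burden 0 (culture animals are below the
detection limit). Closed forms: uptake [Cd](t) = (k_u/k_e)(1 − e^(−k_e t))
with limit k_u·t as k_e → 0 (switched below |k_e| < 1e−10); elimination
[Cd](t) = Cd_A·e^(−k_e t). Estimators invert one A-daphnid / E-daphnid
burden pair: k_e = ln(Cd_A/Cd_E)/Δt_elim and
k_u = k_e·Cd_A/(1 − e^(−k_e·Δt_exp)), dry-weight normalized to k_u* when
weights are given. `expm1`/`log1p` forms avoid cancellation at small k_e,
giving exact inversion to < 1e−10 relative error over k_u* ∈ (0, 100],
k_e ∈ [0, 2]. Negative k_e estimates (E-burden above A-burden under noise)
are returned with a warning, never clipped, and propagate into clade
summaries (mean ± SD with n; single-member clades report SD 0 with a
flag). The clade contrast is reported as summaries only; a mixed model
with isolate as a random effect is out of scope here.

## Synthetic data: what it emulates

The simulator generates every pipeline input with known ground truth:

* **Genome substrate** — by default 4 scaffolds × 250 kb at GC 0.41
  (near the *D. pulex* genome average), with 40 gene models per scaffold
  (1 kb promoter, 4 × 200 bp exons, 300 bp introns with 10 bp splice
  junctions, 300 bp 3′UTR) partitioning every base into exactly one
  region.
* **SNM planting** — per subline and class, Poisson counts with mean
  2·n_c·T·μ_c, where n_c is the analytic eligible-site count (default
  n = 10⁸ analyzed diploid sites, the study's scale) and the default class
  rates split a total of 2.06 × 10⁻⁹ per site per generation (the
  adapted-genotype control estimate) with weights reproducing a Ts/Tv near
  1.07 and a GC→AT bias near 1.8. Positions land on eligible substrate
  bases away from indel masks and scaffold edges. A 5% MNM fraction
  *rearranges* already-drawn SNMs to within 50 bp of a same-subline anchor
  — moved, never added, so totals stay at the Poisson draws.
* **Evidence** — depth ~ Poisson(25) per site × subline (the study's
  ~25× coverage), scaled 1.5×/0.5× inside CNV gains/losses; per-read
  error 10⁻³ to a uniform other base; fwd/rev split at 0.5; multimapped
  reads at 2% (45% inside designated multimap-heavy regions); indel mask
  positions at 10⁻⁴ per bp shared across sublines (they separate the
  founding genotype from the reference); 2.6% of background sites
  ancestrally heterozygous in all sublines (the adapted genotype's π_t).
  Evidence is emitted for truth sites plus a 20,000-site background
  sample; analytic totals carry the denominators.
* **CNVs** — Poisson(0.088·T) per subline (the adapted-control rate),
  log-uniform lengths 3–30 kb, non-overlapping within a subline; windowed
  depth tables carry the copy-ratio signal.
* **Biokinetics and life tables** — closed-form burden pairs with optional
  Gaussian noise; daily offspring schedules emitted verbatim or
  Poisson-perturbed.

All randomness flows through one seeded generator; a fixed seed gives
byte-identical outputs.

### What passing tests do and do not show

The simulator plants ideal signals: independent Poisson depths, uniform
error, perfectly known masks, bi-allelic hets at exactly 50/50. Real
pileups have correlated errors, mapping biases, index hopping and
reference gaps that this generator does not model, so recovery here
validates the *logic and statistics* of the pipeline, not its robustness
to real artifact classes. Two desk-scale distortions deserve note:

* On a 1 Mb substrate, the per-generation CNV count rate implies CNVs
  covering ~6% of the genome per subline, far above the real genome's
  occupancy; SNM analyses see those regions only through the depth
  filters. The SNM-rate recovery validation therefore plants SNMs without
  CNVs.
* True heterozygous sites pass the per-subline screen with probability
  ≈ 0.9 at 25× (band escape plus the orientation rule), so ancestrally
  heterozygous sites frequently drop out of the all-sublines-callable
  denominator, and measured π_t underestimates the planted value; a
  planted het is additionally hom-miscalled at ~10⁻⁴ at the depth floor,
  which at ancestral het sites yields rare LOH-like putations. These are
  properties of the published thresholds, reproduced faithfully rather
  than corrected. The same band escape gives the pooled rate estimator a
  small (≈ −8%, about −1.3 pooled SE at the default conditions) downward
  bias, absorbed by the 3-SE validation band and left uncorrected.

## Numerical and design choices

* Coordinates are 0-based half-open internally; BED native; VCF output is
  1-based per its specification.
* Genotypes are encoded as ordered allele pairs; hom calls carry one
  allele twice. Het allele pair = the two highest-count alleles.
* Exact tests are delegated to scipy (`binomtest`, `fisher_exact`,
  `mannwhitneyu`, `chi2.sf`) and pinned against in-repo enumeration
  oracles to 10⁻¹² on all tables with N ≤ 200.
* The evidence validator rejects negative counts and rows whose allele
  counts plus multimapped reads do not sum to depth.
* Degenerate inputs: zero transversions or zero GC-gaining mutations make
  Ts/Tv and the bias NaN (flagged, not raised); empty clades, zero-length
  site sets, and zero subline-median depths raise `ValueError`.
* Desk-scale test sizes: the validation suite simulates ~300 planted SNMs
  across 12 sublines on 0.1–1 Mb substrates with 10³–10⁴ background sites,
  the false-positive bound runs a 10⁶-site null in ten 10⁵-site chunks,
  and the calibration check uses 400 replicates of 500-draw multinomials —
  sizes chosen so the whole suite runs in about a minute on one core while
  keeping every Monte-Carlo bound at ≥ 3σ separation.

## Known limitations

* The pipeline calls single-nucleotide mutations only; indels, somatic
  mosaics and microsatellite mutations are out of scope.
* The CNV detector is a windowed median-ratio method with declared
  defaults; it does not refine breakpoints with split reads and does not
  genotype CNVs across conditions.
* The putation rule cannot see recurrent mutations (the same site mutated
  independently in ≥ 2 sublines is discarded as unanalyzable); at MA
  sample sizes this loss is negligible.
* Sampled-mode site accounting assumes background sites are exchangeable
  with the genome at large; strong spatial clustering of analyzability
  would bias n_i.
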