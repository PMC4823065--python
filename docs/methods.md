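# Methods

## Setting and assumptions

The package models a longitudinal leukemia-relapse study design: for each
patient, variant calls from bone-marrow samples at diagnosis, at complete
remission (CR, used as the germline reference — minimal residual disease is
assumed negligible), and at relapse after allogeneic transplant, plus the
stem-cell donor's calls. All coordinates are 1-based. Read counts at a site
are treated as binomial draws over independent reads; mutations are assumed
heterozygous in a diploid genome unless a clone model says otherwise, so a
mutation carried by a cell fraction *f* in a sample whose blast (tumor)
fraction is *b* has expected VAF *f·b*/2.

## Somatic candidate selection

The filter layers, in order: (1) per-call quality — mapping quality > 30,
base quality > 15, variant reads > 3, all strict inequalities; (2) removal
of known germline SNPs by exact (chrom, pos, ref, alt) match against a
user-supplied blacklist (no database access at run time); (3) tumor
support — VAF ≥ 0.15 and depth ≥ 20 holding simultaneously in at least one
tumor sample (diagnosis or relapse; a stricter "both samples" mode is a
flag on `FilterThresholds`); (4) remission purity — CR VAF < 0.005, where a
site with no CR record or zero CR depth counts as VAF 0 with a logged
warning; (5) a protein-altering predicted effect (nonsynonymous,
frameshift, stopgain, in-frame indel, splice site — not synonymous/other);
(6) donor exclusion — any donor call at the site that itself passes the
per-call quality rule removes the candidate, with no VAF threshold, since a
variant present in the donor genome reaches the relapse sample through
donor hematopoiesis rather than the leukemia.

Thresholds live in one frozen dataclass so that monotonicity (tightening
never adds candidates) and idempotence are testable properties.

## Blast-adjusted VAF and patterns

`adjusted_vaf(v, w, B) = 100·[v/(v+w)]/(B/100)`, rounded half-up to one
decimal to match how such tables are printed; internal consumers can keep
full precision by dividing themselves. CR records carry no blast value and
return the raw VAF. Values above 100% can arise from sampling noise or an
underestimated blast percentage; they are returned as computed and flagged
(`is_super_clonal`, and a column in the clonal report) rather than clipped.
The packaged read-count table contains two cells whose printed adjusted
values disagree with this formula by ~0.5 points; they are stored as
printed and flagged `discordant_cell`, and exact-reproduction tests skip
exactly those two cells (73 of 75 cells reproduce exactly).

Presence of a mutation at a tumor stage uses variant reads > 3 — the same
strict read-count rule as the quality filter. A presence rule of "any
variant read" would be wrong here: a single stray relapse read at an
otherwise diagnosis-specific site (present in the packaged table at NRF1,
1/73 reads) must not promote the mutation to "shared". Mutations detected
at neither tumor stage are dropped from reports with a warning.

Pattern classification is deliberately set-based, not VAF-based: with S
shared, D diagnosis-specific and R relapse-specific mutation counts, S = 0
gives *second malignancy*, S > 0 with D = R = 0 gives *subclone survival*,
and S > 0 with private mutations on either side gives *common progenitor*.
VAF magnitudes feed the separate rising/stable/falling `vaf_shift` call
(default threshold 5 percentage points — a package choice, as no numeric
threshold accompanies the qualitative description of "significant"
increases), which documents subclone expansion but never changes the
pattern label.

## STR chimerism

A locus is informative when at least one patient(CR)-specific and one
donor-specific allele are each detected in the relapse electropherogram and
some such pair lies within one repeat unit ("less than two repeat units")
— read here as an amplification-efficiency matching criterion, since PCR
yield falls with amplicon length; once a locus qualifies, the ratio sums
over **all** detected specific alleles, not only the qualifying pair (both
choices are arguments to `informative_loci`). Peak detection uses a 50 RFU
analytical threshold by default — a conventional value for capillary
electrophoresis, supplied as a parameter because kits differ. The estimate
is the unweighted mean of per-locus ratios times 100; no peak-height
weighting is applied. Degenerate inputs (no informative locus, zero
specific peak height at a selected locus) raise rather than return a
default.

## Fisher exact test

`fisher_exact_two_sided` enumerates the hypergeometric distribution over
the observed margins in log-factorial (lgamma) arithmetic and sums the
probabilities of all tables no more probable than the observed one
(minimum-likelihood two-sided convention, matching mainstream statistics
packages). A relative tolerance of 1e-7 when comparing table probabilities
absorbs floating-point ties between analytically equal tables. Zero-margin
tables return p = 1 with a warning. Tests check equality against an exact
rational enumeration oracle and against scipy's implementation; the
implementation itself depends on neither.

Cohort fractions take their denominators from explicit table metadata (31
relapsed patients over both cohorts, 28 extension relapsed, 30
non-relapsed), never from record counts, because patients without
mutations have no records. The epigenetic-regulator enrichment counts
carriers within the extension cohort by default: its published numerators
(10 of 28, and 10 of the 13 mutated) count only extension-cohort patients,
while carriers across both cohorts would number 13. The recurrence table
identifies only four mutated non-relapsed patients although five are
reported in aggregate, so the non-relapsed fraction (16.7%) and a
table-derived 2×2 test are not exactly reconstructable from it; analysis
step 05 reports both the table-derived p and the p from the published
carrier counts (13/28 vs 5/30 → 0.023).

## Synthetic data generator

The generator emulates the observable layer of the study, not the biology
underneath:

* **Clone trees.** Perfect phylogeny (child genotypes are supersets of the
  parent's), with per-clone cell fractions at diagnosis and relapse
  summing to ≤ 1 per stage. The three canonical models place 8–9 mutations
  per patient, matching the per-patient mutation counts of the exome
  trios, with minority-clone fractions of 0.3.
* **Read counts.** Depth per site is negative binomial with mean 100
  (the exome study's ~106× mean coverage) and dispersion 0.3, spanning
  roughly the 15–170× per-site spread seen in the printed read counts;
  dispersion 0 gives fixed depth. Variant reads are Binomial(depth,
  *f·b*/2) with *f* the mutation's cell fraction and *b* the stage's blast
  fraction (default 90%, within the >30%-blast sampling criterion and the
  33–95% range of the trio samples). CR sites use
  *p* = residual_cr_fraction · *f*/2, default 0.
* **Contaminants.** 20 heterozygous germline SNPs present in patient and
  donor alike (and listed in the generated blacklist), and 5 donor-private
  heterozygous variants that appear in the relapse sample at
  *p* = (1−*b*)/2 through the non-blast, donor-derived compartment.
* **STR mixtures.** Template genotypes place patient alleles {r, r+2} and
  donor alleles {r+1, r+3} at equal 1000 RFU base heights, so every locus
  is informative and a noise-free mixture is exactly recoverable. Relapse
  peaks are owner-fraction-weighted sums of template heights times
  lognormal noise with coefficient of variation `str_noise_cv` (default
  0.1); optional stutter adds `stutter_rate` of each peak one repeat below
  it (default off).
* **Cohorts.** Per-patient, per-gene Bernoulli indicators with separate
  rates per group; relapsed mutations draw a status uniformly over
  diagnosis-specific/shared/relapse-specific unless a distribution is
  given.

All randomness derives from `SimParams.seed` through one numpy generator.

What the generator does **not** emulate — sequencing error, mapping
artifacts, indel realignment effects, copy-number change and
loss-of-heterozygosity, STR stutter beyond a single fixed-rate peak,
locus-dependent amplification bias — bounds what the recovery tests show:
they demonstrate that the estimators invert the generator's model at
realistic depths and noise levels (pattern recovery ≥ 95% at fixed 100×
depth; chimerism within 3 points of truth in ≥ 95% of replicates at 10%
peak-height noise over 15 loci), not that they are robust to every failure
mode of real exomes or electropherograms.

## Problem sizes

The test suite and acceptance computations run at desk scale by design:
trios carry 8–9 somatic mutations plus 25 contaminants, recovery
properties use 200 replicates, oracle-equivalence checks use randomized
50–100-variant trios, and the Fisher oracle sweeps tables with margins up
to ~26. The whole suite completes in well under a minute.

## Known limitations

* Ploidy is assumed diploid and mutations heterozygous; the VAF-to-cell-
  fraction factor of 2 is wrong under copy-number change (a per-mutation
  multiplier exists on the clone model pathway but defaults to the
  heterozygous case).
* The pattern classifier sees only presence/absence; a relapse clone that
  lost a diagnosis mutation through deletion would read as
  diagnosis-specific.
* The VCF importer reads only the AD FORMAT field plus optional
  GENE/MQ/effect INFO keys; it is not a general-purpose VCF layer.
* The relapse-association gene rule operates at gene level: a gene's
  carriers may individually have diagnosis-specific mutations as long as
  one carrier's mutation persists to or arises at relapse.
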