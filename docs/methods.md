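# Methods

This note documents the models, numerical choices and open design
decisions behind `lofscan`, and what the synthetic study system does and
does not emulate.

## Drought climatology

Weekly VHI values (0–100) below a threshold (default 40, strict
inequality) are drought weeks. Seasons are photoperiodic quarters: 13 ISO
weeks centred on the spring-equinox week (12), summer-solstice week (25),
fall-equinox week (38) and winter-solstice week (51); together they tile
all 52 weeks. The calendar is a config object (`SeasonCalendar`) so
southern-hemisphere or custom windows can be substituted — hemisphere
handling is deliberately not guessed. Seasonal drought frequency is
drought weeks over non-missing weeks, pooled across years per pixel;
seasons with zero observed weeks are missing, not zero.

The drought-timing index is ln((f_spring + ε)/(f_summer + ε)). The
pseudocount default is ε = 1/(2·observed spring+summer weeks) per pixel,
chosen so a single unobserved drought week cannot produce ±∞ while leaving
typical indices essentially unchanged; ε = 0 is allowed, with infinite
ratios suppressed to missing and counted. The index is exactly
antisymmetric under exchanging the two seasons at fixed ε.

Extraction at ecotype locations uses the nearest pixel, not bilinear
interpolation: the water mask is categorical and interpolating across a
coastline would blend land with undefined values. Ecotypes with missing
coordinates, out-of-bounds coordinates, water pixels, or no data are
excluded and reported with a reason.

The seasonal flowering regression includes all four seasons by default
(restrictable to spring+summer); rank-deficient designs raise an error
naming the offending columns rather than silently dropping one. Note that
along a one-dimensional drought-timing gradient spring and summer
frequencies are strongly anticorrelated, so coefficient standard errors on
such data are wide.

## LoF calling

Calls are haploid: ecotypes are fully inbred selfers, and heterozygous
diploid calls (if present) default to missing (configurable to ALT). The
filter cascade is: (1) exactly one annotated transcript — with multiple
gene models exon skipping could rescue function; (2) carrier frequency of
putative frameshift/premature-stop/start-loss variants ≥ 5% (inclusive)
and missing rate < 5% (strict), where "carrier" means an ecotype holding
at least one such variant — carrier-based rather than per-site counting,
because the downstream model is per-ecotype allele state (the per-site
alternative is a flag); (3) translation of each carrier's full variant
complement applied jointly, so compensatory mutations that restore frame or
function are honoured; an allele is LoF iff ≥ 10% (inclusive) of the
reference protein is lost; (4) a re-applied ≥ 5% filter on the translated
LoF frequency, computed among non-missing ecotypes.

On start-codon disruption, translation rescans downstream for the first
in-frame ATG ("late start codon"); the lost fraction is the N-terminal
portion preceding it, and absence of any rescue ATG counts as total loss.
Translation without an in-frame stop (a frameshift that removed it) runs to
the end of the annotated CDS; read-through into the 3' UTR is unknowable
from the CDS alone and the prediction is capped there.

Coordinates: GFF3 and VCF are 1-based inclusive; internal arrays 0-based
half-open; a single adapter (`GeneModel.map_allele`) converts between
them, reverse-complementing alleles for minus-strand genes. Variants are
trimmed/normalized before application and overlapping ALT alleles for one
ecotype raise an error naming the records. Variants whose REF span crosses
an exon junction are out of scope (no splice modelling) and are ignored
with a log entry.

Unique LoF alleles per gene are counted as distinct predicted protein
lengths among LoF carriers. Distinct mutations yielding identical lengths
merge under this proxy; that is accepted as the definition rather than
corrected.

## Association scan

Kinship is identity-in-state: the fraction of shared alleles between two
ecotypes over all variable background markers (constant markers are
dropped with a warning). Structure covariates are the top-k (default 3)
eigenvectors of the kinship matrix itself (no double-centring; variance
explained is eigenvalue over trace, so an identity kinship yields 1/n per
component), with signs normalized so each eigenvector's first nonzero
loading is positive.

Each gene's fit is a binomial GLM (logistic link) of allele state on one
predictor plus the PCs, by IRLS with tolerance 1e-8 and at most 100
iterations. Monomorphic genes, non-converged fits, and (quasi-)separated
fits — detected by |β| > 30 or SE > 1000 — are flagged and carry NaN P
values rather than fabricated ones. Bonferroni adjustment is per scan
family (m = genes tested in that scan). Gene classification uses the
adjusted P < 0.05 (strict) by default; a `use_adjusted=False` flag
switches to raw-P classification, since the raw-vs-adjusted reading of the
significance rule is genuinely ambiguous.

The permutation control permutes ecotype labels (matrix rows) once with a
fixed seed, preserving every gene's allele frequency exactly while severing
genotype–predictor links, then reruns the full scan. One permutation is
the default; the expected outcome is zero Bonferroni-significant genes,
but this is a stochastic negative control — across seeds, a single
surviving gene is a legitimate ~5–10% family-wise tail event and is
reported as observed.

## Selection statistics

The overlap test cross-classifies genes as drought-associated × flowering-
associated (2×2 χ², expected counts from the margins, no continuity
correction); concordant co-associations (summer∧earlier plus spring∧later)
and discordant ones are counted separately, and fold enrichment is
concordant observed over the expected both-associated cell. The direction-
bias test and the knockout sign test share one kernel: the goodness-of-fit
χ² of a k-of-n split against 50:50, again without continuity correction —
that choice reproduces the printed values (57 of 59 → 51.27; 214 of 247 →
132.64) at their stated precision.

MK-style counting removes every codon containing a gap in any sequence,
then classifies per nucleotide site: ingroup variation makes a site
polymorphic (each non-major allele judged synonymous/nonsynonymous by
translating the ingroup-major codon with the allele substituted); ingroup-
monomorphic sites differing from the outgroup are fixed differences. Sites
both polymorphic and divergent count as polymorphic only — standard MK
bookkeeping. Ratios with zero denominators are missing and excluded (and
counted) in group comparisons. Group t-tests are Welch by default (the
equal-variance assumption is unstated in this literature), two-sided.
Unique-allele contrasts log10-transform with a 0.5 pseudocount for zero
counts.

The burden regression sums LoF calls per ecotype over candidate genes
(missing calls count as functional — the burden is a sum, so pairwise
deletion is not available), fits flowering ∼ burden by OLS, and compares
against the quadratic augmentation with a partial F-test.

## Knockout analysis

Line means are adjusted for the blocked design with a linear mixed model:
line fixed, shelf a random intercept, tray a variance component nested in
shelf by default (crossed by flag — the nesting is not observable from the
data layout alone), fitted by REML via statsmodels MixedLM. Since random
blocks have zero mean, the adjusted (least-squares) mean of a line is the
intercept plus its fixed-effect contrast. When the estimated block
variance collapses to zero or the fit degenerates, the model reduces to
plain arithmetic line means and the output says so in a `note` column;
single-replicate lines are kept but flagged. Flowering is days after
planting to the emergence of the first open flower. The sign test counts
lines whose adjusted mean exceeds the wild type's, excludes exact ties
(reported), and applies the shared 50:50 χ² kernel with 1 df.

## Synthetic study system

The generator's defaults are the study conditions the pipeline targets:
flowering effect 1/3 day per LoF allele; a 59-line knockout experiment
with 10 replicates per line plus 30 wild-type replicates in a
shelf-stratified randomized design; 34 years of weekly VHI on a 0–100
scale; drought below 40. Panel scale defaults to 500 ecotypes × 200 genes
(30 spring-late and 10 summer-early causal genes — mirroring the strong
spring/later excess among real candidates), chosen so the full pipeline
runs in seconds on one CPU while leaving the scan well-powered; per-gene
target LoF frequencies are uniform on [0.08, 0.30] (the empirical
distribution is unknown, so it is config, not dogma), with 10 genes
planted at 2% to exercise the frequency filters.

Population structure is k = 3 discrete clusters with Balding–Nichols
background allele frequencies (Fst 0.15) — the simplest structure against
which PC correction can be validated. Carrier status per gene follows
logit p = α_g + β_g·index + cluster offset, with α_g solved by bisection
so the realized global frequency matches its target in expectation.
Flowering is baseline + per-allele effects ± cluster effect + Gaussian
noise (sd 3 days).

Each gene's carriers are split among 1–5 molecular alleles (fewer for
causal genes, mirroring the fewer-but-commoner unique-allele signature)
with Zipf-skewed weights: premature-stop SNPs (a planted TAC codon mutable
to TAA), frameshift indels, and start-loss SNPs with a planted in-frame
rescue ATG. Frameshift truncation cannot be guaranteed a priori, so the
builder plants shifted-frame stop elements (codon pairs reading TAG one
base late or TAA one base early), verifies every allele by direct
splice-and-translation, and rebuilds the gene if verification fails.
Genes are laid on one chromosome with one or two exons and mixed strands;
minus-strand genes carry SNP-type alleles only, keeping VCF left-anchoring
unambiguous. Ortholog alignments plant exact PN/PS/DN/DS counts (Poisson
around group means, elevated nonsynonymous rates for causal genes) plus
occasional gap codons in the outgroup.

What the generator does **not** emulate: linkage and recombination,
coalescent genealogies, sequencing error, real geography, splice-site
variation, large structural variants, and any covariance between the four
predictors beyond what clusters and the drought gradient induce. Passing
tests therefore demonstrate the pipeline's internal correctness and
calibration under the stated generative model — not that real data meet
those assumptions.

One estimator caveat is intentional: under the default conditions the OLS
burden slope is *not* an unbiased estimate of the per-allele effect,
because summer-early burden and shared cluster effects are omitted
variables — precisely the situation of the descriptive regression on real
data. Estimator-recovery tests therefore run on an unconfounded design
(no summer-early genes, no cluster effect on the phenotype); the
confounded default is covered by the structure-correction and permutation
tests instead.

## Problem sizes used in tests

The shared unit-test panel is 300 ecotypes × 60 genes; the acceptance
suite runs one default-scale panel (500 × 200) for the permutation
control and round-trip checks, a 400 × 120 unconfounded panel for burden
recovery, and 200–400-observation simulations for calibration properties.
All seeds are fixed in the tests; the acceptance script takes its seed on
the command line.
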