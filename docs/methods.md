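# Methods

## Model and assumptions

The package implements a conjunctive variant-filtering cascade for
dominant Mendelian prioritization. Its central assumption is a fully
penetrant autosomal-dominant model at the level of a single pedigree: a
causative allele is heterozygous in every affected member and absent in
every unaffected member. This is deliberately strict — one phenocopy,
one reduced-penetrance carrier or one missing genotype call removes a
variant — because the workflow is a prioritization funnel, not an
association test; its purpose is to reduce an exome to a handful of
reviewable candidates. Members with unknown phenotype are not
constrained. For unrelated singletons the segregation requirement
degenerates to heterozygous retention, which is also the behavior of
family mode on a pedigree containing only affected members (tested as the
mode-equivalence property).

All records are decomposed to biallelic form before any predicate runs:
multi-allelic sites become one record per alternate allele, with other
alternate alleles re-coded as reference for that record. This makes every
genotype predicate a statement about allele indices {0, 1} and keeps
decomposition conservation checkable (the number of (sample, alt-allele)
carrier pairs is invariant). Positions are 1-based VCF coordinates and
are never lifted over; the package treats them as opaque identifiers.

Each variant is reduced to one representative transcript annotation: the
uniquely flagged canonical transcript if there is exactly one, otherwise
the annotation with the most severe consequence under the standard VEP
severity ranking, with lexicographic transcript-id tie-breaking. Distinct
gene counts in funnels use this representative symbol. Which transcript a
published table reflects is generally unknowable after the fact; a
deterministic rule was preferred over per-dataset curation.

## Thresholds and their meaning

| Parameter | Default | Units / rationale |
|---|---|---|
| `min_depth_exclusive` | 10 | reads; sample call kept only if DP > 10 (strict) |
| `min_gq` | 99 | Phred; GQ ≥ 99, the cap emitted by standard callers |
| `min_qual` / `min_qd` / `min_mq` / `max_fs` | 10 / 2 / 20 / 200 | GATK hard-filter defaults for site QUAL, quality-by-depth, mapping quality, Fisher strand bias |
| `af_max_high_impact` | 0.01 | gnomAD AF cap for loss-of-function consequences |
| `af_max_other` | 0.0001 | gnomAD AF cap for all other qualifying consequences |
| `min_cadd` | 20 | CADD Phred; top 1% most deleterious genome-wide |
| `min_revel` | 0.5 | REVEL; ClinGen PP3 supporting-evidence threshold |
| `min_am` | 0.564 | AlphaMissense likely-pathogenic cutoff |

Two boundary conventions worth stating: depth is strictly greater than 10
(the stricter of the two plausible readings), and GQ ≥ 99 is taken at
face value as the caller's cap. Missing values never exclude — a variant
absent from gnomAD cannot exceed a frequency bound, and loss-of-function
variants usually have no REVEL/AlphaMissense prediction, so score gates
apply only to scores that exist (otherwise no stop-gain could ever
survive). The frequency tiers are applied per the representative
annotation's impact class; if a variant passes the stricter 0.01% tier it
necessarily passes the 1% tier (tier monotonicity, property-tested).

ClinVar matching is a case-insensitive substring test for
benign/likely-benign after normalizing spaces to underscores, with a
conservative carve-out: entries that also assert pathogenic or
conflicting interpretations are not removed. The exclusion reading for
the score gates is "any present sub-threshold score excludes" — the
alternative (require all three jointly) would make the CADD gate
meaningless for missense variants and was rejected.

Pathway panels map pathway names to uppercase gene-symbol sets; matching
is exact and case-insensitive, with no alias or HGNC resolution (alias
maps can be supplied in the panel YAML). The packaged default panels
enumerate the connective-tissue pathway genes relevant to hEDS
(hyaluronan–ECM axis, ECM remodeling, cell–matrix adhesion and
mechanotransduction — the three "family-shared" pathways — plus seven
further categories). The panel file is a user-editable YAML and makes no
claim of completeness for any pathway; per-gene pathway assignment for
the packaged per-patient candidate table is recorded in the fixture
itself rather than rederived, because the published assignment rule is
not fully specified.

## Stage order and funnel accounting

Stages run in the fixed order quality → inheritance → frequency →
pathogenicity → consequence → pathway. Because all predicates are pure
and conjunctive, any order yields the same final set (property-tested
over predicate permutations); the fixed order exists so funnel reports
are comparable across runs. Funnel invariants — variant and gene counts
non-increasing, gene count ≤ variant count — are enforced at report
construction, so a violating pipeline cannot silently emit a report.
Audit mode records each excluded variant's first failing stage.

## The synthetic-data generator

The generator emulates exactly the features the cascade consumes:
GATK-style site statistics, per-sample DP/GQ, and a VEP-style CSQ block
with gnomAD AF, CADD, REVEL, AlphaMissense and ClinVar fields, on a
synthetic contig with strictly increasing positions and REF/ALT drawn
from {A, C, G, T}. It does not emulate real exome scale (~1.4 M sites),
linkage structure, error-mode correlations, multi-transcript annotation,
or realistic gene lengths — so passing tests demonstrate the logic of
every stage, not performance on genome-scale data.

Causal variants draw every attribute from the compliant region of each
threshold: DP uniform on [15, 80], GQ 99, AF missing with probability
0.9 else uniform below 1e-4, CADD uniform on [20, 40], and (for missense)
REVEL on [0.5, 1] and AlphaMissense on [0.564, 1]; consequences are
sampled 50% missense / 50% loss-of-function terms. Background variants
each violate exactly one named stage, drawn uniformly, keeping all other
attributes compliant; the defaults therefore exclude roughly one sixth of
the background at each stage, which keeps every funnel stage exercised.
Co-segregation violations are produced by genuine Mendelian transmission:
one alternate allele enters through a random founder and is transmitted
with fair coin flips per meiosis, rejection-sampled until the resulting
pattern breaks the dominant rule (a forced hom-ref affected member is the
fallback, never reached for pedigrees with unaffected founders in
practice). Everything is driven by one `numpy` Generator seeded from
`SimParams.seed`; identical parameters give byte-identical VCFs.

## Statistical utilities

The Mann–Whitney U statistic is computed from rank sums with midranks for
ties (via `scipy.stats.mannwhitneyu`); the p-value is exact by
enumeration when the pooled sample has ≤ 12 observations and no ties, and
otherwise uses the normal approximation with tie correction and (by
default, configurable) continuity correction. Two-sided testing is the
default since directionality is rarely pre-registered for imaging
parameter panels. The test suite checks the exact path against an
independent full-enumeration oracle and the Benjamini–Hochberg adjustment
(via `statsmodels`) against the direct step-up cumulative-minimum
formula.

Cohort summaries round half-up to one decimal (matching how clinical
tables are typically printed; banker's rounding would disagree at .x5
boundaries). The packaged clinical table stores pre-tokenized term lists
(semicolon-separated) so term counting is unambiguous; free-text
tokenization on "/" and "," is a caller concern.

Per-subject imaging measurements are not available, so group comparisons
are exposed as procedures only, together with
`synthetic_imaging_cohort`, an explicitly illustrative generator
(truncated normals with a range/4 sigma rule) for demonstrating the
compare-and-adjust path end to end. No imaging p-value is claimed as a
reproduced result.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale: the family
worked example is 10 variants over 6 samples; simulator properties use
200-variant replicates over 5 seeds (1,000 planted variants total) for
the recall/exclusion checks; exhaustive oracles enumerate all 3^6
genotype vectors for the segregation predicate and all rank assignments
for Mann–Whitney samples up to n = 6 per group. Pipelines, writers and
reports are fully deterministic: identical inputs and configuration
produce byte-identical VCF, TSV and JSON outputs.

## Known limitations

- Fully penetrant dominant model only; no recessive, compound-het, X-linked
  or de novo modes, and no allowance for phenocopies or missing calls.
- No ACMG classification, enrichment statistics, network propagation or
  HGVS validation; panel membership is exact symbol matching.
- A single configured gnomAD AF field is used; population-maximum variants
  of the rule are a configuration choice, not a built-in.
- Genome-scale behavior (runtime and funnel magnitudes on ~10^6-variant
  exomes) is out of scope for the shipped test data.
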