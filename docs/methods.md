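# Methods

## PSI at constitutive anchors

A splice junction is identified by its intron's first and last base
(1-based inclusive, the STAR `SJ.out.tab` convention) plus chromosome and
strand. Donor and acceptor sites are strand-aware: on `+` the donor is the
intron start, on `-` the intron end. Junctions are grouped at every shared
donor or acceptor site; a site held by a single junction still forms a
group when it belongs to an annotated intron, so canonical junctions are
quantified even without competing cryptic usage. At most one group member
is marked canonical (an exact match to an annotated intron); when several
transcripts put annotated introns at one site, the member with the smallest
coordinates is taken, deterministically.

PSI of junction *j* in sample *s* is its unique split-read count divided by
the summed counts of all junctions in its anchor group. Multi-mapping
counts are never used: split-read support must be unambiguous.

Two deliberate choices:

- **Coverage filter on the denominator.** "Minimum coverage per junction"
  is interpreted as a floor on the anchor-group total (default 15), because
  the denominator governs the precision of the ratio. Below it, the entire
  anchor is masked in that sample — missing, never zero. Raising the floor
  can therefore only add missingness, never change a surviving value
  (tested as a monotonicity property).
- **Anchor duality.** A cryptic junction may share its donor with one
  canonical junction and its acceptor with another. It is quantified at the
  side whose group contains a canonical member, preferring the donor side
  on ties, because the dominant cryptic class in SF3B1-mutant cells is the
  alternative 3′ acceptor (donor-anchored). Within any one anchor group,
  non-missing PSIs still sum to 1 within 1e-9.

Unknown-strand junctions (STAR code 0) inherit the strand of the unique
overlapping gene span; ambiguous ones are dropped with a warning, and a
declared strand contradicting an annotated intron is an error.

## Differential splicing and event calls

ΔPSI per junction and mutant genotype is the difference of group means over
coverage-surviving samples, against a wild-type reference. A junction needs
at least 2 informative samples in the reference and in one mutant genotype;
otherwise it is marked indeterminate rather than zero. The ranking score is
max |ΔPSI| across mutants — with ~4 clones per genotype a test statistic
would be unstable, so none is used for ranking (a rank-sum p-value can be
computed separately via `cohort.compare_clinical`-style machinery but does
not enter the ordering). Ties break on coordinates so ranking is stable.
Clone-mean PSI (not pooled counts) feeds ΔPSI; pooling would let one deep
clone dominate the genotype mean.

Classification against the annotation: shared donor with a different
acceptor → alternative 3′ acceptor; shared acceptor → alternative 5′ donor;
donor of intron *i* joined to the acceptor of a later intron of the same
transcript → exon skip; a junction strictly inside an annotated intron →
"intron retention proxy" (a junction-count method cannot observe retention
directly); otherwise "other". The signed mature-transcript length change is
positive when intronic sequence becomes exonic; `frame_shift` holds exactly
when that change is not a multiple of 3, and a dedicated test confirms the
arithmetic agrees with translating the reconstructed transcript.

**PTC / NMD.** The mature mRNA is rebuilt with the cryptic junction
replacing its canonical partner (canonical-intron bases rejoin the exonic
set, cryptic-intron bases are excised), translated from the annotated start
codon, and the first in-frame stop that is not the canonical stop is
reported as a premature termination codon. NMD is predicted when that stop
ends more than 50 nt upstream of the final exon–exon junction of the
modified transcript (threshold configurable). Events outside the CDS, or
in-frame events introducing no stop, return "not applicable" rather than
false.

**Hotspot specificity.** Per genotype: *present* if ΔPSI ≥ 0.10 (with ≥ 2
informative samples), *absent* if |ΔPSI| ≤ 0.05, else indeterminate. The
buffer makes "absent" an affirmative claim — the assertion behind a
nonoverlap statement is stronger than non-significance. An event is
"<G>-specific" only when present in exactly one genotype and absent in all
others; pairwise Jaccard indices of present-event sets summarize program
overlap.

## Cohort statistics

- Percentages round half-up to one decimal, two decimals below 0.1 %
  (matching printed values such as 0.08 %); exact zero prints 0.0 %.
- All 2×2 comparisons use the two-sided Fisher exact test (small cells such
  as 1/1327 rule out chi-square); the implementation is scipy's, verified
  in the suite against an exhaustive hypergeometric enumeration for every
  table with margins ≤ 12. Odds ratios: sample ad/bc, switching to the
  conditional MLE when a cell is zero, with the Haldane 0.5-corrected ratio
  reported alongside. A zero margin yields p = 1.0, flagged degenerate.
- Co-mutation landscapes include only cases whose panel covers the common
  gene set (the minimum-panel rule), and a case enters a gene's denominator
  only if that gene was sequenced. Raw p-values carry figure-style star
  tiers (*, **, ***, **** at 0.05/0.01/0.001/0.0001); Benjamini–Hochberg
  q-values are reported alongside for honest reuse.
- WHO 2016 MDS-RS eligibility: > 5 % ring sideroblasts with an *SF3B1*
  mutation (strict inequality), > 15 % without; unknown RS yields unknown
  flags, never false.
- Clinical fields compare by two-sided Mann–Whitney: exact null
  distribution for small untied samples, normal approximation with tie
  correction otherwise (so small-sample results agree with permutation
  enumeration while large cohorts stay fast). Fully tied data is degenerate
  with p = 1.0.
- Survival uses the Kaplan–Meier product-limit estimator and the
  one-degree-of-freedom log-rank (Mantel–Cox) test via lifelines; the suite
  checks both against hand-rolled risk-table oracles at small n and the
  log-rank's type-I error against its nominal level. Median survival is the
  smallest observed time with S ≤ 0.5, undefined if never reached.

## Synthetic data: what it emulates and what it does not

The splice simulator mirrors an isogenic-clone design: by default 4
independent clones per genotype (WT, K700E, E592K), one anchor per
annotated intron, anchor totals Poisson around 200 split reads, and planted
cryptic alternative 3′ acceptors whose true PSI is 0.50 in their hotspot
and 0.02 at baseline (nonzero so that coverage-filter and ranking edge
cases are exercised). Counts split between canonical and cryptic junctions
by a beta-binomial with overdispersion ρ = 0.01: clone-to-clone PSI
variability is the realistic failure mode for ΔPSI calling, though no
published estimate of it exists for this design, so ρ is a modelling
default, not an inference. The toy annotation is 24 four-exon genes named
after the validated target genes (MAP3K7, ZDHHC16, TMEM14C, ABCB7, ... for
the canonical program; EZH2, RAVER2, CEP43, NUTM2A-AS1, ... for the E592K
program) — the names are conventions for fixtures, not assertions about
the real junctions. A synthesized genome writes stop-free CDS codons so
reading-frame and NMD logic operate on well-posed transcripts.

The cohort simulator draws diagnosis class, co-mutations (with uniform
VAFs), RS %, blasts, blood counts, and exponential survival independently
given the variant. Its default diagnosis distributions are the empirical
fractions of the pooled 2,234-case variant × WHO-class table (per-class
totals 1327/242/266/399; the exon 14–16 remainder is pooled under K700E);
co-mutation probabilities, RS means (2 % vs 37 %), and hazards encode the
reported E592K-vs-canonical contrasts. Not modelled: clonal architecture
(VAF correlations between co-mutations), panel heterogeneity beyond a
simple dropout rate, covariate-dependent censoring, and any
expression-level signal. Passing recovery tests therefore demonstrates that
the estimators see what was planted under this noise model — not that real
RNA-seq or registry data contain no further structure.

## Numerical and design notes

- All generators are pure functions of (config, seed); fixtures regenerate
  byte-identically and every table writer stamps its seed in a header
  comment.
- Problem sizes in the test suite and acceptance script (20 simulation
  seeds for recovery, 1000 null log-rank simulations at 100 per arm,
  exhaustive Fisher enumeration to margin 12, cohorts of a few thousand for
  law-of-large-numbers checks) were chosen to keep each check's sampling
  error well inside its assertion band.
- The pipeline persists every stage as files so each module is testable in
  isolation, and a manifest of config, seeds, and content hashes makes a
  run reproducible; rerunning with unchanged inputs is a no-op apart from
  nothing (hashes are identical).
- External prognostic scores (IPSS-R is carried as a plain field; IPSS-M
  and similar calculators are not reimplemented) and multivariate
  prognostic modelling are out of scope, as are read-level simulation,
  alignment, and isoform-level quantification.

## Cohort table columns

`case_id`, `diagnosis` (MDS-RS, MDS-SLD/MLD, MDS-EB, AML, other),
`sf3b1_variant`, `sf3b1_exon`, `comutations` (`GENE:vaf` pairs separated by
`;`), `rs_percent`, `blast_percent`, `platelets`, `hemoglobin`, `anc`,
`ipss_r`, `panel_genes` (comma-separated), `os_time`, `os_event`,
`lfs_time`, `lfs_event`. Unknown values are `NA`; event flags are 0/1.
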