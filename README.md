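# spliceotype

Hotspot-resolved analysis of RNA missplicing and clinical outcomes in
*SF3B1*-mutant myelodysplastic syndromes (MDS) and AML.

Most *SF3B1* hotspot mutations (K700E, K666N, H662Q, ...) force the
spliceosome onto cryptic 3′ splice sites, producing a shared missplicing
program, ring sideroblasts, and comparatively indolent disease. The rarer
E592K variant behaves differently: it partitions into higher-risk WHO 2016
classes, lacks ring sideroblasts, carries a distinct co-mutation profile
(ASXL1/RUNX1/STAG2 co-occurrence, DNMT3A exclusivity), shortens survival, and
missplices a set of genes that does not overlap the canonical program.
`spliceotype` packages the quantitative machinery needed to make and check
claims of that kind:

- **PSI quantification** (`spliceotype.junctions`). For a junction *j*
  anchored at a constitutive donor or acceptor site *g*,

  `PSI(j, s) = n(j, s) / Σ_{m ∈ g} n(m, s)`

  where *n* are unique split-read counts; the whole anchor is masked in
  sample *s* when the denominator is below a minimum coverage (default 15
  split reads). Readers are provided for STAR `SJ.out.tab` and junction
  BED12.
- **Differential splicing and event interpretation**
  (`spliceotype.events`). ΔPSI = mean PSI(mutant) − mean PSI(wild-type) per
  genotype; events are ranked by max |ΔPSI|, classified against the
  annotation (alternative 3′ acceptor, alternative 5′ donor, exon skip,
  intron-retention proxy), checked for frameshifts, and scanned for
  premature termination codons with the classical 50-nt rule for predicting
  nonsense-mediated decay. Hotspot specificity uses a dual threshold:
  *present* at ΔPSI ≥ 0.10, affirmatively *absent* at |ΔPSI| ≤ 0.05, with an
  indeterminate buffer between, and pairwise Jaccard indices of
  present-event sets to quantify (non)overlap.
- **Cohort statistics** (`spliceotype.cohort`). Variant × WHO 2016 diagnosis
  partitioning with pairwise two-sided Fisher exact tests, the WHO
  ring-sideroblast criteria (> 5 % RS when *SF3B1* is mutated, > 15 %
  otherwise), co-mutation landscapes restricted to cases with a common
  sequencing panel (Fisher per gene, Benjamini–Hochberg q-values),
  Mann–Whitney clinical comparisons, and Kaplan–Meier / log-rank
  (Mantel–Cox) survival.
- **Synthetic data** (`spliceotype.simdata`). Seeded generators emulating
  the study designs: isogenic clones per genotype with beta-binomially
  dispersed split-read counts and planted hotspot-specific cryptic events,
  and a clinical cohort with variant-dependent diagnosis, co-mutation, and
  survival structure. Every simulation exports its planted truth.
- **Pipeline** (`spliceotype.pipeline`, `spliceotype` CLI). Stages
  `simulate → psi → diff → classify → cohort → report`, file-persisted with
  a reproducibility manifest.

## Worked example

```python
import spliceotype as st

ann = st.toy_annotation()
sim = st.simulate_junction_counts(ann, st.default_splice_config(seed=42))
records = [r for recs in sim.records_by_sample.values() for r in recs]
groups = st.build_anchor_groups(records, ann)
psi = st.compute_psi(groups, st.counts_frame(records), st.QuantConfig(min_coverage=15))
results = st.delta_psi(psi, sim.genotype_map, reference_genotype="WT")
for r in st.rank_events(results, top_k=3):
    cls = st.classify_event(r.junction, ann)
    print(f"{cls.gene_id:10s} {r.junction}  dPSI(K700E)={r.delta_psi['K700E']:+.3f} "
          f"dPSI(E592K)={r.delta_psi['E592K']:+.3f}  {cls.event_class}")
calls, jaccard = st.call_specificity(results)
n_spec = sum(c.label.endswith("-specific") for c in calls)
print(f"{n_spec} hotspot-specific events, Jaccard(E592K, K700E) = {jaccard[('E592K','K700E')]:.2f}")

p = st.fisher_exact_two_sided([[1, 1326], [10, 389]]).p_value
print(f"E592K in MDS-RS vs AML: Fisher p = {p:.2e}")
```

prints

```
ZDHHC16    chrT:4090-4299:+  dPSI(K700E)=-0.528 dPSI(E592K)=-0.016  degenerate
ZDHHC16    chrT:4090-4279:+  dPSI(K700E)=+0.528 dPSI(E592K)=+0.016  alt_3p_acceptor
ORAI2      chrT:25090-25279:+  dPSI(K700E)=+0.526 dPSI(E592K)=+0.020  alt_3p_acceptor
20 hotspot-specific events, Jaccard(E592K, K700E) = 0.00
E592K in MDS-RS vs AML: Fisher p = 3.49e-06
```

The top-ranked junctions are the planted cryptic alternative 3′ acceptors
(each paired with its canonical partner, whose PSI drops by the same
amount); all twenty planted events are recovered as hotspot-specific with no
overlap between the K700E and E592K programs, and the 2×2 contingency of
E592K counts in MDS-RS (1/1327) versus AML (10/399) is highly significant.

The same analysis runs from the shell:

```sh
spliceotype run --out-dir myrun --seed 42
```

which writes junction fixtures, the PSI matrix, the differential and
classified event tables, cohort statistics, and a manifest under `myrun/`.

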