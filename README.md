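# lfspectrum

Classification of germline *TP53* cohorts into the Li-Fraumeni spectrum
(phenotypic LFS, LFS, attenuated LFS, incidental LFS), with the pedigree
and statistics machinery around it:

- **cohort_model** — typed two-table cohort schema (individuals +
  long-format diagnoses), CSV readers/writers, PED export, closed
  organ/histology vocabularies with validation.
- **pedigree** — family graphs with clinical kinship-degree queries
  (full siblings are first degree; grandparents, avuncular pairs and
  half-siblings second degree).
- **variant_annotation** — HGVS p. shorthand parser (one- and
  three-letter, missense/nonsense/codon-only), hotspot codons
  (175/245/248/273/282), TAD/PR/DNAB/OD/CT domain assignment, and the
  p.R337H-founder / clonal-hematopoiesis exclusion filters.
- **criteria_engine** — classic LFS criteria, Chompret category A
  (familial presentation, multiple primaries) and category B (specific
  tumor types), their union as testing eligibility, and the strict
  under-18 childhood-cancer rule. All thresholds live in a YAML-able
  `CriteriaConfig`.
- **spectrum_classifier** — per-individual spectrum assignment with a
  rationale trace, two-pass cohort classification (cancer-free carriers
  are resolved against their blood relatives' categories), family
  summaries, and the met/not-met case stratification.
- **cohort_stats** — tumor-pattern tabulation at organ and histology
  level, per-label 2×2 comparisons with uncorrected Pearson χ² or an
  exact-integer two-sided Fisher test (chosen when any expected count
  is below 5), table-style formatting, and age summaries.
- **synthetic_cohort** — a seeded generator of template families
  (classic, Chompret-A, category-B-only, attenuated, incidental,
  p.R337H founder, variant-negative phenotypic) with age-phase tumor
  sampling, plus a template-recovery confusion report.
- **cli** — `lfspectrum` command with `simulate`, `classify`,
  `analyze` and `all` subcommands.

## CLI

```sh
# synthetic cohort tables + ground-truth labels
lfspectrum simulate --seed 7 --n-families 100 --out out/

# full pipeline from a simulation (deterministic per seed)
lfspectrum all --seed 7 --out out/

# classify + analyze an existing cohort
lfspectrum analyze --individuals ind.csv --diagnoses dx.csv \
    --exclude-r337h --exclude-ch --out out/
```

Outputs: `assignments.csv` (per-person category + rationale),
`strata.json` (met / not-met / unaffected strata counts),
`tumor_patterns.csv` (two-group table with p-values and test used),
`stats.json` (exclusion report, category counts, age summaries).
Exit codes: 0 ok, 2 schema/data error, 3 config error.

Input schema (CSV, UTF-8):

```
individuals: family_id,individual_id,father_id,mother_id,sex,hgvs_p,clinsig,mosaic,clonal_hematopoiesis,proband
diagnoses:   individual_id,site,morphology,age_at_dx,premenopausal
```

`clinsig` is one of `P_LP`, `VUS`, `conflicting`, `LB_B`, `unknown`;
empty parent ids mean unknown; "before age N" is strict (`age < N`).

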