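# matshare

Analysis toolkit for strain-level (ASV) sharing between mother-infant pairs in
amplicon microbiome surveys, with a paired-cohort simulator that plants
covariate-dependent transmission so every downstream statistic can be checked
against ground truth.

## What it does

- **feature_tables** — validated features × samples count tables, taxonomy maps
  and cohort metadata (plain TSV); control-ASV removal, relative abundance,
  OTU collapse at an identity threshold (default ≥98.5%), exact rarefaction
  expectations and observed richness.
- **synthetic_cohort** — mother-infant cohorts with lognormal adult
  communities, per-OTU strain pools, a configurable transmitted fraction τ
  (base rate + feeding-dependent shifts + optional jitter), an environmental
  background component, multinomial read sampling, and a truth ledger of every
  planted transmission.
- **transmission** — shared-ASV sets per pair; the three per-infant summary
  statistics (count, % of observed ASVs, cumulative relative abundance); the
  full infant × non-own-mother unrelated-pair null; Mann-Whitney comparison
  reports; and the per-OTU pair-level sharing index.
- **ecology** — square-root Bray-Curtis distances, classical-scaling PCoA
  (negative eigenvalues reported, not corrected), the origin-aware OTU table
  splitting each OTU into maternally-shared vs nonshared abundance, UPGMA
  clustering of infants, and per-cluster Steel-Dwass comparisons.
- **nonparametrics** — hand-implemented Mann-Whitney U (exact for small
  tie-free samples), Kruskal-Wallis with η² = (H−k+1)/(n−k),
  Benjamini-Hochberg FDR, Steel-Dwass all-pairs tests (infinite-df
  studentized range), and a per-factor screening driver.
- **cohort_summary** — Kaup index, ±1 SD weight categories, and
  frequency-table summaries with per-variable non-missing denominators and
  half-up one-decimal rounding.

## CLI

```sh
matshare simulate --config cohort.json --seed 1 --outdir cohort/
matshare share --table cohort/table.tsv --metadata cohort/metadata.tsv \
    --out profiles.tsv --null-out unrelated.tsv
matshare sharing-index --table cohort/table.tsv --metadata cohort/metadata.tsv \
    --taxonomy cohort/taxonomy.tsv --out sharing.tsv
matshare ordinate --table cohort/table.tsv --out-prefix ord
matshare cluster --table cohort/table.tsv --metadata cohort/metadata.tsv \
    --taxonomy cohort/taxonomy.tsv --k 8 --out clusters.tsv
matshare stats --profiles profiles.tsv --metadata cohort/metadata.tsv \
    --factors feeding,delivery,antibiotics --out screen.tsv
matshare summarize --metadata cohort/metadata.tsv --out table1.tsv
```

`cohort.json` may override any `SimConfig` field, e.g.
`{"n_pairs": 200, "tau0": 0.3, "background_rate": 0.02}`.

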