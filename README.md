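# signet

Signed transcriptional regulatory-circuit inference for few-sample designs.

`signet` infers activation/inhibition relations between transcription
factors (TFs) and genes from three inputs: gene expression, regulatory
region activity (e.g. ATAC-seq read densities) and TF binding-site
coordinates. Instead of correlation or model fitting — unreliable with
10–20 samples — it:

1. **Discretizes** each entity's per-population mean activity into a
   *pattern*: a tuple of levels 1–4 (min–max binned in log10 space), with
   all-`0` marking silent and all-`5` constant entities
   (`signet.discretize`).
2. **Links** regions to genes within 500 kb (closest-extremity distance)
   and TFs to regions via binding-site overlap (`signet.genomic_links`).
3. **Integrates** entities and reified relations into a queryable graph
   and enumerates candidate TF–region–gene triples with expressed TFs
   (`signet.graph`, optional Turtle export).
4. **Filters and signs** candidates with likelihood constraints: in each
   population the perfect gene level is `max(1, f − (4 − r))` for an
   activation (mirrored through `5 − g` for an inhibition); a deviation
   policy (`delta0`, `delta1`, `delta1_regOFF`, `delta2`) controls how
   many per-population departures are tolerated. Surviving triples are
   merged into unique signed TF–gene relations (`signet.constraints`).
5. **Selects key regulators** per gene pattern by coverage (fraction of
   the pattern's genes targeted) and specificity (fraction of the TF's
   targets inside the pattern), plus an annotation score from local
   GO/citation tables (`signet.key_regulators`).
6. **Validates** against curated TF–gene tables: reachability, binomial
   enrichment and sign concordance (`signet.validation`).

`signet.simulate` generates fully synthetic, seed-deterministic input
bundles with planted signed regulations (the generator inverts the
discretization, so the whole pipeline is exercised), used throughout the
test suite.

## CLI

```sh
# synthetic bundle with 20 planted signed relations
signet simulate --outdir fx --seed 7 --n-planted 20

# full pipeline from a YAML config
signet run-all --config config.yaml
```

`config.yaml` minimally names `expression`, `region_activity`,
`sample_map`, `genes_bed`, `regions_bed`, `tfbs_bed` and `outdir`;
optional keys include `policy` (default `delta1`), `max_distance`
(default 500000), `pseudocount`, `populations` and the coverage/
specificity threshold policy. Individual stages are also exposed as
`patterns`, `links`, `integrate`, `infer`, `classify` and `validate`
subcommands; every stage writes its intermediate table so the unsigned
network can be inspected before constraint filtering.

Input formats: activity tables are TSV (first column entity id, one
column per sample), the sample→population map is a two-column TSV, and
coordinates are BED3+ (BED4 for binding sites, column 4 = TF symbol).

## Notes

- Gene–region distances use whole gene bodies (not TSSs) as supplied in
  the gene BED.
- The constraint engine's table-driven and equation-driven evaluators are
  verified to agree exhaustively; the summed-deviation variant of the
  relaxation is available via `evaluate_triple(..., mode="sum")`.
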