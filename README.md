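# targettriage

An in-silico target-prioritization pipeline for two-tissue transcriptomics:
call differentially expressed genes (DEGs) in each tissue, intersect the
lists by direction, scan chromosomes for positional DEG "hot spots", score
interactome over-connectivity against each DEG set, run gene-set
over-representation, quantify validation qPCR by the 2^-ddCt method, and
triage candidate drug targets through a seven-criterion checklist
(DEG in both tissues, qPCR concordance, enrichment membership,
over-connectivity in both datasets, network hub, cross-tissue hot-spot
membership, existing drug links).

A seeded synthetic-data module generates every input type with planted
ground truth, so the whole chain is testable without any external data.

## Statistical conventions

* DEG gates are closed: `p <= p_max` and `|fc| >= fc_min`
  (defaults 0.05 and 1.1); the location test is Welch's unequal-variance
  t on log2 intensities; fold changes use the signed-ratio convention
  (down-regulation is the negative reciprocal, so no value lies in
  (-1, 1)). No multiple-testing correction is applied at this gate.
* Hot spots: every stretch of consecutive genes bounded by DEGs is tested
  against a hypergeometric null (w genes drawn from a platform universe of
  G genes with K DEGs); stretches with `k >= 5` DEGs and `p <= 0.001` merge
  into maximal hot spots.
* Over-connectivity reports the Actual/n/R/N/Expected/Ratio/z/p record per
  gene, with the focal gene excluded from its own background and the
  neighbor relation taken as the union of in- and out-edges (self-loops
  never count).
* Enrichment is a one-sided hypergeometric test conditioned on the platform
  universe, BH-adjusted across sets.
* qPCR group tests run on the dCt (log) scale; means and SEMs are reported
  on the 2^-ddCt scale with the reference control sample fixed at 1.

## CLI

```bash
targettriage simulate bundle --seed 1 --out demo/      # synthetic inputs + run.yaml
targettriage run --config demo/run.yaml                # full pipeline
targettriage deg --matrix X.tsv --groups g.tsv --case case --control control --out degs.tsv
targettriage overlap --a skin.tsv --b blood.tsv --out overlap.tsv
targettriage hotspots --degs degs.tsv --map genes.bed --out hotspots.tsv
targettriage overconnect --network net.sif --degs degs.tsv --out conn.tsv
targettriage enrich --degs degs.tsv --gmt sets.gmt --universe platform.txt --out enrich.tsv
targettriage qpcr --ct ct.csv --meta groups.csv --out qpcr.tsv
```

`run` writes one TSV per stage plus `summary.json` (stage counts and all
effective thresholds). Exit codes: 0 success, 2 validation failure, 3
stage failure.

Formats: TSV expression matrix (header = sample ids, first column = gene
ids) with a sample→group TSV; BED gene maps (0-based half-open); SIF edge
lists (`source<TAB>relation<TAB>target`, relation ∈ activates / inhibits /
interacts); GMT gene sets; CSV Ct tables (`sample,gene,replicate,ct`)
with a `sample,group` metadata CSV; TSV annotations
(`gene, protein_class, membrane_localized, drugs` with drugs as
semicolon-separated `name:stage`).

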