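# iiinet

Isoform-resolution protein interaction analysis. Most protein–protein
interaction (PPI) resources record interactions at gene level; `iiinet`
refines them to isoform–isoform interactions (IIIs) by scoring every
isoform pair of each known PPI with a logistic regression over two kinds of
evidence: absolute Pearson co-expression across a panel of isoform-level
expression datasets, and a domain–domain interaction (DDI) score derived
from the isoforms' domain compositions (high/medium/low-confidence DDIs map
to scores 3/2/1; the best cross-pair match wins).

The pipeline:

1. **Gold standard** — positives from isoform-specified PPI records plus
   PPIs between single-isoform genes; train/test split by record date
   (strictly after 2012-01-01 → test); negatives from plasma-membrane-only
   × nucleus-only isoform pairs among gold-standard isoforms.
2. **Model** — a (K+2)-coefficient logistic regression (intercept, one
   coefficient per expression dataset, one for DDI), fitted by
   ridge-stabilized IRLS.
3. **Prediction** — candidates are the isoform cross products of known
   gene-level PPIs. Logit score > 2.575 → high confidence; > 1.692 → low
   confidence; additionally each PPI's best-scoring pair is always kept
   ("rescued"), so every PPI yields at least one III.
4. **Modules** — overlapping dense modules (size 3–30, density ≥ 0.7) in
   the predicted network via a greedy seed-and-extend algorithm.
5. **Enrichment** — per-module hypergeometric GO/pathway enrichment
   (BH-adjusted), compared against size-matched random modules.

A fully seeded synthetic-data generator produces all six inputs with
planted ground truth (true IIIs, latent-factor co-expression, coherent
module annotations), so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic world
iii simulate --out world/ --seed 7

# full pipeline
iii run-all --catalog world/catalog.tsv --ppi world/ppi.tsv \
    --ddi world/ddi.tsv --expr world/expr --localization world/localization.tsv \
    --annotation world/annotation.tsv --out results/ --seed 7

# or stage by stage
iii gold --catalog ... --ppi ... --localization ... --out gold.tsv
iii predict --catalog ... --ppi ... --ddi ... --expr DIR --gold gold.tsv \
    --high-threshold 2.575 --low-threshold 1.692 --out predictions.tsv
iii modules --network predictions.tsv --min-size 3 --max-size 30 \
    --density 0.7 --seed 1 --out modules.tsv
iii enrich --modules modules.tsv --annotation world/annotation.tsv \
    --network predictions.tsv --alpha 0.05 --out enrichment.tsv
```

`run-all` also accepts a YAML config (`--config cfg.yaml`) mirroring all
flags; flags override the file. Exit codes: 0 ok, 2 invalid input/config,
3 runtime failure. `run-all` writes `report.json` with per-stage counts,
the fitted coefficients, held-out precision/recall, and enrichment rates.

All file formats are plain TSVs with headers; see the `iiinet.data_io`
module docstring for the exact dialects.

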