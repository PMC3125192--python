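# afas-screen

Design of antisense tiling probes and screening of sense–antisense
expression-balance reversals between paired cancer and normal tissue on a
two-priming-method (oligo-dT vs random) microarray design.

The package provides:

* **probe design** — tiling of fixed-length antisense probes every
  `tile_step` bases of a spliced transcript (GFF3 + FASTA input), with
  exon-junction ("truncated") flagging;
* **synthetic data** — a seeded generator reproducing the paired design
  (N patients × {normal, cancer} × {oligo_dT, random}), poly(A)− antisense
  signal visible mainly under random priming, log-normal noise, per-patient
  scale effects, and planted balance-reversal pairs with ground truth;
* **preprocessing** — global mean scaling against a reference array,
  inclusive detection calls (threshold 100 by default), probe- and
  gene-level positive fractions on per-probe medians across patients;
* **screens** — strict twofold up/down screens on the cancer:normal ratio
  of medians, the balance-reversal screen (strand dominance flips between
  tissues with ≥10% margins in ≥3 of 6 patients), a relaxed preset
  requiring only opposite ≥10% changes, antisense-dominance counting
  (≥3× in both tissues), concerted-change counting with a closed-form
  expectation, per-probe priming-method correlations, and direction
  concordance against external gene lists;
* **null statistics** — a random-shuffling null (per-probe, per-patient
  tissue-label swaps) giving expected count mean ± SD and an empirical p
  for any counting screen; χ² goodness of fit; exact/asymptotic
  Mann-Whitney U;
* **clustering** — deterministic agglomerative clustering of log2
  sense/antisense ratio profiles (correlation or euclidean distance;
  average/complete/single linkage), aligned reordering of a second matrix,
  and heat-map/Newick/TSV export saturating at ±3-fold.

## Command line

All stages are subcommands of `afas-screen`:

```sh
# simulate a dataset with ground truth
afas-screen simulate --seed 42 --out fixtures/

# design probes from gene models
afas-screen design --gff genes.gff3 --fasta genome.fa --step 500 \
    --probe-length 60 --out probes/

# normalize (global mean scaling; default reference = first oligo-dT normal array)
afas-screen normalize --matrix fixtures/matrix.tsv \
    --metadata fixtures/metadata.tsv --out norm/

# run every screen
afas-screen screen --matrix norm/matrix.tsv --metadata norm/metadata.tsv \
    --probes fixtures/probes.tsv --mode random --margin 0.10 --out results/

# shuffle null for a screen count
afas-screen permute --matrix norm/matrix.tsv --metadata norm/metadata.tsv \
    --probes fixtures/probes.tsv --screen balance_reversal \
    --n-shuffles 1000 --seed 7 --out null/

# cluster the log2 sense/antisense ratios and export displays
afas-screen cluster --matrix norm/matrix.tsv --metadata norm/metadata.tsv \
    --probes fixtures/probes.tsv --out figs/

# detection summary tables
afas-screen report --matrix norm/matrix.tsv --metadata norm/metadata.tsv \
    --probes fixtures/probes.tsv --out report/
```

File formats are plain TSV: the expression matrix has a `probe_id` column
followed by one column per sample; the metadata table maps `sample_id` to
`patient_id`, `tissue` (`normal`/`cancer`) and `priming`
(`oligo_dT`/`random`); the probe annotation has `probe_id`, `gene_id`,
`probe_class` (`sense`/`afas`), `afas_index` and `truncated`. Screen
thresholds can be overridden via a TOML `--config` file
(e.g. `margin = 0.2`).

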