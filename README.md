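# ciber

Analysis pipeline for pooled CRISPR screens read out through barcoded
small extracellular vesicles (sEVs).

## The problem

When sEV-producing cells carry a marker–dCas9 fusion (e.g. CD63–dCas9 or
CD9–dCas9), each cell's knockout guide RNA is loaded into the vesicles it
releases — the gRNA spacer becomes a per-cell barcode readable from the
culture supernatant. Sequencing the guide composition of paired cellular
and sEV fractions, with and without active Cas9, turns a single pooled
culture into a genome-scale screen for regulators of sEV release. The
catch is confounding: a knockout that changes cell growth or barcode
transcription changes the guide's abundance in *both* fractions. This
package implements the release-effect statistic that removes that
confounder, plus everything around it: scaffold-anchored read counting,
normalization and filtering, hit calling, cross-marker screen
comparison, TF-IDF term contrast, and a ground-truth synthetic-screen
generator.

## The statistic

Per retained guide, with nRC the normalized read count (mean 1 per
sample within each sublibrary):

```
FC_cells = log2(nRC_cells,Cas9+ / nRC_cells,Cas9−)
FC_sEVs  = log2(nRC_sEVs,Cas9+  / nRC_sEVs,Cas9−)
```

FC_sEVs is regressed on FC_cells (OLS); a guide's **release effect (RE)**
is its residual. The fit is trimmed once: within each gene the highest-
and lowest-residual guides are set aside and the line refit on the rest;
final REs come from the refit line. Gene RE = median of its guides' REs;
z-normalizing gene REs within each sublibrary gives the **z-RE**. Genes
with z-RE > 1.65 are upper hits (knockout increases release), < −1.65
lower hits. Barcodes with nRC < 0.05 in any of the four samples, and
genes left with < 3 barcodes, are excluded beforehand.

See `docs/methods.md` for conventions, degenerate cases, and what the
synthetic generator does and does not emulate.

## Worked example

Simulate a 500-gene screen with 5% planted release regulators, score it
and call hits:

```
$ cat sim.json
{"n_genes": 500, "guides_per_gene": 5, "depth": 500, "frac_release_genes": 0.05, "seed": 42}

$ ciber simulate --config sim.json --outdir screen/
simulated 500 genes x 5 guides into screen

$ ciber score --counts screen/counts.tsv --manifest screen/manifest.tsv \
    --reference screen/reference.tsv --out-guides guides.tsv --out-genes genes.tsv
SIM1: pass-1 R = 0.757 (n=2499), pass-2 slope = 0.904, intercept = -0.044

$ ciber hits --genes genes.tsv --output hits.tsv
12 upper hits, 11 lower hits of 500 genes

$ head -4 genes.tsv
gene    sublibrary      n_guides        re_gene z_re
G00000  SIM1    5       -0.01923005376986542    -0.06704103634826904
G00001  SIM1    5       0.21983839891462137     0.7916826448498642
G00002  SIM1    5       -0.02694568581075585    -0.09475525741978741
```

The pass-1 R = 0.757 is the guide-level correlation between the cellular
and sEV fold changes — the linear dependence the residual statistic
exploits. Of the 12 upper / 11 lower hits at |z-RE| > 1.65, 9 and 10
respectively are genes the simulation actually planted with positive /
negative release effects (`screen/truth.tsv` holds the ground truth);
the remainder are the ~5%-per-tail false-positive rate the threshold
implies. Counting raw reads from FASTQ instead of starting from a count
table: `ciber count --fastq sample.fastq --reference screen/reference.tsv
--output counts.tsv --stats stats.json`.

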