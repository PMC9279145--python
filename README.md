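# seqclass

A desk-scale, fully tested implementation of a chromatin-profile sequence
modelling framework: a deep convolutional model that predicts peak
probabilities for many chromatin profiles from DNA sequence, a clustering
pipeline that derives a vocabulary of **sequence classes** from genome-wide
model predictions, projection-based class scores with directional variant
effects, and the downstream population-genetics statistics built on them.

Everything runs end to end on synthetic data with planted regulatory
structure — no downloads, no GPU. The sequence model is implemented in
NumPy with manual backpropagation (verified against finite differences),
so the package has no deep-learning framework dependency.

## Layout

| Module | Contents |
| --- | --- |
| `seqclass.formats` | FASTA/BED/VCF IO, genome tiling into centred windows, blacklist/N masking, centre-bp peak overlap, profile compendium |
| `seqclass.synthetic` | Seeded generators: motif-planted genomes, cell-type-specific peak profiles, AF-coupled variants, enhancer-driven expression, planted-cluster prediction matrices |
| `seqclass.chromnet` | Model config + construction (dual linear/nonlinear conv blocks, dilated residual blocks, B-spline spatial basis), on-the-fly training with chromosome holdouts, prediction, AUROC/AUPRC evaluation, correlation-structure comparison |
| `seqclass.seqclasses` | Incremental PCA reduction, kNN graph (k=14), Louvain clustering, largest-cluster selection, per-class unit vectors, 100-bp genome annotation |
| `seqclass.scoring` | Class scores (projection), histone/nucleosome-occupancy normalization, Ref/Alt variant effects, positional + effect-based mutation-class assignment |
| `seqclass.genetics` | logFC enrichment (Fisher + BH), expression and eQTL correlations, six-bin effect layout, bidirectional constraint z-scores (per-sign logistic regression + Stouffer), LDSC annot export, conservative h² post-processing |
| `seqclass.cli` / `seqclass.pipeline` | `seqclass` command-line interface and the end-to-end miniature pipeline runner |

## CLI

```bash
seqclass synth --preset small --seed 7 --out cohort/      # synthetic inputs
seqclass tile --genome cohort/genome.fa --window 4000 --step 100 --out windows.bed
seqclass train --genome cohort/genome.fa --profiles cohort/profiles \
    --train-contigs chr1,chr2 --val-contigs chr3 --test-contigs chr4 \
    --steps 2500 --optimizer adam --seq-len 384 --out model.npz
seqclass predict --model model.npz --windows windows.bed --genome cohort/genome.fa --out preds.tsv
seqclass fit --preds preds.tsv --n-components 180 --k 14 --keep 40 --out scm/
seqclass annotate --scm scm/ --windows windows.bed --out annotation.bed
seqclass veffect --model model.npz --scm scm/ --vcf cohort/variants.vcf \
    --genome cohort/genome.fa --out effects.tsv
seqclass constraint --effects effects.tsv --vcf cohort/variants.vcf --out constraint.tsv
seqclass ldsc-annot --annotation annotation.bed --vcf cohort/variants.vcf --out ldsc.annot.tsv
seqclass h2-post --estimates h2_estimates.tsv --out h2_conservative.tsv
seqclass run --preset small --seed 7 --out run/            # whole pipeline + manifest
```

Exit codes: 0 ok, 1 user error, 2 internal error.

## Notes

- All coordinates are 0-based half-open internally; VCF positions are
  1-based on input. The centre base of an even-length window
  `[start, start+L)` is the base at `start + L/2`.
- Every generator and the whole fitting pipeline are deterministic under
  their seed arguments.
- Model checkpoints are single-file `.npz` archives with the config
  embedded; sequence-class models serialize to a directory of TSV/JSON
  files.
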