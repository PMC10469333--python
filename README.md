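# edscan

Two-phase enhancer modeling, in silico saturated mutagenesis, and
credible-set variant prioritization — testable end to end on a synthetic
regulome with planted motifs and planted causal variants.

The pipeline:

1. **synthetic_regulome** — generates a multi-chromosome genome in which
   enhancers are defined by co-occurring "H3K27ac" and "accessibility"
   peaks, carry planted PWM motif instances (per-PWM "TF" tracks cover
   them), and genetic signals have one motif-disrupting causal SNP plus
   positional LD-companion SNPs and credible-set PPAs.
2. **enhancer_model** — phase one: a small convolutional network mapping a
   2,000 bp one-hot window to per-feature peak probabilities; phase two: a
   classifier on the phase-one feature vector giving an enhancer
   probability. Enhancers are 2 kb windows centered on peak intersections.
   Models are implemented on a self-contained seeded NumPy NN framework
   (`edscan.nn`) — no deep-learning dependency.
3. **saturated_mutagenesis** — per-base enhancer-damage (ED) scores
   (reference probability minus mean over the three alternative bases;
   positive = damaging) and segmentation into damaging (EDR) and
   strengthening (ESR) runs.
4. **tfbs_from_ed** — classifiers predicting TFBS overlap of called
   regions from the ED profile alone, with a sequence-only baseline.
5. **snp_perturbation** — per-SNP IEP scores
   `iep = max(P_ref, P_alt) * |P_alt - P_ref|` with catalog percentiles and
   EDR/ESR overlap annotation.
6. **credible_set_prioritization** — IEP ratio of the top two scores per
   credible set, threshold calibration against known-causal reference
   signals (hypergeometric test), EDR/ESR overlap enrichment, and
   credible-vs-LD enrichment curves.
7. **motif_tools / stats_eval / genomic_io** — PWM scanning and allelic
   deltas, shared statistics (auROC/auPRC, rank tests, exact tails,
   BH-FDR, matched-background enrichment), and FASTA/BED/SNP/MEME I/O.

## CLI

```bash
edscan simulate --config demo.yaml --seed 1 --out-dir sim/
edscan call-enhancers --genome sim/genome.fa \
    --h3k27ac sim/tracks/H3K27ac.bed --accessibility sim/tracks/accessibility.bed \
    --out enhancers.bed
edscan train-phase1 --genome sim/genome.fa --tracks-dir sim/tracks \
    --out-dir models/ --seed 1 --holdout-chroms chr4
edscan train-phase2 --genome sim/genome.fa --model-dir models/ \
    --enhancers enhancers.bed --seed 1
edscan predict --genome sim/genome.fa --model-dir models/ \
    --windows enhancers.bed --out probs.tsv
edscan mutagenesis --genome sim/genome.fa --model-dir models/ \
    --enhancers enhancers.bed --out-prefix mut --tau-sd 1.0
edscan score-snps --genome sim/genome.fa --model-dir models/ \
    --snps sim/snps.tsv --out scores.tsv
edscan prioritize --scores scores.tsv --credible-sets sim/credible_sets.tsv \
    --ratio-threshold 24 --out results.tsv
```

Every stage writes a manifest (version, seed, config hash) beside its
outputs; identical seeds give byte-identical simulation outputs and
bit-identical model predictions.

## Notes on scores

The IEP formula and the region-calling threshold are declared
reimplementation choices (the source study defines both only in
supplementary material): IEP weights the allelic probability shift by the
stronger allele's enhancer probability and is symmetric under allele swap;
region calling thresholds at `tau_sd` times a trimmed profile SD
(`sigma_mode="full"` gives the plain SD rule).
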