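# cobind

Peak-architecture and co-regulation analysis for a pair of cooperating
transcription factors, exercised end-to-end on synthetic data with planted
ground truth.

## The problem

When a bHLH factor (binding the palindromic G-box, CACGTG) and a single
zinc-finger DOF factor (binding the short, genome-wide-common consensus
[T/A]AAAG) act on the same genes, the evidence for cooperation is
distributed across several layers of genomics data: where the DOF factor's
ChIP-seq peaks sit relative to genes, how many G-box and DOF motifs the
peaks carry and how those motifs are spaced, whether per-peak occupancy
drops when the partner factor is knocked out, whether binding strength
scales with motif content, and whether the genes that respond
transcriptionally in both mutants are the same genes that carry the binding
changes. `cobind` implements that entire analysis chain as a library with a
CLI, plus a synthetic-data generator that plants all of the structure the
chain is supposed to detect — so every stage can be tested for exact or
calibrated recovery.

The core quantities:

- **Peak→gene assignment**: a peak is linked to every gene whose window
  [TSS − 3 kb, TES + 1 kb] (gene orientation) contains the peak center;
  positional structure is summarized on a metagene axis and compared with a
  95% envelope from 1,000 random peak sets with the observed length
  multiset placed uniformly.
- **Motif architecture**: exact IUPAC scanning on both strands; per-peak
  copy-number tables; start-to-start spacing histograms (5-bp bins) with
  promoter background; binomial central-enrichment tests.
- **Binding strength vs motif count**: Kruskal–Wallis with tie correction,
  pairwise Wilcoxon rank-sum with BH adjustment, compact letter display.
- **Differential occupancy**: median-of-ratios normalization, moderated t
  on log2(count + 0.5), BH FDR ≤ 0.05.
- **Co-regulation**: DEG filtering at |FC| ≥ 1.5 and adjusted p < 0.05,
  hypergeometric overlap, direction consistency, and the four-way
  intersection (shared DEGs ∩ bound-by-A ∩ bound-by-B ∩ reduced binding)
  with per-gene provenance.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic dataset (seed 1) and write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_annotate_peaks.py
python analysis/03_motif_architecture.py
python analysis/04_binding_strength.py
python analysis/05_coregulation.py
```

Output (abridged):

```
genes: 300, peaks: 600
planted cooperative genes: 10
1167 links: 587 peaks -> 296 genes (multi-assignment allowed)
peaks with a site within 3 kb 5' of a TSS: 90.0%
upstream-flank bins above the null hi95: 13
gbox (CACGTG):
  copies per peak: {0: '69.8%', 1: '19.7%', 2: '7.2%', 3: '3.3%'}
  spacing mode 22.5 bp (n=83); background mode None bp
dof (AAAAG):
  copies per peak: {0: '5.7%', 1: '8.2%', 2: '50.5%', 3: '35.7%'}
  spacing mode 17.5 bp (n=731); background mode 147.5 bp
binding strength vs G-box count:
  Kruskal-Wallis H = 319.63, p = 5.61e-69
  letters: {'0': 'd', '1': 'c', '2': 'b', '>=3': 'a'}
differential occupancy (wild_type vs pif4):
  63 of 600 peaks at FDR <= 0.05 (60 down, 3 up)
DEGs: pif4 60, cdfq 60, shared 30 (hypergeometric p = 2.19e-09)
direction agreement among shared DEGs: 11 up/up, 16 down/down, 3 opposite (10%)
cooperative genes: 10 (planted 10; recovered exactly: True)
```

Reading the numbers: 90% of peaks sit within 3 kb upstream of a TSS (80%
planted there plus chance proximity), and every upstream metagene bin
exceeds the randomized envelope. The recovered motif copy-number fractions
match the planted plan (~20% of peaks with one G-box, 87% with ≥2 DOF
motifs), and the 5-bp spacing histograms peak in the bins containing the
planted 25/15 bp means, with no such mode in promoter background. Binding
strength rises monotonically with G-box count (all four groups separated,
distinct letters). Differential occupancy recovers the 60 peaks with
planted binding loss (plus 3 false positives, consistent with FDR ≤ 0.05),
and the final intersection returns exactly the 10 planted cooperative
genes.

The same pipeline runs behind one command:

```bash
cobind all --outdir out --seed 1           # simulate-first, default config
cobind validate --config my_config.yaml   # check a config file
```

A YAML config can instead point `inputs:` at existing FASTA/GFF3/narrowPeak/
TSV files; stages whose inputs are missing are skipped and flagged in the
JSON run report.

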