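# Methods

`cobind` re-implements, as a tested pipeline over synthetic data with planted
ground truth, the peak-architecture and co-regulation analyses used to argue
that one transcription factor (a bHLH binding the G-box CACGTG, "PIF4")
strengthens and re-targets the DNA binding of a partner single zinc-finger DOF
factor (binding [T/A]AAAG, "CDF2"). The pipeline covers peak-to-gene
assignment, randomized positional nulls, motif count/spacing/centrality
statistics, binding-strength stratification, differential peak occupancy
between genotypes, and the multi-set intersection that defines cooperatively
regulated genes. Upstream read processing (mapping, peak calling), de novo
motif discovery, differential-expression model fitting and GO enrichment are
out of scope; their products (peaks, counts, DEG tables) are inputs.

## Coordinate and scanning conventions

All intervals are 0-based half-open; GFF3 is converted at the read boundary.
Sequences are uppercased on read, so scanning is case-insensitive by
construction. Chromosome names are taken verbatim.

Motif scanning is exact IUPAC-consensus matching on both strands, with
minus-strand hits reported at their forward-strand start. A palindromic
consensus (CACGTG) is scanned on the forward strand only so it is never
double-counted. `N` never matches. The default counting policy reports every
match including overlapping ones; a greedy left-to-right non-overlapping
policy is available (for the built-in motifs the two differ only for motifs
with non-trivial self-overlap; AAAAG has none). Two DOF specs are built in:
the strict core `AAAAG` (the default for count/spacing/stratification
analyses) and the broader `WAAAG`.

## Peak-to-gene assignment and the metagene profile

A peak is assigned to **every** gene whose window — `upstream_window`
(default 3,000 bp) 5' of the TSS through `downstream_window` (default
1,000 bp) 3' of the TES, in gene orientation, boundaries inclusive — contains
the peak's anchor. The anchor is the peak center by default (`summit`
optional); multi-assignment is deliberate, since a peak between divergent
promoters is evidence for both genes. Signed distances run anchor→TSS in gene
orientation, negative upstream.

The metagene axis concatenates the upstream flank (rescaled to [-1, 0)), the
gene body (rescaled to [0, 1]) and the downstream flank ((1, 2]). Each link
contributes one point; densities are normalized by the **number of peaks**,
so the profile sums to the per-peak link rate (slightly above the assigned
fraction under multi-assignment). Normalizing per link instead would rescale
every random set onto the observed curve and cancel exactly the positional
enrichment the comparison is meant to detect, because random sets link far
fewer of their peaks. Bin count is configuration, not contract (default 50).

The null envelope re-places the observed peak-length multiset uniformly:
for each peak, a (chromosome, start) pair is drawn uniformly over all
positions where the peak fits, which makes chromosome choice proportional to
placeable positions. Per-bin means and interpolated 2.5/97.5 percentiles over
`n_sets` (default 1,000) sets form the envelope. No blacklist is applied —
the null matches lengths only. The envelope estimates fixed population
percentiles; its width does not shrink as `n_sets` grows (only its
estimation error does).

## Motif architecture statistics

Per-peak motif counts include the zero class, so frequency tables sum to the
number of peaks. Spacing distances are start-to-start between consecutive
same-motif hits within a region, strand ignored, pooled across regions;
regions with fewer than two hits contribute nothing. The histogram uses 5-bp
bins anchored at zero and the mode estimate is the center of the maximal bin
— wide enough to smooth count noise, narrow enough to separate the 15 vs
25 bp regimes of interest. Background spacing uses the promoters (default
1,000 bp 5' of the TSS, gene orientation, a declared convention) of genes
*not* in the target set.

Central enrichment counts hits whose match center lies within ±w of the peak
center, for a ladder of half-widths w. The expected central fraction under
uniform placement is the mean over peaks of min(2w, placeable span) /
placeable span, where the placeable span is peak length − motif length + 1.
The one-sided binomial upper-tail p is Bonferroni-adjusted over the ladder
and the smallest adjusted p is flagged. Note that in the synthetic data
multi-copy motif runs are centrally enriched by a real geometric effect:
a run must fit inside the peak, which biases run centers toward the middle.

## Binding-strength stratification

Peak scores are grouped by motif count (counts ≥ `max_group` pooled).
Kruskal–Wallis H is computed from ranks with tie correction, p from
chi-square with g−1 df. All unordered group pairs are tested by two-sided
Wilcoxon rank-sum (normal approximation with tie correction, no continuity
correction) and BH-adjusted across pairs (the adjustment method is a
declared convention; the source analyses state only "pairwise Wilcox
tests"). Letters are assigned by insert-and-absorb, which guarantees exactly
that two groups share a letter iff their adjusted p ≥ α (default 0.05). Both
rank statistics are implemented from the rank formulas and validated against
independent reference implementations to 1e-10 in the tests.

## Differential peak occupancy

The packaged differential-binding engine used in the original analyses is
replaced by a transparent, simulation-verifiable chain:

1. **Normalization** — median-of-ratios size factors (geometric-mean
   reference over rows positive in all samples; library-size fallback with a
   warning when no such row exists).
2. **Transform** — log2(normalized count + 0.5). The 0.5 pseudocount is the
   standard variance stabilization for NB counts at this scale.
3. **Test** — a two-sided t on the difference of condition means. By default
   the pooled within-condition variances are squeezed toward an empirical
   prior (scaled inverse-chi-square fitted by matching moments of log s²,
   with the trigamma inversion solved by Newton iteration), and the t
   reference gains the prior degrees of freedom. With 3 replicates per
   condition a plain Welch t has ~4 df per peak and, at the planted effect
   sizes and NB dispersion this package simulates, cannot reach useful
   sensitivity at a BH-adaptive threshold; borrowing variance information
   across peaks is what makes per-peak testing workable at this design, and
   under the simulated conditions it achieves ~0.97 sensitivity at empirical
   FDR ≈ 0.06 (measured by the test suite). `moderate_variance=False`
   restores the plain Welch chain.
4. **FDR** — BH across peaks; `significant` means fdr ≤ 0.05.

log2fc is condition-2 minus condition-1 on the log2 scale, so the chain is
antisymmetric under label swap. Known limitations: no dispersion–mean trend,
no spike-in or background normalization, and mild anti-conservativeness in
the extreme tail from the non-normality of log NB counts (absorbed by the
FDR margin at the simulated scales).

## Co-regulation set logic

DEG filtering retains genes with |log2fc| ≥ log2(1.5) (inclusive) and
adjusted p < 0.05 (strict), mirroring the stated thresholds; direction is
the sign of log2fc. Overlap significance is the hypergeometric upper tail
P(X ≥ k) with the universe defaulting to genes present in both tables (the
choice of test and universe are declared conventions). Direction consistency
partitions shared DEGs into same-up / same-down / opposite; the fraction is
reported as null when the intersection is empty. The cooperative set is the
exact four-way intersection of shared DEGs, genes bound by each factor, and
genes linked to peaks with significant negative log2fc, with per-gene
provenance. Row z-scores (population SD; constant rows → zeros with a
warning) support expression heatmaps of the result.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions and every planted quantity is recorded in a `TruthBundle` that an
independent checker verifies against the emitted files (rescan of every
peak, set membership of every planted id).

**What it emulates, and the defaults.** A 2×500 kb i.i.d. genome at
base composition (0.3, 0.2, 0.2, 0.3); 300 non-overlapping genes of
500–2,500 bp with Bernoulli(½) strands; 600 non-overlapping peaks of length
Normal(300, 50) truncated at 50 bp, 80% of which have their center within
3 kb upstream of a random TSS (echoing the ~82% upstream share of the real
peak set) and the rest uniform. Per-peak motif copy numbers follow
(0.71, 0.20, 0.06, 0.03) for the G-box — about 20% of peaks with one copy
and ~9% with more — and (0.05, 0.08, 0.50, 0.37) for the DOF core — 87%
with two or more, at most three. Consecutive copies are spaced
Normal(25, 5) bp (G-box) and Normal(15, 4) bp (DOF), start-to-start,
truncated at motif length + 1. Counts are NB (Gamma–Poisson) with mean 100,
dispersion 0.1 (var = μ + 0.1 μ²), 3 replicates per condition, per-sample
size factors log-uniform in [0.7, 1.4]; 10% of peaks lose binding in the
second ("pif4") condition with effect log2fc −2, drawn preferentially from
G-box-carrying peaks. DEG tables for two genotypes plant 60 DEGs each with a
30-gene shared set (enriched relative to independence over the 300-gene
universe), 10% opposite directions among shared genes, and planted
magnitudes safely across the 1.5-fold boundary. Values the source analyses
do not state (genome size, gene/peak numbers, peak length, NB mean,
DEG-set sizes) were fixed once at desk-scale-realistic magnitudes.

**Planting discipline.** Motif instances are written in place (never
inserted), so coordinates cannot shift; peaks are kept non-overlapping so a
redraw of one peak cannot corrupt another. After writing, each peak is
rescanned; if the random background or a collision produced any unplanned
match of a planned motif, the peak's background is redrawn and replanted
(up to 100 times, then an error naming the peak). This guarantees the
scanner's view of every peak equals the planted truth exactly — the property
the recovery tests rely on. Peak scores are linear in planted G-box count
(base 5, +2 per copy, Gaussian noise SD 1, truncated positive), giving the
stratification a real monotone signal.

**The cooperative truth.** Cooperative genes are chosen among
promoter-bound genes with at least one G-box peak, preferring genes with two
or more promoter peaks so the planted gene-level binding evidence is
redundant — as it is for real multi-peak target genes — and every such peak
is forced into the affected set. The shared-DEG set is the cooperative genes
plus filler genes chosen outside all binding layers and excluded from the
partner factor's target list, so the end-to-end intersection can be checked
for exact recovery with no structural false-positive path. The partner
("PIF4") target list is the cooperative genes plus a random 30% of the
remaining genes.

**Determinism.** One `SeedSequence` is spawned into independent child
streams in a fixed order (genome, genes, peaks, motifs, scores, counts,
degs); the counts stream is further split into selection and noise
substreams so configurations with identical means yield identical matrices.
Identical configs give byte-identical outputs.

**What passing tests do and do not show.** The generator's genome is i.i.d.
and its peaks are disjoint intervals with exactly planted motif content;
real chromatin has nucleotide composition structure, repeats, overlapping
and clustered peaks, background motif gradients, and count dispersion that
varies with mean. Recovery at the planted conditions demonstrates that the
statistics are implemented correctly and calibrated under their own
assumptions, not that the pipeline's numbers on real data would match any
published value.

## Problem sizes used by the automated checks

The calibration and recovery checks run at desk scale, sized so that each
property is measured where its statistics are informative: scanner/oracle
equivalence on 1,000 random 200-bp sequences; overlap-test enumeration for
universes up to 12; spacing-mode recovery over 500 peaks × 40 seeds;
envelope calibration with 2,000 uniformly placed peaks × 1,000 random sets ×
20 seeds (peaks drawn by the same i.i.d. placement model as the null — the
generator's non-overlap constraint is a different point process and would
read as over-coverage); positional-signal detection with 1,000 peaks, 100
genes and 12 metagene bins (coarse bins give each upstream bin enough counts
for a per-bin exceedance test); differential-binding recovery on 2,000 peaks
× 20 seeds; and end-to-end cooperative recovery over 20 seeds at the default
conditions with a reduced (20-set) envelope, which is not under test there.
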