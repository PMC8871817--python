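# hybcap

Target-enrichment (Hyb-Seq) panel design and evaluation for
phylogenomics.

Hybridization capture studies — for example building a custom bait set
for a plant family such as Cactaceae, alongside a lineage-specific
subset of the universal Angiosperms353 kit — involve a series of
computational steps *around* the off-the-shelf assembly, alignment and
tree-inference tools: choosing single-copy target loci from candidate
gene sets, designing and QC-filtering tiled probes, summarising how
much of each target each sample recovered, and asking how much the
resulting gene trees agree with the species tree. `hybcap` implements
exactly those steps for people who design or evaluate capture panels.

## What it computes

**Locus selection.** Starting from an orthology classification
(MarkerMiner-style `locus_id → {strictly_single_copy,
mostly_single_copy, other}`), the filter cascade keeps strictly
single-copy loci whose gene structure suits capture (at least one exon
> 120 bp; every annotated intron ≥ 100 bp), screens candidates against
non-target references (mitochondrial/plastid genomes, other panels)
with an exhaustive Smith–Waterman local alignment (match +1, mismatch
−1, gap open −2, gap extend −1; identity counted over alignment
columns, both strands), and collapses near-identical loci
(≥ 99 % identity over ≥ 100 bp) to one representative. A 10 %-gap
alignment-column trimmer covers the standard pre-tree cleaning step.

**Probe design.** Probes of length 120 nt are tiled at 3× coverage
(step = 120/3 = 40 bp, with an optional 3′-anchored end probe), probes
with single-nucleotide runs longer than 12 bp are removed, and probes
aligning at ≥ 98 % identity over ≥ 80 bp (either strand) are collapsed
to one copy, with per-stage provenance counts.

**Recovery evaluation.** From a HybPiper-style `seq_lengths` table
(samples × loci recovered bp, plus per-locus target lengths) and read
counts, it derives per-sample statistics (% on-target reads, genes
with sequences, loci at ≥ 25/50/75 % of target length), the
length-proportion matrix behind recovery heatmaps, the no-hit cell
fraction, per-clade recovered locus sets with the pairwise overlap
table, and paralog-warning tallies.

**Gene-tree concordance.** For every internal edge of a species tree,
each gene tree is classified as concordant, conflicting (with the
observed conflicting bipartition recorded; the most frequent across
trees is the "top alternative") or uninformative (missing taxa or
polytomy), phyparts-style, on unrooted splits restricted to shared
taxa.

**Synthetic fixtures.** Seeded generators produce every input above
with planted ground truth (loci that must fail each filter, realized
gene-tree draws with exact expected concordance records), so the whole
pipeline is testable end to end without downloads.

## Worked example

```bash
hybcap simulate all --seed 1 --out sim_out
hybcap stats sim_out/targets.fasta
```

prints (stdout)

```
panel	n_loci	n_sequences	total_bp	min	max	mean
panel	138	842	682942	42	1771	811.0950118764846
```

i.e. the simulated candidate set holds 138 loci (133 strictly
single-copy candidates plus 5 multi-copy decoys) carried by 842
reference sequences. Running the filter cascade in Python:

```python
from hybcap import filters, simulate

res = simulate.simulate_locus_set(seed=1)
final, report = filters.apply_cascade(
    res.registry, res.classification, res.structures, res.organelle
)
print(len(final.loci))                 # 120
print(sorted(report["structure_fail"])[:3], len(report["structure_fail"]))
print(len(report["screen_fail"]))      # 5
```

retains 120 of the 133 candidates: 8 loci fail the exon/intron rule and
5 are flagged by the organelle screen — matching the generator's
planted ground truth exactly. Designing probes on the retained panel:

```bash
hybcap design final_panel.fasta --outdir probes_out
# probes: 13883 tiled -> 13883 after homopolymer filter -> 13883 after collapse
```

and concordance on the simulated gene trees:

```bash
hybcap concord sim_out/species_tree.nwk sim_out/gene_trees.nwk
```

emits one TSV row per species-tree node with the four counts
(concordant / top alternative / other conflict / uninformative) and
their fractions; on the simulated set they equal the generator's
realized expectations, e.g. counts `139 20 7 34` (concordant fraction
0.695 at a nominal 0.7, the rest split between the two alternative
topologies and trees missing a focal taxon) at the A,B node for
seed 1.

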