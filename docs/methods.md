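# Methods

This note records the models, conventions and design choices behind
`hybcap`, in the spirit of a methods appendix: what each component
assumes, which parameters matter and why their defaults are what they
are, what the synthetic data does and does not emulate, and where the
design was genuinely open.

## Conventions used throughout

* **Coordinates** are 0-based, half-open everywhere (probe spans,
  alignment hits). A single convention avoids off-by-one drift between
  the screening and probe-design layers.
* **Target-file headers** encode `taxon<sep>locus` and are split on the
  *last* separator occurrence (default `-`), because taxon names
  routinely contain the separator (`Ariocarpus-retusus-g7` →
  taxon `Ariocarpus-retusus`, locus `g7`).
* **Residue validation** warns on IUPAC ambiguity codes (other than N)
  and fails on anything outside the IUPAC alphabet;
  transcriptome-derived references legitimately contain ambiguities.
* **Local alignment** uses one scoring convention for every similarity
  decision in the toolkit: match +1, mismatch −1, affine gaps with open
  −2 and extend −1 (a gap of length k costs 2 + (k − 1)); identity =
  matches / alignment columns, gap columns counting as non-matches;
  N never matches, comparison is case-insensitive; both query strands
  are searched and score ties prefer the forward strand. The traceback
  is fully deterministic (cell preference diagonal → vertical →
  horizontal; best cell = first maximum in row-major order), which
  makes alignments — not just scores — reproducible and lets an
  independent re-implementation agree exactly. The dynamic program is
  exhaustive (full Gotoh matrix, numba-compiled); no heuristic seeding
  affects results.
* **k-mer prefilter.** For the high-identity checks only (probe
  collapsing at 98 %/80 bp, locus deduplication at 99 %/100 bp) a
  shared-20-mer prefilter skips hopeless pairs. This is lossless, not
  approximate: an alignment with ≥ 98 % identity over ≥ 80 columns has
  at most 2 non-match columns among ≥ 79 matches and therefore contains
  an exact run of ≥ 26 matching bases (≥ 49 for the 99 %/100 bp rule),
  so any qualifying pair necessarily shares a 20-mer. The 70 %-identity
  organelle screen never uses the prefilter, because no such run is
  guaranteed at that threshold.

## Locus-selection cascade

Stages, in order: (1) keep loci classified strictly single-copy;
(2) keep loci with at least one exon strictly longer than 120 bp and
with every annotated intron at least 100 bp (a locus without introns
passes the intron clause vacuously — the "all introns" reading is a
deliberate choice; the alternative "at least one intron" reading is
not implemented); (3) flag and remove loci whose best local alignment
against any non-target reference reaches 70 % identity over 100
columns; (4) collapse loci that align at ≥ 99 % identity over ≥ 100 bp
into one representative, computed on the transitive closure of
duplicate pairs, retaining the first-panel locus and breaking ties by
lexicographically smallest id.

The exon bound is strict (an exon of exactly 120 bp fails) while the
intron bound is inclusive; the asymmetry is intentional and mirrors
how such suitability rules are usually phrased ("more than" vs "or
more"). The screen operates at nucleotide level; screens against
protein databases in the original workflows are BLASTx-based, and the
identity/length thresholds here are declared defaults, configurable to
match whatever stringency a user's BLAST screen used, not values
derived from any particular study. Deduplication treats "identical"
as ≥ 99 % identity rather than byte equality, since reciprocal-BLAST
style duplicate detection reports near-identical hits.

The column trimmer keeps exactly the alignment columns whose gap
fraction is ≤ 0.10 (inclusive at the boundary) and is idempotent by
construction.

## Probe design

* `probe_length` = 120 nt, the standard bait length.
* `tiling_factor` = 3 is interpreted as step = probe_length / factor =
  40 bp, i.e. 3× average coverage — the usual bait-design meaning of
  "n× tiled". Interior bases are covered exactly 3 times.
* **End anchoring** (on by default): when the last regular tile stops
  short of the 3′ end, one extra probe pinned to the end is added so
  target ends are never uncovered. "All possible probes" layouts leave
  end semantics open; this is the package's choice and is toggleable.
* **Homopolymer rule**: probes whose longest single-nucleotide run
  exceeds 12 bp are removed (run of exactly 12 is kept). Runs are
  case-insensitive and broken by N. Vendor pipelines rarely publish
  their exact threshold; 12 is a common bait-QC heuristic, declared
  here as a default rather than inferred.
* **Redundancy collapse**: probe pairs aligning at ≥ 98 % identity over
  ≥ 80 columns (either strand) are collapsed to the earlier probe in
  (locus, taxon, start) order, iterated to a fixpoint; the result is
  independent of input file order. **Exemption:** probes cut from the
  same source sequence with overlapping spans are never collapsed.
  Overlapping 3×-tiles share an identical 80 bp block *by
  construction*; collapsing them would undo the deliberate tiling
  redundancy and reduce every panel to ~1× coverage, which is plainly
  not what redundancy collapsing is for (published panel sizes are
  close to full tiling counts, minus a minority of filtered probes).
  The fixpoint guarantee ("no retained pair meets the criterion") holds
  with the same exemption.

## Recovery statistics

* When a locus has several reference sequences the target-length
  denominator is their arithmetic mean (HybPiper's convention;
  configurable to max).
* The ≥ 25/50/75 % thresholds are inclusive.
* Over-recovery (recovered longer than the reference, common when the
  reference is a transcript and the assembly includes introns) is kept
  and flagged in statistics but capped at 1.5 for heatmap display;
  exact zeros are preserved as the no-hit class.
* The no-hit fraction is defined over (sample × locus) cells.
* "Genes with contigs" vs "genes with sequences" requires assembler
  internals; without a contig table the two collapse to the same count,
  and a boolean contig matrix can be supplied when available.
* Clade-level recovery counts a locus for a clade when at least one of
  the clade's samples recovered it; the overlap table is symmetric with
  off-diagonal entries bounded by the smaller diagonal.

## Gene-tree concordance

All comparisons happen on unrooted splits; rooting is display-only, and
re-rooting a gene tree never changes a classification. For a species
split S and a gene tree G: restrict S to the taxa G samples; if either
restricted side has < 2 taxa, G is uninformative at S. Otherwise G is
concordant if the restricted split occurs among G's splits (also
restricted to shared taxa), conflicting if any of G's restricted
splits is incompatible with it (two splits on one taxon set conflict
iff all four side intersections are non-empty), and uninformative
otherwise (polytomy at the relevant region). Missing-taxon and
polytomy uninformativeness are tallied together, as in standard
concordance pies, but are distinguishable in verbose use.

A conflicting gene tree may display several splits incompatible with
S. Each of them is entered into the frequency table; the **top
alternative** is the split observed in the most gene trees (ties
broken by canonical order: the side containing the lexicographically
smallest taxon, listed first), `n_top_alternative` counts the trees
displaying it, and the remaining conflicting trees are
`n_other_conflict`. This containment semantics keeps all four counts
invariant under consistent taxon relabelling — a per-tree "pick one
conflicting split" rule would not be — and the four counts always sum
to the number of gene trees. Because conflict percentages are quoted
against different denominators in the literature, fractions are
available normalised both by all trees and by informative trees only.

Support-value collapsing is off by default; an optional threshold
collapses gene-tree edges labelled below it before classification.

## Synthetic data

All generators draw from NumPy's PCG64 (`numpy.random.default_rng`)
with an explicit seed; the draw order is part of the contract, so a
fixed seed gives byte-identical outputs across platforms.

* **Locus sets** default to 133 strictly single-copy candidates among
  1859 mostly single-copy ids, with 8 planted structure failures
  (alternating all-exons-≤120 bp and one-short-intron modes), 5 loci
  embedding an exact 150–300 bp substring of a synthetic organelle
  reference, and 5 multi-copy decoys carrying sequences — the ledger
  of a realistic panel-building round at desk scale. Exon counts are
  1–5 of 140–400 bp, introns 100–300 bp, and each locus carries 4–8
  reference taxa (≈ 6 on average, matching deposited panels with
  several hundred reference sequences per ~120 loci). The organelle
  reference is a 2 kb random sequence: long enough to exercise the
  screen, short enough that the exhaustive alignment stays fast; a
  real 150 kb plastome would only change the constant factor. Planted
  failure sets are disjoint by construction, so the expected final
  panel is exactly `n_strict − n_structure_fail − n_organelle_like`.
* **Recovery** uses a 36-sample design across five clades
  (17/10/5/3/1) with per-clade recovery probabilities
  0.95/0.92/0.85/0.80/0.70 — a monotone ingroup→distant-lineage decay
  of the kind capture experiments show — recovered lengths of
  0.3–1.2 × target (so over-recovery occurs), total read counts of
  0.2–2 M with 0.05–3 % on-target, and paralog warnings at 0.007 per
  recovered cell (tens of warnings per panel, concentrated nowhere).
* **Gene trees** default to an 8-taxon species tree with two
  NNI-style alternative topologies (weights 0.6/0.4 of the discordant
  mass), concordance probability 0.7 and a 10 % per-taxon missing
  rate. Expected per-node records are computed from the *realized*
  draws — via the generator's own nested-tuple split arithmetic, a
  code path separate from the Newick-parsing pipeline — so
  concordance tests are exact rather than statistical.

What the fixtures deliberately do **not** emulate: sequence evolution
(no substitution models — simulated loci are random DNA, so the
similarity screens face easier negatives than homologous real
sequences), coalescent branch lengths, read-level data, or assembler
behaviour. Passing the planted-truth tests therefore demonstrates that
the *bookkeeping and decision rules* are correct, not that thresholds
are well calibrated for any particular genome.

## Problem sizes and numerics

The default simulation scale (133 candidate loci × ~6 reference taxa,
2 kb organelle reference, 36 samples, 200 gene trees) keeps the full
pipeline — including the exhaustive both-strand Smith–Waterman screen
of every reference sequence — at around a minute on one core, which is
the scale the test suite and the acceptance script use. Alignment
scores are float64; all threshold comparisons are exact (≥/>) with no
epsilon, which is safe because scores and identities at these scoring
parameters are ratios of small integers.

## Known limitations

* The screens are nucleotide-level; a translated (BLASTx-like) mode is
  not implemented, so protein-level similarity below ~70 % nucleotide
  identity will not be flagged.
* `read_trees` expects one Newick string per line (the common
  gene-trees file layout); multi-line single trees are not supported.
* The recovery module consumes recovered-length tables; it does not
  recompute them from reads or assemblies.
* E-value statistics are out of scope; screen decisions are purely
  identity/length thresholds.
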