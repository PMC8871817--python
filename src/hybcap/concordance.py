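"""Gene-tree / species-tree concordance per internal node.

For every internal edge of the species tree, each gene tree is
classified against the edge's bipartition (split):

* concordant - the species split, restricted to the taxa the gene tree
  actually samples, occurs among the gene tree's splits;
* conflict - the gene tree contains a split incompatible with the
  restricted species split (two splits on the same taxon set conflict
  iff all four pairwise side intersections are non-empty); the observed
  conflicting split is recorded, and per node the most frequent one is
  the "top alternative";
* uninformative - the restriction leaves fewer than two taxa on either
  side (missing taxa), or the gene tree is unresolved at that split.

All comparisons are on unrooted splits, so re-rooting a gene tree never
changes a classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


class TreeFileError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Bipartition:
    """Canonical unrooted split: two disjoint taxon sets.

    ``side_a`` is the side containing the lexicographically smallest
    taxon, each side stored as a sorted tuple, making equality and
    ordering well defined.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]

    @classmethod
    def of(cls, side: frozenset | set, taxa: frozenset | set) -> "Bipartition":
        other = set(taxa) - set(side)
        s1, s2 = sorted(side), sorted(other)
        if not s1 or not s2:
            raise ValueError("a bipartition needs two non-empty sides")
        if s2[0] < s1[0]:
            s1, s2 = s2, s1
        return cls(tuple(s1), tuple(s2))

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.side_a) | frozenset(self.side_b)

    @property
    def is_informative(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def restrict(self, taxa: set | frozenset) -> "Bipartition | None":
        """Restriction to a taxon subset; None when a side collapses
        below two taxa (uninformative on that subset)."""
        a = set(self.side_a) & taxa
        b = set(self.side_b) & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.of(a, a | b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """Split incompatibility on a shared taxon set: all four side
        intersections non-empty."""
        a1, b1 = set(self.side_a), set(self.side_b)
        a2, b2 = set(other.side_a), set(other.side_b)
        return bool(a1 & a2) and bool(a1 & b2) and bool(b1 & a2) and bool(b1 & b2)

    def __str__(self) -> str:
        return ",".join(self.side_a) + "|" + ",".join(self.side_b)


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per species-tree edge tallies over all gene trees."""

    node_id: str
    species_bipartition: Bipartition
    n_concordant: int
    n_top_alternative: int
    n_other_conflict: int
    n_uninformative: int
    top_alternative: Bipartition | None = None

    @property
    def total(self) -> int:
        return (
            self.n_concordant
            + self.n_top_alternative
            + self.n_other_conflict
            + self.n_uninformative
        )


def read_trees(source) -> list[dendropy.Tree]:
    """Read one or more Newick trees from a path or string.

    Each tree gets its own taxon namespace (gene trees legitimately
    sample different taxa). A duplicate leaf label within one tree is
    an error.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    trees = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            tree = dendropy.Tree.get(
                data=line,
                schema="newick",
                taxon_namespace=dendropy.TaxonNamespace(),
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeFileError(f"Newick parse error at tree {ln}: {exc}") from exc
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dups = {l for l in labels if labels.count(l) > 1}
        if dups:
            raise TreeFileError(
                f"tree {ln}: duplicate leaf label(s) {sorted(dups)}"
            )
        trees.append(tree)
    if not trees:
        raise TreeFileError("no trees found")
    return trees


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def informative_bipartitions(
    tree: dendropy.Tree, min_support: float | None = None
) -> set[Bipartition]:
    """All informative splits of the unrooted form of a tree.

    With ``min_support``, edges whose internal-node support label is
    below the threshold are treated as collapsed (their split dropped)
    before classification; unlabeled edges are kept.
    """
    taxa = leaf_labels(tree)
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if min_support is not None and node.label is not None:
            try:
                if float(node.label) < min_support:
                    continue
            except ValueError:
                pass
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(Bipartition.of(below, taxa))
    return out


def classify_gene_tree(
    species_bipartition: Bipartition,
    gene_tree: dendropy.Tree | set[Bipartition],
    gene_taxa: frozenset | None = None,
    min_support: float | None = None,
) -> tuple[str, Bipartition | None]:
    """Classify one gene tree against one species-tree split.

    Returns ("concordant", None), ("conflict", observed_split) or
    ("uninformative", None). ``gene_tree`` may be a parsed tree or a
    precomputed split set (then ``gene_taxa`` is required).
    """
    status, conflicting = classify_conflicting_set(
        species_bipartition, gene_tree, gene_taxa=gene_taxa, min_support=min_support
    )
    if status == "conflict":
        return "conflict", min(conflicting)
    return status, None


def classify_conflicting_set(
    species_bipartition: Bipartition,
    gene_tree: dendropy.Tree | set[Bipartition],
    gene_taxa: frozenset | None = None,
    min_support: float | None = None,
) -> tuple[str, set[Bipartition]]:
    """Like :func:`classify_gene_tree` but returning every conflicting
    restricted split the gene tree displays (empty unless the status is
    "conflict")."""
    if isinstance(gene_tree, set):
        if gene_taxa is None:
            raise ValueError("gene_taxa required with a precomputed split set")
        splits = gene_tree
    else:
        gene_taxa = leaf_labels(gene_tree)
        splits = informative_bipartitions(gene_tree, min_support=min_support)
    shared = set(gene_taxa) & set(species_bipartition.taxa)
    restricted = species_bipartition.restrict(shared)
    if restricted is None:
        return "uninformative", set()
    observed: set[Bipartition] = set()
    for s in splits:
        r = s.restrict(shared)
        if r is not None:
            observed.add(r)
    if restricted in observed:
        return "concordant", set()
    conflicting = {s for s in observed if restricted.conflicts_with(s)}
    if conflicting:
        return "conflict", conflicting
    return "uninformative", set()


def node_concordance(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    min_support: float | None = None,
) -> list[ConcordanceRecord]:
    """Tally concordance/conflict/uninformative counts at every
    informative species-tree split.

    A conflicting gene tree may display several splits incompatible
    with the species split; each contributes to the frequency table, and
    the top alternative is the split observed in the most gene trees
    (ties broken by canonical order). n_top_alternative counts the gene
    trees displaying that split; the remaining conflicting trees are
    n_other_conflict, so the four counts always sum to the number of
    gene trees and the tallies are invariant under consistent taxon
    relabelling.
    """
    gene_data = [
        (leaf_labels(t), informative_bipartitions(t, min_support=min_support))
        for t in gene_trees
    ]
    records = []
    for sp_bip in sorted(informative_bipartitions(species_tree)):
        n_conc = n_uninf = n_conflict = 0
        containment: dict[Bipartition, int] = {}
        for taxa, splits in gene_data:
            status, conflicting = classify_conflicting_set(
                sp_bip, splits, gene_taxa=taxa
            )
            if status == "concordant":
                n_conc += 1
            elif status == "uninformative":
                n_uninf += 1
            else:
                n_conflict += 1
                for s in conflicting:
                    containment[s] = containment.get(s, 0) + 1
        if containment:
            top = min(containment, key=lambda b: (-containment[b], b))
            n_top = containment[top]
            n_other = n_conflict - n_top
        else:
            top, n_top, n_other = None, 0, 0
        records.append(
            ConcordanceRecord(
                node_id=",".join(
                    sp_bip.side_a
                    if len(sp_bip.side_a) <= len(sp_bip.side_b)
                    else sp_bip.side_b
                ),
                species_bipartition=sp_bip,
                n_concordant=n_conc,
                n_top_alternative=n_top,
                n_other_conflict=n_other,
                n_uninformative=n_uninf,
                top_alternative=top,
            )
        )
    return records


def pie_fractions(record: ConcordanceRecord) -> tuple[float, float, float, float]:
    """Concordant / top-alternative / other-conflict / uninformative
    fractions of all gene trees at one node (Fig.-style pies)."""
    if record.total == 0:
        raise ValueError("no gene trees tallied at this node")
    t = record.total
    return (
        record.n_concordant / t,
        record.n_top_alternative / t,
        record.n_other_conflict / t,
        record.n_uninformative / t,
    )


def informative_fractions(record: ConcordanceRecord) -> tuple[float, float, float]:
    """The same three informative classes normalised by informative
    trees only (the other denominator concordance percentages are
    quoted with)."""
    n_inf = record.total - record.n_uninformative
    if n_inf == 0:
        raise ValueError("no informative gene trees at this node")
    return (
        record.n_concordant / n_inf,
        record.n_top_alternative / n_inf,
        record.n_other_conflict / n_inf,
    )


def records_to_tsv(records: list[ConcordanceRecord]) -> str:
    header = (
        "node_id\tn_concordant\tn_top_alternative\tn_other_conflict\t"
        "n_uninformative\tfrac_concordant\tfrac_top_alternative\t"
        "frac_other_conflict\tfrac_uninformative\ttop_alternative"
    )
    lines = [header]
    for r in records:
        fr = pie_fractions(r) if r.total else (0.0, 0.0, 0.0, 0.0)
        lines.append(
            f"{r.node_id}\t{r.n_concordant}\t{r.n_top_alternative}\t"
            f"{r.n_other_conflict}\t{r.n_uninformative}\t"
            + "\t".join(f"{x:.6g}" for x in fr)
            + "\t"
            + (str(r.top_alternative) if r.top_alternative else ".")
        )
    return "\n".join(lines) + "\n"
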