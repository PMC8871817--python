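"""Seeded generators for every input the toolkit consumes, with
planted ground truth.

The generators emulate the data shapes of a transcriptome-based panel
design study: a candidate locus set with an orthology classification
and exon/intron structures (with planted filter failures and
organelle-contaminated loci), per-sample capture recovery with a clade
structure, and gene trees drawn around a known species tree.

All randomness flows through :class:`numpy.random.Generator` seeded
with NumPy's PCG64 bit generator; draw order is fixed by the code
below, so a fixed seed gives byte-identical outputs across runs and
platforms. The defaults mirror the scale of the study the fixtures
emulate: 133 strictly single-copy candidates of which 8 fail the
structure rule and 5 match organelle references (leaving 120), a
36-sample capture panel split over five clades, and an eight-taxon
species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import dendropy

from .concordance import Bipartition, ConcordanceRecord
from .filters import LocusStructure
from .recovery import RecoveryMatrix
from .registry import LocusRegistry, TargetSequence

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# locus set


@dataclass
class LocusSimConfig:
    """Candidate locus set with planted filter failures."""

    n_strict: int = 133
    n_mostly: int = 1859
    n_mostly_in_registry: int = 5  # multi-copy loci that carry sequences
    n_structure_fail: int = 8
    n_organelle_like: int = 5
    n_taxa_range: tuple[int, int] = (4, 8)
    exon_count_range: tuple[int, int] = (1, 5)
    exon_len_range: tuple[int, int] = (140, 400)
    intron_len_range: tuple[int, int] = (100, 300)
    organelle_len: int = 2000
    organelle_insert_range: tuple[int, int] = (150, 300)

    def validate(self):
        if self.n_structure_fail + self.n_organelle_like > self.n_strict:
            raise ValueError("more planted failures than strict candidates")
        for name in (
            "n_taxa_range",
            "exon_count_range",
            "exon_len_range",
            "intron_len_range",
            "organelle_insert_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"degenerate range {name}={lo, hi}")


@dataclass
class LocusSimResult:
    registry: LocusRegistry
    structures: dict[str, LocusStructure]
    classification: list[tuple[str, str]]
    organelle: list[tuple[str, str]]  # (id, sequence) FASTA records
    ground_truth: dict[str, set[str]]


def _rand_range(rng, lo_hi) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def simulate_locus_set(
    config: LocusSimConfig = LocusSimConfig(), seed: int = 0
) -> LocusSimResult:
    """Generate a candidate locus set with recorded ground truth.

    Planted failures are disjoint: ``n_structure_fail`` strict loci
    violate the exon/intron rule (alternating all-short-exon and
    short-intron modes), ``n_organelle_like`` strict loci embed an
    exact organelle substring of at least 150 bp, and
    ``n_mostly_in_registry`` multi-copy loci carry sequences but are
    labelled mostly_single_copy. ``ground_truth`` lists exactly which
    loci each cascade stage should remove and the expected final set.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    strict_ids = [f"g{i + 1:04d}" for i in range(config.n_strict)]
    mostly_ids = [f"m{i + 1:04d}" for i in range(config.n_mostly)]
    classification = [(lid, "strictly_single_copy") for lid in strict_ids] + [
        (lid, "mostly_single_copy") for lid in mostly_ids
    ]

    planted = rng.choice(
        config.n_strict,
        size=config.n_structure_fail + config.n_organelle_like,
        replace=False,
    )
    structure_fail = {strict_ids[i] for i in planted[: config.n_structure_fail]}
    organelle_like = {strict_ids[i] for i in planted[config.n_structure_fail :]}

    organelle_seq = random_dna(rng, config.organelle_len)

    registry = LocusRegistry()
    structures: dict[str, LocusStructure] = {}
    mostly_in_registry = set(mostly_ids[: config.n_mostly_in_registry])

    fail_mode = 0
    for lid in strict_ids + sorted(mostly_in_registry):
        n_exons = _rand_range(rng, config.exon_count_range)
        if lid in structure_fail:
            fail_mode += 1
            if fail_mode % 2 == 1 or n_exons == 1:
                # no exon exceeds the strict >120 bp bound
                exons = tuple(_rand_range(rng, (40, 120)) for _ in range(n_exons))
                introns = tuple(
                    _rand_range(rng, config.intron_len_range)
                    for _ in range(n_exons - 1)
                )
            else:
                exons = tuple(
                    _rand_range(rng, config.exon_len_range) for _ in range(n_exons)
                )
                introns = list(
                    _rand_range(rng, config.intron_len_range)
                    for _ in range(n_exons - 1)
                )
                introns[int(rng.integers(0, len(introns)))] = _rand_range(rng, (30, 99))
                introns = tuple(introns)
        else:
            exons = tuple(
                _rand_range(rng, config.exon_len_range) for _ in range(n_exons)
            )
            introns = tuple(
                _rand_range(rng, config.intron_len_range) for _ in range(n_exons - 1)
            )
        structures[lid] = LocusStructure(lid, exons, introns)

        seq_len = sum(exons)
        n_taxa = _rand_range(rng, config.n_taxa_range)
        for t in range(n_taxa):
            seq = random_dna(rng, seq_len)
            if lid in organelle_like and t == 0:
                ins_len = min(_rand_range(rng, config.organelle_insert_range), seq_len)
                src = int(rng.integers(0, config.organelle_len - ins_len + 1))
                dst = int(rng.integers(0, seq_len - ins_len + 1))
                seq = (
                    seq[:dst]
                    + organelle_seq[src : src + ins_len]
                    + seq[dst + ins_len :]
                )
            registry.add(TargetSequence(lid, f"Taxon{t + 1:02d}", seq))

    expected_final = set(strict_ids) - structure_fail - organelle_like
    return LocusSimResult(
        registry=registry,
        structures=structures,
        classification=classification,
        organelle=[("chloroplast_ref", organelle_seq)],
        ground_truth={
            "strict": set(strict_ids),
            "structure_fail": structure_fail,
            "organelle_like": organelle_like,
            "mostly_in_registry": mostly_in_registry,
            "expected_final": expected_final,
        },
    )


# ---------------------------------------------------------------------------
# recovery


@dataclass(frozen=True)
class CladeSpec:
    name: str
    n_samples: int
    p_recover: float
    frac_range: tuple[float, float] = (0.3, 1.2)


DEFAULT_CLADES = (
    CladeSpec("Cactoideae", 17, 0.95),
    CladeSpec("Opuntioideae", 10, 0.92),
    CladeSpec("Outgroup", 5, 0.85),
    CladeSpec("Leuenbergeria_Pereskia", 3, 0.80),
    CladeSpec("Maihuenia", 1, 0.70),
)


@dataclass
class RecoverySimConfig:
    clades: tuple[CladeSpec, ...] = DEFAULT_CLADES
    reads_total_range: tuple[int, int] = (200_000, 2_000_000)
    on_target_range: tuple[float, float] = (0.0005, 0.03)
    p_paralog_warning: float = 0.007  # per recovered (sample, locus) cell

    def validate(self):
        for c in self.clades:
            if not 0.0 <= c.p_recover <= 1.0:
                raise ValueError(f"{c.name}: p_recover outside [0, 1]")
            if c.n_samples < 1:
                raise ValueError(f"{c.name}: need at least one sample")


@dataclass
class RecoverySimResult:
    matrix: RecoveryMatrix
    reads: dict[str, tuple[int, int]]
    clade_map: dict[str, str]
    paralog_warnings: list[tuple[str, str]]


def simulate_recovery(
    registry: LocusRegistry,
    config: RecoverySimConfig = RecoverySimConfig(),
    seed: int = 0,
) -> RecoverySimResult:
    """Per-sample capture outcomes over the registry's loci.

    Each sample recovers each locus independently with its clade's
    probability; the recovered length is the locus target length times
    a uniform draw from the clade's fraction range (values above 1
    model recovery running past a transcript-derived reference).
    """
    config.validate()
    if len(registry) == 0:
        raise ValueError("registry is empty")
    rng = np.random.default_rng(seed)
    loci = registry.locus_ids
    target_bp = np.array(
        [np.mean([s.length for s in registry.loci[l]]) for l in loci]
    )
    samples, clade_map, rows = [], {}, []
    reads: dict[str, tuple[int, int]] = {}
    warnings_rows: list[tuple[str, str]] = []
    for clade in config.clades:
        for k in range(clade.n_samples):
            sample = f"{clade.name}_s{k + 1:02d}"
            samples.append(sample)
            clade_map[sample] = clade.name
            hit = rng.random(len(loci)) < clade.p_recover
            frac = rng.uniform(*clade.frac_range, size=len(loci))
            row = np.where(hit, np.maximum(1, np.rint(frac * target_bp)), 0)
            rows.append(row.astype(int))
            total = int(rng.integers(*config.reads_total_range))
            mapped = int(round(total * rng.uniform(*config.on_target_range)))
            reads[sample] = (total, min(mapped, total))
            for j in np.flatnonzero(hit):
                if rng.random() < config.p_paralog_warning:
                    warnings_rows.append((sample, loci[j]))
    matrix = RecoveryMatrix(samples, loci, np.array(rows), target_bp)
    return RecoverySimResult(matrix, reads, clade_map, warnings_rows)


# ---------------------------------------------------------------------------
# gene trees


def _newick_to_tuple(newick: str):
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=dendropy.TaxonNamespace(),
        suppress_internal_node_taxa=True,
    )

    def convert(node):
        if node.is_leaf():
            return node.taxon.label
        return tuple(convert(c) for c in node.child_nodes())

    return convert(tree.seed_node)


def _tuple_leaves(topo) -> frozenset:
    if isinstance(topo, str):
        return frozenset([topo])
    out = set()
    for child in topo:
        out |= _tuple_leaves(child)
    return frozenset(out)


def _tuple_splits(topo) -> set[Bipartition]:
    """Informative splits of a nested-tuple topology (unrooted)."""
    taxa = _tuple_leaves(topo)
    out: set[Bipartition] = set()

    def walk(node):
        if isinstance(node, str):
            return
        below = _tuple_leaves(node)
        if 2 <= len(below) <= len(taxa) - 2:
            out.add(Bipartition.of(below, taxa))
        for child in node:
            walk(child)

    if not isinstance(topo, str):
        for child in topo:
            walk(child)
    return out


def _prune_tuple(topo, keep: set):
    if isinstance(topo, str):
        return topo if topo in keep else None
    kids = [k for k in (_prune_tuple(c, keep) for c in topo) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _tuple_to_newick(topo) -> str:
    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return render(topo) + ";"


DEFAULT_SPECIES_NEWICK = "((((A,B),(C,D)),(E,F)),(G,H));"
DEFAULT_ALTERNATIVES = (
    "((((A,C),(B,D)),(E,F)),(G,H));",
    "((((A,B),(E,F)),(C,D)),(G,H));",
)


@dataclass
class GeneTreeSimConfig:
    species_newick: str = DEFAULT_SPECIES_NEWICK
    alternative_newicks: tuple[str, ...] = DEFAULT_ALTERNATIVES
    alternative_weights: tuple[float, ...] = (0.6, 0.4)
    p_concordant: float = 0.7
    missing_taxon_rate: float | dict[str, float] = 0.1
    n_gene_trees: int = 200

    def validate(self):
        if not 0.0 <= self.p_concordant <= 1.0:
            raise ValueError("p_concordant outside [0, 1]")
        if len(self.alternative_weights) != len(self.alternative_newicks):
            raise ValueError("one weight per alternative topology required")
        if self.alternative_newicks and abs(sum(self.alternative_weights) - 1.0) > 1e-9:
            raise ValueError("alternative weights must sum to 1")


@dataclass
class GeneTreeSimResult:
    gene_tree_newicks: list[str]
    expected_records: list[ConcordanceRecord]
    realized_topology_counts: dict[int, int]  # -1 = concordant draw


def simulate_gene_trees(
    config: GeneTreeSimConfig = GeneTreeSimConfig(), seed: int = 0
) -> GeneTreeSimResult:
    """Draw gene trees around a species tree and record exact expected
    concordance tallies.

    Each gene tree takes the species topology with probability
    ``p_concordant``, otherwise one of the alternative topologies per
    the weights; each taxon is then dropped independently at the
    missing rate. Expected per-node records are computed from the
    REALIZED draws with the generator's own split arithmetic over the
    nested-tuple topologies, so concordance tests are exact rather than
    statistical.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    species = _newick_to_tuple(config.species_newick)
    taxa = sorted(_tuple_leaves(species))
    alternatives = [_newick_to_tuple(n) for n in config.alternative_newicks]
    if isinstance(config.missing_taxon_rate, dict):
        miss = {t: config.missing_taxon_rate.get(t, 0.0) for t in taxa}
    else:
        miss = {t: config.missing_taxon_rate for t in taxa}

    newicks: list[str] = []
    drawn: list[tuple[frozenset, set[Bipartition]]] = []
    topo_counts: dict[int, int] = {}
    for _ in range(config.n_gene_trees):
        if alternatives and rng.random() >= config.p_concordant:
            idx = int(
                rng.choice(len(alternatives), p=np.array(config.alternative_weights))
            )
            topo = alternatives[idx]
        else:
            idx = -1
            topo = species
        topo_counts[idx] = topo_counts.get(idx, 0) + 1
        keep = {t for t in taxa if rng.random() >= miss[t]}
        pruned = _prune_tuple(topo, keep)
        if pruned is None or isinstance(pruned, str):
            # a tree needs at least two leaves to be written; keep the
            # draw but emit a minimal star over the kept taxa
            keep = keep or {taxa[0], taxa[1]}
            pruned = tuple(sorted(keep)) if len(keep) > 1 else (taxa[0], taxa[1])
        newicks.append(_tuple_to_newick(pruned))
        drawn.append((_tuple_leaves(pruned), _tuple_splits(pruned)))

    expected = []
    for sp_bip in sorted(_tuple_splits(species)):
        n_conc = n_uninf = n_conflict = 0
        containment: dict[Bipartition, int] = {}
        for gene_taxa, gene_splits in drawn:
            shared = set(gene_taxa) & set(sp_bip.taxa)
            restricted = sp_bip.restrict(shared)
            if restricted is None:
                n_uninf += 1
                continue
            observed = {
                r for r in (s.restrict(shared) for s in gene_splits) if r is not None
            }
            if restricted in observed:
                n_conc += 1
                continue
            conflicting = {s for s in observed if restricted.conflicts_with(s)}
            if conflicting:
                n_conflict += 1
                for s in conflicting:
                    containment[s] = containment.get(s, 0) + 1
            else:
                n_uninf += 1
        if containment:
            top = min(containment, key=lambda b: (-containment[b], b))
            n_top = containment[top]
            n_other = n_conflict - n_top
        else:
            top, n_top, n_other = None, 0, 0
        expected.append(
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
    return GeneTreeSimResult(newicks, expected, topo_counts)


# ---------------------------------------------------------------------------
# aggregate


@dataclass
class SimulationConfig:
    """One seed, one config per generator."""

    seed: int = 0
    locus: LocusSimConfig = field(default_factory=LocusSimConfig)
    recovery: RecoverySimConfig = field(default_factory=RecoverySimConfig)
    gene_trees: GeneTreeSimConfig = field(default_factory=GeneTreeSimConfig)
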