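"""Locus-selection cascade for building a single-copy target panel.

The cascade mirrors the way capture panels are assembled from
transcriptome-derived candidate sets:

1. keep only loci classified strictly single-copy by the orthology
   screen (MarkerMiner-style classification table);
2. keep loci whose gene structure supports capture: at least one exon
   strictly longer than 120 bp, and every annotated intron at least
   100 bp;
3. discard loci with strong local-alignment similarity to non-target
   references (organelle genomes, other panels);
4. collapse near-identical loci across panels to one representative.

A gap-threshold alignment-column trimmer (the usual 10 %-gap cleaning
rule applied to per-locus alignments before tree inference) lives here
too.

Similarity screens use the toolkit's Smith-Waterman convention
(:mod:`hybcap._align`): nucleotide-level, both strands, identity counted
over alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _align
from .registry import LocusRegistry, TargetSequence, registry_from_sequences

CATEGORIES = {"strictly_single_copy", "mostly_single_copy", "other"}


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the locus-selection cascade.

    ``min_exon_bp_exclusive`` is a strict lower bound (an exon of
    exactly 120 bp fails); ``min_intron_bp`` is inclusive. Screen and
    dedup identities are fractions over alignment columns.
    """

    min_exon_bp_exclusive: int = 120
    min_intron_bp: int = 100
    screen_min_identity: float = 0.70
    screen_min_hit_bp: int = 100
    dedup_min_identity: float = 0.99
    dedup_min_overlap_bp: int = 100
    max_gap_fraction: float = 0.10

    def __post_init__(self):
        for name in ("screen_min_identity", "dedup_min_identity", "max_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "min_exon_bp_exclusive",
            "min_intron_bp",
            "screen_min_hit_bp",
            "dedup_min_overlap_bp",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class LocusStructure:
    """Exon/intron lengths of one locus, in gene order."""

    locus_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...] = ()

    def __post_init__(self):
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"non-positive length in {self.locus_id}")
        if self.intron_lengths and self.exon_lengths:
            if len(self.intron_lengths) != len(self.exon_lengths) - 1:
                raise ValueError(
                    f"{self.locus_id}: {len(self.intron_lengths)} introns "
                    f"inconsistent with {len(self.exon_lengths)} exons"
                )


@dataclass(frozen=True)
class ScreenHit:
    """One qualifying local alignment between a target locus sequence
    and a non-target reference."""

    query_locus_id: str
    reference_id: str
    alignment_identity: float
    alignment_length_bp: int
    strand: str
    query_start: int
    query_end: int


def read_classification(path) -> list[tuple[str, str]]:
    """Read a 2-column (locus_id, category) TSV; header row optional."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 2 columns, got {len(parts)}")
            if ln == 1 and parts[1] not in CATEGORIES and parts[0].lower() in {
                "locus_id",
                "locus",
            }:
                continue
            rows.append((parts[0], parts[1]))
    seen = set()
    for locus, _ in rows:
        if locus in seen:
            raise ValueError(f"duplicate locus_id {locus!r} in classification")
        seen.add(locus)
    return rows


def select_strictly_single_copy(table: list[tuple[str, str]]) -> set[str]:
    """Ids labelled strictly_single_copy; unknown labels are an error."""
    out = set()
    for locus, category in table:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r} for locus {locus!r}"
            )
        if category == "strictly_single_copy":
            out.add(locus)
    return out


def passes_structure_filter(
    structure: LocusStructure, params: FilterParams = FilterParams()
) -> tuple[bool, str]:
    """Exon/intron suitability rule.

    Passes iff max exon length is strictly greater than
    ``min_exon_bp_exclusive`` AND every annotated intron is at least
    ``min_intron_bp`` (a locus with no introns passes the intron clause
    vacuously). Returns (ok, reason); reason names the first failing
    rule.
    """
    if not structure.exon_lengths or max(structure.exon_lengths) <= params.min_exon_bp_exclusive:
        return False, f"no exon >{params.min_exon_bp_exclusive} bp"
    short = [x for x in structure.intron_lengths if x < params.min_intron_bp]
    if short:
        return False, f"intron <{params.min_intron_bp} bp"
    return True, "ok"


def screen_nontarget(
    loci: LocusRegistry,
    references: LocusRegistry | list[tuple[str, str]],
    params: FilterParams = FilterParams(),
) -> list[ScreenHit]:
    """Flag target sequences similar to non-target references.

    For every (locus sequence, reference) pair the best local alignment
    over both strands is computed exhaustively; a hit is recorded when
    it reaches ``screen_min_identity`` over ``screen_min_hit_bp``
    columns. Output is sorted by (query header, reference id,
    query_start). No heuristic prefilter is applied here: at a 70 %
    identity threshold a k-mer filter would not be lossless.
    """
    refs = _as_pairs(references)
    if not refs:
        raise ValueError("references must be non-empty")
    hits = []
    for seq in loci:
        for ref_id, ref_seq in refs:
            aln = _align.sw_align_both_strands(seq.residues, ref_seq)
            if _align.meets_similarity(
                aln, params.screen_min_identity, params.screen_min_hit_bp
            ):
                hits.append(
                    ScreenHit(
                        query_locus_id=seq.locus_id,
                        reference_id=ref_id,
                        alignment_identity=aln.identity,
                        alignment_length_bp=aln.n_columns,
                        strand=aln.strand,
                        query_start=aln.query_start,
                        query_end=aln.query_end,
                    )
                )
    hits.sort(key=lambda h: (h.query_locus_id, h.reference_id, h.query_start))
    return hits


def flagged_loci(hits: list[ScreenHit]) -> set[str]:
    """Locus ids with at least one screen hit."""
    return {h.query_locus_id for h in hits}


def _as_pairs(references) -> list[tuple[str, str]]:
    if isinstance(references, LocusRegistry):
        return [(s.header, s.residues) for s in references]
    return list(references)


@dataclass
class RemovalReport:
    """Duplicate-collapse bookkeeping: removed locus -> retained
    representative."""

    removed: dict[str, str] = field(default_factory=dict)


def deduplicate_loci(
    a: LocusRegistry,
    b: LocusRegistry | None = None,
    params: FilterParams = FilterParams(),
    use_prefilter: bool = True,
) -> tuple[LocusRegistry, RemovalReport]:
    """Collapse near-identical loci within the union of two panels.

    Two loci are duplicates when any pair of their reference sequences
    has a best local alignment with identity >= ``dedup_min_identity``
    over >= ``dedup_min_overlap_bp`` columns (either strand). Collapse
    acts on the transitive closure of duplicate pairs; the retained
    representative is the locus from panel ``a`` if possible, breaking
    ties by lexicographically smallest locus id.

    The 12-mer prefilter is lossless at the default thresholds (a
    qualifying alignment necessarily contains a long exact match run)
    and only skips alignments that provably cannot qualify.
    """
    entries: list[tuple[int, str, TargetSequence]] = []
    for panel_rank, reg in enumerate(r for r in (a, b) if r is not None):
        for seq in reg:
            entries.append((panel_rank, seq.locus_id, seq))

    # union-find over locus keys (panel_rank, locus_id)
    keys = sorted({(rank, lid) for rank, lid, _ in entries})
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            # smaller key (panel first, then id) becomes the root
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    if use_prefilter:
        candidates = sorted(
            _align.kmer_candidate_pairs([e[2].residues for e in entries])
        )
    else:
        candidates = [
            (i, j) for i in range(len(entries)) for j in range(i + 1, len(entries))
        ]
    for i, j in candidates:
        rank_i, lid_i, si = entries[i]
        rank_j, lid_j, sj = entries[j]
        if (rank_i, lid_i) == (rank_j, lid_j):
            continue
        if find((rank_i, lid_i)) == find((rank_j, lid_j)):
            continue
        aln = _align.sw_align_both_strands(si.residues, sj.residues)
        if _align.meets_similarity(
            aln, params.dedup_min_identity, params.dedup_min_overlap_bp
        ):
            union((rank_i, lid_i), (rank_j, lid_j))

    report = RemovalReport()
    kept: list[TargetSequence] = []
    for rank, lid, seq in entries:
        root = find((rank, lid))
        if root == (rank, lid):
            kept.append(seq)
        else:
            report.removed[lid] = root[1]
    # preserve original order, one entry per retained (taxon, locus)
    out = LocusRegistry()
    seen = set()
    for seq in kept:
        key = (seq.taxon_id, seq.locus_id)
        if key not in seen:
            seen.add(key)
            out.add(seq)
    return out, report


def trim_alignment_columns(
    alignment: list[str], params: FilterParams = FilterParams()
) -> list[str]:
    """Keep exactly the columns whose gap ('-') fraction is <=
    ``max_gap_fraction``; row order and count unchanged. Idempotent."""
    if not alignment:
        return []
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment: rows differ in length")
    n = len(alignment)
    keep = [
        c
        for c in range(width)
        if sum(row[c] == "-" for row in alignment) / n <= params.max_gap_fraction
    ]
    return ["".join(row[c] for c in keep) for row in alignment]


def apply_cascade(
    registry: LocusRegistry,
    classification: list[tuple[str, str]],
    structures: dict[str, LocusStructure],
    nontarget_refs,
    params: FilterParams = FilterParams(),
) -> tuple[LocusRegistry, dict[str, set[str] | dict[str, str]]]:
    """Run the full selection cascade and report removals per stage.

    Stages: strictly-single-copy selection, exon/intron structure rule,
    non-target similarity screen, duplicate collapse. Returns the
    retained registry and a per-stage removal report.
    """
    strict = select_strictly_single_copy(classification)
    not_strict = set(registry.loci) - strict

    stage1 = registry_from_sequences(
        s for s in registry if s.locus_id in strict
    )
    structure_fail = {
        lid
        for lid in stage1.loci
        if lid in structures
        and not passes_structure_filter(structures[lid], params)[0]
    }
    stage2 = registry_from_sequences(
        s for s in stage1 if s.locus_id not in structure_fail
    )
    hits = screen_nontarget(stage2, nontarget_refs, params)
    screened = flagged_loci(hits)
    stage3 = registry_from_sequences(
        s for s in stage2 if s.locus_id not in screened
    )
    final, dedup_report = deduplicate_loci(stage3, None, params)
    report = {
        "not_strictly_single_copy": not_strict,
        "structure_fail": structure_fail,
        "screen_fail": screened,
        "dedup_removed": dedup_report.removed,
    }
    return final, report
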