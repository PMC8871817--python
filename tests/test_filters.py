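"""Locus-selection cascade: classification, structure rule, similarity
screens, duplicate collapse, and alignment-column trimming."""

import numpy as np
import pytest

from conftest import random_dna
from hybcap import filters
from hybcap.filters import (
    FilterParams,
    LocusStructure,
    deduplicate_loci,
    flagged_loci,
    passes_structure_filter,
    screen_nontarget,
    select_strictly_single_copy,
    trim_alignment_columns,
)
from hybcap.registry import TargetSequence, registry_from_sequences
from hybcap.simulate import LocusSimConfig, simulate_locus_set


class TestSingleCopySelection:
    def test_label_filter(self):
        table = [
            ("g1", "strictly_single_copy"),
            ("g2", "mostly_single_copy"),
            ("g3", "strictly_single_copy"),
        ]
        assert select_strictly_single_copy(table) == {"g1", "g3"}

    def test_empty_table(self):
        assert select_strictly_single_copy([]) == set()

    def test_candidate_scale_counts(self):
        """Counts at the scale orthology screens typically return:
        1859 mostly + 133 strictly single-copy candidates."""
        table = [(f"m{i}", "mostly_single_copy") for i in range(1859)] + [
            (f"g{i}", "strictly_single_copy") for i in range(133)
        ]
        assert len(select_strictly_single_copy(table)) == 133

    def test_unknown_category_names_row(self):
        with pytest.raises(ValueError, match="g2"):
            select_strictly_single_copy([("g1", "strictly_single_copy"), ("g2", "weird")])


class TestStructureFilter:
    @pytest.mark.parametrize(
        "exons,introns,expect_pass,reason_part",
        [
            ((150, 80), (120,), True, "ok"),
            ((120,), (), False, "no exon >120"),
            ((500, 200), (50,), False, "intron <100"),
            ((121,), (), True, "ok"),  # strict > boundary
            ((500,), (), True, "ok"),  # no introns: clause vacuous
            ((500, 300, 200), (100, 100), True, "ok"),  # >= boundary
        ],
    )
    def test_rules(self, exons, introns, expect_pass, reason_part):
        ok, reason = passes_structure_filter(LocusStructure("g", exons, introns))
        assert ok is expect_pass
        assert reason_part in reason

    def test_inconsistent_intron_count_rejected(self):
        with pytest.raises(ValueError, match="introns"):
            LocusStructure("g", (150, 150), (100, 100))


class TestScreen:
    def test_exact_substring_flagged(self, rng):
        ref = random_dna(rng, 600)
        query = random_dna(rng, 100) + ref[200:350] + random_dna(rng, 100)
        reg = registry_from_sequences([TargetSequence("g1", "T1", query)])
        hits = screen_nontarget(reg, [("chloro", ref)])
        assert flagged_loci(hits) == {"g1"}
        assert hits[0].alignment_identity == 1.0
        assert hits[0].alignment_length_bp >= 150
        assert hits[0].strand == "+"

    def test_revcomp_block_flagged_minus_strand(self, rng):
        from hybcap._align import revcomp

        ref = random_dna(rng, 400)
        query = random_dna(rng, 80) + revcomp(ref[100:250]) + random_dna(rng, 80)
        reg = registry_from_sequences([TargetSequence("g1", "T1", query)])
        hits = screen_nontarget(reg, [("chloro", ref)])
        assert flagged_loci(hits) == {"g1"}
        assert hits[0].strand == "-"

    def test_random_query_not_flagged(self, rng):
        """Unrelated random sequences stay below the 70%/100 bp bar
        (confirmed against the exhaustive oracle in the fuzz suite)."""
        reg = registry_from_sequences(
            [TargetSequence("g1", "T1", random_dna(rng, 500))]
        )
        hits = screen_nontarget(reg, [("chloro", random_dna(rng, 500))])
        assert hits == []

    def test_empty_references_rejected(self, small_registry):
        with pytest.raises(ValueError, match="non-empty"):
            screen_nontarget(small_registry, [])

    def test_deterministic_ordering(self, rng):
        block = random_dna(rng, 200)
        reg = registry_from_sequences(
            [
                TargetSequence("g2", "T1", block),
                TargetSequence("g1", "T1", block),
            ]
        )
        hits = screen_nontarget(reg, [("r2", block), ("r1", block)])
        keys = [(h.query_locus_id, h.reference_id) for h in hits]
        assert keys == sorted(keys)


class TestDedup:
    def test_identical_locus_in_both_panels(self, rng):
        seq = random_dna(rng, 300)
        a = registry_from_sequences([TargetSequence("g1", "T1", seq)])
        b = registry_from_sequences([TargetSequence("x9", "T2", seq)])
        kept, report = deduplicate_loci(a, b)
        assert set(kept.loci) == {"g1"}  # panel a representative wins
        assert report.removed == {"x9": "g1"}

    def test_95pct_identity_both_kept(self, rng):
        seq = list(random_dna(rng, 200))
        mutated = seq.copy()
        for pos in np.linspace(5, 195, 10, dtype=int):
            mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
        a = registry_from_sequences([TargetSequence("g1", "T1", "".join(seq))])
        b = registry_from_sequences([TargetSequence("g2", "T1", "".join(mutated))])
        kept, report = deduplicate_loci(a, b)
        assert set(kept.loci) == {"g1", "g2"}
        assert report.removed == {}

    def test_three_mutually_identical(self, rng):
        seq = random_dna(rng, 250)
        a = registry_from_sequences(
            [
                TargetSequence("g3", "T1", seq),
                TargetSequence("g1", "T1", seq),
                TargetSequence("g2", "T1", seq),
            ]
        )
        kept, report = deduplicate_loci(a)
        assert set(kept.loci) == {"g1"}  # lexicographically smallest id
        assert report.removed == {"g2": "g1", "g3": "g1"}

    def test_output_has_no_duplicate_pair(self, rng):
        """Re-screening the deduplicated panel finds no qualifying pair."""
        from hybcap._align import meets_similarity, sw_align_both_strands

        base = random_dna(rng, 300)
        seqs = [base, base, random_dna(rng, 300), random_dna(rng, 280)]
        a = registry_from_sequences(
            [TargetSequence(f"g{i}", "T1", s) for i, s in enumerate(seqs)]
        )
        kept, _ = deduplicate_loci(a)
        params = FilterParams()
        remaining = list(kept)
        for i in range(len(remaining)):
            for j in range(i + 1, len(remaining)):
                aln = sw_align_both_strands(
                    remaining[i].residues, remaining[j].residues
                )
                assert not meets_similarity(
                    aln, params.dedup_min_identity, params.dedup_min_overlap_bp
                )

    def test_prefilter_matches_exhaustive(self, rng):
        """With and without the k-mer prefilter the result is identical."""
        seq = random_dna(rng, 200)
        seqs = [seq, seq, random_dna(rng, 200), random_dna(rng, 150)]
        a = registry_from_sequences(
            [TargetSequence(f"g{i}", "T1", s) for i, s in enumerate(seqs)]
        )
        kept1, rep1 = deduplicate_loci(a, use_prefilter=True)
        kept2, rep2 = deduplicate_loci(a, use_prefilter=False)
        assert kept1 == kept2
        assert rep1.removed == rep2.removed


class TestTrimColumns:
    def test_column_over_threshold_removed(self):
        rows = ["A-" for _ in range(8)] + ["AA", "AA"]  # col 1: 80% gaps
        out = trim_alignment_columns(rows)
        assert out == ["A"] * 10

    def test_boundary_10pct_kept(self):
        rows = ["AA"] * 9 + ["A-"]  # col 1: exactly 10% gaps
        assert trim_alignment_columns(rows) == rows

    def test_gap_free_identity(self):
        rows = ["ACGT", "AGGT", "ACCT"]
        assert trim_alignment_columns(rows) == rows

    def test_idempotent_and_criteria_satisfied(self, rng):
        n_rows, n_cols = 12, 40
        rows = []
        for _ in range(n_rows):
            row = list(random_dna(rng, n_cols))
            for c in range(n_cols):
                if rng.random() < 0.15:
                    row[c] = "-"
            rows.append("".join(row))
        once = trim_alignment_columns(rows)
        assert trim_alignment_columns(once) == once
        for c in range(len(once[0]) if once else 0):
            gaps = sum(row[c] == "-" for row in once)
            assert gaps / n_rows <= 0.10

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_alignment_columns(["ACGT", "ACG"])


class TestCascade:
    def test_planted_failures_removed_exactly(self):
        """At reduced scale the cascade removes exactly the planted loci."""
        config = LocusSimConfig(
            n_strict=20,
            n_mostly=10,
            n_mostly_in_registry=2,
            n_structure_fail=2,
            n_organelle_like=2,
            n_taxa_range=(1, 2),
            organelle_len=800,
        )
        res = simulate_locus_set(config, seed=5)
        final, report = filters.apply_cascade(
            res.registry, res.classification, res.structures, res.organelle
        )
        gt = res.ground_truth
        assert report["structure_fail"] == gt["structure_fail"]
        assert report["screen_fail"] == gt["organelle_like"]
        assert set(final.loci) == gt["expected_final"]
        assert len(final.loci) == 16

    def test_no_planted_failures_removes_nothing(self):
        config = LocusSimConfig(
            n_strict=10,
            n_mostly=5,
            n_mostly_in_registry=0,
            n_structure_fail=0,
            n_organelle_like=0,
            n_taxa_range=(1, 2),
            organelle_len=600,
        )
        res = simulate_locus_set(config, seed=3)
        final, _ = filters.apply_cascade(
            res.registry, res.classification, res.structures, res.organelle
        )
        assert set(final.loci) == set(res.registry.loci)
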