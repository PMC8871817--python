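"""Capture-recovery statistics from per-sample, per-locus recovered
lengths (the HybPiper ``seq_lengths``/``stats`` layout).

The central object is a samples x loci matrix of recovered sequence
lengths (bp; 0 = no hit) together with per-locus target lengths used as
denominators. From it the module derives the descriptive statistics a
capture experiment is judged by: per-sample locus counts at >=25/50/75 %
of target length, on-target read percentages, the length-proportion
matrix behind recovery heatmaps, per-clade locus recovery and pairwise
clade overlap tables, and paralog-warning tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import LocusRegistry

TARGET_ROW_LABELS = {"meanlength", "targetlength", "target_length", "mean_length"}
OVER_RECOVERY_CAP = 1.5


@dataclass
class RecoveryMatrix:
    """Recovered bp per (sample, locus) plus per-locus target lengths."""

    samples: list[str]
    loci: list[str]
    recovered_bp: np.ndarray  # int, samples x loci
    target_bp: np.ndarray  # float, per locus

    def __post_init__(self):
        self.recovered_bp = np.asarray(self.recovered_bp)
        self.target_bp = np.asarray(self.target_bp, dtype=float)
        if self.recovered_bp.shape != (len(self.samples), len(self.loci)):
            raise ValueError("matrix shape inconsistent with sample/locus lists")
        if self.target_bp.shape != (len(self.loci),):
            raise ValueError("target_bp length inconsistent with locus list")
        if (self.recovered_bp < 0).any():
            raise ValueError("negative recovered length")
        if (self.target_bp <= 0).any():
            raise ValueError("target_bp must be positive for every locus")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.recovered_bp, index=self.samples, columns=self.loci)


@dataclass(frozen=True)
class SampleStats:
    sample_id: str
    pct_on_target: float
    genes_with_contigs: int
    genes_with_seqs: int
    n_ge_25: int
    n_ge_50: int
    n_ge_75: int


def target_lengths_from_registry(
    registry: LocusRegistry, how: str = "mean"
) -> dict[str, float]:
    """Per-locus target length: mean (HybPiper's convention) or max of
    the locus's reference sequence lengths."""
    if how not in {"mean", "max"}:
        raise ValueError(f"unknown aggregation {how!r}")
    agg = np.mean if how == "mean" else np.max
    return {
        lid: float(agg([s.length for s in bucket]))
        for lid, bucket in registry.loci.items()
    }


def read_seq_lengths(path, target_lengths: dict[str, float] | None = None) -> RecoveryMatrix:
    """Read a seq_lengths TSV.

    Layout: first row = label + locus ids; if the second row's first
    field is a target-length label (MeanLength/TargetLength) it supplies
    the denominators (dialect A), otherwise ``target_lengths`` must be
    given (dialect B). Remaining rows: sample id + integer recovered
    lengths. Blank cells become 0 with a warning; non-numeric cells are
    an error naming the offending row and column.
    """
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty seq_lengths file")
    loci = rows[0][1:]
    body = rows[1:]
    targets = None
    if body and body[0][0].strip().lower() in TARGET_ROW_LABELS:
        targets = [float(x) for x in body[0][1:]]
        body = body[1:]
    elif target_lengths is not None:
        missing = [l for l in loci if l not in target_lengths]
        if missing:
            raise ValueError(f"no target length for loci {missing}")
        targets = [target_lengths[l] for l in loci]
    else:
        raise ValueError(
            f"{path}: no target-length row and no target_lengths provided"
        )
    samples, data = [], []
    for row in body:
        sample = row[0]
        if len(row) != len(loci) + 1:
            raise ValueError(
                f"sample {sample!r}: expected {len(loci) + 1} columns, got {len(row)}"
            )
        vals = []
        for j, cell in enumerate(row[1:]):
            if cell.strip() == "":
                warnings.warn(
                    f"blank cell at sample {sample!r}, locus {loci[j]!r}; using 0",
                    stacklevel=2,
                )
                vals.append(0)
                continue
            try:
                vals.append(int(float(cell)))
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell {cell!r} at sample {sample!r}, "
                    f"locus {loci[j]!r}"
                ) from exc
        samples.append(sample)
        data.append(vals)
    return RecoveryMatrix(samples, loci, np.array(data, dtype=int), np.array(targets))


def write_seq_lengths(matrix: RecoveryMatrix, path) -> None:
    """Write the dialect-A layout (target lengths as a MeanLength row)."""
    with open(path, "w") as fh:
        fh.write("Species\t" + "\t".join(matrix.loci) + "\n")
        fh.write(
            "MeanLength\t" + "\t".join(f"{t:g}" for t in matrix.target_bp) + "\n"
        )
        for i, sample in enumerate(matrix.samples):
            fh.write(
                sample + "\t" + "\t".join(str(v) for v in matrix.recovered_bp[i]) + "\n"
            )


def read_read_counts(path) -> dict[str, tuple[int, int]]:
    """Read a (sample, reads_total, reads_mapped) TSV; header optional."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0].lower() in {"sample", "sample_id"}:
                continue
            if len(parts) != 3:
                raise ValueError(f"line {ln}: expected 3 columns")
            total, mapped = int(parts[1]), int(parts[2])
            if mapped > total:
                raise ValueError(f"{parts[0]}: reads_mapped > reads_total")
            out[parts[0]] = (total, mapped)
    return out


def sample_stats(
    matrix: RecoveryMatrix,
    reads: dict[str, tuple[int, int]],
    contig_flags: np.ndarray | None = None,
) -> list[SampleStats]:
    """Per-sample descriptive statistics.

    genes_with_seqs counts loci with any recovered sequence;
    genes_with_contigs comes from ``contig_flags`` when the assembler's
    contig table is available and otherwise equals genes_with_seqs (the
    two collapse without assembler internals). Thresholds are inclusive:
    a locus recovered at exactly 25 % of target length counts in
    n_ge_25.
    """
    missing = [s for s in matrix.samples if s not in reads]
    if missing:
        raise ValueError(f"read counts missing for samples {missing}")
    frac = matrix.recovered_bp / matrix.target_bp[None, :]
    out = []
    for i, sample in enumerate(matrix.samples):
        total, mapped = reads[sample]
        if total == 0:
            warnings.warn(f"{sample}: zero total reads", stacklevel=2)
            pct = 0.0
        else:
            pct = 100.0 * mapped / total
        with_seqs = int((matrix.recovered_bp[i] > 0).sum())
        with_contigs = (
            int(contig_flags[i].sum()) if contig_flags is not None else with_seqs
        )
        out.append(
            SampleStats(
                sample_id=sample,
                pct_on_target=pct,
                genes_with_contigs=with_contigs,
                genes_with_seqs=with_seqs,
                n_ge_25=int((frac[i] >= 0.25).sum()),
                n_ge_50=int((frac[i] >= 0.50).sum()),
                n_ge_75=int((frac[i] >= 0.75).sum()),
            )
        )
    return out


def stats_frame(stats: list[SampleStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats]).set_index("sample_id")


def length_proportion_matrix(
    matrix: RecoveryMatrix, cap: float = OVER_RECOVERY_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Recovered/target length ratios for heatmap display.

    Ratios above ``cap`` (recovery longer than the reference, common
    with transcript-derived targets) are capped and flagged; exact
    zeros are preserved as the no-hit class. Returns (proportions,
    over_recovery_flags).
    """
    frac = matrix.recovered_bp / matrix.target_bp[None, :]
    over = frac > cap
    return np.minimum(frac, cap), over


def no_hit_fraction(matrix: RecoveryMatrix) -> float:
    """Percentage of (sample, locus) cells with no recovered sequence."""
    return 100.0 * float((matrix.recovered_bp == 0).sum()) / matrix.recovered_bp.size


def read_clade_map(path) -> dict[str, str]:
    """Read a (sample, clade) TSV; header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0].lower() in {"sample", "sample_id"}:
                continue
            if len(parts) != 2:
                raise ValueError(f"clade map row {parts!r}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def clade_recovery(
    matrix: RecoveryMatrix, clades: dict[str, str]
) -> dict[str, set[str]]:
    """Loci recovered per clade: a locus counts for a clade when at
    least one of the clade's samples recovered it."""
    unlabelled = [s for s in matrix.samples if s not in clades]
    if unlabelled:
        raise ValueError(f"samples without clade label: {unlabelled}")
    out: dict[str, set[str]] = {}
    for i, sample in enumerate(matrix.samples):
        got = {matrix.loci[j] for j in np.flatnonzero(matrix.recovered_bp[i] > 0)}
        out.setdefault(clades[sample], set()).update(got)
    for clade in set(clades[s] for s in matrix.samples):
        out.setdefault(clade, set())
    return out


def overlap_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Symmetric clade x clade table: diagonal = loci recovered per
    clade, off-diagonal = loci shared between clades."""
    labels = list(sets)
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            m[i, j] = len(sets[a] & sets[b]) if i != j else len(sets[a])
    return pd.DataFrame(m, index=labels, columns=labels)


def read_paralog_warnings(path) -> list[tuple[str, str]]:
    """Read a (sample_id, locus_id) warnings TSV; header optional."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not line.strip() or parts[0].lower() in {"sample", "sample_id"}:
                continue
            if len(parts) != 2:
                raise ValueError(f"warnings row {parts!r}: expected 2 columns")
            rows.append((parts[0], parts[1]))
    return rows


@dataclass(frozen=True)
class ParalogSummary:
    total: int
    n_samples_with_warnings: int
    per_sample: dict[str, int]
    per_clade: dict[str, int]


def paralog_summary(
    warnings_rows: list[tuple[str, str]], clades: dict[str, str]
) -> ParalogSummary:
    """Tally paralog warnings by sample and clade."""
    per_sample: dict[str, int] = {}
    per_clade: dict[str, int] = {}
    for sample, _locus in warnings_rows:
        per_sample[sample] = per_sample.get(sample, 0) + 1
        clade = clades.get(sample, "unknown")
        per_clade[clade] = per_clade.get(clade, 0) + 1
    return ParalogSummary(
        total=len(warnings_rows),
        n_samples_with_warnings=len(per_sample),
        per_sample=per_sample,
        per_clade=per_clade,
    )
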