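"""Target-reference FASTA handling for hybridization-capture panels.

A target file holds one or more reference sequences per locus, with
headers encoding ``taxon<sep>locus`` (the convention used by HybPiper
target files). Because taxon names routinely contain the separator
(e.g. ``Ariocarpus-retusus-g7``), the split is on the LAST separator.

All coordinates in the toolkit are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
_VALID = set("ACGTU") | IUPAC_AMBIGUITY


class TargetFileError(ValueError):
    """Malformed target-reference file content."""


@dataclass(frozen=True)
class TargetSequence:
    """One taxon's reference copy of one locus."""

    locus_id: str
    taxon_id: str
    residues: str

    def __post_init__(self):
        if not self.locus_id or not self.taxon_id:
            raise ValueError("locus_id and taxon_id must be non-empty")
        if not self.residues:
            raise ValueError(
                f"empty sequence for {self.taxon_id}/{self.locus_id}"
            )
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise TargetFileError(
                f"non-IUPAC characters {sorted(bad)} in "
                f"{self.taxon_id}/{self.locus_id}"
            )
        amb = set(self.residues.upper()) & (IUPAC_AMBIGUITY - {"N"})
        if amb:
            warnings.warn(
                f"ambiguity codes {sorted(amb)} in "
                f"{self.taxon_id}/{self.locus_id}",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def header(self) -> str:
        return f"{self.taxon_id}-{self.locus_id}"


@dataclass
class LocusRegistry:
    """Ordered mapping locus_id -> list of TargetSequence.

    Within a locus, sequence order follows the source file; the
    (taxon_id, locus_id) pair is unique across the registry.
    """

    loci: dict[str, list[TargetSequence]] = field(default_factory=dict)

    def add(self, seq: TargetSequence) -> None:
        bucket = self.loci.setdefault(seq.locus_id, [])
        if any(s.taxon_id == seq.taxon_id for s in bucket):
            raise TargetFileError(
                f"duplicate (taxon, locus) pair: "
                f"({seq.taxon_id}, {seq.locus_id})"
            )
        bucket.append(seq)

    def __iter__(self) -> Iterator[TargetSequence]:
        for bucket in self.loci.values():
            yield from bucket

    def __len__(self) -> int:
        return sum(len(b) for b in self.loci.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, LocusRegistry):
            return NotImplemented
        return list(self.loci.items()) == list(other.loci.items())

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci)

    def sequences_for(self, locus_id: str) -> list[TargetSequence]:
        return list(self.loci[locus_id])


@dataclass(frozen=True)
class RegistryStats:
    """Descriptive statistics of a target panel.

    Two means are reported: ``seq_mean_bp`` averages over individual
    reference sequences, ``per_locus_mean_bp`` averages the summed
    reference length per locus (panels deposited with several reference
    taxa per locus are commonly summarised either way).  Means are NaN
    for an empty registry.
    """

    n_loci: int
    n_sequences: int
    total_bp: int
    seq_min_bp: int
    seq_max_bp: int
    seq_mean_bp: float
    per_locus_mean_bp: float


def parse_header(header: str, sep: str = "-") -> tuple[str, str]:
    """Split a FASTA header into (taxon_id, locus_id) on the last
    occurrence of ``sep``."""
    taxon, found, locus = header.rpartition(sep)
    if not found or not taxon or not locus:
        raise TargetFileError(
            f"header {header!r} does not split into taxon{sep}locus"
        )
    return taxon, locus


def read_targets(path, header_separator: str = "-") -> LocusRegistry:
    """Read a target-reference FASTA into a LocusRegistry.

    Case is preserved and record order within a locus follows the file.
    An empty file yields an empty registry with a warning; headers
    lacking the separator and duplicate (taxon, locus) pairs raise
    :class:`TargetFileError`.
    """
    registry = LocusRegistry()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        taxon, locus = parse_header(record.id, header_separator)
        registry.add(TargetSequence(locus, taxon, str(record.seq)))
        n += 1
    if n == 0:
        warnings.warn(f"no FASTA records in {path}", stacklevel=2)
    return registry


def write_targets(registry: LocusRegistry, path, header_separator: str = "-") -> None:
    """Write a registry back to FASTA (80-column wrapped).

    Round-trips exactly: ``read_targets(write_targets(R)) == R``.
    """
    records = [
        SeqRecord(
            Seq(s.residues),
            id=f"{s.taxon_id}{header_separator}{s.locus_id}",
            description="",
        )
        for s in registry
    ]
    if not records:
        warnings.warn("writing an empty registry", stacklevel=2)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def registry_from_sequences(seqs: Iterable[TargetSequence]) -> LocusRegistry:
    registry = LocusRegistry()
    for s in seqs:
        registry.add(s)
    return registry


def registry_stats(registry: LocusRegistry) -> RegistryStats:
    """Panel descriptors: locus/sequence counts, total bp, length range
    and the two panel means."""
    lengths = [s.length for s in registry]
    n_loci = len(registry.loci)
    if not lengths:
        return RegistryStats(0, 0, 0, 0, 0, float("nan"), float("nan"))
    per_locus = [sum(s.length for s in b) for b in registry.loci.values()]
    return RegistryStats(
        n_loci=n_loci,
        n_sequences=len(lengths),
        total_bp=sum(lengths),
        seq_min_bp=min(lengths),
        seq_max_bp=max(lengths),
        seq_mean_bp=sum(lengths) / len(lengths),
        per_locus_mean_bp=sum(per_locus) / n_loci,
    )


def stats_tsv(stats: RegistryStats, panel: str = "panel") -> str:
    """Stats as a 2-line TSV with header row; means unrounded."""
    header = "panel\tn_loci\tn_sequences\ttotal_bp\tmin\tmax\tmean"
    row = (
        f"{panel}\t{stats.n_loci}\t{stats.n_sequences}\t{stats.total_bp}"
        f"\t{stats.seq_min_bp}\t{stats.seq_max_bp}\t{stats.seq_mean_bp}"
    )
    return header + "\n" + row + "\n"


def subset_by_ids(
    registry: LocusRegistry,
    locus_ids: set[str] | None = None,
    taxon_ids: set[str] | None = None,
) -> tuple[LocusRegistry, dict[str, list[str]]]:
    """Restrict a registry to the given loci and/or taxa.

    Returns the subset and a report of requested ids absent from the
    registry (missing ids are reported, never silently dropped).
    """
    out = LocusRegistry()
    for seq in registry:
        if locus_ids is not None and seq.locus_id not in locus_ids:
            continue
        if taxon_ids is not None and seq.taxon_id not in taxon_ids:
            continue
        out.add(seq)
    missing: dict[str, list[str]] = {"loci": [], "taxa": []}
    if locus_ids is not None:
        missing["loci"] = sorted(locus_ids - set(registry.loci))
    if taxon_ids is not None:
        present = {s.taxon_id for s in registry}
        missing["taxa"] = sorted(taxon_ids - present)
    return out, missing


def merge_registries(
    a: LocusRegistry,
    b: LocusRegistry,
    collision_policy: str = "error",
    panel_names: tuple[str, str] = ("A", "B"),
) -> LocusRegistry:
    """Union of two panels' loci.

    On a locus_id collision either raise (``policy="error"``) or keep
    both loci under panel-prefixed ids (``policy="prefix"``).
    """
    if collision_policy not in {"error", "prefix"}:
        raise ValueError(f"unknown collision policy {collision_policy!r}")
    collisions = set(a.loci) & set(b.loci)
    if collisions and collision_policy == "error":
        raise TargetFileError(
            f"locus id collision(s): {sorted(collisions)}"
        )
    out = LocusRegistry()
    for src, name in ((a, panel_names[0]), (b, panel_names[1])):
        for seq in src:
            locus = seq.locus_id
            if locus in collisions:
                locus = f"{name}:{locus}"
            out.add(TargetSequence(locus, seq.taxon_id, seq.residues))
    return out
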