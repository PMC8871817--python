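"""In-silico hybridization probe (bait) design.

Probes are fixed-length oligos (default 120 nt) tiled across every
target reference at n-fold average coverage (default 3x, i.e. step =
probe_length / tiling_factor = 40 bp), then passed through two QC
filters: removal of probes containing long single-nucleotide runs, and
collapsing of redundant probes that align at high identity (default
98 % over at least 80 bp, either strand).

Overlapping tiles cut from the same source sequence share identical
subsequence by construction; that overlap is deliberate tiling
redundancy, so the collapse step only considers probe pairs from
different source sequences or from non-overlapping spans of the same
source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import groupby

from . import _align
from .registry import LocusRegistry, TargetSequence


@dataclass(frozen=True)
class ProbeDesignParams:
    probe_length: int = 120
    tiling_factor: int = 3
    max_homopolymer_run: int = 12
    collapse_min_identity: float = 0.98
    collapse_min_overlap_bp: int = 80
    end_anchor: bool = True

    def __post_init__(self):
        if self.probe_length < 1 or self.tiling_factor < 1:
            raise ValueError("probe_length and tiling_factor must be >= 1")
        if self.probe_length % self.tiling_factor != 0:
            raise ValueError(
                f"probe_length {self.probe_length} not divisible by "
                f"tiling_factor {self.tiling_factor}"
            )
        if not 0.0 <= self.collapse_min_identity <= 1.0:
            raise ValueError("collapse_min_identity must be in [0, 1]")
        if self.collapse_min_overlap_bp > self.probe_length:
            raise ValueError("collapse_min_overlap_bp exceeds probe_length")

    @property
    def step(self) -> int:
        return self.probe_length // self.tiling_factor


@dataclass(frozen=True)
class Probe:
    """One designed probe; coordinates are 0-based half-open on the
    source reference sequence."""

    probe_id: str
    source_taxon_id: str
    source_locus_id: str
    start: int
    end: int
    residues: str

    def __post_init__(self):
        if self.end - self.start != len(self.residues):
            raise ValueError(f"{self.probe_id}: span/sequence length mismatch")

    @property
    def source_key(self) -> tuple[str, str]:
        return (self.source_taxon_id, self.source_locus_id)


@dataclass
class ProbePanel:
    """Designed probes with per-stage provenance counts."""

    probes: list[Probe]
    params: ProbeDesignParams
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)


def tile_probes(
    sequence: TargetSequence, params: ProbeDesignParams = ProbeDesignParams()
) -> list[Probe]:
    """All tiling positions of one reference sequence.

    Starts run at 0, step, 2*step, ... while a full-length probe fits;
    with ``end_anchor`` an extra probe pinned to the 3' end is appended
    whenever the last regular tile stops short of the sequence end.
    Sequences shorter than the probe length yield no probes (warning).
    """
    L = sequence.length
    k = params.probe_length
    if L < k:
        warnings.warn(
            f"{sequence.taxon_id}/{sequence.locus_id}: length {L} bp "
            f"shorter than probe length {k}; no probes",
            stacklevel=2,
        )
        return []
    starts = list(range(0, L - k + 1, params.step))
    if params.end_anchor and starts[-1] + k < L:
        starts.append(L - k)
    return [
        Probe(
            probe_id=f"{sequence.taxon_id}-{sequence.locus_id}_{s}-{s + k}",
            source_taxon_id=sequence.taxon_id,
            source_locus_id=sequence.locus_id,
            start=s,
            end=s + k,
            residues=sequence.residues[s : s + k],
        )
        for s in starts
    ]


def expected_tile_count(L: int, params: ProbeDesignParams = ProbeDesignParams()) -> int:
    """Closed-form tiling count for a sequence of length L."""
    k, step = params.probe_length, params.step
    if L < k:
        return 0
    n = (L - k) // step + 1
    if params.end_anchor and (L - k) % step != 0:
        n += 1
    return n


def max_homopolymer(seq: str) -> int:
    """Longest single-nucleotide run; case-insensitive, and N (or any
    ambiguity code) never extends a run."""
    best = 0
    for base, run in groupby(seq.upper()):
        if base in "ACGT":
            best = max(best, sum(1 for _ in run))
    return best


def filter_homopolymers(
    probes: list[Probe], params: ProbeDesignParams = ProbeDesignParams()
) -> tuple[list[Probe], list[Probe]]:
    """Partition probes into (kept, removed); removed iff the longest
    homopolymer run is strictly greater than ``max_homopolymer_run``."""
    kept, removed = [], []
    for p in probes:
        (removed if max_homopolymer(p.residues) > params.max_homopolymer_run else kept).append(p)
    return kept, removed


def _sort_key(p: Probe):
    return (p.source_locus_id, p.source_taxon_id, p.start)


def _exempt(a: Probe, b: Probe) -> bool:
    """Same-source overlapping tiles are deliberate redundancy."""
    return a.source_key == b.source_key and a.start < b.end and b.start < a.end


def probes_redundant(
    a: Probe, b: Probe, params: ProbeDesignParams = ProbeDesignParams()
) -> bool:
    """Collapse criterion for a probe pair (exemption not applied)."""
    aln = _align.sw_align_both_strands(a.residues, b.residues)
    return _align.meets_similarity(
        aln, params.collapse_min_identity, params.collapse_min_overlap_bp
    )


def collapse_similar(
    probes: list[Probe],
    params: ProbeDesignParams = ProbeDesignParams(),
    use_prefilter: bool = True,
) -> tuple[list[Probe], dict[str, str]]:
    """Remove redundant probes until no retained pair qualifies.

    Probes are processed in (locus, taxon, start) order; the earlier
    probe of a qualifying pair is the representative and the later one
    is removed, so the result is independent of input file order. The
    12-mer prefilter is lossless at the default identity threshold.

    Returns (kept, report) with report mapping removed probe ids to
    their representative's id.
    """
    ordered = sorted(probes, key=_sort_key)
    if use_prefilter:
        pairs = _align.kmer_candidate_pairs([p.residues for p in ordered])
        neighbours: dict[int, list[int]] = {}
        for i, j in pairs:
            neighbours.setdefault(j, []).append(i)
            neighbours.setdefault(i, []).append(j)
    else:
        neighbours = {
            i: list(range(len(ordered))) for i in range(len(ordered))
        }
    alive = [True] * len(ordered)
    report: dict[str, str] = {}
    for idx, cand in enumerate(ordered):
        rep = None
        for i in sorted(neighbours.get(idx, ())):
            if i >= idx or not alive[i]:
                continue
            p = ordered[i]
            if _exempt(p, cand):
                continue
            if probes_redundant(p, cand, params):
                rep = p
                break
        if rep is None:
            continue
        alive[idx] = False
        report[cand.probe_id] = rep.probe_id
    kept = [p for i, p in enumerate(ordered) if alive[i]]
    return kept, report


def design_probe_panel(
    registry: LocusRegistry, params: ProbeDesignParams = ProbeDesignParams()
) -> ProbePanel:
    """Tile every reference, drop homopolymer probes, collapse
    redundancy panel-wide; provenance counts recorded per stage."""
    if len(registry) == 0:
        raise ValueError("registry is empty")
    tiled: list[Probe] = []
    for seq in sorted(registry, key=lambda s: (s.locus_id, s.taxon_id)):
        tiled.extend(tile_probes(seq, params))
    kept, _removed = filter_homopolymers(tiled, params)
    collapsed, report = collapse_similar(kept, params)
    collapsed.sort(key=_sort_key)
    return ProbePanel(
        probes=collapsed,
        params=params,
        provenance={
            "tiled": len(tiled),
            "after_homopolymer": len(kept),
            "after_collapse": len(collapsed),
            "collapse_report": len(report),
        },
    )


def panel_to_fasta(panel: ProbePanel) -> str:
    return "".join(f">{p.probe_id}\n{p.residues}\n" for p in panel.probes)


def panel_to_bed(panel: ProbePanel, stage: str = "final") -> str:
    """6-column BED-like TSV: source id, start, end, probe id, stage,
    strand (probes are designed on the forward strand)."""
    lines = [
        f"{p.source_taxon_id}-{p.source_locus_id}\t{p.start}\t{p.end}"
        f"\t{p.probe_id}\t{stage}\t+"
        for p in panel.probes
    ]
    return "\n".join(lines) + ("\n" if lines else "")
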