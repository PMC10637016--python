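"""Reference-frame consensus calling and unrecovered-interval reporting.

Filtered hits from all libraries are projected onto the reference
coordinate frame; each covered position accumulates weighted base calls
(weight = hit identity, which down-weights misassigned fragments), and the
consensus picks the heaviest base per position.  Positions with no call
become ``N`` and are merged into maximal unrecovered intervals — the
analogue of the control-region gap a transcriptome-based assembly cannot
close.  The genome is treated as circular for interval merging but
reported linearized at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnnotatedGenome, MitomineError, revcomp
from .mining import MiningParams

__all__ = [
    "ConsensusError",
    "ConsensusResult",
    "project_hits",
    "call_consensus",
    "gap_report",
    "build_consensus",
]

GAP_CHAR = "N"


class ConsensusError(MitomineError):
    pass


@dataclass
class ConsensusResult:
    """Consensus sequence plus coverage bookkeeping.

    ``intervals`` are maximal unrecovered runs, 1-based inclusive on the
    reference frame; an interval with start > end wraps across the
    origin of the circular genome.
    """

    seq: str
    depth: np.ndarray
    intervals: list = field(default_factory=list)
    reference_name: str = "reference"

    @property
    def reference_length(self) -> int:
        return len(self.seq)

    @staticmethod
    def interval_length(iv, genome_length: int) -> int:
        start, end = iv
        if start <= end:
            return end - start + 1
        return genome_length - start + 1 + end

    @property
    def total_gap(self) -> int:
        return sum(
            self.interval_length(iv, self.reference_length)
            for iv in self.intervals
        )

    @property
    def total_recovered(self) -> int:
        return self.reference_length - self.total_gap


def _oriented_segment(contig_seq: str, hit) -> str:
    seg = contig_seq[hit.qstart - 1 : hit.qend]
    return revcomp(seg) if hit.strand == "-" else seg


def project_hits(
    hits,
    contigs: dict,
    reference: AnnotatedGenome,
    params: MiningParams = MiningParams(),
) -> dict:
    """Per-position weighted base calls from all hits.

    Returns a dict: 1-based reference position -> list of
    (base, weight, library).  Contig insertions relative to the reference
    contribute no call; contig deletions leave the position to other hits.
    """
    L = len(reference)
    aligner = None
    calls: dict = {}
    for h in hits:
        if not (1 <= h.sstart <= h.send <= L):
            raise ConsensusError(
                f"hit {h.contig_id}->{h.region} "
                f"({h.sstart}..{h.send}) outside reference (1..{L})"
            )
        if h.contig_id not in contigs:
            raise ConsensusError(f"hit names unknown contig {h.contig_id!r}")
        if h.ref_aln and h.qry_aln:
            ref_aln, qry_aln = h.ref_aln, h.qry_aln
        else:
            # hits loaded from TSV carry no alignment: recompute on the
            # hit's own segments with the same scoring scheme
            if aligner is None:
                aligner = params.global_aligner()
            rseg = reference.seq[h.sstart - 1 : h.send]
            qseg = _oriented_segment(contigs[h.contig_id], h)
            best = aligner.align(rseg, qseg)[0]
            ref_aln, qry_aln = str(best[0]), str(best[1])
        pos = h.sstart
        w = h.identity
        lib = h.library
        for rb, qb in zip(ref_aln, qry_aln):
            if rb == "-":
                continue  # insertion in contig: dropped
            if qb != "-":
                calls.setdefault(pos, []).append((qb, w, lib))
            pos += 1
        if pos - 1 != h.send:
            raise ConsensusError(
                f"hit {h.contig_id}->{h.region}: alignment spans "
                f"{h.sstart}..{pos - 1}, expected end {h.send}"
            )
    return calls


def _pick_base(entries) -> str:
    weight: dict = {}
    libs: dict = {}
    for base, w, lib in entries:
        weight[base] = weight.get(base, 0.0) + w
        libs.setdefault(base, set()).add(lib)
    top = max(weight.values())
    tied = sorted(b for b, w in weight.items() if w == top)
    if len(tied) == 1:
        return tied[0]
    # tie on weight: plurality of distinct libraries, then smallest base
    best_libs = max(len(libs[b]) for b in tied)
    tied = [b for b in tied if len(libs[b]) == best_libs]
    return min(tied)


def call_consensus(calls: dict, reference: AnnotatedGenome) -> ConsensusResult:
    """Weighted-majority consensus on the reference frame."""
    L = len(reference)
    depth = np.zeros(L, dtype=np.int32)
    chars = [GAP_CHAR] * L
    for pos, entries in calls.items():
        depth[pos - 1] = len(entries)
        chars[pos - 1] = _pick_base(entries)
    intervals = _gap_intervals(depth, circular=reference.circular)
    return ConsensusResult(
        seq="".join(chars),
        depth=depth,
        intervals=intervals,
        reference_name=reference.name,
    )


def _gap_intervals(depth: np.ndarray, circular: bool) -> list:
    L = len(depth)
    uncovered = depth == 0
    if uncovered.all():
        return [(1, L)]
    if not uncovered.any():
        return []
    intervals = []
    start = None
    for i in range(L):
        if uncovered[i] and start is None:
            start = i + 1
        elif not uncovered[i] and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, L))
    # merge across the origin on a circular genome
    if (
        circular
        and len(intervals) >= 2
        and intervals[0][0] == 1
        and intervals[-1][1] == L
    ):
        first, last = intervals[0], intervals[-1]
        intervals = intervals[1:-1]
        intervals.append((last[0], first[1]))  # wrapping interval
    return intervals


def _interval_positions(iv, L: int):
    start, end = iv
    if start <= end:
        return range(start, end + 1)
    return list(range(start, L + 1)) + list(range(1, end + 1))


def gap_report(
    result: ConsensusResult, reference: AnnotatedGenome
) -> pd.DataFrame:
    """One row per unrecovered interval with the reference features it
    overlaps, plus a totals row."""
    L = result.reference_length
    rows = []
    for iv in result.intervals:
        pos = set(_interval_positions(iv, L))
        names = [
            f.name
            for f in reference.features
            if not set(range(f.start, f.end + 1)).isdisjoint(pos)
        ]
        rows.append(
            {
                "start": iv[0],
                "end": iv[1],
                "length": ConsensusResult.interval_length(iv, L),
                "features": ",".join(names),
            }
        )
    rows.append(
        {
            "start": "total",
            "end": "",
            "length": result.total_gap,
            "features": "",
        }
    )
    return pd.DataFrame(rows, columns=["start", "end", "length", "features"])


def build_consensus(
    hits,
    contigs: dict,
    reference: AnnotatedGenome,
    params: MiningParams = MiningParams(),
) -> ConsensusResult:
    """Convenience wrapper: project hits then call the consensus."""
    calls = project_hits(hits, contigs, reference, params)
    return call_consensus(calls, reference)
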