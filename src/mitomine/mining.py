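"""BLASTn-like mining of mitochondrial regions from contigs.

A k-mer index over the reference regions seeds the search.  Seed matches
are projected onto genome diagonals and clustered per contig, so a contig
spanning several adjacent regions (the polycistronic-transcript case)
anchors one contiguous window on the reference; the contig is aligned to
that window by an exact local alignment (Smith-Waterman with affine gaps,
via Biopython's C aligner), and the alignment is split into one hit per
reference region it crosses.  Short tRNA regions that carry no intact
seed of their own at genus-level divergence are still recovered — their
flanking genes anchor the window — matching what a whole-genome ClustalW
layout achieves.

Hits are always reported on the reference forward strand: ``sstart <=
send`` are reference coordinates, ``qstart <= qend`` original-contig
coordinates, and ``strand`` records the orientation ("-" meaning the
contig's reverse complement aligns to the reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .core import AnnotatedGenome, MitomineError, ValidationError, revcomp

__all__ = [
    "MiningParams",
    "Hit",
    "ReferenceIndex",
    "index_reference",
    "scan_contig",
    "filter_hits",
    "best_per_region",
    "mine_contigs",
    "write_hits_tsv",
    "read_hits_tsv",
]

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "qstart", "qend",
    "sstart", "send", "strand", "score",
]


@dataclass(frozen=True)
class MiningParams:
    """Search knobs; BLASTn-like defaults tuned for genus-level
    (<= ~22%) nucleotide divergence."""

    k: int = 11
    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 1
    min_identity: float = 0.75
    min_length: int = 50
    # a seed cluster is aligned only if it holds >= min_seeds matches
    # (4 overlapping k-mers = one exact 14-mer, which random sequence
    # almost never produces); the reference window of an alignment is the
    # contig's diagonal projection +- band_pad
    min_seeds: int = 4
    band_pad: int = 30

    def __post_init__(self) -> None:
        if not 4 <= self.k <= 15:
            raise ValidationError("seed length k must lie in [4, 15]")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValidationError("min_identity must lie in (0, 1]")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError("gap penalties must be >= 0")
        if self.min_seeds < 1:
            raise ValidationError("min_seeds must be >= 1")

    def local_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("local")

    def global_aligner(self) -> Align.PairwiseAligner:
        return self._aligner("global")

    def _aligner(self, mode: str) -> Align.PairwiseAligner:
        # a gap of length L costs gap_open + L * gap_extend
        return Align.PairwiseAligner(
            mode=mode,
            match_score=self.match,
            mismatch_score=self.mismatch,
            open_gap_score=-(self.gap_open + self.gap_extend),
            extend_gap_score=-self.gap_extend,
        )

    def score_columns(self, ref_aln: str, qry_aln: str) -> float:
        """Score of an explicit alignment under this scheme."""
        score = 0.0
        gap_run = 0
        for rb, qb in zip(ref_aln, qry_aln):
            if rb == "-" or qb == "-":
                score -= self.gap_extend + (self.gap_open if not gap_run else 0)
                gap_run += 1
            else:
                gap_run = 0
                score += self.match if rb == qb else self.mismatch
        return score


@dataclass
class Hit:
    """One local alignment of a contig to one reference region."""

    contig_id: str
    region: str
    sstart: int
    send: int
    qstart: int
    qend: int
    strand: str
    length: int       # aligned columns, gaps included
    identity: float
    score: float
    # aligned strings (reference row, oriented-contig row); cached for the
    # consensus stage, never serialized
    ref_aln: str = field(default="", repr=False, compare=False)
    qry_aln: str = field(default="", repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sstart > self.send or self.qstart > self.qend:
            raise ValidationError(
                f"hit {self.contig_id}->{self.region}: start > end"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError("identity must lie in [0, 1]")

    @property
    def library(self) -> str:
        """Library id encoded in the contig header (``<lib>|contig<n>``)."""
        return self.contig_id.split("|", 1)[0]


class ReferenceIndex:
    """Exact k-mer index over reference regions; postings are
    (region name, 0-based genome position of the k-mer start)."""

    def __init__(self, genome: AnnotatedGenome, k: int):
        if not 4 <= k <= 15:
            raise ValidationError("k must lie in [4, 15]")
        self.k = k
        self.genome = genome
        self.region_bounds = {}   # name -> (start, end) 1-based inclusive
        self.kmers: dict = {}
        for f in genome.features:
            seq = genome.seq[f.start - 1 : f.end]
            if len(seq) < k:
                logger.warning(
                    "region %s (%d bp) shorter than k=%d: skipped",
                    f.name, len(seq), k,
                )
                continue
            self.region_bounds[f.name] = (f.start, f.end)
            for off in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[off : off + k], []).append(
                    (f.name, f.start - 1 + off)
                )

    def n_positions(self, region: str) -> int:
        s, e = self.region_bounds[region]
        return max(0, e - s + 1 - self.k + 1)

    def genome_seeds(self, seq: str) -> list:
        """All seed matches of ``seq`` as (genome position, query
        position), both 0-based."""
        k = self.k
        out = []
        seen = set()
        for i in range(len(seq) - k + 1):
            for _, gpos in self.kmers.get(seq[i : i + k], ()):
                if (gpos, i) not in seen:
                    seen.add((gpos, i))
                    out.append((gpos, i))
        return out


def index_reference(genome: AnnotatedGenome, k: int = 11) -> ReferenceIndex:
    return ReferenceIndex(genome, k)


def _cluster_seeds(seeds, tol: int) -> list:
    """Group seeds by genome diagonal (gpos - qpos) within ``tol``."""
    by_diag = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    clusters = []
    for g, q in by_diag:
        d = g - q
        if clusters and d - clusters[-1][-1][0] + clusters[-1][-1][1] <= tol:
            clusters[-1].append((g, q))
        else:
            clusters.append([(g, q)])
    return clusters


def scan_contig(
    index: ReferenceIndex,
    contig_id: str,
    seq: str,
    params: MiningParams = MiningParams(),
) -> list:
    """All region hits for one contig, both orientations.

    Overlapping hits to the same region keep only the higher score
    (ties: higher identity, then forward strand).
    """
    seq = seq.upper()
    if len(seq) < index.k:
        return []
    aligner = params.local_aligner()
    ref_seq = index.genome.seq
    hits = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        seeds = index.genome_seeds(oriented)
        for cluster in _cluster_seeds(seeds, params.band_pad):
            if len(cluster) < params.min_seeds:
                continue
            hits.extend(
                _align_cluster(
                    index, contig_id, oriented, len(seq), strand,
                    cluster, ref_seq, aligner, params,
                )
            )
    return _merge_overlapping(hits)


def _align_cluster(index, contig_id, oriented, contig_len, strand, cluster,
                   ref_seq, aligner, params):
    # reference window: the contig projected through its seed diagonals
    lo = max(0, min(g - q for g, q in cluster) - params.band_pad)
    hi = min(
        len(ref_seq),
        max(g + (len(oriented) - q) for g, q in cluster) + params.band_pad,
    )
    window = ref_seq[lo:hi]
    alns = aligner.align(window, oriented)
    if alns.score <= 0:
        return []
    best = alns[0]
    tblocks, qblocks = best.aligned
    t0 = int(tblocks[0][0])
    q0 = int(qblocks[0][0])
    ref_aln, qry_aln = str(best[0]), str(best[1])
    return _split_by_region(
        index, contig_id, contig_len, strand,
        lo + t0 + 1, q0 + 1, ref_aln, qry_aln, params,
    )


def _split_by_region(index, contig_id, contig_len, strand, ref_start,
                     qry_start, ref_aln, qry_aln, params):
    """Cut one alignment into per-region hits at region boundaries.

    Insertion columns (gap in the reference) are attached to the region
    of the preceding reference base; deletion columns at segment edges
    are trimmed so every hit starts and ends on an aligned base.
    """
    segments: dict = {}
    rpos = ref_start - 1   # 0-based position of next reference base
    qpos = qry_start - 1   # 0-based position of next query base
    ordered = sorted(index.region_bounds.items(), key=lambda kv: kv[1][0])
    ptr = 0
    active_prev: list = []
    for rb, qb in zip(ref_aln, qry_aln):
        if rb == "-":
            for name in active_prev:  # insertion: stays with last region
                seg = segments[name]
                seg["cols"].append((rb, qb))
                seg["q1"] = qpos
            qpos += 1
            continue
        here = rpos + 1  # 1-based
        while ptr < len(ordered) and ordered[ptr][1][1] < here:
            ptr += 1
        active = []
        j = ptr
        while j < len(ordered) and ordered[j][1][0] <= here:
            if ordered[j][1][1] >= here:
                active.append(ordered[j][0])
            j += 1
        for name in active:
            seg = segments.setdefault(
                name, {"cols": [], "r0": here, "r1": here,
                       "q0": None, "q1": None}
            )
            seg["cols"].append((rb, qb))
            seg["r1"] = here
            if qb != "-":
                if seg["q0"] is None:
                    seg["q0"] = qpos
                seg["q1"] = qpos
        active_prev = active
        rpos += 1
        if qb != "-":
            qpos += 1
    hits = []
    for name, seg in segments.items():
        cols = seg["cols"]
        # trim deletion columns at the segment edges
        while cols and cols[0][1] == "-":
            seg["r0"] += 1
            cols = cols[1:]
        while cols and cols[-1][1] == "-":
            seg["r1"] -= 1
            cols = cols[:-1]
        if not cols or seg["q0"] is None or seg["r0"] > seg["r1"]:
            continue
        ref_sub = "".join(c[0] for c in cols)
        qry_sub = "".join(c[1] for c in cols)
        matches = sum(1 for rb, qb in cols if rb == qb and rb != "-")
        ncols = len(cols)
        q0, q1 = seg["q0"], seg["q1"]          # 0-based oriented frame
        if strand == "+":
            qstart, qend = q0 + 1, q1 + 1
        else:
            qstart, qend = contig_len - q1, contig_len - q0
        hits.append(
            Hit(
                contig_id=contig_id,
                region=name,
                sstart=seg["r0"],
                send=seg["r1"],
                qstart=qstart,
                qend=qend,
                strand=strand,
                length=ncols,
                identity=matches / ncols,
                score=params.score_columns(ref_sub, qry_sub),
                ref_aln=ref_sub,
                qry_aln=qry_sub,
            )
        )
    return hits


def _merge_overlapping(hits: list) -> list:
    by_region: dict = {}
    for h in hits:
        by_region.setdefault(h.region, []).append(h)
    kept = []
    for region in by_region:
        cand = sorted(
            by_region[region],
            key=lambda h: (-h.score, -h.identity, h.strand),
        )
        chosen = []
        for h in cand:
            if all(h.send < c.sstart or h.sstart > c.send for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.sstart, h.region, h.contig_id))
    return kept


def filter_hits(hits, params: MiningParams, region_lengths=None) -> list:
    """Keep hits with identity >= min_identity and aligned length >= the
    effective minimum length (inclusive thresholds; order preserved).

    The length threshold is capped at the target region's own length when
    ``region_lengths`` is given, so short tRNA regions stay findable.
    """
    out = []
    for h in hits:
        min_len = params.min_length
        if region_lengths and h.region in region_lengths:
            min_len = min(min_len, region_lengths[h.region])
        if h.identity >= params.min_identity and h.length >= min_len:
            out.append(h)
    return out


def best_per_region(hits) -> dict:
    """Group hits by region, each list sorted by score desc, then
    identity desc, then contig id asc.  Regions with no hits are absent."""
    grouped: dict = {}
    for h in hits:
        grouped.setdefault(h.region, []).append(h)
    for region in grouped:
        grouped[region].sort(key=lambda h: (-h.score, -h.identity, h.contig_id))
    return grouped


def mine_contigs(
    reference: AnnotatedGenome,
    contigs: dict,
    params: MiningParams = MiningParams(),
) -> list:
    """Scan every contig of ``contigs`` (id -> sequence) and return the
    filtered hit list."""
    index = index_reference(reference, params.k)
    region_lengths = {
        name: e - s + 1 for name, (s, e) in index.region_bounds.items()
    }
    hits = []
    for cid in sorted(contigs):
        hits.extend(scan_contig(index, cid, contigs[cid], params))
    return filter_hits(hits, params, region_lengths)


def hits_to_frame(hits) -> pd.DataFrame:
    rows = [
        {
            "qseqid": h.contig_id, "sseqid": h.region,
            "pident": round(100.0 * h.identity, 2), "length": h.length,
            "qstart": h.qstart, "qend": h.qend,
            "sstart": h.sstart, "send": h.send,
            "strand": h.strand, "score": h.score,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits, path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise MitomineError(f"hit table missing columns: {sorted(missing)}")
    return [
        Hit(
            contig_id=str(r.qseqid), region=str(r.sseqid),
            sstart=int(r.sstart), send=int(r.send),
            qstart=int(r.qstart), qend=int(r.qend),
            strand=str(r.strand), length=int(r.length),
            identity=float(r.pident) / 100.0, score=float(r.score),
        )
        for r in df.itertuples()
    ]
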