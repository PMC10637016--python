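"""Gene-map annotation of a consensus mitogenome.

Reference features are projected onto the consensus (which shares the
reference coordinate frame in this substitution-only pipeline), protein-
coding genes are refined to a valid open reading frame under the
invertebrate mitochondrial genetic code, and the classic mitogenome
bookkeeping is computed: start/stop codons, amino-acid counts
(size/3 - 1, the terminal codon encoding no residue), and signed
intergenic spacing ``In`` where positive values are noncoding spacers and
negative values overlaps between adjacent regions.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import (
    INVERTEBRATE_MITO_TABLE,
    AnnotatedGenome,
    GeneFeature,
    MitomineError,
    revcomp,
)

__all__ = [
    "AnnotationError",
    "DEFAULT_START_CODONS",
    "DEFAULT_STOP_CODONS",
    "amino_acid_count",
    "intergenic",
    "project_features",
    "refine_pcg",
    "annotate_genome",
    "gene_table",
]

logger = logging.getLogger(__name__)

# Canonical + alternative initiation codons seen in malacostracan
# mitogenomes (methionine, valine, isoleucine, threonine, leucine,
# tyrosine starts).
DEFAULT_START_CODONS = (
    "ATG", "GTG", "ATT", "ATC", "ATA", "ACG", "ACT", "CTT", "TAT",
)
# TGA is accepted as a termination signal but logged: under the
# invertebrate mitochondrial code it normally encodes tryptophan.
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODE_STOPS = set(INVERTEBRATE_MITO_TABLE.stop_codons)  # internal-stop check
GAP_CHAR = "N"


class AnnotationError(MitomineError):
    pass


def amino_acid_count(length_bp: int, stop_complete: bool = True) -> int:
    """Residues encoded by a PCG of ``length_bp`` with a complete 3-nt
    stop codon: length/3 - 1."""
    if not stop_complete:
        raise AnnotationError(
            "truncated stop codons are not supported; gene lengths must "
            "include a complete 3-nt stop"
        )
    if length_bp % 3:
        raise AnnotationError(
            f"PCG length {length_bp} is not a multiple of 3"
        )
    return length_bp // 3 - 1


def intergenic(features, genome_length: int, circular: bool = True) -> list:
    """Signed spacing In(f) = start(next) - end(f) - 1 for each feature,
    in input order (features must be sorted by start).  On a circular
    genome the last feature wraps to the first."""
    feats = [f for f in features]
    values = []
    for i, f in enumerate(feats):
        if i + 1 < len(feats):
            nxt = feats[i + 1].start
        elif circular:
            nxt = feats[0].start + genome_length
        else:
            values.append(None)
            continue
        values.append(nxt - f.end - 1)
    return values


def _gap_runs(seq: str):
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == GAP_CHAR and start is None:
            start = i + 1
        elif ch != GAP_CHAR and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def project_features(
    reference: AnnotatedGenome, consensus_seq: str
) -> list:
    """Copy reference features onto a same-frame consensus.

    Features wholly inside gap (N) runs are flagged unrecovered; features
    with gapped leading/trailing bases are trimmed and flagged incomplete.
    """
    if len(consensus_seq) != len(reference):
        raise AnnotationError(
            "consensus and reference lengths differ "
            f"({len(consensus_seq)} vs {len(reference)}); the projection "
            "requires a shared coordinate frame"
        )
    out = []
    for f in reference.features:
        sub = consensus_seq[f.start - 1 : f.end]
        n_real = sum(ch != GAP_CHAR for ch in sub)
        if n_real == 0:
            out.append(f.copy(unrecovered=True, incomplete=True))
            continue
        lead = len(sub) - len(sub.lstrip(GAP_CHAR))
        trail = len(sub) - len(sub.rstrip(GAP_CHAR))
        new_start = f.start + lead
        new_end = f.end - trail
        incomplete = n_real < f.size
        out.append(
            f.copy(start=new_start, end=new_end, incomplete=incomplete)
        )
    return out


def _codon(seq_f: str, pos0: int) -> str:
    return seq_f[pos0 : pos0 + 3]


def refine_pcg(
    consensus_seq: str,
    draft: GeneFeature,
    start_codons=DEFAULT_START_CODONS,
    stop_codons=DEFAULT_STOP_CODONS,
    window: int = 18,
) -> GeneFeature:
    """Refine a projected protein-coding gene to a clean reading frame.

    The start codon is the accepted triplet closest to the projected
    start within +-``window`` nt (in frame; ATG preferred on distance
    ties); the stop is the first in-frame stop ending at or after the
    projected end; the frame in between must be free of internal stops
    under the invertebrate mitochondrial code.
    """
    if draft.cls != "PCG":
        raise AnnotationError(f"{draft.name}: refine_pcg needs a PCG")
    if draft.unrecovered:
        raise AnnotationError(f"{draft.name}: gene is unrecovered")
    L = len(consensus_seq)
    if draft.strand == "H":
        seq_f = revcomp(consensus_seq)
        d_start = L - draft.end + 1
        d_end = L - draft.start + 1
    else:
        seq_f = consensus_seq
        d_start, d_end = draft.start, draft.end

    offsets = sorted(
        range(-window, window + 1, 3), key=lambda o: (abs(o), o)
    )
    candidates = []
    for off in offsets:
        p = d_start + off
        if p < 1 or p + 2 > L:
            continue
        tri = _codon(seq_f, p - 1)
        if tri in start_codons:
            candidates.append((abs(off), 0 if tri == "ATG" else 1, p, tri))
    candidates.sort()

    def _finish(p_start: int):
        # first in-frame stop ending at/after the projected end
        p = p_start
        while p + 2 <= L:
            tri = _codon(seq_f, p - 1)
            if p + 2 >= d_end and tri in stop_codons:
                return p, tri
            p += 3
        return None

    chosen = None
    for _, _, p_start, start_tri in candidates:
        found = _finish(p_start)
        if found is None:
            continue
        p_stop, stop_tri = found
        body = range(p_start + 3, p_stop, 3)
        if any(_codon(seq_f, q - 1) in _CODE_STOPS for q in body):
            continue
        chosen = (p_start, start_tri, p_stop, stop_tri)
        break

    if chosen is None:
        if candidates:
            raise AnnotationError(
                f"{draft.name}: internal stop codon in every candidate frame"
            )
        logger.warning(
            "%s: no accepted start codon within +-%d nt of the projected "
            "start; keeping projected coordinates", draft.name, window,
        )
        return draft.copy()

    p_start, start_tri, p_stop, stop_tri = chosen
    if stop_tri == "TGA":
        logger.warning(
            "%s: TGA used as termination signal (encodes Trp under the "
            "invertebrate mitochondrial code)", draft.name,
        )
    new_len = p_stop + 2 - p_start + 1
    if draft.strand == "H":
        new_start = L - (p_stop + 2) + 1
        new_end = L - p_start + 1
    else:
        new_start, new_end = p_start, p_stop + 2
    aa_letter = INVERTEBRATE_MITO_TABLE.forward_table.get(start_tri, "?")
    return draft.copy(
        start=new_start,
        end=new_end,
        start_codon=start_tri,
        start_aa=aa_letter,
        stop_codon=stop_tri,
        aa_count=amino_acid_count(new_len),
    )


def annotate_genome(
    consensus_seq: str,
    reference: AnnotatedGenome,
    start_codons=DEFAULT_START_CODONS,
    stop_codons=DEFAULT_STOP_CODONS,
    window: int = 18,
    name: str = "consensus",
) -> AnnotatedGenome:
    """Full annotation: project, refine PCGs, compute In."""
    feats = project_features(reference, consensus_seq)
    refined = []
    for f in feats:
        if f.cls == "PCG" and not f.unrecovered:
            try:
                f = refine_pcg(
                    consensus_seq, f,
                    start_codons=start_codons, stop_codons=stop_codons,
                    window=window,
                )
            except AnnotationError as e:
                # keep the projected coordinates; the gene table shows no
                # codons for this gene
                logger.warning("%s; keeping projected coordinates", e)
                f = f.copy(incomplete=True)
        refined.append(f)
    recovered = [f for f in refined if not f.unrecovered]
    recovered.sort(key=lambda f: f.start)
    in_values = intergenic(
        recovered, len(consensus_seq), circular=reference.circular
    )
    for f, v in zip(recovered, in_values):
        f.intergenic = v
    order = {f.name: i for i, f in enumerate(reference.features)}
    refined.sort(key=lambda f: order[f.name])
    return AnnotatedGenome(
        seq=consensus_seq, features=refined,
        circular=reference.circular, name=name,
    )


def gene_table(genome: AnnotatedGenome) -> pd.DataFrame:
    """Tabular gene map: one row per feature, dashes for unrecovered."""
    rows = []
    for f in genome.features:
        if f.unrecovered:
            rows.append(
                {
                    "gene": f.name, "class": f.cls, "start": "-", "end": "-",
                    "size": "-", "start_codon": "-", "aa_letter": "-",
                    "stop_codon": "-", "strand": f.strand, "aa": "-",
                    "In": "-", "flags": "unrecovered",
                }
            )
            continue
        flags = "incomplete" if f.incomplete else ""
        rows.append(
            {
                "gene": f.name,
                "class": f.cls,
                "start": f.start,
                "end": f.end,
                "size": f.size,
                "start_codon": f.start_codon or "-",
                "aa_letter": f.start_aa or "-",
                "stop_codon": f.stop_codon or "-",
                "strand": f.strand,
                "aa": f.aa_count if f.aa_count is not None else "-",
                "In": f.intergenic if f.intergenic is not None else "-",
                "flags": flags,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "class", "start", "end", "size", "start_codon",
            "aa_letter", "stop_codon", "strand", "aa", "In", "flags",
        ],
    )


def features_from_gene_table(df: pd.DataFrame) -> list:
    """Rebuild GeneFeature objects from a serialized gene table."""
    feats = []
    for _, r in df.iterrows():
        if str(r["start"]) == "-":
            continue
        feats.append(
            GeneFeature(
                name=str(r["gene"]),
                cls=str(r["class"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r["strand"]),
                incomplete="incomplete" in str(r["flags"]),
            )
        )
    return feats
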