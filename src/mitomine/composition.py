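"""Base-composition reporting for a mitogenome and its region classes.

Reports A/C/G/T percentages plus A+T and G+C for the whole genome and for
the protein-coding, tRNA and rRNA classes.  Within a class, feature
intervals are merged into a positional union first, so overlapping genes
are counted once; noncoding spacers contribute only to the whole-genome
scope.  Gap (``N``) and ambiguity characters are excluded from both
numerator and denominator, and the reported size is the number of counted
bases.  Percentages are kept at full precision internally and rounded
half-up to 2 decimals only at serialization.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import AnnotatedGenome, MitomineError

__all__ = [
    "CompositionError",
    "base_composition",
    "merge_intervals",
    "class_composition",
    "composition_report",
    "format_report",
]

_COUNTED = "ACGT"
SCOPES = (("Mitogenome", None), ("PCGs", "PCG"), ("tRNAs", "tRNA"),
          ("rRNA", "rRNA"))


logger = logging.getLogger(__name__)


class CompositionError(MitomineError):
    pass


def base_composition(seq: str) -> dict:
    """A/C/G/T percentages over the countable bases of ``seq``."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in _COUNTED}
    size = sum(counts.values())
    if size == 0:
        raise CompositionError("sequence has no countable A/C/G/T bases")
    pct = {b: 100.0 * c / size for b, c in counts.items()}
    return {
        "size": size,
        "A": pct["A"], "C": pct["C"], "G": pct["G"], "T": pct["T"],
        "AT": pct["A"] + pct["T"], "GC": pct["G"] + pct["C"],
    }


def merge_intervals(intervals) -> list:
    """Union of 1-based inclusive intervals, as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def class_composition(genome: AnnotatedGenome, cls: str) -> dict:
    """Composition over the positional union of a class's recovered
    features (forward strand; each genomic position counted once)."""
    ivs = [
        (f.start, f.end)
        for f in genome.features
        if f.cls == cls and not f.unrecovered
    ]
    if not ivs:
        raise CompositionError(f"no recovered features of class {cls!r}")
    union = merge_intervals(ivs)
    seq = "".join(genome.seq[s - 1 : e] for s, e in union)
    return base_composition(seq)


def composition_report(genome: AnnotatedGenome) -> pd.DataFrame:
    """Whole-genome, PCG, tRNA and rRNA composition rows (full
    precision)."""
    rows = []
    for label, cls in SCOPES:
        if cls is None:
            comp = base_composition(genome.seq)
        else:
            try:
                comp = class_composition(genome, cls)
            except CompositionError as e:
                logger.warning("scope %s omitted: %s", label, e)
                continue
        rows.append({"region": label, **comp})
    return pd.DataFrame(
        rows, columns=["region", "size", "A", "C", "G", "T", "AT", "GC"]
    )


def _round2(x: float) -> float:
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Serialization view: percentages rounded half-up to 2 decimals."""
    out = report.copy()
    for col in ("A", "C", "G", "T", "AT", "GC"):
        out[col] = out[col].map(_round2)
    return out
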