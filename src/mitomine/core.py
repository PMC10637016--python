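"""Core containers shared by every pipeline stage.

The central object is :class:`AnnotatedGenome`: a (usually circular)
nucleotide sequence plus an ordered list of :class:`GeneFeature` records
with 1-based inclusive coordinates, the convention used by every external
artifact this package reads or writes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Data import CodonTable

__all__ = [
    "FeatureClass",
    "GeneFeature",
    "AnnotatedGenome",
    "MitomineError",
    "ValidationError",
    "revcomp",
    "INVERTEBRATE_MITO_TABLE",
    "GENETIC_CODE_ID",
]

# Invertebrate mitochondrial code (NCBI translation table 5): TGA=Trp,
# AGA/AGG=Ser, so the only true stops are TAA and TAG.
GENETIC_CODE_ID = 5
INVERTEBRATE_MITO_TABLE = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control")
FeatureClass = str

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


class MitomineError(Exception):
    """Base class for every error this package raises on purpose."""


class ValidationError(MitomineError):
    """Invalid input object (layout, feature list, config...)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One mitogenome region on the genome coordinate frame.

    Coordinates are 1-based inclusive.  ``strand`` uses the mitochondrial
    L (light) / H (heavy) convention; L maps to "+" in GFF3 output.
    Codon/amino-acid fields are populated for protein-coding genes only.
    ``intergenic`` is the signed spacing to the next feature (positive:
    noncoding spacer, negative: overlap).
    """

    name: str
    cls: FeatureClass
    start: int
    end: int
    strand: str = "L"
    start_codon: Optional[str] = None
    start_aa: Optional[str] = None
    stop_codon: Optional[str] = None
    aa_count: Optional[int] = None
    intergenic: Optional[int] = None
    incomplete: bool = False
    unrecovered: bool = False

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValidationError(
                f"feature {self.name!r}: unknown class {self.cls!r}"
            )
        if self.strand not in ("L", "H"):
            raise ValidationError(
                f"feature {self.name!r}: strand must be 'L' or 'H'"
            )
        if not self.unrecovered and not (1 <= self.start <= self.end):
            raise ValidationError(
                f"feature {self.name!r}: bad coordinates "
                f"{self.start}..{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def copy(self, **changes) -> "GeneFeature":
        return replace(self, **changes)


@dataclass
class AnnotatedGenome:
    """A nucleotide sequence plus its ordered feature list."""

    seq: str
    features: list = field(default_factory=list)
    circular: bool = True
    name: str = "genome"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_seq(self, name: str, oriented: bool = True) -> str:
        """Sequence of a named feature; reverse-complemented for H strand
        when ``oriented`` so the result reads in coding sense."""
        f = self.feature(name)
        s = self.seq[f.start - 1 : f.end]
        if oriented and f.strand == "H":
            s = revcomp(s)
        return s

    def validate(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate feature names")
        for f in self.features:
            if not f.unrecovered and f.end > len(self.seq):
                raise ValidationError(
                    f"feature {f.name!r} ends at {f.end} beyond genome "
                    f"length {len(self.seq)}"
                )

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(
            seq=self.seq,
            features=[f.copy() for f in self.features],
            circular=self.circular,
            name=self.name,
            meta=dict(self.meta),
        )
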