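"""Readers and writers for the pipeline's external artifacts.

One coordinate convention everywhere: 1-based inclusive, matching the
gene-map tables of the mitogenome literature.  FASTA goes through
Biopython; sequences are upper-cased on read and wrapped at 70 columns on
write.  Strand letters L/H map to +/- in GFF3.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .core import AnnotatedGenome, GeneFeature, MitomineError

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_features_tsv",
    "write_features_tsv",
    "write_gff3",
    "write_newick",
    "write_matrix_square_tsv",
    "write_matrix_lower_tsv",
    "write_feature_block",
]

IUPAC = set("ACGTRYSWKMBDHVN")

GFF3_TYPES = {"PCG": "gene", "tRNA": "tRNA", "rRNA": "rRNA",
              "control": "D_loop"}


class FormatError(MitomineError):
    pass


def _find_line(path, record_id: str, bad_char: str = None) -> int:
    """Locate the offending record (or character) for error messages."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_id = line[1:].split()[0] if line[1:].strip() else ""
                in_record = header_id == record_id
                if in_record and bad_char is None:
                    return lineno
            elif in_record and bad_char is not None:
                if bad_char in line.upper():
                    return lineno
    return 0


def read_fasta(path) -> list:
    """Parse FASTA records; sequences upper-cased, IUPAC-validated."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise FormatError(
                f"{path}: record with empty id near line "
                f"{_find_line(path, '')}"
            )
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            ch = sorted(bad)[0]
            raise FormatError(
                f"{path}: non-IUPAC character {ch!r} in record "
                f"{rec.id!r} (line {_find_line(path, rec.id, ch)})"
            )
        rec = SeqRecord(Seq(seq), id=rec.id, description=rec.description)
        records.append(rec)
    return records


def write_fasta(records, path) -> None:
    """Write records wrapped at 70 columns."""
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)


def read_features_tsv(path) -> list:
    """Feature table: name, class, start, end, strand (1-based
    inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "class", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: feature table missing columns {sorted(missing)}"
        )
    return [
        GeneFeature(
            name=str(r.name_), cls=str(r.cls), start=int(r.start),
            end=int(r.end), strand=str(r.strand),
        )
        for r in df.rename(
            columns={"name": "name_", "class": "cls"}
        ).itertuples()
    ]


def write_features_tsv(features, path) -> None:
    rows = [
        {"name": f.name, "class": f.cls, "start": f.start, "end": f.end,
         "strand": f.strand}
        for f in features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gff3(genome: AnnotatedGenome, path, source="mitomine") -> None:
    lines = ["##gff-version 3"]
    for f in genome.features:
        if f.cls not in GFF3_TYPES:
            raise FormatError(f"unknown feature class {f.cls!r}")
        if f.unrecovered:
            continue
        strand = "+" if f.strand == "L" else "-"
        attrs = f"ID={f.name};Name={f.name}"
        if f.incomplete:
            attrs += ";partial=true"
        lines.append(
            "\t".join(
                [
                    genome.name, source, GFF3_TYPES[f.cls], str(f.start),
                    str(f.end), ".", strand, ".", attrs,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_feature_block(genome: AnnotatedGenome, path) -> None:
    """GenBank-style FEATURES block (the block only, not a full record)."""
    kind = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
            "control": "D-loop"}
    lines = ["FEATURES             Location/Qualifiers"]
    for f in genome.features:
        if f.unrecovered:
            continue
        loc = f"{f.start}..{f.end}"
        if f.strand == "H":
            loc = f"complement({loc})"
        lines.append(f"     {kind[f.cls]:<16}{loc}")
        lines.append(f'                     /gene="{f.name}"')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_newick(tree, path, include_support: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(include_support=include_support) + "\n")


def _fmt2(x: float) -> str:
    import math
    from decimal import ROUND_HALF_UP, Decimal

    x = float(x)
    if math.isnan(x):
        return "NA"
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def write_matrix_square_tsv(matrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.labels) + "\n")
        for i, lab in enumerate(matrix.labels):
            vals = [_fmt2(matrix.values[i, j])
                    for j in range(len(matrix.labels))]
            fh.write(lab + "\t" + "\t".join(vals) + "\n")


def write_matrix_lower_tsv(matrix, path) -> None:
    """Lower-triangular layout, the shape divergence tables are printed
    in."""
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.labels[:-1]) + "\n")
        for i, lab in enumerate(matrix.labels):
            vals = [_fmt2(matrix.values[i, j]) for j in range(i)]
            fh.write(lab + ("\t" if vals else "") + "\t".join(vals) + "\n")
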