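"""End-to-end orchestration: mine -> consensus -> annotate -> compose ->
distance/tree, driven by a single YAML config, with a machine-readable
run manifest.  Reruns with the same config reproduce byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

import Bio
import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_genome, gene_table
from .composition import composition_report, format_report
from .consensus import build_consensus, gap_report
from .core import AnnotatedGenome, MitomineError, ValidationError
from .divergence import bootstrap_support, distance_matrix, nj_tree
from .io import (
    read_fasta,
    read_features_tsv,
    write_fasta,
    write_gff3,
    write_matrix_lower_tsv,
    write_matrix_square_tsv,
    write_newick,
)
from .mining import MiningParams, mine_contigs, write_hits_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_genome"]


class PipelineError(MitomineError):
    def __init__(self, stage: str, last_artifact: str, cause: Exception):
        self.stage = stage
        self.last_artifact = last_artifact
        super().__init__(
            f"stage {stage!r} failed (last good artifact: "
            f"{last_artifact or 'none'}): {cause}"
        )


@dataclass
class PipelineConfig:
    reference_fasta: str
    reference_features: str
    contig_fastas: list
    outdir: str
    mining: MiningParams = field(default_factory=MiningParams)
    annotation_window: int = 18
    divergence_mode: str = "whole"
    divergence_gene: str = None
    deletion: str = "pairwise"
    bootstrap: int = 100
    seed: int = 0
    comparators: list = field(default_factory=list)  # {name, fasta, features}
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ref = raw.get("reference", {})
        div = raw.get("divergence", {})
        cfg = cls(
            reference_fasta=ref.get("fasta", ""),
            reference_features=ref.get("features", ""),
            contig_fastas=list(raw.get("contigs", [])),
            outdir=raw.get("outdir", "run"),
            mining=MiningParams(**raw.get("mining", {})),
            annotation_window=raw.get("annotation", {}).get("window", 18),
            divergence_mode=div.get("mode", "whole"),
            divergence_gene=div.get("gene"),
            deletion=div.get("deletion", "pairwise"),
            bootstrap=div.get("bootstrap", 100),
            seed=div.get("seed", 0),
            comparators=list(div.get("comparators", [])),
            log_level=raw.get("log_level", "INFO"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.reference_fasta, self.reference_features]
        paths += list(self.contig_fastas)
        for c in self.comparators:
            paths += [c.get("fasta", ""), c.get("features", "")]
        for p in paths:
            if not p or not os.path.exists(p):
                raise ValidationError(f"missing input path: {p!r}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")


def load_genome(fasta_path, features_path, name=None) -> AnnotatedGenome:
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValidationError(
            f"{fasta_path}: expected exactly one genome record, found "
            f"{len(records)}"
        )
    feats = read_features_tsv(features_path)
    g = AnnotatedGenome(
        seq=str(records[0].seq),
        features=feats,
        name=name or records[0].id,
    )
    g.validate()
    return g


def run_pipeline(config: PipelineConfig) -> str:
    """Execute every stage; returns the run directory path."""
    config.validate()
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda n: os.path.join(config.outdir, n)  # noqa: E731
    artifacts = []
    last = ""

    def stage(name, fn):
        nonlocal last
        logger.info("stage %s", name)
        try:
            result = fn()
        except Exception as e:  # re-raise with stage context
            raise PipelineError(name, last, e) from e
        if artifacts:
            last = artifacts[-1]
        return result

    def _load():
        reference = load_genome(
            config.reference_fasta, config.reference_features,
            name="reference",
        )
        contigs = {}
        for path in config.contig_fastas:
            for rec in read_fasta(path):
                if rec.id in contigs:
                    raise ValidationError(f"duplicate contig id {rec.id!r}")
                contigs[rec.id] = str(rec.seq)
        return reference, contigs

    reference, contigs = stage("load", _load)

    def _mine():
        hits = mine_contigs(reference, contigs, config.mining)
        write_hits_tsv(hits, out("hits.tsv"))
        artifacts.append(out("hits.tsv"))
        return hits

    hits = stage("mine", _mine)

    def _consensus():
        result = build_consensus(hits, contigs, reference, config.mining)
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        write_fasta(
            [SeqRecord(Seq(result.seq), id="consensus", description="")],
            out("consensus.fa"),
        )
        pd.DataFrame(
            {"position": np.arange(1, len(result.seq) + 1),
             "depth": result.depth}
        ).to_csv(out("depth.tsv"), sep="\t", index=False)
        gap_report(result, reference).to_csv(
            out("gaps.tsv"), sep="\t", index=False
        )
        artifacts.extend([out("consensus.fa"), out("depth.tsv"),
                          out("gaps.tsv")])
        return result

    cons = stage("consensus", _consensus)

    def _annotate():
        annotated = annotate_genome(
            cons.seq, reference, window=config.annotation_window,
            name="consensus",
        )
        gene_table(annotated).to_csv(
            out("genes.tsv"), sep="\t", index=False
        )
        write_gff3(annotated, out("genes.gff3"))
        artifacts.extend([out("genes.tsv"), out("genes.gff3")])
        return annotated

    annotated = stage("annotate", _annotate)

    def _compose():
        report = format_report(composition_report(annotated))
        report.to_csv(out("composition.tsv"), sep="\t", index=False,
                      float_format="%.2f")
        artifacts.append(out("composition.tsv"))
        return report

    stage("compose", _compose)

    if config.comparators:

        def _distance():
            taxa = [annotated]
            for c in config.comparators:
                taxa.append(
                    load_genome(c["fasta"], c["features"], name=c["name"])
                )
            matrix = distance_matrix(
                taxa, mode=config.divergence_mode,
                gene=config.divergence_gene, deletion=config.deletion,
            )
            write_matrix_square_tsv(matrix, out("distances.tsv"))
            write_matrix_lower_tsv(matrix, out("distances_lower.tsv"))
            artifacts.extend(
                [out("distances.tsv"), out("distances_lower.tsv")]
            )
            return taxa, matrix

        def _tree(taxa, matrix):
            if matrix.undefined_pairs():
                logger.warning("undefined distances; skipping tree")
                return None
            if len(taxa) < 3:
                logger.warning(
                    "only %d taxa; neighbor joining needs 3, skipping tree",
                    len(taxa),
                )
                return None
            if config.bootstrap > 0:
                # bootstrap over the same truncated sequences as the matrix
                from .divergence import _extract_sequences

                _, seqs = _extract_sequences(
                    taxa, config.divergence_mode, config.divergence_gene
                )
                tree = bootstrap_support(
                    seqs, [t.name for t in taxa], b=config.bootstrap,
                    seed=config.seed,
                )
            else:
                tree = nj_tree(matrix)
            write_newick(tree, out("tree.nwk"))
            artifacts.append(out("tree.nwk"))
            return tree

        taxa, matrix = stage("distance", _distance)
        stage("tree", lambda: _tree(taxa, matrix))

    def _manifest():
        manifest = {
            "mitomine_version": __version__,
            "biopython_version": Bio.__version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "bootstrap": config.bootstrap,
            "mining": vars(config.mining).copy(),
            "annotation_window": config.annotation_window,
            "divergence_mode": config.divergence_mode,
            "divergence_gene": config.divergence_gene,
            "deletion": config.deletion,
            "inputs": {
                "reference_fasta": config.reference_fasta,
                "reference_features": config.reference_features,
                "contig_fastas": list(config.contig_fastas),
            },
            "artifacts": artifacts,
        }
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        artifacts.append(out("manifest.json"))

    stage("manifest", _manifest)
    return config.outdir
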