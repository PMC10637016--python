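"""Shared fixtures: one synthetic study, built once per session.

The simulated conditions mirror the study design the pipeline targets:
a 37-region circular reference mitogenome, six tissue-replicate contig
libraries (androgen gland / hepatopancreas / muscle x 2), and a
control-region exclusion emulating the D-loop's absence from mature
transcripts.
"""

import pytest
from hypothesis import HealthCheck, settings

from mitomine.consensus import build_consensus
from mitomine.mining import mine_contigs
from mitomine.synth import (
    MutationModel,
    build_reference,
    default_layout,
    default_library_specs,
    evolve_genome,
    simulate_library,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _contig_dict(genome, specs):
    contigs = {}
    for spec in specs:
        for rec in simulate_library(genome, spec):
            contigs[rec.id] = str(rec.seq)
    return contigs


@pytest.fixture(scope="session")
def reference():
    return build_reference(default_layout(), seed=7)


@pytest.fixture(scope="session")
def full_run(reference):
    """Zero-divergence, error-free, full-coverage run (no exclusions)."""
    contigs = _contig_dict(
        reference, default_library_specs(excluded=(), seed=3, n_contigs=40)
    )
    hits = mine_contigs(reference, contigs)
    result = build_consensus(hits, contigs, reference)
    return {"contigs": contigs, "hits": hits, "consensus": result}


@pytest.fixture(scope="session")
def gap_run(reference):
    """Zero-divergence run with the control region excluded (the
    transcriptome D-loop gap)."""
    contigs = _contig_dict(
        reference,
        default_library_specs(excluded=("D-loop",), seed=5, n_contigs=40),
    )
    hits = mine_contigs(reference, contigs)
    result = build_consensus(hits, contigs, reference)
    return {"contigs": contigs, "hits": hits, "consensus": result}


@pytest.fixture(scope="session")
def diverged_run(reference):
    """Congener-divergence run: target evolved at d=0.1, kappa=2,
    control region excluded."""
    target = evolve_genome(
        reference, MutationModel(d_sim=0.1, kappa=2.0, seed=11)
    )
    contigs = _contig_dict(
        target,
        default_library_specs(excluded=("D-loop",), seed=5, n_contigs=40),
    )
    hits = mine_contigs(reference, contigs)
    result = build_consensus(hits, contigs, reference)
    return {
        "target": target, "contigs": contigs, "hits": hits,
        "consensus": result,
    }
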