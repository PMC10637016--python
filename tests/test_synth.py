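"""Synthetic-data generator: layouts, reference genomes, K2P evolution,
contig libraries."""

import numpy as np
import pytest

from mitomine.composition import base_composition
from mitomine.core import INVERTEBRATE_MITO_TABLE, ValidationError, revcomp
from mitomine.divergence import count_substitutions, k2p_distance
from mitomine.synth import (
    GenerationError,
    GenomeLayout,
    LibrarySpec,
    MutationModel,
    RegionSpec,
    build_reference,
    default_layout,
    default_library_specs,
    evolve_genome,
    simulate_library,
)

STOPS = set(INVERTEBRATE_MITO_TABLE.stop_codons)


def small_layout():
    return GenomeLayout(
        regions=[
            RegionSpec("geneA", "PCG", 300, "L"),
            RegionSpec("trnX", "tRNA", 60, "L"),
            RegionSpec("rrnS", "rRNA", 197, "L"),
            RegionSpec("ctl", "control", 3, "L"),
        ]
    )


class TestLayout:
    def test_regions_tile_by_construction(self):
        g = build_reference(small_layout(), seed=7)
        assert len(g) == 560
        coords = [(f.start, f.end) for f in g.features]
        assert coords == [(1, 300), (301, 360), (361, 557), (558, 560)]

    @pytest.mark.parametrize(
        "bad",
        [
            [RegionSpec("a", "PCG", 301, "L"),
             RegionSpec("c", "control", 10, "L")],        # PCG not %3
            [RegionSpec("a", "rRNA", 100, "L")],          # no control
            [RegionSpec("a", "rRNA", 100, "L"),
             RegionSpec("a", "control", 10, "L")],        # duplicate name
            [RegionSpec("a", "rRNA", 0, "L"),
             RegionSpec("c", "control", 10, "L")],        # zero length
        ],
    )
    def test_invalid_layouts_rejected(self, bad):
        with pytest.raises(ValidationError):
            GenomeLayout(regions=bad)

    def test_default_layout_mirrors_mitogenome_structure(self, reference):
        feats = reference.features
        assert len(feats) == 37
        assert sum(f.strand == "H" for f in feats) == 1
        assert feats[0].name == "COI"  # linearized at the COI start
        by_cls = {}
        for f in feats:
            by_cls[f.cls] = by_cls.get(f.cls, 0) + 1
        assert by_cls == {"PCG": 13, "tRNA": 21, "rRNA": 2, "control": 1}


class TestBuildReference:
    def test_at_fraction_near_target(self, reference):
        at = base_composition(reference.seq)["AT"]
        assert abs(at - 61.0) < 2.0

    def test_pcgs_have_clean_reading_frames(self, reference):
        for f in reference.features:
            if f.cls != "PCG":
                continue
            seq = reference.feature_seq(f.name)
            assert seq[:3] == "ATG"
            assert seq[-3:] in STOPS
            internal = {seq[i : i + 3] for i in range(3, len(seq) - 3, 3)}
            assert not internal & STOPS

    def test_deterministic_under_fixed_seed(self):
        a = build_reference(small_layout(), seed=42)
        b = build_reference(small_layout(), seed=42)
        assert a.seq == b.seq
        assert build_reference(small_layout(), seed=43).seq != a.seq


class TestEvolve:
    def test_zero_divergence_is_identity(self, reference):
        ev = evolve_genome(reference, MutationModel(d_sim=0.0, seed=1))
        assert ev.seq == reference.seq
        assert ev.meta["substitutions"] == 0

    def test_substitution_count_conservation(self, reference):
        ev = evolve_genome(reference, MutationModel(d_sim=0.1, seed=2))
        mismatches = sum(a != b for a, b in zip(reference.seq, ev.seq))
        assert mismatches == ev.meta["substitutions"]
        assert [f.name for f in ev.features] == [
            f.name for f in reference.features
        ]

    def test_high_kappa_suppresses_transversions(self, reference):
        ev = evolve_genome(
            reference,
            MutationModel(d_sim=0.05, kappa=1e6, seed=3,
                          preserve_orfs=False),
        )
        counts = count_substitutions(reference.seq, ev.seq)
        assert counts.v == 0
        assert counts.s > 0

    def test_saturating_divergence_warns(self, reference):
        with pytest.warns(UserWarning, match="saturates"):
            evolve_genome(reference, MutationModel(d_sim=5.0, seed=4))

    def test_k2p_recovery_across_seeds(self):
        """Monte-Carlo parameter recovery on a 10-kb genome."""
        layout = GenomeLayout(
            regions=[RegionSpec("rrn", "rRNA", 10000, "L"),
                     RegionSpec("ctl", "control", 100, "L")]
        )
        hits = 0
        for s in range(100):
            g = build_reference(layout, seed=500 + s)
            ev = evolve_genome(g, MutationModel(d_sim=0.2, kappa=2.0,
                                                seed=900 + s))
            d = k2p_distance(count_substitutions(g.seq, ev.seq))
            hits += abs(d - 0.2) <= 0.02
        assert hits >= 95

    def test_orf_preservation_keeps_frames_clean(self, reference):
        ev = evolve_genome(reference, MutationModel(d_sim=0.2, seed=6))
        for f in ev.features:
            if f.cls != "PCG":
                continue
            seq = ev.feature_seq(f.name)
            internal = {seq[i : i + 3] for i in range(3, len(seq) - 3, 3)}
            assert not internal & STOPS


class TestSimulateLibrary:
    def test_exact_contig_is_genome_substring(self, reference):
        spec = LibrarySpec(library_id="AG1", n_contigs=20, min_length=200,
                           max_length=900, seed=8)
        for rec in simulate_library(reference, spec):
            s = str(rec.seq)
            doubled = reference.seq + reference.seq  # circular substrings
            assert s in doubled or revcomp(s) in doubled
            assert rec.id.startswith("AG1|contig")

    def test_footprints_exclude_control_exactly(self, reference):
        spec = LibrarySpec(
            library_id="HEP1", n_contigs=400, min_length=200,
            max_length=1200, excluded=("D-loop",), seed=9,
        )
        _, fps = simulate_library(reference, spec, return_footprints=True)
        ctl = reference.feature("D-loop")
        L = len(reference)
        covered = np.zeros(L, dtype=bool)
        for start, length in fps:
            for p in range(start - 1, start - 1 + length):
                covered[p % L] = True
        ctl_mask = np.zeros(L, dtype=bool)
        ctl_mask[ctl.start - 1 : ctl.end] = True
        assert not (covered & ctl_mask).any()
        # high coverage: everything outside the control interval covered
        assert covered.sum() == L - ctl.size

    def test_unknown_excluded_region_rejected(self, reference):
        with pytest.raises(GenerationError, match="nosuch"):
            simulate_library(
                reference,
                LibrarySpec(library_id="X", excluded=("nosuch",), seed=1),
            )

    def test_oversized_min_length_rejected(self, reference):
        allowed = len(reference) - reference.feature("D-loop").size
        with pytest.raises(GenerationError, match="exceeds"):
            simulate_library(
                reference,
                LibrarySpec(
                    library_id="X", min_length=allowed + 1,
                    max_length=allowed + 2, excluded=("D-loop",), seed=1,
                ),
            )

    def test_six_libraries_with_distinct_ids(self, reference):
        specs = default_library_specs(seed=4, n_contigs=5)
        assert len(specs) == 6
        ids = set()
        for spec in specs:
            for rec in simulate_library(reference, spec):
                assert rec.id not in ids
                ids.add(rec.id)
        libs = {i.split("|")[0] for i in ids}
        assert libs == {"AG1", "AG2", "HEP1", "HEP2", "MUS1", "MUS2"}

    def test_determinism(self, reference):
        spec = LibrarySpec(library_id="MUS1", n_contigs=10, seed=12,
                           error_rate=0.01)
        a = simulate_library(reference, spec)
        b = simulate_library(reference, spec)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_error_rate_changes_bases(self, reference):
        clean = simulate_library(
            reference, LibrarySpec(library_id="A", n_contigs=5, seed=13)
        )
        noisy = simulate_library(
            reference,
            LibrarySpec(library_id="A", n_contigs=5, seed=13,
                        error_rate=0.05),
        )
        diffs = sum(
            a != b
            for ra, rb in zip(clean, noisy)
            for a, b in zip(str(ra.seq), str(rb.seq))
        )
        assert diffs > 0
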