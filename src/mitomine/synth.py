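"""Synthetic mitogenome and transcriptome-contig generator.

Everything downstream of raw-read assembly is testable offline with the
objects built here: a circular reference mitogenome with a realistic
37-region gene order (13 protein-coding genes, 21 tRNAs, 2 rRNAs and one
control region), a congener-like target genome diverged from it under the
Kimura two-parameter substitution process, and per-tissue contig libraries
that emulate polycistronic mitochondrial transcripts — including the
hallmark failure mode of transcriptome-based mitogenome recovery, the
missing control region (D-loop), which is absent from mature transcripts.

Coordinates in all outputs are 1-based inclusive, matching the rest of the
package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    FEATURE_CLASSES,
    INVERTEBRATE_MITO_TABLE,
    AnnotatedGenome,
    GeneFeature,
    MitomineError,
    ValidationError,
    revcomp,
)

__all__ = [
    "RegionSpec",
    "GenomeLayout",
    "MutationModel",
    "LibrarySpec",
    "GenerationError",
    "default_layout",
    "build_reference",
    "evolve_genome",
    "k2p_event_probabilities",
    "simulate_library",
    "simulate_libraries",
    "default_library_specs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = set(INVERTEBRATE_MITO_TABLE.stop_codons)  # {"TAA", "TAG"}


class GenerationError(MitomineError):
    """Raised when a library spec cannot be satisfied by the genome."""


@dataclass(frozen=True)
class RegionSpec:
    name: str
    cls: str
    length: int
    strand: str = "L"


@dataclass
class GenomeLayout:
    """Ordered, gap-free, overlap-free region plan for a circular genome."""

    regions: list
    at_fraction: float = 0.61

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.regions:
            raise ValidationError("layout has no regions")
        if not 0.0 < self.at_fraction < 1.0:
            raise ValidationError("at_fraction must lie in (0, 1)")
        names = set()
        n_control = 0
        for r in self.regions:
            if r.length < 1:
                raise ValidationError(f"region {r.name!r}: length < 1")
            if r.cls not in FEATURE_CLASSES:
                raise ValidationError(f"region {r.name!r}: class {r.cls!r}")
            if r.strand not in ("L", "H"):
                raise ValidationError(f"region {r.name!r}: strand {r.strand!r}")
            if r.name in names:
                raise ValidationError(f"region {r.name!r}: duplicate name")
            names.add(r.name)
            if r.cls == "control":
                n_control += 1
            if r.cls == "PCG" and r.length % 3:
                raise ValidationError(
                    f"region {r.name!r}: PCG length {r.length} not a "
                    "multiple of 3"
                )
        if n_control != 1:
            raise ValidationError(
                f"layout must contain exactly one control region "
                f"(found {n_control})"
            )

    @property
    def genome_length(self) -> int:
        return sum(r.length for r in self.regions)


def default_layout(at_fraction: float = 0.61) -> GenomeLayout:
    """Gene order and sizes of a *Macrobrachium*-style mitogenome.

    13 PCGs, 21 tRNAs, 2 rRNAs and a 793-bp control region, all on the
    light strand except tRNA-Gln (heavy strand); genome linearized at the
    COI start, total 15,527 bp.
    """
    t, P, R, C = "tRNA", "PCG", "rRNA", "control"
    rows = [
        ("COI", P, 1560, "L"),
        ("tRNA-Leu(L1)", t, 30, "L"),
        ("COII", P, 696, "L"),
        ("tRNA-Lys", t, 70, "L"),
        ("tRNA-Asp", t, 61, "L"),
        ("ATP8", P, 168, "L"),
        ("ATP6", P, 675, "L"),
        ("COIII", P, 789, "L"),
        ("tRNA-Gly", t, 71, "L"),
        ("ND3", P, 366, "L"),
        ("tRNA-Ala", t, 63, "L"),
        ("tRNA-Arg", t, 66, "L"),
        ("tRNA-Asn", t, 65, "L"),
        ("tRNA-Ser(S1)", t, 67, "L"),
        ("tRNA-Glu", t, 69, "L"),
        ("tRNA-Phe", t, 65, "L"),
        ("ND5", P, 1707, "L"),
        ("tRNA-His", t, 83, "L"),
        ("ND4", P, 1335, "L"),
        ("ND4L", P, 300, "L"),
        ("tRNA-Thr", t, 55, "L"),
        ("tRNA-Pro", t, 66, "L"),
        ("ND6", P, 528, "L"),
        ("Cytb", P, 1137, "L"),
        ("tRNA-Ser(S2)", t, 85, "L"),
        ("ND1", P, 939, "L"),
        ("tRNA-Leu(L2)", t, 78, "L"),
        ("16S", R, 1297, "L"),
        ("tRNA-Val", t, 66, "L"),
        ("12S", R, 846, "L"),
        ("D-loop", C, 793, "L"),
        ("tRNA-Gln", t, 67, "H"),
        ("tRNA-Met", t, 70, "L"),
        ("ND2", P, 996, "L"),
        ("tRNA-Trp", t, 69, "L"),
        ("tRNA-Cys", t, 63, "L"),
        ("tRNA-Tyr", t, 66, "L"),
    ]
    return GenomeLayout(
        regions=[RegionSpec(*r) for r in rows], at_fraction=at_fraction
    )


def _random_bases(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p)


_CODON_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pcg_codons(rng: np.random.Generator, n_codons: int, at: float) -> str:
    """Random protein-coding sequence: ATG start, TAA/TAG stop, no
    internal in-frame stop under the invertebrate mitochondrial code."""
    mid = n_codons - 2
    arr = _random_bases(rng, 3 * mid, at).reshape(mid, 3)
    # reject the two true stop codons (TAA=300/302 in base-4 with T=3,A=0,G=2)
    stop_rows = np.array([[3, 0, 0], [3, 0, 2]])
    while True:
        bad = (arr[:, None, :] == stop_rows[None, :, :]).all(-1).any(-1)
        if not bad.any():
            break
        arr[bad] = _random_bases(rng, 3 * int(bad.sum()), at).reshape(-1, 3)
    body = b"".join(_BASES[arr].tobytes().split()).decode()
    stop = "TAA" if rng.random() < 0.5 else "TAG"
    return "ATG" + body + stop


def build_reference(layout: GenomeLayout, seed: int) -> AnnotatedGenome:
    """Generate an annotated reference genome realizing ``layout``.

    Deterministic under a fixed seed.  Features tile the genome with zero
    intergenic space; every PCG starts with ATG, ends with TAA/TAG and is
    free of internal in-frame stops.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    parts = []
    features = []
    pos = 1
    for r in layout.regions:
        if r.cls == "PCG":
            s = _pcg_codons(rng, r.length // 3, layout.at_fraction)
            if r.strand == "H":
                s = revcomp(s)
        else:
            idx = _random_bases(rng, r.length, layout.at_fraction)
            s = _BASES[idx].tobytes().decode()
        parts.append(s)
        features.append(
            GeneFeature(
                name=r.name, cls=r.cls, start=pos, end=pos + r.length - 1,
                strand=r.strand,
            )
        )
        pos += r.length
    g = AnnotatedGenome(
        seq="".join(parts), features=features, circular=True, name="reference"
    )
    g.validate()
    return g


@dataclass(frozen=True)
class MutationModel:
    """Kimura-1980 substitution model for genome evolution.

    ``d_sim`` is the expected number of substitutions per site and
    ``kappa`` the transition/transversion *rate* ratio (alpha/beta).
    With ``preserve_orfs`` (default), substitutions that would create an
    internal in-frame stop codon in a protein-coding gene are reverted —
    a minimal stand-in for purifying selection, keeping the evolved
    genome annotatable like a real congener.
    """

    d_sim: float = 0.2
    kappa: float = 2.0
    seed: int = 0
    preserve_orfs: bool = True

    def __post_init__(self) -> None:
        if self.d_sim < 0:
            raise ValidationError("d_sim must be >= 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")


def k2p_event_probabilities(d_sim: float, kappa: float):
    """(p_same, p_transition, p_each_transversion) after divergence d_sim.

    With transition rate alpha and per-transversion rate beta,
    d = (alpha + 2 beta) t and kappa = alpha/beta; the finite-time change
    probabilities follow from the K2P transition matrix exponential.
    """
    bt = d_sim / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def evolve_genome(genome: AnnotatedGenome, model: MutationModel) -> AnnotatedGenome:
    """Substitution-only K2P evolution; coordinates are preserved.

    The realized substitution count is stored in ``meta['substitutions']``.
    A warning is emitted when the expected observed proportions leave the
    K2P estimable domain (1 - 2P - Q <= 0).
    """
    p_same, p_ts, p_tv = k2p_event_probabilities(model.d_sim, model.kappa)
    # in expectation 1-2P-Q = exp(-2(alpha+beta)t) stays positive, but
    # near zero the realized counts routinely cross the domain boundary
    if 1.0 - 2.0 * p_ts - 2.0 * p_tv <= 0.01:
        warnings.warn(
            "divergence effectively saturates the K2P estimator "
            "(expected 1 - 2P - Q <= 0.01); downstream distances may be "
            "undefined",
            stacklevel=2,
        )
    rng = np.random.default_rng(model.seed)
    idx = np.frombuffer(genome.seq.encode(), dtype="S1")
    code = np.zeros(len(idx), dtype=np.int8)
    for b, i in _CODON_IDX.items():
        code[idx == b.encode()] = i
    u = rng.random(len(code))
    out = code.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = u >= p_same + p_ts + p_tv
    out[ts_mask] = code[ts_mask] ^ 2      # A<->G, C<->T
    out[tv1_mask] = code[tv1_mask] ^ 1
    out[tv2_mask] = code[tv2_mask] ^ 3
    if model.preserve_orfs:
        _revert_internal_stops(genome, code, out)
    n_sub = int((out != code).sum())
    seq = _BASES[out].tobytes().decode()
    evolved = AnnotatedGenome(
        seq=seq,
        features=[f.copy() for f in genome.features],
        circular=genome.circular,
        name=f"{genome.name}_evolved",
        meta={"substitutions": n_sub, "d_sim": model.d_sim,
              "kappa": model.kappa},
    )
    return evolved


_STOP_CODES = {(3, 0, 0), (3, 0, 2)}  # TAA, TAG in A/C/G/T=0/1/2/3 coding


def _revert_internal_stops(genome, code: np.ndarray, out: np.ndarray) -> None:
    """Undo substitutions that create internal in-frame stops in PCGs.

    The reference has stop-free frames, so reverting the mutated sites of
    an offending codon always resolves it.
    """
    for f in genome.features:
        if f.cls != "PCG":
            continue
        lo, hi = f.start - 1, f.end  # 0-based half-open
        if f.strand == "H":
            # read on the reverse complement: codon positions run hi-1
            # down to lo, complemented (base ^ 3 complements A<->T, C<->G)
            idx = np.arange(hi - 1, lo - 1, -1)
            view = out[idx] ^ 3
        else:
            idx = np.arange(lo, hi)
            view = out[idx]
        ncod = len(idx) // 3
        for c in range(1, ncod - 1):  # internal codons only
            tri = tuple(int(b) for b in view[3 * c : 3 * c + 3])
            if tri in _STOP_CODES:
                for p in idx[3 * c : 3 * c + 3]:
                    out[p] = code[p]


@dataclass(frozen=True)
class LibrarySpec:
    """One cDNA library: tissue+replicate id plus contig sampling knobs.

    ``sampling='transcript'`` (default) emits contigs that are runs of
    adjacent complete features — the polycistronic-transcript picture —
    with (min_length, max_length) as soft bounds; ``sampling='uniform'``
    draws uniform lengths at uniform circular positions.  ``excluded``
    names features no contig may overlap (e.g. the control region, absent
    from mature transcripts).
    """

    library_id: str
    n_contigs: int = 80
    min_length: int = 200
    max_length: int = 1200
    error_rate: float = 0.0
    excluded: tuple = ()
    seed: int = 0
    sampling: str = "transcript"

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValidationError("error_rate must lie in [0, 1)")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValidationError("bad contig length range")
        if self.sampling not in ("transcript", "uniform"):
            raise ValidationError(f"unknown sampling {self.sampling!r}")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    code = np.zeros(len(seq), dtype=np.int8)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for b, i in _CODON_IDX.items():
        code[arr == b.encode()] = i
    hit = rng.random(len(code)) < rate
    shift = rng.integers(1, 4, size=len(code)).astype(np.int8)
    code[hit] = (code[hit] + shift[hit]) % 4
    return _BASES[code].tobytes().decode()


def _circular_substring(seq: str, start0: int, length: int) -> str:
    """0-based start, wrapping across the origin if needed."""
    L = len(seq)
    start0 %= L
    if start0 + length <= L:
        return seq[start0 : start0 + length]
    return seq[start0:] + seq[: start0 + length - L]


def _allowed_runs(genome: AnnotatedGenome, excluded: set):
    """Maximal circular runs of adjacent non-excluded features, as lists
    of feature indices."""
    feats = genome.features
    n = len(feats)
    allowed = [f.name not in excluded for f in feats]
    if all(allowed):
        return [list(range(n))], True  # single run covering the circle
    # rotate so position 0 is excluded, then split linearly
    first_bad = allowed.index(False) if False in allowed else 0
    order = [(first_bad + i) % n for i in range(n)]
    runs, cur = [], []
    for i in order:
        if allowed[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs, False


def simulate_library(
    genome: AnnotatedGenome, spec: LibrarySpec, return_footprints: bool = False
):
    """Simulate one library's contig set from ``genome``.

    Every contig is a substring of the genome or its reverse complement
    (probability 0.5 each), never overlapping an excluded feature, with
    independent per-base substitution errors at ``spec.error_rate``.
    Returns Bio.SeqRecord objects with ids ``<library_id>|contig<n>``.
    """
    excluded = set(spec.excluded)
    known = {f.name for f in genome.features}
    missing = excluded - known
    if missing:
        raise GenerationError(
            f"excluded region(s) not in genome: {sorted(missing)}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.sampling == "uniform":
        records, fps = _simulate_uniform(genome, spec, excluded, rng)
    else:
        records, fps = _simulate_transcript(genome, spec, excluded, rng)
    if return_footprints:
        return records, fps
    return records


def _simulate_transcript(genome, spec, excluded, rng):
    feats = genome.features
    runs, whole_circle = _allowed_runs(genome, excluded)
    max_run_bp = (
        len(genome)
        if whole_circle
        else max(sum(feats[i].size for i in run) for run in runs)
    )
    if spec.min_length > max_run_bp:
        raise GenerationError(
            f"min contig length {spec.min_length} exceeds the largest "
            f"non-excluded interval ({max_run_bp} bp)"
        )
    run_of = {}
    for ri, run in enumerate(runs):
        for i in run:
            run_of[i] = ri
    pickable = [i for run in runs for i in run]
    records, footprints = [], []
    for c in range(spec.n_contigs):
        anchor = pickable[int(rng.integers(len(pickable)))]
        run = runs[run_of[anchor]]
        pos_in_run = run.index(anchor)
        target = int(rng.integers(spec.min_length, spec.max_length + 1))
        lo = hi = pos_in_run
        total = feats[anchor].size
        # grow the transcript feature-by-feature toward the target length
        while total < target:
            can_lo = lo > 0 or (whole_circle and hi - lo + 1 < len(run))
            can_hi = hi < len(run) - 1 or (
                whole_circle and hi - lo + 1 < len(run)
            )
            if not can_lo and not can_hi:
                break
            go_lo = can_lo and (not can_hi or rng.random() < 0.5)
            if go_lo:
                lo -= 1
                total += feats[run[lo % len(run)]].size
            else:
                hi += 1
                total += feats[run[hi % len(run)]].size
        first = feats[run[lo % len(run)]]
        start0 = first.start - 1
        seq = _circular_substring(genome.seq, start0, total)
        footprints.append((start0 % len(genome) + 1, total))
        seq = _apply_errors(seq, spec.error_rate, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        records.append(_record(spec.library_id, c + 1, seq))
    return records, footprints


def _simulate_uniform(genome, spec, excluded, rng):
    L = len(genome)
    if not excluded:
        arcs = [(0, L)]  # (0-based start, length), whole circle
    else:
        runs, _ = _allowed_runs(genome, excluded)
        feats = genome.features
        arcs = []
        for run in runs:
            start0 = feats[run[0]].start - 1
            length = sum(feats[i].size for i in run)
            arcs.append((start0, length))
    if spec.min_length > max(a[1] for a in arcs):
        raise GenerationError(
            f"min contig length {spec.min_length} exceeds the largest "
            f"non-excluded interval ({max(a[1] for a in arcs)} bp)"
        )
    records, footprints = [], []
    for c in range(spec.n_contigs):
        clen = int(rng.integers(spec.min_length, spec.max_length + 1))
        feasible = [(s, al) for s, al in arcs if al >= clen]
        while not feasible:
            clen = int(rng.integers(spec.min_length, spec.max_length + 1))
            feasible = [(s, al) for s, al in arcs if al >= clen]
        weights = np.array([al - clen + 1 for _, al in feasible], dtype=float)
        k = int(rng.choice(len(feasible), p=weights / weights.sum()))
        s, al = feasible[k]
        wraps_whole = not excluded
        offset = int(rng.integers(0, al if wraps_whole else al - clen + 1))
        start0 = (s + offset) % L
        seq = _circular_substring(genome.seq, start0, clen)
        footprints.append((start0 + 1, clen))
        seq = _apply_errors(seq, spec.error_rate, rng)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        records.append(_record(spec.library_id, c + 1, seq))
    return records, footprints


def _record(library_id: str, n: int, seq: str) -> SeqRecord:
    rid = f"{library_id}|contig{n}"
    return SeqRecord(Seq(seq), id=rid, description="")


def simulate_libraries(genome: AnnotatedGenome, specs) -> dict:
    """Map of library id -> contig records for a list of LibrarySpecs."""
    out = {}
    for spec in specs:
        if spec.library_id in out:
            raise ValidationError(f"duplicate library id {spec.library_id!r}")
        out[spec.library_id] = simulate_library(genome, spec)
    return out


def default_library_specs(
    excluded=("D-loop",), seed: int = 0, n_contigs: int = 80,
    error_rate: float = 0.0,
) -> list:
    """Six libraries — androgen gland, hepatopancreas, muscle x 2
    replicates — mirroring the study design."""
    tissues = ("AG", "HEP", "MUS")
    specs = []
    for ti, tissue in enumerate(tissues):
        for rep in (1, 2):
            specs.append(
                LibrarySpec(
                    library_id=f"{tissue}{rep}",
                    n_contigs=n_contigs,
                    excluded=tuple(excluded),
                    error_rate=error_rate,
                    seed=seed * 1000 + ti * 10 + rep,
                )
            )
    return specs
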