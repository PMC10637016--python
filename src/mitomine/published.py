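"""Published reference values for *Macrobrachium* mitogenomes.

The gene map of the *M. amazonicum* mitogenome (GenBank ON513382.1,
14,960 bp, control region unrecovered) and the whole-mitogenome
Kimura-1980 divergence matrix among *Macrobrachium* congeners and two
outgroup caridean prawns, as printed in the literature.  These are
inputs for cross-checking this package's arithmetic and tree building
against published numbers — not outputs of the pipeline.

Coordinates are 1-based inclusive on the deposited sequence.
"""

from __future__ import annotations

import numpy as np

from .divergence import DistanceMatrix

__all__ = [
    "AMAZONICUM_GENES",
    "amazonicum_pcg_coordinates",
    "macrobrachium_k2p_matrix",
]

# name, class, start, end, strand  (PCG/tRNA/rRNA rows with published
# coordinates; the D-loop was not recovered and has none)
AMAZONICUM_GENES = [
    ("COI", "PCG", 1, 1560, "L"),
    ("tRNA-Leu(L1)", "tRNA", 1561, 1590, "L"),
    ("COII", "PCG", 1591, 2286, "L"),
    ("tRNA-Lys", "tRNA", 2285, 2354, "L"),
    ("tRNA-Asp", "tRNA", 2355, 2415, "L"),
    ("ATP8", "PCG", 2416, 2583, "L"),
    ("ATP6", "PCG", 2577, 3251, "L"),
    ("COIII", "PCG", 3256, 4044, "L"),
    ("tRNA-Gly", "tRNA", 4045, 4115, "L"),
    ("ND3", "PCG", 4116, 4481, "L"),
    ("tRNA-Ala", "tRNA", 4472, 4534, "L"),
    ("tRNA-Arg", "tRNA", 4534, 4599, "L"),
    ("tRNA-Asn", "tRNA", 4601, 4665, "L"),
    ("tRNA-Ser(S1)", "tRNA", 4666, 4732, "L"),
    ("tRNA-Glu", "tRNA", 4733, 4801, "L"),
    ("tRNA-Phe", "tRNA", 4801, 4865, "L"),
    ("ND5", "PCG", 4866, 6572, "L"),
    ("tRNA-His", "tRNA", 6573, 6655, "L"),
    # ND4's published end coordinate (7983) contradicts its published
    # size (1335 bp), its overlap with ND4L (-7) and the 11,196-bp PCG
    # total; end 7990 is the unique value consistent with all three.
    ("ND4", "PCG", 6656, 7990, "L"),
    ("ND4L", "PCG", 7984, 8283, "L"),
    ("tRNA-Thr", "tRNA", 8284, 8338, "L"),
    ("tRNA-Pro", "tRNA", 8338, 8403, "L"),
    ("ND6", "PCG", 8404, 8931, "L"),
    ("Cytb", "PCG", 8931, 10067, "L"),
    ("tRNA-Ser(S2)", "tRNA", 10068, 10158, "L"),
    ("ND1", "PCG", 10153, 11091, "L"),
    ("tRNA-Leu(L2)", "tRNA", 11092, 11169, "L"),
    ("16S", "rRNA", 11170, 12466, "L"),
    ("tRNA-Val", "tRNA", 12467, 12532, "L"),
    ("12S", "rRNA", 12533, 13378, "L"),
    ("tRNA-Ile", "tRNA", 13403, 13424, "L"),
    ("tRNA-Gln", "tRNA", 13452, 13518, "H"),
    ("tRNA-Met", "tRNA", 13698, 13767, "L"),
    ("ND2", "PCG", 13768, 14763, "L"),
    ("tRNA-Trp", "tRNA", 14762, 14830, "L"),
    ("tRNA-Cys", "tRNA", 14832, 14894, "L"),
    ("tRNA-Tyr", "tRNA", 14895, 14960, "L"),
]


def amazonicum_pcg_coordinates() -> dict:
    """Published PCG coordinates: gene -> (start, end)."""
    return {
        name: (start, end)
        for name, cls, start, end, _ in AMAZONICUM_GENES
        if cls == "PCG"
    }


_K2P_TAXA = [
    "M. amazonicum",
    "M. rosenbergii AY659990.1",
    "M. rosenbergii KY865098.1",
    "M. nipponense HQ830201.1",
    "M. lanchesteri FJ797435.1",
    "M. bullatum KM978918.1",
    "E. carinicauda EF560650.1",
    "R. variabilis MH714460.1",
]

_K2P_LOWER = [
    [],
    [0.21],
    [0.21, 0.08],
    [0.21, 0.21, 0.21],
    [0.22, 0.17, 0.17, 0.20],
    [0.21, 0.21, 0.21, 0.18, 0.21],
    [0.35, 0.36, 0.36, 0.35, 0.35, 0.35],
    [0.36, 0.37, 0.37, 0.35, 0.36, 0.36, 0.39],
]


def macrobrachium_k2p_matrix() -> DistanceMatrix:
    """Published near-whole-mitogenome K2P divergences (8 taxa)."""
    n = len(_K2P_TAXA)
    values = np.zeros((n, n))
    for i, row in enumerate(_K2P_LOWER):
        for j, d in enumerate(row):
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(_K2P_TAXA), values=values)
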