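"""BI/BII backbone substates and base–phosphate hydrogen bonds.

The phosphodiester ε (C3'-O3') and ζ (O3'-P) torsions of B-DNA occupy
coupled rotamer combinations: BI = (ε trans, ζ gauche−), canonical B-DNA,
and BII = (ε gauche−, ζ trans).  Because the two states sit on opposite
sides of ε = ζ, the wrapped difference ε − ζ classifies them robustly
(BI ≈ −90°, BII ≈ +90°) without committing to hard rotamer-wheel cutoffs.
BII states are strongly coupled to the formation of a C8-H…O3' hydrogen
bond between a 3'-purine's C8-H group and the O3' of its 5'-phosphate; a
4 Å heavy-atom cutoff separates bonded from unbonded states, and the bond
cannot form when the 3' base is a pyrimidine (all RY steps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import wrap_signed
from .sequence import Occurrence, is_purine, complement
from .trajectory import SeriesTable

__all__ = [
    "torsion_wheel",
    "classify_bi_bii",
    "bii_occupancy",
    "hbond_state",
    "hbond_applicable",
    "conditional_association",
    "junction_context_map",
    "CouplingReport",
]

DEFAULT_HBOND_CUTOFF = 4.0  # Å, heavy-atom C8…O3'

#: Rotamer wheel bins (decision: thirds of the wheel centred on 60/180/300°).
_WHEEL_BINS = ((0.0, 120.0, "g+"), (120.0, 240.0, "t"), (240.0, 360.0, "g-"))


def torsion_wheel(angle_deg) -> str | np.ndarray:
    """Rotamer state of a torsion: g+ [0°,120°), t [120°,240°), g− [240°,360°)."""
    a = np.asarray(angle_deg, dtype=float) % 360.0
    out = np.where(a < 120.0, "g+", np.where(a < 240.0, "t", "g-"))
    return out.item() if out.ndim == 0 else out


def classify_bi_bii(epsilon, zeta) -> np.ndarray:
    """Classify snapshots as BI (False) or BII (True) from ε and ζ.

    BII iff the wrapped difference ε − ζ, mapped to (−180°, 180°], is
    strictly positive; ε = ζ falls to BI by convention.  Invariant to adding
    full turns to either torsion.
    """
    d = wrap_signed(np.asarray(epsilon, dtype=float) - np.asarray(zeta, dtype=float))
    return np.asarray(d) > 0.0


def atypical_wheel_fraction(epsilon, zeta) -> float:
    """Diagnostic: fraction of snapshots with ε or ζ in the g+ well (rare;
    such snapshots are still assigned by the ε−ζ sign rule)."""
    e = np.asarray(epsilon, dtype=float) % 360.0
    z = np.asarray(zeta, dtype=float) % 360.0
    atyp = (e < 120.0) | (z < 120.0)
    return float(np.mean(atyp)) if atyp.size else 0.0


def bii_occupancy(epsilon, zeta=None) -> float:
    """Percentage of snapshots in the BII state.

    Accepts either (ε, ζ) series or a pre-classified boolean series.
    """
    if zeta is None:
        states = np.asarray(epsilon, dtype=bool)
    else:
        states = classify_bi_bii(epsilon, zeta)
    if states.size == 0:
        raise ValueError("empty series")
    return 100.0 * float(np.mean(states))


def pooled_bii_occupancy(epsilon_w, zeta_w, epsilon_c, zeta_c) -> float:
    """BII occupancy pooling both strands of a self-symmetric step, whose
    strands are physically indistinguishable."""
    w = classify_bi_bii(epsilon_w, zeta_w)
    c = classify_bi_bii(epsilon_c, zeta_c)
    return 100.0 * float(np.mean(np.concatenate([w, c])))


def hbond_applicable(step: str, strand: str = "W") -> bool:
    """Whether the C8-H…O3' bond can form at a junction on a given strand:
    requires a purine 3' base along that strand's reading of the step."""
    s = step.upper()
    if len(s) != 2:
        raise ValueError("a step is a 2-letter sequence")
    three_prime = s[1] if strand == "W" else complement(s[0])
    return is_purine(three_prime)


def hbond_state(c8_o3_distance, cutoff: float = DEFAULT_HBOND_CUTOFF) -> np.ndarray:
    """Bonded flag per snapshot: bonded iff distance < cutoff (strict).

    Distances must be non-negative; NaN (inapplicable junction) raises.
    """
    d = np.asarray(c8_o3_distance, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("C8–O3' distance absent (3'-pyrimidine junction?)")
    if np.any(d < 0):
        raise ValueError("negative distance")
    return d < cutoff


@dataclass(frozen=True)
class CouplingReport:
    """Conditional association between BII states and C8-H…O3' bonds."""

    p_hb_given_bii: float | None  # percent
    p_bii_given_hb: float | None  # percent
    table: np.ndarray  # 2x2 counts, rows BI/BII, cols unbonded/bonded
    n: int


def conditional_association(bii_series, hbond_series) -> CouplingReport:
    """Conditional relative frequencies P(HB|BII), P(BII|HB) in percent,
    plus the 2×2 contingency table (rows BI/BII, columns unbonded/bonded).

    A zero-count conditioning event yields None for that conditional.
    """
    b = np.asarray(bii_series, dtype=bool)
    h = np.asarray(hbond_series, dtype=bool)
    if b.shape != h.shape:
        raise ValueError("series must be aligned")
    table = np.array(
        [
            [np.sum(~b & ~h), np.sum(~b & h)],
            [np.sum(b & ~h), np.sum(b & h)],
        ],
        dtype=np.int64,
    )
    n_bii = table[1].sum()
    n_hb = table[:, 1].sum()
    p_hb_bii = 100.0 * table[1, 1] / n_bii if n_bii else None
    p_bii_hb = 100.0 * table[1, 1] / n_hb if n_hb else None
    return CouplingReport(p_hb_bii, p_bii_hb, table, int(b.size))


def junction_context_map(occurrence: Occurrence, n_levels: int) -> dict[str, tuple[int, str]]:
    """Resolve the six backbone segments around a central step.

    W and C are the two strands of the central junction of a tetranucleotide
    occurrence; W5'/W3' (C5'/C3') are the junctions adjacent in the 5' and 3'
    directions along the fragment's Watson (Crick) backbone.  Returns
    ``{label: (absolute junction index, absolute strand)}``, honouring the
    strand swap for Crick-read occurrences.
    """
    c = occurrence.start + 1  # central junction, absolute index
    if c - 1 < 1 or c + 1 > n_levels - 1:
        raise ValueError("occurrence too close to the oligomer edge")
    if occurrence.strand == "Watson":
        frag_w, frag_c = "W", "C"
        down, up = c - 1, c + 1  # 5' and 3' junctions along fragment-Watson
    else:
        frag_w, frag_c = "C", "W"
        down, up = c + 1, c - 1  # absolute indices reverse along the Crick reading
    return {
        "W5'": (down, frag_w),
        "W": (c, frag_w),
        "W3'": (up, frag_w),
        "C5'": (up, frag_c),
        "C": (c, frag_c),
        "C3'": (down, frag_c),
    }


def central_hbond_series(table: SeriesTable, occurrence: Occurrence, strand: str = "W"):
    """C8–O3' distance series of the central junction on a fragment strand
    (fragment-Watson by default); raises when inapplicable or absent."""
    c = occurrence.start + 1
    abs_strand = strand if occurrence.strand == "Watson" else ("C" if strand == "W" else "W")
    if not table.has("c8o3", c, abs_strand):
        raise KeyError(f"no C8–O3' distances at junction {c} strand {abs_strand}")
    return table.get("c8o3", c, abs_strand)
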