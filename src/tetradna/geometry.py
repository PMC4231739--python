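"""Frame-based helical parameters, torsions, sugar pucker and WC distances.

Helical parameters follow the Cambridge convention: each base carries a
right-handed orthonormal reference frame; a base-pair frame is the symmetric
mean of the Watson frame and the 180°-x-flipped Crick frame; inter-base-pair
parameters (shift, slide, rise / tilt, roll, twist) come from the symmetric
mid-frame decomposition of the transformation between two base-pair frames,
and intra-base-pair parameters (shear, stretch, stagger / buckle, propeller,
opening) from the same machinery applied across one pair.  With this
construction, swapping the Watson/Crick naming negates exactly shift, tilt,
shear and buckle and leaves the other parameters unchanged.

Rotational decomposition: the relative rotation between the two frames is
expressed as a rotation vector in the coordinates of the half-way (mid)
frame; its x, y, z components are tilt, roll and twist (or buckle, propeller,
opening).  The translation is the origin difference expressed in mid-frame
coordinates.  The construction is exactly invertible and gimbal-safe up to a
total rotation of 180°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._standard_bases import RING_ATOMS, STANDARD_BASES, WC_BONDS

__all__ = [
    "Frame",
    "InterBP",
    "IntraBP",
    "torsion",
    "pucker",
    "base_pair_frame",
    "inter_bp_params",
    "intra_bp_params",
    "reconstruct_frame",
    "wc_heavy_atom_distances",
    "fit_standard_frame",
    "read_pdb_residues",
]

_ORTHO_TOL = 1e-8

INTER_BP_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
INTRA_BP_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")


def wrap_signed(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees to (−180°, 180°]."""
    return -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)


def wrap_positive(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees to [0°, 360°)."""
    return np.asarray(angle) % 360.0


@dataclass(frozen=True)
class Frame:
    """A base or base-pair reference frame: origin (Å) and a right-handed
    orthonormal axis triad (columns x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        r = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("frame axes are left-handed (det < 0)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "axes", r)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def flipped(self) -> "Frame":
        """Frame rotated 180° about its own x axis (y, z negated)."""
        return Frame(self.origin, self.axes @ np.diag([1.0, -1.0, -1.0]))


@dataclass(frozen=True)
class InterBP:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


@dataclass(frozen=True)
class IntraBP:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.shear,
            self.stretch,
            self.stagger,
            self.buckle,
            self.propeller,
            self.opening,
        )


# ---------------------------------------------------------------------------
# Torsions and sugar pucker
# ---------------------------------------------------------------------------

def torsion(p1, p2, p3, p4) -> float:
    """IUPAC dihedral angle about the p2–p3 bond, in degrees on [0°, 360°).

    Zero for a cis (eclipsed) arrangement, 180° for trans; the sign follows
    the right-hand rule looking from p2 to p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-9:
            raise ValueError("degenerate geometry: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry: collinear consecutive points")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return float(wrap_positive(math.degrees(math.atan2(y, x))))


_PUCKER_DEN = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


def pucker(nu0: float, nu1: float, nu2: float, nu3: float, nu4: float) -> tuple[float | None, float]:
    """Pseudorotation phase and amplitude of a furanose ring.

    Altona–Sundaralingam parameterization of the five endocyclic torsions,
    ν_j = τ_m · cos(P + 144°·(j − 2)); returns (phase in [0°, 360°) or None
    when the ring is planar, amplitude ≥ 0 in degrees).
    """
    nus = [wrap_signed(v) for v in (nu0, nu1, nu2, nu3, nu4)]
    num = (nus[1] + nus[4]) - (nus[0] + nus[3])
    den = _PUCKER_DEN * nus[2]
    amp = math.hypot(num / _PUCKER_DEN, nus[2])
    if amp < 1e-6:
        return None, 0.0
    phase = math.degrees(math.atan2(num, den))
    return float(wrap_positive(phase)), float(amp)


def pucker_torsions(phase: float, amplitude: float) -> tuple[float, ...]:
    """Inverse parameterization: the five ring torsions for (P, τ_m)."""
    return tuple(
        amplitude * math.cos(math.radians(phase + 144.0 * (j - 2))) for j in range(5)
    )


# ---------------------------------------------------------------------------
# Frames and helical parameters
# ---------------------------------------------------------------------------

def _half_rotation(r_rel: np.ndarray) -> np.ndarray:
    rv = Rotation.from_matrix(r_rel).as_rotvec()
    return Rotation.from_rotvec(rv / 2.0).as_matrix()


def base_pair_frame(frame_w: Frame, frame_c: Frame, warn_threshold: float = 90.0):
    """Mean base-pair frame of a Watson and a Crick base frame.

    The Crick frame is first flipped 180° about its own x axis (so both
    frames' z axes point along the same helical direction), then the half-way
    rotation between the two frames is taken and origins are averaged.
    Returns ``(Frame, antiparallel_warning)`` where the flag is set when the
    frames remain misaligned by more than ``warn_threshold`` degrees after
    the flip.
    """
    fc = frame_c.flipped()
    r_rel = frame_w.axes.T @ fc.axes
    angle = math.degrees(np.linalg.norm(Rotation.from_matrix(r_rel).as_rotvec()))
    warning = angle > warn_threshold
    mid_axes = frame_w.axes @ _half_rotation(r_rel)
    origin = 0.5 * (frame_w.origin + fc.origin)
    return Frame(origin, mid_axes), warning


def _relative_params(frame1: Frame, frame2: Frame) -> tuple[float, ...]:
    """Symmetric mid-frame decomposition frame1 → frame2.

    Returns (dx, dy, dz, rx, ry, rz): translation of the origin difference in
    mid-frame coordinates and rotation-vector components (degrees) of the
    relative rotation, whose axis is shared by both end frames and the mid
    frame.
    """
    r_rel = frame1.axes.T @ frame2.axes
    rv = Rotation.from_matrix(r_rel).as_rotvec(degrees=True)
    mid = frame1.axes @ Rotation.from_rotvec(rv / 2.0, degrees=True).as_matrix()
    t = mid.T @ (frame2.origin - frame1.origin)
    return (float(t[0]), float(t[1]), float(t[2]), float(rv[0]), float(rv[1]), float(rv[2]))


def inter_bp_params(frame1: Frame, frame2: Frame) -> InterBP:
    """Inter-base-pair parameters between consecutive base-pair frames."""
    dx, dy, dz, rx, ry, rz = _relative_params(frame1, frame2)
    return InterBP(shift=dx, slide=dy, rise=dz, tilt=rx, roll=ry, twist=rz)


def intra_bp_params(frame_w: Frame, frame_c: Frame) -> IntraBP:
    """Intra-base-pair parameters between the two base frames of one pair.

    The Crick frame is flipped about its x axis first; translations are
    shear/stretch/stagger, rotations buckle/propeller/opening.
    """
    dx, dy, dz, rx, ry, rz = _relative_params(frame_w, frame_c.flipped())
    return IntraBP(shear=dx, stretch=dy, stagger=dz, buckle=rx, propeller=ry, opening=rz)


def reconstruct_frame(frame1: Frame, params: InterBP) -> Frame:
    """Inverse of :func:`inter_bp_params`: the frame2 that yields ``params``
    relative to ``frame1``.  Exact round trip by construction."""
    rv = np.array([params.tilt, params.roll, params.twist], dtype=float)
    half = Rotation.from_rotvec(rv / 2.0, degrees=True).as_matrix()
    full = Rotation.from_rotvec(rv, degrees=True).as_matrix()
    mid = frame1.axes @ half
    origin = frame1.origin + mid @ np.array([params.shift, params.slide, params.rise])
    return Frame(origin, frame1.axes @ full)


# ---------------------------------------------------------------------------
# Watson–Crick distances and frame fitting
# ---------------------------------------------------------------------------

def wc_heavy_atom_distances(
    pair_type: str,
    watson_atoms: dict[str, np.ndarray],
    crick_atoms: dict[str, np.ndarray],
) -> list[float]:
    """Heavy-atom donor–acceptor distances of the canonical hydrogen bonds.

    ``pair_type`` names the pair by its Watson base first (e.g. "AT", "GC",
    "CG"); A:T pairs have two canonical bonds, G:C pairs three.
    """
    pt = pair_type.upper()
    if pt not in WC_BONDS:
        raise ValueError(f"unknown pair type {pair_type!r}")
    out = []
    for wa, ca in WC_BONDS[pt]:
        if wa not in watson_atoms:
            raise KeyError(f"missing Watson-base atom {wa!r} for pair {pt}")
        if ca not in crick_atoms:
            raise KeyError(f"missing Crick-base atom {ca!r} for pair {pt}")
        out.append(float(np.linalg.norm(np.asarray(watson_atoms[wa]) - np.asarray(crick_atoms[ca]))))
    return out


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition moving → fixed.

    Returns (R, t, rmsd) with fixed ≈ moving @ R.T + t.
    """
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = fc - r @ mc
    moved = moving @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return r, t, rmsd


def fit_standard_frame(
    base_atoms: dict[str, np.ndarray], base_type: str
) -> tuple[Frame, float]:
    """Fit the standard base geometry to observed atoms; return its frame.

    The packaged standard geometry of ``base_type`` is rigidly superposed
    (least squares over the shared ring atoms) onto the observed coordinates;
    the standard frame (identity at the origin) transformed by the fitted
    motion is returned together with the superposition RMSD (Å).
    """
    bt = base_type.upper()
    if bt not in STANDARD_BASES:
        raise ValueError(f"unknown base type {base_type!r}")
    names = [a for a in RING_ATOMS[bt] if a in base_atoms]
    if len(names) < 3:
        raise ValueError(
            f"need at least 3 matched ring atoms for {bt}, got {len(names)}"
        )
    std = np.array([STANDARD_BASES[bt][a] for a in names], dtype=float)
    obs = np.array([np.asarray(base_atoms[a], dtype=float) for a in names])
    r, t, rmsd = _kabsch(std, obs)
    return Frame(t, r), rmsd


def read_pdb_residues(path) -> list[dict]:
    """Read a single-model PDB file into per-residue atom maps.

    Returns a list of ``{"name": res name, "chain": id, "number": resseq,
    "atoms": {atom name: xyz array}}`` for standard nucleotide residues.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("fixture", str(path))
    model = next(structure.get_models())
    residues = []
    for chain in model:
        for res in chain:
            atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float) for a in res}
            name = res.get_resname().strip()
            residues.append(
                {"name": name, "chain": chain.id, "number": res.get_id()[1], "atoms": atoms}
            )
    return residues
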