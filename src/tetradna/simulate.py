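"""Synthetic Markov-switching trajectory generator.

Real tetranucleotide statistics come from microsecond MD trajectories far too
large to ship, so this module generates per-snapshot parameter series with
the same *statistical* structure: per-context (wrapped-)Gaussian parameter
distributions, hidden-Markov switching between conformational substates with
distinct shift/slide/twist means, BI/BII backbone states with ε/ζ emitted
from the corresponding rotamer combinations, C8-H…O3' distances coupled to
the BII state so that the analysis recovers the target conditional
association, and rare Watson–Crick base-pair breaking events.

Substate dynamics are first-order Markov at one-snapshot resolution with a
configurable mean dwell (default ≈ 100 snapshots): occupancies and couplings
are what the analysis measures; kinetics are free parameters.

The BII ↔ hydrogen-bond coupling is parameterized by the two target
conditional probabilities P(HB|BII), P(BII|HB) plus the BII marginal.  The
implied 2×2 joint table is solved in closed form *through* the bonded /
unbonded distance-emission overlap at the 4 Å cutoff, so that the measured
conditionals (classifying by distance) equal the targets in expectation; the
solution is validated for feasibility when the generator is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .geometry import Frame, InterBP, reconstruct_frame
from .sequence import complement, is_purine, reverse_complement
from .trajectory import SeriesTable

__all__ = [
    "SubstateSpec",
    "ContextModel",
    "GeneratorSpec",
    "paper2014",
    "generate_series",
    "generate_frames",
]

INTER = ("shift", "slide", "rise", "tilt", "roll", "twist")

#: ε/ζ rotamer emission centres (degrees) for the two backbone states.
BI_BACKBONE = {"epsilon": (187.0, 10.0), "zeta": (265.0, 10.0)}  # ε t / ζ g−
BII_BACKBONE = {"epsilon": (250.0, 10.0), "zeta": (172.0, 10.0)}  # ε g− / ζ t

#: Context-independent backbone / sugar emissions (mean, SD, degrees).
COMMON_BACKBONE = {
    "alpha": (295.0, 10.0),
    "beta": (175.0, 12.0),
    "gamma": (55.0, 10.0),
    "chi": (250.0, 12.0),
    "phase": (140.0, 25.0),
    "amplitude": (38.0, 4.0),
}

#: Intra-BP and BP-axis emissions (mean, SD).  Propeller −11°, inclination
#: 7° and Xdisp −1.5 Å reproduce the sequence-averaged B-DNA structure.
INTRA_EMISSIONS = {
    "shear": (0.0, 0.3),
    "stretch": (0.0, 0.15),
    "stagger": (0.0, 0.4),
    "buckle": (0.0, 10.0),
    "propeller": (-11.0, 8.0),
    "opening": (2.0, 6.0),
}
AXIS_EMISSIONS = {
    "xdisp": (-1.5, 0.5),
    "ydisp": (0.0, 0.5),
    "inclination": (7.0, 5.0),
    "tip": (0.0, 5.0),
}


@dataclass(frozen=True)
class SubstateSpec:
    """One conformational substate: emission means/SDs for the six inter-BP
    parameters and (optional) coupled backbone-state probabilities."""

    label: str
    weight: float
    means: dict[str, float]
    sds: dict[str, float]
    watson_bii: float | None = None  # P(central Watson BII | substate)
    crick_bii: float | None = None
    flank3_bii: float | None = None  # P(each 3'-junction BII | substate)


@dataclass(frozen=True)
class ContextModel:
    """Substate set and switching timescale for one sequence context."""

    substates: tuple[SubstateSpec, ...]
    dwell: float = 100.0  # mean snapshots between resampling events

    def __post_init__(self):
        w = sum(s.weight for s in self.substates)
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"substate weights must sum to 1 (got {w})")
        if self.dwell < 1.0:
            raise ValueError("dwell must be >= 1 snapshot")

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.substates])

    def stationary_bii(self, strand: str) -> float | None:
        """Stationary central-junction BII probability on a strand, when the
        backbone state is substate-coupled; None when independent."""
        probs = [s.watson_bii if strand == "W" else s.crick_bii for s in self.substates]
        if any(p is None for p in probs):
            return None
        return float(np.dot(self.weights, probs))


@dataclass
class GeneratorSpec:
    """Full parameterization of the synthetic trajectory model."""

    contexts: dict[str, ContextModel] = field(default_factory=dict)
    default_context: ContextModel | None = None
    # BII ↔ C8-H…O3' hydrogen-bond coupling targets
    p_hb_given_bii: float = 0.90
    p_bii_given_hb: float = 0.87
    bonded_mu: float = 3.5
    bonded_sd: float = 0.2
    unbonded_mu: float = 4.8
    unbonded_sd: float = 0.4
    hbond_cutoff: float = 4.0
    # independent backbone chains (junction/strand not substate-coupled)
    default_bii: float = 0.15
    backbone_dwell: float = 100.0
    # Watson–Crick pairing
    wc_mu: float = 2.95
    wc_sd: float = 0.08
    wc_break_rate: float = 0.002
    wc_break_dwell: float = 20.0
    wc_broken_mu: float = 4.3
    wc_broken_sd: float = 0.4
    # emitted field groups
    fields: tuple[str, ...] = ("inter", "backbone", "hbond", "wc", "intra", "axis")
    snapshot_spacing_ps: float = 1.0

    def resolve(self, tetra: str) -> tuple[ContextModel, bool]:
        """Context model for an absolute Watson-strand tetranucleotide
        reading; ``flipped`` means the model's reading is the reverse
        complement (shift/tilt means negate, strand roles swap)."""
        up = tetra.upper()
        rc = reverse_complement(up)
        # specific (4-letter) keys take precedence over step (2-letter) keys
        for want_len in (4, 2):
            for key, model in self.contexts.items():
                k = key.upper()
                if len(k) != want_len:
                    continue
                probe_up = up if want_len == 4 else up[1:3]
                probe_rc = rc if want_len == 4 else rc[1:3]
                if k == probe_up:
                    return model, False
                if k == probe_rc:
                    return model, True
        if self.default_context is None:
            raise KeyError(f"no context model for {tetra!r}")
        return self.default_context, False

    def hbond_regime_probs(self, p_bii: float) -> tuple[float, float]:
        """Closed-form bonded-regime probabilities (a, q) given BII / BI.

        Solved so that, after emitting distances from the overlapping bonded
        and unbonded regimes, the *measured* conditionals at the cutoff equal
        the targets: P(d<cutoff | BII) = p_hb_given_bii and
        P(BII | d<cutoff) = p_bii_given_hb.
        """
        if not 0 < p_bii < 1:
            raise ValueError("BII marginal must be in (0, 1)")
        pb_in = norm.cdf((self.hbond_cutoff - self.bonded_mu) / self.bonded_sd)
        pu_in = norm.cdf((self.hbond_cutoff - self.unbonded_mu) / self.unbonded_sd)
        span = pb_in - pu_in
        a = (self.p_hb_given_bii - pu_in) / span
        target_bi = (
            self.p_hb_given_bii * p_bii * (1.0 / self.p_bii_given_hb - 1.0) / (1.0 - p_bii)
        )
        q = (target_bi - pu_in) / span
        if not (0.0 <= a <= 1.0 and q <= 1.0):
            raise ValueError(
                f"infeasible hydrogen-bond coupling: regime probabilities a={a:.3f}, q={q:.3f}"
            )
        # For small BII marginals the unbonded emission's leakage below the
        # cutoff already exceeds the bonded probability P(BII|HB) demands of
        # BI snapshots; q = 0 is then the closest achievable coupling.
        return float(a), float(max(q, 0.0))


# ---------------------------------------------------------------------------
# Preset
# ---------------------------------------------------------------------------

def _canonical_state(label="canonical", weight=1.0, *, shift=0.0, slide=-0.3,
                     twist=32.5, rise=3.35, tilt=0.0, roll=2.0,
                     shift_sd=0.4, slide_sd=0.5, twist_sd=5.0,
                     watson_bii=None, crick_bii=None, flank3_bii=None):
    return SubstateSpec(
        label,
        weight,
        {"shift": shift, "slide": slide, "rise": rise, "tilt": tilt, "roll": roll, "twist": twist},
        {"shift": shift_sd, "slide": slide_sd, "rise": 0.25, "tilt": 3.0, "roll": 5.0, "twist": twist_sd},
        watson_bii,
        crick_bii,
        flank3_bii,
    )


def paper2014() -> GeneratorSpec:
    """The packaged preset encoding the reported microsecond statistics.

    Provenance of the numbers (sequence-averaged B-DNA statistics of the
    source trajectories):

    * canonical state: twist 32.5° (reported sequence-averaged twist),
      propeller −11°, inclination 7°, Xdisp −1.5 Å (pass-through values in
      :data:`INTRA_EMISSIONS` / :data:`AXIS_EMISSIONS`);
    * CG context: twist wells near 20° and 40°;
    * RR steps: high-twist substate offset ≈ +5° above canonical, tied to
      the Watson backbone BII state;
    * YR steps: low-twist substate offset ≈ −15° below canonical, tied to a
      BII state in at least one 3'-flanking junction;
    * BII ↔ C8-H…O3' coupling targeting P(HB|BII) = 0.90 and
      P(BII|HB) = 0.87.
    """
    rr = ContextModel(
        (
            _canonical_state("canonical", 0.75, shift=-0.3, slide=-0.5, twist=33.0,
                             twist_sd=4.0, watson_bii=0.0, crick_bii=0.08),
            _canonical_state("high_twist", 0.25, shift=-0.5, slide=0.0, twist=38.0,
                             twist_sd=4.0, watson_bii=1.0, crick_bii=0.08),
        )
    )
    cg = ContextModel(
        (
            _canonical_state("low_twist", 0.5, shift=0.0, slide=-0.2, twist=20.0,
                             twist_sd=6.0, watson_bii=0.1, crick_bii=0.1, flank3_bii=0.9),
            _canonical_state("high_twist", 0.5, shift=0.0, slide=-0.4, twist=40.0,
                             twist_sd=6.0, watson_bii=0.1, crick_bii=0.1, flank3_bii=0.05),
        )
    )
    yr = ContextModel(
        (
            _canonical_state("canonical", 0.8, twist=32.5, watson_bii=0.1,
                             crick_bii=0.1, flank3_bii=0.05),
            _canonical_state("low_twist", 0.2, twist=17.5, watson_bii=0.1,
                             crick_bii=0.1, flank3_bii=0.9),
        )
    )
    ry = ContextModel((_canonical_state("canonical", 1.0, twist=32.5),))
    negative_shift = ContextModel((_canonical_state("canonical", 1.0, shift=-0.3),))
    contexts = {
        "AA": negative_shift, "GG": rr, "GA": rr, "AG": rr,
        "CG": cg, "TA": yr, "TG": yr,
        "AT": ry, "GC": ry, "GT": negative_shift,
    }
    return GeneratorSpec(contexts=contexts, default_context=ry)


# ---------------------------------------------------------------------------
# Simulation machinery
# ---------------------------------------------------------------------------

def _markov_states(rng, n: int, weights: np.ndarray, dwell: float) -> np.ndarray:
    """Stationary first-order chain: with probability 1/dwell per snapshot the
    state is resampled from the stationary weights; else it persists."""
    resample = rng.random(n) < 1.0 / dwell
    resample[0] = True
    draws = rng.choice(len(weights), size=n, p=weights / weights.sum())
    idx = np.where(resample, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    return draws[idx]


def _two_state_chain(rng, n: int, p: float, dwell: float) -> np.ndarray:
    return _markov_states(rng, n, np.array([1.0 - p, p]), dwell).astype(bool)


def _wrapped_normal(rng, n: int, mu: float, sd: float) -> np.ndarray:
    return (rng.normal(mu, sd, n)) % 360.0


def generate_series(
    spec: GeneratorSpec,
    sequence: str,
    n: int,
    seed: int,
    name: str | None = None,
) -> SeriesTable:
    """Simulate a parameter series for a duplex of the given Watson-strand
    sequence (a 4-mer fragment or a full oligomer).

    Fully reproducible per seed.  Emitted columns follow the trajectory
    dialect; the field groups in ``spec.fields`` select what is emitted.
    Cross-junction substate↔flanking-backbone coupling (``flank3_bii``) is
    honoured for 4-level fragments, where the central junction's substate
    chain drives the BII flags of the two 3'-flanking junctions.
    """
    seq = sequence.upper()
    n_lev = len(seq)
    if n_lev < 2:
        raise ValueError("need at least 2 levels")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {"snapshot": np.arange(n)}
    fragment = n_lev == 4

    # --- per-junction context models and substate chains -------------------
    junctions = range(1, n_lev)
    models: dict[int, tuple[ContextModel, bool]] = {}
    for j in junctions:
        if j - 1 >= 1 and j + 2 <= n_lev:
            tetra = seq[j - 2 : j + 2]
        else:
            # edge junction: pad the context so the central step is its own
            step = seq[j - 1 : j + 1]
            tetra = step[0] + step + step[1]
        models[j] = spec.resolve(tetra)

    states: dict[int, np.ndarray] = {}
    for j in junctions:
        model, _ = models[j]
        states[j] = _markov_states(rng, n, model.weights, model.dwell)

    # --- backbone BI/BII flags per (junction, strand) ----------------------
    bii: dict[tuple[int, str], np.ndarray] = {}
    for j in junctions:
        model, flipped = models[j]
        for strand in ("W", "C"):
            model_strand = ("C" if strand == "W" else "W") if flipped else strand
            probs = np.array(
                [
                    (s.watson_bii if model_strand == "W" else s.crick_bii) or 0.0
                    if (s.watson_bii if model_strand == "W" else s.crick_bii) is not None
                    else np.nan
                    for s in model.substates
                ]
            )
            if np.any(np.isnan(probs)):
                bii[(j, strand)] = _two_state_chain(rng, n, spec.default_bii, spec.backbone_dwell)
            else:
                p_t = probs[states[j]]
                bii[(j, strand)] = rng.random(n) < p_t

    # fragment-mode coupling: central substate drives the 3'-flank junctions
    if fragment:
        model, flipped = models[2]
        flank = np.array(
            [np.nan if s.flank3_bii is None else s.flank3_bii for s in model.substates]
        )
        if not np.any(np.isnan(flank)):
            p_t = flank[states[2]]
            # W3' = junction 3 Watson; C3' = junction 1 Crick (swap if flipped)
            w3 = (3, "C") if flipped else (3, "W")
            c3 = (1, "W") if flipped else (1, "C")
            bii[w3] = rng.random(n) < p_t
            bii[c3] = rng.random(n) < p_t

    # --- inter-BP emissions -------------------------------------------------
    if "inter" in spec.fields:
        for j in junctions:
            model, flipped = models[j]
            st = states[j]
            means = np.array([[s.means[p] for p in INTER] for s in model.substates])
            sds = np.array([[s.sds[p] for p in INTER] for s in model.substates])
            if flipped:
                means = means * np.array([-1, 1, 1, -1, 1, 1])  # shift, tilt negate
            draws = rng.normal(means[st], sds[st])
            for k, p in enumerate(INTER):
                cols[f"{p}_{j}"] = draws[:, k]

    # --- backbone emissions -------------------------------------------------
    if "backbone" in spec.fields:
        for strand in ("W", "C"):
            for k in range(1, n_lev + 1):
                j = k if strand == "W" else n_lev - k  # junction owning ε/ζ
                if 1 <= j <= n_lev - 1:
                    b = bii[(j, strand)]
                    for p in ("epsilon", "zeta"):
                        mu_bi, sd_bi = BI_BACKBONE[p]
                        mu_bii, sd_bii = BII_BACKBONE[p]
                        vals = np.where(
                            b,
                            _wrapped_normal(rng, n, mu_bii, sd_bii),
                            _wrapped_normal(rng, n, mu_bi, sd_bi),
                        )
                        cols[f"{p}_{k}_{strand}"] = vals
                for p, (mu, sd) in COMMON_BACKBONE.items():
                    if p == "amplitude":
                        cols[f"{p}_{k}_{strand}"] = rng.normal(mu, sd, n)
                    else:
                        cols[f"{p}_{k}_{strand}"] = _wrapped_normal(rng, n, mu, sd)

    # --- C8-H…O3' distances -------------------------------------------------
    if "hbond" in spec.fields:
        for j in junctions:
            for strand in ("W", "C"):
                three_prime = seq[j] if strand == "W" else complement(seq[j - 1])
                if not is_purine(three_prime):
                    continue  # 3'-pyrimidine: bond cannot form, column absent
                model, flipped = models[j]
                model_strand = ("C" if strand == "W" else "W") if flipped else strand
                p_b = model.stationary_bii(model_strand)
                if p_b is None or not 0 < p_b < 1:
                    p_b = spec.default_bii
                a, q = spec.hbond_regime_probs(p_b)
                b = bii[(j, strand)]
                regime = rng.random(n) < np.where(b, a, q)
                dist = np.where(
                    regime,
                    rng.normal(spec.bonded_mu, spec.bonded_sd, n),
                    rng.normal(spec.unbonded_mu, spec.unbonded_sd, n),
                )
                cols[f"c8o3_{j}_{strand}"] = np.clip(dist, 2.5, None)

    # --- Watson–Crick distances ---------------------------------------------
    if "wc" in spec.fields:
        for lev in range(1, n_lev + 1):
            n_bonds = 3 if seq[lev - 1] in "GC" else 2
            broken = _two_state_chain(rng, n, spec.wc_break_rate, spec.wc_break_dwell)
            for b_i in range(1, n_bonds + 1):
                intact = rng.normal(spec.wc_mu, spec.wc_sd, n)
                burst = np.clip(
                    rng.normal(spec.wc_broken_mu, spec.wc_broken_sd, n), 3.6, None
                )
                cols[f"wcdist{b_i}_{lev}"] = np.where(broken, burst, intact)

    # --- intra-BP and BP-axis pass-through ----------------------------------
    for group, emissions in (("intra", INTRA_EMISSIONS), ("axis", AXIS_EMISSIONS)):
        if group in spec.fields:
            for lev in range(1, n_lev + 1):
                for p, (mu, sd) in emissions.items():
                    cols[f"{p}_{lev}"] = rng.normal(mu, sd, n)

    import pandas as pd

    meta = {
        "name": name or seq,
        "sequence": seq,
        "snapshot_spacing_ps": spec.snapshot_spacing_ps,
        "seed": seed,
    }
    return SeriesTable(pd.DataFrame(cols), meta)


def generate_frames(params: list[InterBP], start: Frame | None = None) -> list[Frame]:
    """Base-pair frame sequence realizing a series of inter-BP parameters.

    Frames are stacked from ``start`` (identity by default) by the exact
    inverse of the mid-frame decomposition, so recomputing inter-BP
    parameters from consecutive frames recovers the inputs to round-off.
    """
    frame = start or Frame(np.zeros(3), np.eye(3))
    frames = [frame]
    for p in params:
        frame = reconstruct_frame(frame, p)
        frames.append(frame)
    return frames
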