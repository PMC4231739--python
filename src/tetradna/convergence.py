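"""Sampling-convergence diagnostics for trajectory series.

Two complementary checks: (i) repeat-position agreement — the repeating
oligomer design places two occurrences of the same tetranucleotide at levels
6–9 and 10–13, whose parameter averages must agree for a converged
trajectory; (ii) half-trajectory agreement — averages over either half of
the trajectory must agree with the full-trajectory averages.  Differences of
angular parameters are circular (wrapped to [0°, 180°]).

The default thresholds are the agreement bounds observed for well-converged
microsecond trajectories: repeat positions within 0.25 Å (translational
helical), 2° (rotational helical) and 5° (backbone dihedrals and puckers);
half-trajectory within 0.1 Å / 2° / 3°, except ε and ζ which may reach 8°.
They are quality-control defaults, all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import CircAccumulator
from .geometry import INTER_BP_NAMES, INTRA_BP_NAMES
from .sequence import OligomerDesign, Occurrence
from .trajectory import ANGULAR_PARAMS, SeriesTable, central_selection

__all__ = [
    "AgreementThresholds",
    "AgreementReport",
    "repeat_agreement",
    "half_trajectory_agreement",
    "equilibration_trim",
]

TRANSLATIONAL_HELICAL = set(INTER_BP_NAMES[:3]) | set(INTRA_BP_NAMES[:3]) | {"xdisp", "ydisp"}
ROTATIONAL_HELICAL = set(INTER_BP_NAMES[3:]) | set(INTRA_BP_NAMES[3:]) | {"inclination", "tip"}
BACKBONE = {"alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi", "phase"}


def param_class(name: str) -> str | None:
    base = name.split("_")[0]
    if base in TRANSLATIONAL_HELICAL:
        return "translational"
    if base in ROTATIONAL_HELICAL:
        return "rotational"
    if base in BACKBONE:
        return "backbone"
    return None


@dataclass(frozen=True)
class AgreementThresholds:
    translational: float  # Å
    rotational: float  # degrees
    backbone: float  # degrees
    overrides: dict = field(default_factory=dict)  # per-parameter-base degrees/Å

    def limit(self, param: str) -> float | None:
        base = param.split("_")[0]
        if base in self.overrides:
            return self.overrides[base]
        cls = param_class(param)
        if cls is None:
            return None
        return getattr(self, cls)


REPEAT_THRESHOLDS = AgreementThresholds(0.25, 2.0, 5.0)
HALF_THRESHOLDS = AgreementThresholds(0.1, 2.0, 3.0, overrides={"epsilon": 8.0, "zeta": 8.0})


@dataclass
class AgreementReport:
    """Per-parameter mean differences against per-class thresholds."""

    rows: list  # (parameter, class, |Δmean|, threshold, ok)
    thresholds: AgreementThresholds

    @property
    def passed(self) -> bool:
        return all(r[4] for r in self.rows)

    def max_delta(self, cls: str) -> float:
        vals = [r[2] for r in self.rows if r[1] == cls]
        return max(vals) if vals else 0.0

    def failures(self) -> list:
        return [r for r in self.rows if not r[4]]


def _mean(values: np.ndarray, circular: bool) -> float | None:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return None
    if circular:
        return CircAccumulator().add(v).mean
    return float(np.mean(v))


def _delta(m1: float, m2: float, circular: bool) -> float:
    if circular:
        return abs(float(-((-(m1 - m2) + 180.0) % 360.0 - 180.0)))
    return abs(m1 - m2)


def _compare(series_a: dict, series_b: dict, thresholds: AgreementThresholds) -> AgreementReport:
    rows = []
    for param in sorted(set(series_a) & set(series_b)):
        if param.startswith("_"):
            continue
        lim = thresholds.limit(param)
        if lim is None:
            continue
        circ = param.split("_")[0] in ANGULAR_PARAMS
        ma = _mean(np.asarray(series_a[param], dtype=float), circ)
        mb = _mean(np.asarray(series_b[param], dtype=float), circ)
        if ma is None or mb is None:
            continue
        d = _delta(ma, mb, circ)
        rows.append((param, param_class(param), d, lim, d <= lim))
    return AgreementReport(rows, thresholds)


def repeat_agreement(
    table: SeriesTable,
    design: OligomerDesign,
    thresholds: AgreementThresholds = REPEAT_THRESHOLDS,
) -> AgreementReport:
    """Compare parameter means between the repeated tetranucleotides at
    levels 6–9 and 10–13 of a repeating oligomer design.

    Both occurrences are read on the Watson strand (the design repeats in
    phase every four levels), so central-step selections are directly
    comparable; any strand-flip sign correction is handled by the selection.
    """
    seq = design.sequence
    t1, t2 = seq[5:9], seq[9:13]
    if t1 != t2:
        raise ValueError(
            f"design {design.name} lacks identical repeats at levels 6–9/10–13"
        )
    occ1 = Occurrence(t1, "Watson", 6, (6, 7, 8, 9))
    occ2 = Occurrence(t2, "Watson", 10, (10, 11, 12, 13))
    sel1 = central_selection(occ1, table)
    sel2 = central_selection(occ2, table)
    return _compare(sel1, sel2, thresholds)


def half_trajectory_agreement(
    table: SeriesTable,
    thresholds: AgreementThresholds = HALF_THRESHOLDS,
) -> AgreementReport:
    """Compare each half-trajectory's parameter means with the full ones.

    Reports, per parameter column, the larger of the two half-vs-full
    differences.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 snapshots")
    half = n // 2
    rows = []
    for col in table.df.columns:
        if col == "snapshot":
            continue
        lim = thresholds.limit(col)
        if lim is None:
            continue
        circ = col.split("_")[0] in ANGULAR_PARAMS
        full = table.df[col].to_numpy(dtype=float)
        m_full = _mean(full, circ)
        if m_full is None:
            continue
        deltas = []
        for part in (full[:half], full[half:]):
            m_part = _mean(part, circ)
            if m_part is not None:
                deltas.append(_delta(m_part, m_full, circ))
        d = max(deltas)
        rows.append((col, param_class(col), d, lim, d <= lim))
    return AgreementReport(rows, thresholds)


def equilibration_trim(table: SeriesTable, n_discard: int | None = None,
                       fraction: float = 0.1) -> SeriesTable:
    """Drop the leading snapshots as an extended equilibration period.

    Default discards the first 10% of the trajectory (100 ns of a 1 μs run
    at the native snapshot spacing).
    """
    if n_discard is None:
        n_discard = int(round(fraction * len(table)))
    if n_discard >= len(table):
        raise ValueError(f"cannot discard {n_discard} of {len(table)} snapshots")
    if n_discard == 0:
        return table
    return table.iloc_slice(n_discard)
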