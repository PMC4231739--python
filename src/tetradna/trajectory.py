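"""Series data model, file dialect, central-step selection and WC filtering.

A trajectory analysis run consumes one record per MD snapshot holding, for an
N-level (N base-pair) duplex: intra-BP parameters and optional pass-through
BP-axis/groove values per level, inter-BP parameters per junction (junction j
sits between levels j and j+1, 1-based), backbone torsions and sugar pucker
per nucleotide per strand (each strand numbered 5'→3' in its own direction),
base–phosphate C8–O3' distances per junction per strand where a 3'-purine is
present, and Watson–Crick heavy-atom distances per level.

Dialect: UTF-8 CSV with a declared header, one row per snapshot, empty
fields for missing values, and a JSON sidecar (``<path>.meta.json``) carrying
metadata (oligomer name, sequence, snapshot spacing in ps).  Columns are
named ``<parameter>_<index>`` with an optional ``_W``/``_C`` strand suffix;
unknown parameters are preserved as pass-through.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence import Occurrence
from .geometry import INTER_BP_NAMES, INTRA_BP_NAMES

__all__ = [
    "SeriesTable",
    "read_series",
    "write_series",
    "central_selection",
    "wc_filter",
    "strand_flip",
    "junction_backbone_addresses",
    "crick_index",
]

JUNCTION_PARAMS = set(INTER_BP_NAMES)
LEVEL_PARAMS = set(INTRA_BP_NAMES) | {
    "xdisp", "ydisp", "inclination", "tip",  # BP-axis pass-through
    "minw", "mind", "majw", "majd",  # groove pass-through
    "wcdist1", "wcdist2", "wcdist3",
}
NUCLEOTIDE_PARAMS = {
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
    "phase", "amplitude",
}
JUNCTION_STRAND_PARAMS = {"c8o3"}

#: Parameters whose sign flips when the Watson/Crick naming is swapped.
SIGN_FLIP_PARAMS = {"shift", "tilt", "shear", "buckle"}

#: Angular parameters (degrees, circular); everything else is linear (Å).
ANGULAR_PARAMS = {
    "tilt", "roll", "twist", "buckle", "propeller", "opening",
    "inclination", "tip",
} | NUCLEOTIDE_PARAMS - {"amplitude"}

_COLUMN_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)_(\d+)(?:_([WC]))?$")


def parse_column(name: str):
    """Split a column name into (parameter, index, strand-or-None); returns
    None for pass-through columns that do not follow the dialect."""
    m = _COLUMN_RE.match(name)
    if not m:
        return None
    param, idx, strand = m.group(1), int(m.group(2)), m.group(3)
    return param, idx, strand


def crick_index(level: int, n_levels: int) -> int:
    """Nucleotide index along the Crick strand (its own 5'→3' numbering)
    of the nucleotide paired with Watson level ``level``."""
    return n_levels + 1 - level


def junction_backbone_addresses(junction: int, strand: str, n_levels: int) -> dict:
    """Backbone torsion addresses integral to a base-pair step.

    For junction j read 5'→3' along ``strand``, ε and ζ belong to the
    5'-side nucleotide of the phosphodiester linkage and α, β, γ to the
    3'-side nucleotide.  Returns ``{param: (nucleotide index, strand)}`` in
    each strand's own numbering.
    """
    if strand == "W":
        five, three = junction, junction + 1
    elif strand == "C":
        five = crick_index(junction + 1, n_levels)
        three = crick_index(junction, n_levels)
    else:
        raise ValueError("strand must be 'W' or 'C'")
    return {
        "epsilon": (five, strand),
        "zeta": (five, strand),
        "alpha": (three, strand),
        "beta": (three, strand),
        "gamma": (three, strand),
    }


@dataclass
class SeriesTable:
    """An ordered collection of per-snapshot parameter records.

    Thin wrapper around a pandas DataFrame (one row per snapshot, ``snapshot``
    index column) plus run metadata.  Layout is validated on construction:
    snapshot indices must be strictly increasing and, when both level- and
    junction-keyed parameters are present, junction count must equal
    level count − 1.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "snapshot" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "snapshot", np.arange(len(self.df)))
        snap = self.df["snapshot"].to_numpy()
        if len(snap) and np.any(np.diff(snap) <= 0):
            row = int(np.argmax(np.diff(snap) <= 0)) + 1
            raise ValueError(f"snapshot index not strictly increasing at row {row + 1}")
        self._validate_layout()

    def _validate_layout(self):
        n_lev, n_junc = None, None
        for col in self.df.columns:
            parsed = parse_column(col)
            if parsed is None:
                continue
            param, idx, strand = parsed
            if param in JUNCTION_PARAMS:
                n_junc = max(n_junc or 0, idx)
            elif param in JUNCTION_STRAND_PARAMS:
                pass  # sparse (purine-only) columns do not define the layout
            elif param in LEVEL_PARAMS:
                n_lev = max(n_lev or 0, idx)
        seq = self.meta.get("sequence")
        if seq is not None:
            n_lev = max(n_lev or 0, len(seq))
        if n_lev is not None and n_junc is not None and n_junc != n_lev - 1:
            raise ValueError(
                f"junction count {n_junc} inconsistent with level count {n_lev}"
            )
        self._n_levels = n_lev
        self._n_junctions = n_junc if n_junc is not None else (n_lev - 1 if n_lev else None)

    # -- accessors ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_levels(self):
        return self._n_levels

    @property
    def n_junctions(self):
        return self._n_junctions

    @property
    def sequence(self):
        return self.meta.get("sequence")

    def column(self, param: str, index: int, strand: str | None = None) -> str:
        return f"{param}_{index}" + (f"_{strand}" if strand else "")

    def has(self, param: str, index: int, strand: str | None = None) -> bool:
        return self.column(param, index, strand) in self.df.columns

    def get(self, param: str, index: int, strand: str | None = None) -> np.ndarray:
        col = self.column(param, index, strand)
        if col not in self.df.columns:
            raise KeyError(f"column {col!r} not present")
        return self.df[col].to_numpy(dtype=float)

    def iloc_slice(self, start: int, stop: int | None = None) -> "SeriesTable":
        return SeriesTable(self.df.iloc[start:stop].reset_index(drop=True), dict(self.meta))


def write_series(table: SeriesTable, path) -> None:
    """Write a series table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(table.meta, indent=1, sort_keys=True))


def read_series(path, meta: dict | None = None) -> SeriesTable:
    """Read a series table written by :func:`write_series`.

    Rejects ragged rows (naming the offending row), missing headers and
    non-monotone snapshot indices; unknown columns are kept as pass-through.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("empty series file") from None
        width = len(header)
        for i, row in enumerate(reader, start=2):
            if len(row) != width:
                raise ValueError(f"ragged row at line {i}: {len(row)} fields, expected {width}")
    df = pd.read_csv(path)
    if meta is None:
        sidecar = path.with_name(path.name + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SeriesTable(df, meta)


# ---------------------------------------------------------------------------
# Strand flip and central-step selection
# ---------------------------------------------------------------------------

def strand_flip(table: SeriesTable) -> SeriesTable:
    """The same physical trajectory with the Watson/Crick naming swapped.

    Levels and junctions are renumbered end-for-end, strand suffixes swap,
    and the four naming-dependent parameters (shift, tilt, shear, buckle)
    change sign.  Applying the flip twice is the identity.
    """
    n = table.n_levels
    if n is None:
        raise ValueError("cannot flip a table with unknown level count")
    out = {}
    for col in table.df.columns:
        parsed = parse_column(col)
        if parsed is None:
            out[col] = table.df[col]
            continue
        param, idx, strand = parsed
        vals = table.df[col]
        if param in SIGN_FLIP_PARAMS:
            vals = -vals
        if param in JUNCTION_PARAMS:
            new = f"{param}_{n - idx}"
        elif param in JUNCTION_STRAND_PARAMS:
            new = f"{param}_{n - idx}_{'C' if strand == 'W' else 'W'}"
        elif param in NUCLEOTIDE_PARAMS:
            new = f"{param}_{idx}_{'C' if strand == 'W' else 'W'}"
        elif param in LEVEL_PARAMS:
            new = f"{param}_{n + 1 - idx}"
        else:
            new = col
        out[new] = vals
    df = pd.DataFrame(out)
    meta = dict(table.meta)
    if meta.get("sequence"):
        from .sequence import reverse_complement

        meta["sequence"] = reverse_complement(meta["sequence"])
    return SeriesTable(df, meta)


def central_selection(occurrence: Occurrence, table: SeriesTable) -> dict[str, np.ndarray]:
    """Central-step (or central-level) series of a sequence fragment.

    For a 4-level occurrence, returns the inter-BP parameters of the central
    junction plus ε, ζ, α, β, γ for that junction on both strands, each read
    5'→3' along its own backbone and named relative to the *fragment* (its
    Watson strand is the strand carrying the occurrence's reading).  When the
    occurrence is on the Crick strand, shift and tilt are sign-corrected and
    the strand roles swap.  C8–O3' distances for the central junction are
    included per strand when present.

    A 3-level (trinucleotide) occurrence instead yields the central level's
    intra-BP parameters plus χ and sugar pucker of both nucleotides.
    """
    n = table.n_levels
    if n is None:
        raise ValueError("table has no level structure")
    levels = occurrence.levels
    on_crick = occurrence.strand == "Crick"
    flip = -1.0 if on_crick else 1.0
    out: dict[str, np.ndarray] = {}

    if len(levels) % 2 == 0:
        c = levels[0] + len(levels) // 2 - 1  # junction between the middle levels
        if c < 1 or c > (table.n_junctions or 0):
            raise ValueError(f"central junction {c} outside table junctions")
        for p in INTER_BP_NAMES:
            v = table.get(p, c)
            out[p] = flip * v if p in SIGN_FLIP_PARAMS else v
        frag_w, frag_c = ("C", "W") if on_crick else ("W", "C")
        for frag_strand, abs_strand in (("W", frag_w), ("C", frag_c)):
            addr = junction_backbone_addresses(c, abs_strand, n)
            for p, (idx, s) in addr.items():
                if table.has(p, idx, s):
                    out[f"{p}_{frag_strand}"] = table.get(p, idx, s)
            if table.has("c8o3", c, abs_strand):
                out[f"c8o3_{frag_strand}"] = table.get("c8o3", c, abs_strand)
        out["_junction"] = c
    else:
        m = levels[len(levels) // 2]
        for p in INTRA_BP_NAMES:
            if table.has(p, m):
                v = table.get(p, m)
                out[p] = flip * v if p in SIGN_FLIP_PARAMS else v
        frag_w, frag_c = ("C", "W") if on_crick else ("W", "C")
        for frag_strand, abs_strand in (("W", frag_w), ("C", frag_c)):
            idx = m if abs_strand == "W" else crick_index(m, n)
            for p in ("chi", "phase", "amplitude"):
                if table.has(p, idx, abs_strand):
                    out[f"{p}_{frag_strand}"] = table.get(p, idx, abs_strand)
        out["_level"] = m
    return out


def wc_filter(table: SeriesTable, cutoff: float = 3.5, permissive: bool = False) -> np.ndarray:
    """Mask of broken-pair-affected inter-BP values.

    Returns a boolean array of shape (n_snapshots, n_junctions) that is True
    where the junction's parameters must be discarded because either
    adjoining base pair has any Watson–Crick heavy-atom distance strictly
    greater than ``cutoff`` (Å).  Intra-BP parameters are never masked.

    When no WC distance columns are present the filter refuses unless
    ``permissive`` is set, in which case everything is unmasked and a
    warning is emitted.
    """
    n_lev, n_junc = table.n_levels, table.n_junctions
    if not n_lev or not n_junc:
        raise ValueError("table has no junction structure")
    broken_level = np.zeros((len(table), n_lev), dtype=bool)
    found = False
    for lev in range(1, n_lev + 1):
        for b in ("wcdist1", "wcdist2", "wcdist3"):
            if table.has(b, lev):
                found = True
                d = table.get(b, lev)
                broken_level[:, lev - 1] |= np.nan_to_num(d, nan=0.0) > cutoff
    if not found:
        if not permissive:
            raise ValueError("no Watson–Crick distance columns present; cannot filter")
        import warnings

        warnings.warn("no WC distance columns; returning all-unmasked filter")
        return np.zeros((len(table), n_junc), dtype=bool)
    return broken_level[:, :-1] | broken_level[:, 1:]
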