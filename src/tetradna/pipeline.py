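"""End-to-end analysis pipeline: trim → filter → statistics → states → report.

Runs the full tetranucleotide analysis on one series table (a 4-level
fragment or a full oligomer): equilibration trimming, Watson–Crick integrity
filtering, central-step summary statistics, distribution-shape
classification, BI/BII and hydrogen-bond analysis, ζ–helical correlation
matrices, substate density decomposition, and convergence diagnostics.
Every report is stamped with the configuration hash and seed for
provenance; stages are individually invocable and compose to the same
result as the monolithic run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import backbone as bb
from . import circstats as cs
from . import convergence as cv
from . import substates as ss
from . import trajectory as tj
from .sequence import Occurrence, build_oligomer, centermost_occurrence, ry_code
from .trajectory import SeriesTable

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("tetradna")

STAGES = (
    "trim",
    "wc_filter",
    "statistics",
    "shapes",
    "backbone",
    "correlations",
    "substates",
    "convergence",
)


@dataclass
class RunConfig:
    """Analysis cutoffs and knobs; serialized verbatim into every report."""

    wc_cutoff: float = 3.5  # Å, Watson–Crick heavy-atom break threshold
    hbond_cutoff: float = 4.0  # Å, C8-H…O3' bonded/unbonded separation
    corr_threshold: float = 0.4  # |r| masking threshold for correlation maps
    lin_scale: float = 5.0  # Å, linear→angle conversion scale
    rot_bin: float = 2.0  # degrees, rotational histogram bin width
    trans_bin: float = 0.1  # Å, translational histogram bin width
    density_bins: tuple[float, float, float] = (0.25, 0.25, 2.0)
    isolevels: tuple[float, ...] = (0.15, 0.30, 0.45, 0.60)
    trim_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("wc_cutoff", "hbond_cutoff", "corr_threshold", "lin_scale",
                     "rot_bin", "trans_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["density_bins"] = list(self.density_bins)
        d["isolevels"] = list(self.isolevels)
        return d

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("density_bins", "isolevels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 — re-raise with stage context
                raise PipelineError(name, str(exc)) from exc
            log.info("STAGE %s ok", name)
            return out

        return wrapped

    return deco


def _summary(series: np.ndarray, circular: bool) -> dict:
    v = np.asarray(series, dtype=float)
    v = v[np.isfinite(v)]
    stats = cs.circ_moments(v) if circular else cs.linear_moments(v)
    return {
        "mean": stats.mean,
        "sd": stats.sd,
        "min": stats.minimum,
        "max": stats.maximum,
        "range": stats.range,
        "n": stats.n,
        "circular": circular,
    }


@_stage("statistics")
def statistics_stage(selection: dict, mask: np.ndarray) -> dict:
    out = {}
    for param, series in selection.items():
        if param.startswith("_"):
            continue
        base = param.split("_")[0]
        circ = base in tj.ANGULAR_PARAMS
        v = np.asarray(series, dtype=float)
        if base in tj.JUNCTION_PARAMS:  # inter-BP: apply the WC filter
            v = v[~mask]
        out[param] = _summary(v, circ)
    return out


@_stage("shapes")
def shapes_stage(selection: dict, mask: np.ndarray) -> dict:
    out = {}
    for param in ("shift", "slide", "twist"):
        if param not in selection:
            continue
        v = np.asarray(selection[param], dtype=float)[~mask]
        shape = ss.classify_shape(v, circular=False)
        out[param] = {
            "label": shape.label,
            "peaks": [float(p) for p in np.atleast_1d(shape.peaks)],
            "skewness": shape.skewness,
            "excess_kurtosis": shape.excess_kurtosis,
        }
    return out


@_stage("backbone")
def backbone_stage(table: SeriesTable, occ: Occurrence, selection: dict,
                   config: RunConfig, step: str) -> dict:
    out = {"step": step, "strands": {}}
    pooled = []
    for strand in ("W", "C"):
        eps = selection.get(f"epsilon_{strand}")
        zet = selection.get(f"zeta_{strand}")
        if eps is None or zet is None:
            continue
        bii = bb.classify_bi_bii(eps, zet)
        entry = {
            "bii_percent": bb.bii_occupancy(bii),
            "atypical_wheel_fraction": bb.atypical_wheel_fraction(eps, zet),
        }
        pooled.append(bii)
        if bb.hbond_applicable(step, strand) and f"c8o3_{strand}" in selection:
            hb = bb.hbond_state(selection[f"c8o3_{strand}"], config.hbond_cutoff)
            rep = bb.conditional_association(bii, hb)
            entry.update(
                hbond_percent=100.0 * float(np.mean(hb)),
                p_hb_given_bii=rep.p_hb_given_bii,
                p_bii_given_hb=rep.p_bii_given_hb,
                contingency=rep.table.tolist(),
            )
        else:
            entry["hbond"] = "inapplicable (3'-pyrimidine)"
        out["strands"][strand] = entry
    from .sequence import reverse_complement

    if step.upper() == reverse_complement(step) and len(pooled) == 2:
        out["pooled_bii_percent"] = 100.0 * float(np.mean(np.concatenate(pooled)))
    return out


@_stage("correlations")
def correlations_stage(table: SeriesTable, occ: Occurrence, mask: np.ndarray,
                       config: RunConfig) -> dict:
    n_lev = table.n_levels
    ctx = bb.junction_context_map(occ, n_lev)
    keep = ~mask
    series, flags = {}, {}
    c = occ.start + 1
    flip = occ.strand == "Crick"
    for p in tj.JUNCTION_PARAMS:
        if table.has(p, c):
            v = table.get(p, c)
            if flip and p in tj.SIGN_FLIP_PARAMS:
                v = -v
            series[p] = v[keep]
            flags[p] = p in tj.ANGULAR_PARAMS
    for label, (j, strand) in ctx.items():
        idx, s = tj.junction_backbone_addresses(j, strand, n_lev)["zeta"]
        if table.has("zeta", idx, s):
            series[f"zeta[{label}]"] = table.get("zeta", idx, s)[keep]
            flags[f"zeta[{label}]"] = True
    names, mat, sig = cs.corr_matrix(series, flags, config.corr_threshold, config.lin_scale)
    return {
        "names": names,
        "matrix": [[None if not np.isfinite(v) else round(float(v), 4) for v in row] for row in mat],
        "mask": sig.tolist(),
    }


@_stage("substates")
def substates_stage(table: SeriesTable, occ: Occurrence, selection: dict,
                    mask: np.ndarray, config: RunConfig) -> dict:
    oriented, flipped = ss.reading_direction(occ.tetra)
    family = ry_code(oriented[1:3])
    keep = ~mask
    sign = -1.0 if flipped else 1.0
    shift = sign * np.asarray(selection["shift"])[keep]
    slide = np.asarray(selection["slide"])[keep]
    twist = np.asarray(selection["twist"])[keep]
    kwargs = {}
    # backbone conditioning relative to the *oriented* reading
    eff_occ = occ
    if flipped:
        other = "Crick" if occ.strand == "Watson" else "Watson"
        eff_occ = Occurrence(oriented, other, occ.start, occ.levels)
    ctx = bb.junction_context_map(eff_occ, table.n_levels)
    def bii_at(label):
        j, strand = ctx[label]
        addr = tj.junction_backbone_addresses(j, strand, table.n_levels)
        (ei, es), (zi, zs) = addr["epsilon"], addr["zeta"]
        return bb.classify_bi_bii(table.get("epsilon", ei, es), table.get("zeta", zi, zs))[keep]

    if family == "RR":
        kwargs["watson_bii"] = bii_at("W")
    elif family == "YR":
        kwargs["w3_bii"] = bii_at("W3'")
        kwargs["c3_bii"] = bii_at("C3'")
    assignment = ss.assign_substates(shift, slide, twist, family, **kwargs)
    grid = ss.density3d(shift, slide, twist, config.density_bins)
    return {
        "reading": oriented,
        "family": family,
        "fractions": assignment.fractions(),
        "centers": {k: [round(float(x), 3) for x in v] for k, v in assignment.centers.items()},
        "isolevel_regions": {
            str(lvl): [
                {"peak": [round(float(x), 3) for x in r["peak"]], "size": r["size"]}
                for r in grid.regions(lvl)
            ]
            for lvl in config.isolevels
        },
    }


@_stage("convergence")
def convergence_stage(table: SeriesTable) -> dict:
    report = {"half_trajectory": _agreement_dict(cv.half_trajectory_agreement(table))}
    seq = table.sequence or ""
    if len(seq) == 18 and seq[5:9] == seq[9:13]:
        design = build_oligomer(seq[9:13])
        if design.sequence == seq:
            report["repeat_positions"] = _agreement_dict(cv.repeat_agreement(table, design))
    return report


def _agreement_dict(rep: cv.AgreementReport) -> dict:
    return {
        "passed": rep.passed,
        "max_delta": {
            cls: rep.max_delta(cls) for cls in ("translational", "rotational", "backbone")
        },
        "failures": [
            {"parameter": r[0], "delta": r[2], "threshold": r[3]} for r in rep.failures()
        ],
    }


def run_pipeline(
    table: SeriesTable,
    tetra: str | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Execute all analysis stages on a series table.

    ``tetra`` selects the analyzed tetranucleotide (defaulting to a 4-level
    fragment's own sequence); within longer oligomers its centermost
    occurrence is used.  Returns the full report bundle as a dict.
    """
    config = config or RunConfig()
    seq = table.sequence
    if seq is None:
        raise PipelineError("trim", "series table lacks a sequence in its metadata")
    if tetra is None:
        if len(seq) != 4:
            raise PipelineError("trim", "tetra must be named for multi-level tables")
        tetra = seq
    trimmed = cv.equilibration_trim(table, fraction=config.trim_fraction)
    log.info("STAGE trim ok n=%d", len(trimmed))
    try:
        mask_all = tj.wc_filter(trimmed, config.wc_cutoff)
    except Exception as exc:
        raise PipelineError("wc_filter", str(exc)) from exc
    log.info("STAGE wc_filter ok masked=%.4f", float(mask_all.mean()))

    from .sequence import reverse_complement

    t = tetra.upper()
    if len(seq) == 4:
        if t == seq:
            occ = Occurrence(t, "Watson", 1, (1, 2, 3, 4))
        elif t == reverse_complement(seq):
            occ = Occurrence(t, "Crick", 1, (1, 2, 3, 4))
        else:
            raise PipelineError("trim", f"{tetra!r} is not this fragment's context")
    else:
        occ = centermost_occurrence(t, _as_design(seq))
    selection = tj.central_selection(occ, trimmed)
    jmask = mask_all[:, selection["_junction"] - 1]
    step = occ.tetra[1:3]

    report = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seed": config.seed,
        "sequence": seq,
        "tetranucleotide": occ.tetra,
        "occurrence": {"strand": occ.strand, "start": occ.start, "levels": list(occ.levels)},
        "n_snapshots": len(trimmed),
        "wc_masked_fraction": float(jmask.mean()),
        "statistics": statistics_stage(selection, jmask),
        "shapes": shapes_stage(selection, jmask),
        "backbone": backbone_stage(trimmed, occ, selection, config, step),
        "correlations": correlations_stage(trimmed, occ, jmask, config),
        "substates": substates_stage(trimmed, occ, selection, jmask, config),
        "convergence": convergence_stage(trimmed),
    }
    return report


def _as_design(seq: str):
    from .sequence import OligomerDesign

    return OligomerDesign(seq[9:13] if len(seq) == 18 else seq[:4], seq)


def write_report(report: dict, outdir) -> Path:
    """Write the report bundle (JSON + tidy CSV tables) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
    import csv as _csv

    with open(outdir / "statistics.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["tetranucleotide", "parameter", "mean", "sd", "min", "max", "range", "n"])
        for param, s in report["statistics"].items():
            w.writerow([report["tetranucleotide"], param, s["mean"], s["sd"],
                        s["min"], s["max"], s["range"], s["n"]])
    with open(outdir / "shapes.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["tetranucleotide", "parameter", "label", "peaks"])
        for param, s in report["shapes"].items():
            w.writerow([report["tetranucleotide"], param, s["label"],
                        ";".join(f"{p:.2f}" for p in s["peaks"])])
    return outdir / "report.json"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
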