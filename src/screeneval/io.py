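"""File I/O, scheme configuration, and the end-to-end evaluation report.

Matrices travel as CSV or XLSX (first column hospital id, one column per
indicator, header row required); legacy XLS inputs should be re-saved as
XLSX or CSV first.  Schemes serialise to a YAML/JSON mapping with one
entry per indicator.  :func:`run_evaluation` executes the full pipeline —
subjective weights, entropy weights, multiplicative combination, weighted
scoring, ranking, and pairwise methodology comparison — and
:func:`write_report` materialises the result as a report directory
(weights.csv, rankings.csv, weight_changes.csv, comparisons.csv,
report.json).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .comparison import ComparisonMetrics, comparison_frame, compare_methodologies
from .evaluation import RankingTable, evaluate
from .indicators import (
    Attribute,
    BoundMode,
    IndicatorDefinition,
    PerformanceMatrix,
    SchemeError,
    ScoringBand,
    attributes_of,
)
from .weighting import (
    DegenerateDataError,
    WeightVector,
    combine_msn,
    entropy_weights,
    normalize,
    shift,
    subjective_weights,
    weight_change,
)

__all__ = [
    "EvaluationReport",
    "read_matrix",
    "write_matrix",
    "load_scheme",
    "dump_scheme",
    "run_evaluation",
    "write_report",
]

logger = logging.getLogger("screeneval")


def _version() -> str:
    try:
        return metadata.version("screeneval")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------- matrices

def read_matrix(
    path: str | Path,
    scheme: Sequence[IndicatorDefinition] | None = None,
) -> PerformanceMatrix:
    """Read a hospitals x indicators points matrix from CSV or XLSX.

    When a scheme is given, columns are reconciled against it by indicator
    id (any column order is accepted, unknown or missing columns are
    errors) and cell ranges are validated.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame = pd.read_excel(path, index_col=0)
    elif path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, index_col=0)
    else:
        raise SchemeError(f"unsupported matrix format {path.suffix!r} "
                          "(use .csv or .xlsx; re-save legacy .xls as .xlsx)")
    frame.columns = [str(c) for c in frame.columns]
    frame.index = [str(h) for h in frame.index]
    if not frame.map(lambda v: isinstance(v, (int, float))).all().all():
        raise SchemeError(f"{path}: non-numeric cell encountered")
    if scheme is not None:
        wanted = [ind.id for ind in scheme]
        unknown = set(frame.columns) - set(wanted)
        if unknown:
            raise SchemeError(f"{path}: unknown indicator columns {sorted(unknown)}")
        missing = set(wanted) - set(frame.columns)
        if missing:
            raise SchemeError(f"{path}: missing indicator columns {sorted(missing)}")
        frame = frame[wanted]
        for ind in scheme:
            col = frame[ind.id]
            if (col > ind.max_points).any():
                raise SchemeError(
                    f"{path}: {ind.id} holds values above max_points "
                    f"{ind.max_points}"
                )
    return PerformanceMatrix.from_frame(frame)


def write_matrix(matrix: PerformanceMatrix, path: str | Path) -> None:
    """Write a matrix to CSV or XLSX (chosen by suffix)."""
    path = Path(path)
    frame = matrix.to_frame()
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path)
    else:
        frame.to_csv(path, float_format="%.12g")


# ------------------------------------------------------------------ scheme

def _band_to_dict(band: ScoringBand) -> dict:
    out: dict = {"points": band.points, "mode": band.mode.value}
    if band.exact is not None:
        out["exact"] = band.exact
        return out
    if math.isfinite(band.lower):
        out["lower"] = band.lower
    if math.isfinite(band.upper):
        out["upper"] = band.upper
    if band.lower_inclusive is not True:
        out["lower_inclusive"] = band.lower_inclusive
    if band.upper_inclusive is not False:
        out["upper_inclusive"] = band.upper_inclusive
    return out


def _band_from_dict(d: dict) -> ScoringBand:
    return ScoringBand(
        points=int(d["points"]),
        lower=float(d.get("lower", -math.inf)),
        upper=float(d.get("upper", math.inf)),
        mode=BoundMode(d.get("mode", "absolute")),
        lower_inclusive=bool(d.get("lower_inclusive", True)),
        upper_inclusive=bool(d.get("upper_inclusive", False)),
        exact=None if d.get("exact") is None else float(d["exact"]),
    )


def dump_scheme(scheme: Sequence[IndicatorDefinition], path: str | Path) -> None:
    """Serialise a scheme to YAML (or JSON when the suffix is .json)."""
    entries = [
        {
            "id": ind.id,
            "name": ind.name,
            "attribute": ind.attribute.value,
            "assigned_score": ind.assigned_score,
            "reference_standard": ind.reference_standard,
            "bands": [_band_to_dict(b) for b in ind.bands],
        }
        for ind in scheme
    ]
    path = Path(path)
    text = (
        json.dumps({"indicators": entries}, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump({"indicators": entries}, sort_keys=False)
    )
    path.write_text(text)


def load_scheme(path: str | Path) -> list[IndicatorDefinition]:
    """Load a scheme from a YAML or JSON configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "indicators" not in raw:
        raise SchemeError(f"{path}: expected a top-level 'indicators' list")
    out = []
    for entry in raw["indicators"]:
        out.append(
            IndicatorDefinition(
                id=str(entry["id"]),
                name=str(entry.get("name", entry["id"])),
                attribute=Attribute(entry["attribute"]),
                assigned_score=int(entry["assigned_score"]),
                bands=tuple(_band_from_dict(b) for b in entry["bands"]),
                reference_standard=(
                    None if entry.get("reference_standard") is None
                    else float(entry["reference_standard"])
                ),
            )
        )
    return out


def apply_standards(
    scheme: Sequence[IndicatorDefinition],
    standards: dict[str, float],
) -> list[IndicatorDefinition]:
    """Attach reference standards (indicator id -> value) to a scheme."""
    unknown = set(standards) - {ind.id for ind in scheme}
    if unknown:
        raise SchemeError(f"standards name unknown indicators {sorted(unknown)}")
    return [
        ind.with_standard(standards[ind.id]) if ind.id in standards else ind
        for ind in scheme
    ]


# ------------------------------------------------------------------ report

@dataclass(frozen=True)
class EvaluationReport:
    """Complete, regenerable output of one evaluation run."""

    scheme: tuple[IndicatorDefinition, ...]
    matrix: PerformanceMatrix
    weights: dict[str, WeightVector]          # subjective/objective/combined/original
    weight_changes: pd.DataFrame              # subjective -> objective, percent
    rankings: dict[str, RankingTable]
    comparisons: list[ComparisonMetrics]
    provenance: dict = field(default_factory=dict)
    warnings_: tuple[str, ...] = ()

    def weights_frame(self) -> pd.DataFrame:
        rows = []
        for name, wv in self.weights.items():
            for ind_id, w in zip(wv.indicator_ids, wv.weights):
                rows.append({"methodology": name, "indicator_id": ind_id,
                             "weight": w})
        return pd.DataFrame(rows)

    def rankings_frame(self) -> pd.DataFrame:
        """Wide table: one hospital/score/rank column triple per methodology."""
        blocks = []
        for name, rt in self.rankings.items():
            f = rt.frame.reset_index()
            f.columns = [f"{name}_hospital", f"{name}_score", f"{name}_rank"]
            blocks.append(f)
        return pd.concat(blocks, axis=1)


def run_evaluation(
    matrix: PerformanceMatrix,
    scheme: Sequence[IndicatorDefinition],
    reading: str = "no_radical",
    provenance: dict | None = None,
) -> EvaluationReport:
    """Execute the full weighting-evaluation-comparison pipeline.

    Stages: subjective weights -> normalisation + shift -> entropy weights
    -> multiplicative combination -> weighted scoring and ranking under
    the original (unit-weight), subjective, objective and combined
    methodologies -> pairwise comparison metrics.  Deterministic given
    its inputs.  A degenerate matrix (no column carries information)
    degrades to equal objective weights with a logged warning rather than
    failing.
    """
    scheme_ids = tuple(ind.id for ind in scheme)
    if matrix.indicator_ids != scheme_ids:
        raise SchemeError("matrix indicator columns do not match the scheme")

    notes: list[str] = []
    logger.info("stage: subjective weights")
    w_subj = subjective_weights(scheme)

    logger.info("stage: entropy weights")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        normalized = normalize(matrix, attributes_of(scheme))
        shifted = shift(normalized)
        try:
            w_obj = entropy_weights(shifted).weights
        except DegenerateDataError as exc:
            logger.warning("entropy weighting degenerate: %s", exc)
            notes.append(f"degraded mode: {exc}; equal objective weights used")
            w_obj = WeightVector.equal(matrix.indicator_ids)
    notes.extend(str(w.message) for w in caught)

    logger.info("stage: combined weights")
    w_comb = combine_msn([w_subj, w_obj])
    w_orig = WeightVector.unit(matrix.indicator_ids)

    logger.info("stage: scoring and ranking")
    weights = {
        "original": w_orig,
        "subjective": w_subj,
        "objective": w_obj,
        "combined": w_comb,
    }
    rankings = {
        name: evaluate(matrix, wv, methodology=name)
        for name, wv in weights.items()
    }

    logger.info("stage: methodology comparison")
    try:
        comparisons = compare_methodologies(list(rankings.values()), reading)
    except Exception as exc:  # degenerate score profiles
        logger.warning("comparison degenerate: %s", exc)
        notes.append(f"degraded mode: comparison skipped ({exc})")
        comparisons = []

    prov = dict(provenance or {})
    prov.setdefault("tool_version", _version())
    return EvaluationReport(
        scheme=tuple(scheme),
        matrix=matrix,
        weights=weights,
        weight_changes=weight_change(w_subj, w_obj),
        rankings=rankings,
        comparisons=comparisons,
        provenance=prov,
        warnings_=tuple(notes),
    )


def write_report(report: EvaluationReport, outdir: str | Path) -> Path:
    """Write the report directory: CSV tables plus a JSON twin."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    report.weights_frame().to_csv(outdir / "weights.csv", index=False,
                                  float_format=fmt)
    report.rankings_frame().to_csv(outdir / "rankings.csv", index=False,
                                   float_format=fmt)
    wc = report.weight_changes.reset_index()
    wc.to_csv(outdir / "weight_changes.csv", index=False, float_format=fmt)
    comparison_frame(report.comparisons).to_csv(
        outdir / "comparisons.csv", index=False, float_format=fmt
    )
    payload = {
        "provenance": report.provenance,
        "warnings": list(report.warnings_),
        "weights": {
            name: dict(zip(wv.indicator_ids, map(float, wv.weights)))
            for name, wv in report.weights.items()
        },
        "weight_changes": {
            ind: None if not bool(row["defined"]) else float(row["pct_change"])
            for ind, row in report.weight_changes.iterrows()
        },
        "rankings": {
            name: [
                {"hospital_id": h, "score": float(r["score"]),
                 "rank": int(r["rank"])}
                for h, r in rt.frame.iterrows()
            ]
            for name, rt in report.rankings.items()
        },
        "comparisons": [
            {
                "method_a": m.pair[0],
                "method_b": m.pair[1],
                "head_tail_rate": m.head_tail_rate,
                "discrimination_delta": m.discrimination_delta,
            }
            for m in report.comparisons
        ],
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))
    return outdir


def read_matrix_with_digest(
    path: str | Path,
    scheme: Sequence[IndicatorDefinition] | None = None,
) -> tuple[PerformanceMatrix, dict]:
    """Read a matrix and return it with an input-digest provenance record."""
    path = Path(path)
    return read_matrix(path, scheme), {
        "input": str(path), "sha256_16": _digest(path)
    }
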