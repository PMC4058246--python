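"""The virtual-screening funnel.

Compounds flow through three gates: a rule-of-five drug-likeness filter, an
activity gate requiring an acceptable predicted pEC50 from *all* supplied
prediction models, and a final ranking of the survivors by an externally
supplied dock score.  Docking itself is out of scope — the dock score is an
injected column, so any docking engine's output can be plugged in.  Every
compound's fate is recorded (no silent drops): the report always has one row
per library compound.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

from .descriptors import DescriptorConventions, DEFAULT_CONVENTIONS, descriptor_vector
from .molgraph import MolecularGraph, MolGraphError, physchem_counts
from .qsar import QsarModel


@dataclass
class LipinskiThresholds:
    """Rule-of-five limits; failure requires a strict exceedance (> 500 fails,
    exactly 500 passes — the usual reading of "no more than")."""

    mw: float = 500.0
    hbd: int = 5
    hba: int = 10
    logp: float = 5.0


@dataclass
class ScreenConfig:
    activity_threshold: float = 5.0  # pEC50 of 10 μM
    lipinski: LipinskiThresholds = field(default_factory=LipinskiThresholds)
    conventions: DescriptorConventions = DEFAULT_CONVENTIONS


@dataclass
class ScreenRecord:
    """One compound's journey through the funnel."""

    compound_id: str
    lipinski_pass: bool | None = None
    lipinski_flags: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)
    activity_pass: bool | None = None
    dock_score: float | None = None
    rank: int | None = None
    error: str | None = None
    annotations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "lipinski_pass": self.lipinski_pass,
            "lipinski_flags": dict(self.lipinski_flags),
            "predictions": dict(self.predictions),
            "activity_pass": self.activity_pass,
            "dock_score": self.dock_score,
            "rank": self.rank,
            "error": self.error,
            "annotations": dict(self.annotations),
        }


def lipinski_filter(
    g: MolecularGraph,
    thresholds: LipinskiThresholds | None = None,
) -> tuple[bool, dict]:
    """Rule-of-five verdict with per-criterion flags.

    logP is taken from the graph's annotations (it is an externally supplied
    property here); when absent the criterion is marked ``not evaluated`` and
    passes with a warning.
    """
    thr = thresholds or LipinskiThresholds()
    mw, hbd, hba = physchem_counts(g)
    flags = {
        "mw": {"value": mw, "pass": not mw > thr.mw},
        "hbd": {"value": hbd, "pass": not hbd > thr.hbd},
        "hba": {"value": hba, "pass": not hba > thr.hba},
    }
    logp = g.annotations.get("logP")
    if logp is None:
        warnings.warn(f"logP not supplied for {g.name!r}; criterion not evaluated")
        flags["logp"] = {"value": None, "pass": True, "evaluated": False}
    else:
        flags["logp"] = {"value": float(logp), "pass": not logp > thr.logp, "evaluated": True}
    verdict = all(f["pass"] for f in flags.values())
    return verdict, flags


def activity_gate(predictions: dict[str, float], threshold: float) -> bool:
    """True iff the *least* optimistic of the model predictions clears the bar."""
    values = [float(v) for v in predictions.values()]
    if not values or any(not math.isfinite(v) for v in values):
        raise ValueError("activity gate needs finite predictions from every model")
    return min(values) >= threshold


def run_screen(
    library: list[MolecularGraph],
    models: dict[str, QsarModel],
    dock_scores: dict[str, float] | None = None,
    cfg: ScreenConfig | None = None,
    annotations: dict[str, dict] | None = None,
) -> list[ScreenRecord]:
    """Apply the full funnel to a compound library.

    ``models`` maps a label (e.g. ``mlr``/``svr``/``bayes``) to a predictor;
    ``frozen-table`` models predict by compound id, everything else from the
    computed descriptor vector.  Survivors of both gates that have a dock
    score are ranked by dock score descending (ties broken by compound id);
    every other compound keeps rank ``None``.  The returned list is ordered:
    ranked compounds first, then the rest in library order.
    """
    cfg = cfg or ScreenConfig()
    dock_scores = dock_scores or {}
    annotations = annotations or {}
    records: list[ScreenRecord] = []
    for g in library:
        rec = ScreenRecord(compound_id=g.name,
                           annotations=dict(annotations.get(g.name, {})))
        rec.dock_score = dock_scores.get(g.name)
        try:
            rec.lipinski_pass, rec.lipinski_flags = lipinski_filter(g, cfg.lipinski)
            vec = descriptor_vector(g, cfg.conventions)
            for label, model in models.items():
                if model.kind == "frozen-table":
                    rec.predictions[label] = model.predict_by_id(g.name)
                else:
                    rec.predictions[label] = model.predict(vec)
            rec.activity_pass = activity_gate(rec.predictions, cfg.activity_threshold)
        except (MolGraphError, KeyError, ValueError) as exc:
            rec.error = str(exc)
        records.append(rec)

    ranked = sorted(
        (r for r in records
         if r.error is None and r.lipinski_pass and r.activity_pass
         and r.dock_score is not None),
        key=lambda r: (-r.dock_score, r.compound_id),
    )
    for pos, rec in enumerate(ranked, start=1):
        rec.rank = pos
    rest = [r for r in records if r.rank is None]
    return ranked + rest


def report_dataframe(records: list[ScreenRecord]):
    """Flat report table mirroring a ranked-results layout."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id,
            "rank": r.rank,
            "dock_score": r.dock_score,
            "lipinski_pass": r.lipinski_pass,
            "activity_pass": r.activity_pass,
            "error": r.error,
        }
        row.update({f"pEC50_{k}": v for k, v in r.predictions.items()})
        row.update(r.annotations)
        rows.append(row)
    return pd.DataFrame(rows)


def write_audit_log(records: list[ScreenRecord], path) -> None:
    """JSONL audit trail: one line per compound, full gate detail."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")
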