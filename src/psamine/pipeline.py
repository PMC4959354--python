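"""End-to-end orchestration: cohort -> transform -> mine -> select -> survival.

``run_pipeline`` executes the full discovery procedure driven by a nested
configuration (see :data:`DEFAULT_CONFIG`): read or simulate a cohort,
impute covariates, build before-/after-nadir velocity sequences, fit both
discretizations per segment, mine frequent per-class patterns, select the
predictive then the most informative pattern, and compare it against the
classical dichotomized prognostic factors. All tabular/JSON artifacts are
written to the configured output directory; outputs are deterministic under
a fixed seed.

A segment may legitimately terminate early: when the supervised
discretization accepts no split it is recorded as not applicable, and when
no pattern improves on the baseline significantly the segment reports
"no predictive patterns".
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import PatientRecord, cohort_summary, impute_missing, read_cohort
from .mining import Pattern, mine_class_patterns
from .selection import (EvaluationResult, pattern_feature, select_informative,
                        select_predictive)
from .simulate import SimConfig, generate_cohort
from .survival import compare_prognostics
from .transform import (AFTER_NADIR, BEFORE_NADIR, MDLPDiscretizer,
                        EqualFrequencyDiscretizer, compute_velocities,
                        discretize, find_nadir, split_at_nadir)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "io": {"measurements": None, "covariates": None, "outdir": None},
    "sim": {},  # SimConfig overrides; used when io paths are absent
    "impute": {"strategy": "median_mode"},
    "transform": {"segments": [AFTER_NADIR, BEFORE_NADIR], "n_bins": 5},
    "mining": {"min_support": 0.3, "max_length": 3, "counting_mode": "per_sequence"},
    "selection": {"n_folds": 10, "alpha": 0.05, "frequency_basis": "pattern_support"},
    "survival": {"thresholds": {}},
}


def merge_config(overrides: Mapping | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: Mapping) -> None:
        for k, v in src.items():
            if isinstance(v, Mapping) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides)
    return cfg


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def patient_segments(record: PatientRecord):
    """(before, after) velocity sequences for one patient (may be empty)."""
    if len(record.measurements) < 2:
        return split_at_nadir([], 0.0, record.id)
    _, t_nadir = find_nadir(record.measurements)
    points = compute_velocities(record.measurements)
    return split_at_nadir(points, t_nadir, record.id)


def _fit_segment_schemes(records, vseqs, n_bins):
    """Pool a segment's PSAV instances and fit both discretizations."""
    values, labels = [], []
    for r in records:
        seq = vseqs[r.id]
        cls = "event" if r.event else "nonevent"
        for p in seq.points:
            values.append(p.psav)
            labels.append(cls)
    values = np.asarray(values)
    schemes = {}
    notes = []
    eq = EqualFrequencyDiscretizer(n_bins=n_bins).fit(values)
    schemes["equal_frequency"] = eq.scheme_
    md = MDLPDiscretizer().fit(values, np.asarray(labels))
    if len(md.scheme_.labels) == 1:
        notes.append("entropy-based discretization not applicable (no accepted split)")
        logger.info(notes[-1])
    else:
        schemes["entropy_mdlp"] = md.scheme_
    return schemes, notes


def _run_segment(records, segment, seg_vseqs, cfg):
    """Transform + mine + select for one nadir segment. Returns a result dict."""
    out = {"segment": segment, "notes": [], "schemes": {}, "candidates": [],
           "evaluations": [], "final_pattern": None, "selection_log": None,
           "sequences": {}, "n_patients_with_sequence": 0}

    nonempty = [r for r in records if len(seg_vseqs[r.id]) > 0]
    out["n_patients_with_sequence"] = len(nonempty)
    if len(nonempty) < 2:
        out["notes"].append("too few patients with velocity data in this segment")
        return out

    with _stage(f"discretization[{segment}]"):
        schemes, notes = _fit_segment_schemes(nonempty, seg_vseqs,
                                              cfg["transform"]["n_bins"])
    out["notes"].extend(notes)
    out["schemes"] = schemes

    mining_cfg = cfg["mining"]
    candidates: list[Pattern] = []
    sequences = {}
    for name, scheme in schemes.items():
        seqs = [
            discretize(seg_vseqs[r.id], scheme, "event" if r.event else "nonevent")
            for r in records
        ]
        sequences[name] = seqs
        with _stage(f"mining[{segment}/{name}]"):
            non, eve = mine_class_patterns(
                seqs, mining_cfg["min_support"], mining_cfg["max_length"],
                mining_cfg["counting_mode"], scheme=name)
        candidates.extend(non)
        candidates.extend(eve)
    out["sequences"] = sequences
    out["candidates"] = candidates
    if not candidates:
        out["notes"].append("no frequent candidate patterns")
        return out

    sel_cfg = cfg["selection"]
    with _stage(f"selection[{segment}]"):
        accepted, results = select_predictive(
            candidates, records, sequences, alpha=sel_cfg["alpha"],
            n_folds=sel_cfg["n_folds"], seed=cfg["seed"])
    out["evaluations"] = results
    if not accepted:
        out["notes"].append("no predictive patterns")
        return out
    with _stage(f"informative[{segment}]"):
        final, log = select_informative(accepted, schemes,
                                        sel_cfg["frequency_basis"])
    out["final_pattern"] = final
    out["selection_log"] = log
    return out


def run_pipeline(config: Mapping | None = None, outdir=None) -> dict:
    """Run the full discovery pipeline; return the report dict.

    ``config`` is merged over :data:`DEFAULT_CONFIG`. ``outdir`` (or
    ``config["io"]["outdir"]``), when given, receives the artifacts:
    cohort_summary.json, schemes.json, candidates.csv, evaluation.csv,
    selection.json, survival.csv, survival_curves.csv and run.log.
    """
    cfg = merge_config(config)
    outdir = Path(outdir or cfg["io"]["outdir"]) if (outdir or cfg["io"]["outdir"]) else None

    handler = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("psamine").addHandler(handler)
        logging.getLogger("psamine").setLevel(logging.INFO)

    try:
        with _stage("cohort"):
            if cfg["io"]["measurements"]:
                records = read_cohort(cfg["io"]["measurements"], cfg["io"]["covariates"])
            else:
                sim = SimConfig(**{**cfg["sim"], "seed": cfg["seed"]})
                records = generate_cohort(sim)
        with _stage("impute"):
            records = impute_missing(records, cfg["impute"]["strategy"])

        with _stage("transform"):
            segs = {r.id: patient_segments(r) for r in records}
            by_segment = {
                BEFORE_NADIR: {pid: s[0] for pid, s in segs.items()},
                AFTER_NADIR: {pid: s[1] for pid, s in segs.items()},
            }

        report: dict = {"config": cfg, "cohort_summary": cohort_summary(records),
                        "segments": {}, "survival": []}
        for segment in cfg["transform"]["segments"]:
            report["segments"][segment] = _run_segment(
                records, segment, by_segment[segment], cfg)

        # survival comparison uses the after-nadir final pattern when present
        seg_res = report["segments"].get(AFTER_NADIR)
        if seg_res and seg_res["final_pattern"] is not None:
            final = seg_res["final_pattern"]
            seqs = seg_res["sequences"][final.scheme]
            ids = [r.id for r in records]
            indicator = pattern_feature(seqs, final, ids)
            with _stage("survival"):
                report["survival"] = compare_prognostics(
                    records, indicator, cfg["survival"]["thresholds"])

        if outdir:
            _write_artifacts(report, outdir)
        return report
    finally:
        if handler:
            logging.getLogger("psamine").removeHandler(handler)
            handler.close()


# --- artifact serialization ----------------------------------------------------


def _write_artifacts(report: dict, outdir: Path) -> None:
    (outdir / "cohort_summary.json").write_text(
        json.dumps(report["cohort_summary"], indent=2) + "\n")

    schemes_doc = {}
    cand_rows = []
    eval_rows = []
    selection_doc = {}
    for segment, res in report["segments"].items():
        schemes_doc[segment] = {name: s.to_dict() for name, s in res["schemes"].items()}
        for p in res["candidates"]:
            cand_rows.append({
                "segment": segment, "method": p.scheme, "class": p.class_origin,
                "pattern": str(p), "support": p.support,
                "instance_count": p.instance_count,
            })
        for r in res["evaluations"]:
            eval_rows.append({
                "segment": segment, "method": r.pattern.scheme,
                "pattern": str(r.pattern), "class": r.pattern.class_origin,
                "mean_auc_baseline": float(np.mean(r.fold_auc_baseline)),
                "sd_auc_baseline": float(np.std(r.fold_auc_baseline, ddof=1)),
                "mean_auc_augmented": float(np.mean(r.fold_auc_augmented)),
                "sd_auc_augmented": float(np.std(r.fold_auc_augmented, ddof=1)),
                "mean_cindex_baseline": float(np.mean(r.fold_cindex_baseline)),
                "mean_cindex_augmented": float(np.mean(r.fold_cindex_augmented)),
                "sd_cindex_augmented": float(np.std(r.fold_cindex_augmented, ddof=1)),
                "mean_delta_auc": r.mean_delta_auc,
                "mean_delta_cindex": r.mean_delta_cindex,
                "p_auc": r.p_auc, "p_cindex": r.p_cindex,
                "accepted": r.accepted,
                "reject_reasons": "; ".join(r.reject_reasons),
            })
        selection_doc[segment] = {
            "final_pattern": str(res["final_pattern"]) if res["final_pattern"] else None,
            "scheme": res["final_pattern"].scheme if res["final_pattern"] else None,
            "notes": res["notes"],
            "log": res["selection_log"],
        }

    (outdir / "schemes.json").write_text(json.dumps(schemes_doc, indent=2) + "\n")
    pd.DataFrame(cand_rows).to_csv(outdir / "candidates.csv", index=False)
    pd.DataFrame(eval_rows).to_csv(outdir / "evaluation.csv", index=False)
    (outdir / "selection.json").write_text(json.dumps(selection_doc, indent=2) + "\n")

    surv_rows, curve_rows = [], []
    for c in report["survival"]:
        surv_rows.append({
            "grouping": c.grouping_name, "threshold": c.threshold,
            "n_group0": c.group_sizes[0], "n_group1": c.group_sizes[1],
            "logrank_statistic": c.logrank_statistic, "p_value": c.p_value,
        })
        for gname, pts in c.curve_points.items():
            for t, s, n in pts:
                curve_rows.append({"grouping": c.grouping_name, "group": gname,
                                   "time": t, "survival": s, "at_risk": n})
    pd.DataFrame(surv_rows).to_csv(outdir / "survival.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(outdir / "survival_curves.csv", index=False)
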