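"""End-to-end orchestration of the agreement assessment.

One call (:func:`run_full_assessment`) takes a configuration, obtains a
study pair (simulated or loaded from a manifest), intersects it, binarizes
drug response on the full panels before restriction, computes per-datatype
consistency reports, compares the consistency distributions between data
types, runs the information-leak design comparison, and writes everything
as CSV/JSON plus a human-readable summary.  Every number appearing in the
text summary is present in the machine-readable outputs, and reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, consistency, simulate
from .calling import BinaryCallMatrix, ThresholdConfig, call_fixed, call_waterfall
from .io import PairedStudy, PgxError, StudyBundle, load_manifest

ALL_STEPS = ("consistency", "datatype_comparison", "design_comparison")


@dataclass
class RunConfig:
    """Configuration of a full assessment run."""

    out_dir: Path
    seed: int = 0
    manifest: Path | None = None            # load a study pair from disk ...
    sim_params: simulate.SimulationParams | None = None  # ... or simulate one
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    min_pairs: int = consistency.DEFAULT_MIN_PAIRS
    sig_q: float = association.DEFAULT_SIG_Q
    design_reps: int = 20
    steps: tuple[str, ...] = ALL_STEPS

    def __post_init__(self) -> None:
        if self.manifest is None and self.sim_params is None:
            self.sim_params = simulate.SimulationParams(seed=self.seed)
        unknown = set(self.steps) - set(ALL_STEPS)
        if unknown:
            raise ValueError(f"unknown steps: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        sim_params = None
        if "simulate" in cfg:
            sim_params = simulate.SimulationParams(**(cfg["simulate"] or {}))
        manifest = cfg.get("manifest")
        if manifest is not None:
            manifest = (path.parent / manifest).resolve()
        thresholds = ThresholdConfig(**(cfg.get("thresholds") or {}))
        return cls(
            out_dir=Path(out_dir or cfg.get("out_dir", "pgxagree_out")),
            seed=int(cfg.get("seed", 0)),
            manifest=manifest,
            sim_params=sim_params,
            thresholds=thresholds,
            min_pairs=int(cfg.get("min_pairs", consistency.DEFAULT_MIN_PAIRS)),
            sig_q=float(cfg.get("sig_q", association.DEFAULT_SIG_Q)),
            design_reps=int(cfg.get("design_reps", 20)),
            steps=tuple(cfg.get("steps", ALL_STEPS)),
        )


def _aligned_calls(bundle: StudyBundle, pair: PairedStudy, measure: str,
                   method: str, cfg: ThresholdConfig) -> BinaryCallMatrix | None:
    """Calls from the FULL panel, restricted to the pair's common labels."""
    m = bundle.sensitivity.get(measure)
    if m is None:
        return None
    if method == "WATERFALL":
        calls = call_waterfall(m, cfg, restrict_to=pair.common_cell_lines)
    else:
        calls = call_fixed(m, cfg)
        calls.calls = calls.calls.loc[pair.common_cell_lines]
    calls.calls = calls.calls.loc[:, pair.common_drugs]
    calls.per_drug_cutoff = {d: calls.per_drug_cutoff[d] for d in pair.common_drugs}
    return calls


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, float) and np.isnan(v):
            out[k] = None
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def run_full_assessment(cfg: RunConfig) -> dict:
    """Run the configured steps and write the report bundle.

    Returns a dict with the in-memory results (reports, comparison tables)
    and writes CSV/JSON files plus ``summary.txt`` and ``status.json``
    under ``cfg.out_dir``.  Raises on the first failing step after writing
    the status file, so partial outputs are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict = {"steps_completed": [], "counts": {}}
    results: dict = {}
    try:
        # --- obtain the study pair -------------------------------------
        if cfg.manifest is not None:
            bundle_a, bundle_b = load_manifest(cfg.manifest)
        else:
            sim = simulate.generate_pair(cfg.sim_params)
            bundle_a, bundle_b = sim.study_a, sim.study_b
        from .io import intersect_studies
        pair = intersect_studies(bundle_a, bundle_b)
        results["pair"] = pair
        status["counts"].update({
            "common_cell_lines": len(pair.common_cell_lines),
            "common_drugs": len(pair.common_drugs),
            "common_genes": len(pair.common_genes),
            "drop_report": pair.drop_report,
        })
        status["steps_completed"].append("intersect")

        summary_blocks: dict[str, dict] = {}

        if "consistency" in cfg.steps:
            reports: dict[str, consistency.ConsistencyReport] = {}
            for dtype in ("AUC", "IC50", "EXPRESSION", "CNV", "MUTATION"):
                present_a = (dtype in pair.study_a.sensitivity
                             or dtype in pair.study_a.profiles)
                present_b = (dtype in pair.study_b.sensitivity
                             or dtype in pair.study_b.profiles)
                if not (present_a and present_b):
                    continue
                reports[dtype] = consistency.per_entity_consistency(
                    pair, dtype, cfg.thresholds, min_pairs=cfg.min_pairs)
            for measure in ("AUC", "IC50"):
                for method in ("WATERFALL", "FIXED"):
                    ca = _aligned_calls(bundle_a, pair, measure, method,
                                        cfg.thresholds)
                    cb = _aligned_calls(bundle_b, pair, measure, method,
                                        cfg.thresholds)
                    if ca is None or cb is None:
                        continue
                    rep = consistency.calls_consistency(
                        ca, cb, cfg.thresholds, min_pairs=cfg.min_pairs)
                    reports[rep.datatype] = rep
            for measure in ("AUC", "IC50"):
                call_key = f"CALLS_{measure}_WATERFALL"
                if measure in reports and call_key in reports:
                    merged = consistency.merge_reports(
                        reports[measure], reports[call_key], cfg.thresholds)
                    reports[f"UNION_{measure}"] = merged
            for name, rep in reports.items():
                rep.to_frame().to_csv(out / f"consistency_{name}.csv", index=False)
                summary_blocks[name] = _jsonable(rep.summary)
            results["reports"] = reports
            _write_json(summary_blocks, out / "consistency_summary.json")
            status["steps_completed"].append("consistency")

        if "datatype_comparison" in cfg.steps and results.get("reports"):
            reports = results["reports"]
            comps = []
            for genomic in ("CNV", "EXPRESSION"):
                for pharm in ("AUC", "IC50"):
                    if genomic in reports and pharm in reports:
                        c = consistency.compare_datatype_consistency(
                            reports[genomic], reports[pharm], "greater")
                        comps.append(_jsonable(c))
            results["datatype_comparisons"] = comps
            _write_json(comps, out / "datatype_comparisons.json")
            pd.DataFrame(comps).to_csv(out / "datatype_comparisons.csv", index=False)
            status["steps_completed"].append("datatype_comparison")

        if "design_comparison" in cfg.steps:
            params = cfg.sim_params or simulate.SimulationParams(seed=cfg.seed)
            table = association.run_design_comparison(
                params, n_reps=cfg.design_reps, seed=cfg.seed, sig_q=cfg.sig_q)
            table.to_csv(out / "design_comparison.csv", index=False)
            dsum = (table.groupby("design_id")[["effect_rho", "hit_kappa"]]
                    .mean().round(6))
            design_summary = {k: _jsonable(v) for k, v in
                              dsum.to_dict(orient="index").items()}
            results["design_comparison"] = table
            results["design_summary"] = design_summary
            _write_json(design_summary, out / "design_summary.json")
            status["steps_completed"].append("design_comparison")

        # --- human-readable summary (numbers sourced from the JSON) ----
        lines = [f"pgxagree assessment (seed={cfg.seed})", ""]
        for name, block in summary_blocks.items():
            lines.append(f"[{name}] " + ", ".join(
                f"{k}={v}" for k, v in block.items() if k != "union_note"))
            if "fraction_pass_union" in block:
                lines.append(f"  note: fraction_pass_union is {consistency.UNION_NOTE}")
        for c in results.get("datatype_comparisons", []):
            lines.append(
                f"[comparison] {c['datatype_a']} vs {c['datatype_b']}: "
                f"one-sided rank-sum W={c['statistic']}, p={c['p']}")
        for did, row in results.get("design_summary", {}).items():
            lines.append(f"[design {did}] mean effect_rho={row['effect_rho']}, "
                         f"mean hit_kappa={row['hit_kappa']}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

        status["ok"] = True
        return results
    finally:
        _write_json(status, out / "status.json")
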