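"""End-to-end pipeline: simulate -> train -> evaluate -> localize -> swap ->
segment, with a reproducible run manifest.

The config is a plain mapping (usually loaded from YAML/JSON).  A single
base seed fans out to per-stage seeds through a fixed counter scheme
(``stage_seed = base_seed + 1000 * stage_index``), so stages are
independently reproducible and a rerun from the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, localize, microstates, synth
from .io import read_epochset, read_layout, select_contacts, write_epochset, write_layout

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "train", "evaluate", "localize", "swap", "segment")


def _stage_seed(base: int, stage: str) -> int:
    return int(base) + 1000 * STAGES.index(stage)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    completed: list = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages in order, writing TSV reports plus a
    manifest under ``out_dir``.  Raises on a missing input section before
    any stage runs; a stage failure leaves the manifest partially filled
    and re-raises."""
    if "seed" not in config or ("simulate" not in config and "epochs" not in config):
        raise ValueError("config needs a 'seed' and either 'simulate' or 'epochs'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = list(config.get("stages", STAGES))
    manifest = RunManifest(config=config, seed=seed)

    def _done(stage: str, path: Path, t0: float) -> None:
        manifest.outputs[stage] = str(path)
        manifest.checksums[stage] = _checksum(path)
        manifest.timings_s[stage] = round(time.time() - t0, 3)
        manifest.completed.append(stage)
        manifest.save(out / "manifest.json")

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    if "simulate" in config and "simulate" in stages:
        s_seed = _stage_seed(seed, "simulate")
        manifest.stage_seeds["simulate"] = s_seed
        sim_cfg = dict(config["simulate"])
        preset = sim_cfg.pop("preset", "paper-like")
        maker = {
            "paper-like": synth.paper_like,
            "fast": synth.fast_preset,
            "null": synth.null_preset,
        }[preset]
        cfg = maker(seed=s_seed)
        if sim_cfg:
            from dataclasses import replace

            cfg = replace(cfg, **sim_cfg)
        ds = synth.sample_epochset(cfg)
        data_dir = out / "epochs"
        write_epochset(ds.epochs, data_dir)
        write_layout(ds.layout, out / "layout.tsv")
        truth = pd.DataFrame(
            {
                "trial_id": list(ds.true_paths),
                "path_rle": [
                    ";".join(
                        f"{s}x{r}"
                        for s, r in zip(
                            p[np.concatenate([[0], np.flatnonzero(np.diff(p) != 0) + 1])],
                            microstates.run_lengths(p),
                        )
                    )
                    for p in ds.true_paths.values()
                ],
            }
        )
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        es, layout = ds.epochs, ds.layout
        _done("simulate", data_dir, t0)
    else:
        es = read_epochset(config["epochs"])
        layout = read_layout(config["layout"])

    layout = select_contacts(layout, config.get("selection", "most_distant"))
    es_sel = es.restrict(layout.selected_ids)
    s_trials = es_sel.subset(condition="S")
    X, y, rts = s_trials.data_list(), s_trials.days(), s_trials.rts()

    # ---- train (Q selection + cross-validation) ---------------------------
    q_grid = config.get("q_grid")
    q1, q2 = config.get("q1", 3), config.get("q2", 4)
    n_splits = int(config.get("n_splits", 10))
    cv_seed = _stage_seed(seed, "train")
    report = None
    if "train" in stages:
        t0 = time.time()
        manifest.stage_seeds["train"] = cv_seed
        if q_grid is not None:
            reports, (q1, q2) = classify.select_q_pair(
                X, y, q_grid, n_splits=n_splits, seed=cv_seed, keep_models=True
            )
            grid_df = pd.DataFrame([r.summary() for r in reports.values()])
            grid_df.to_csv(out / "q_grid.tsv", sep="\t", index=False)
            report = reports[(q1, q2)]
        else:
            report = classify.cross_validate_pair(
                X, y, q1, q2, n_splits=n_splits, seed=cv_seed, keep_models=True
            )
        pd.DataFrame(
            {"split": range(report.n_splits), "area": report.areas,
             "accuracy": report.accuracies}
        ).to_csv(out / "cv_s.tsv", sep="\t", index=False)
        _done("train", out / "cv_s.tsv", t0)

    # ---- evaluate (controls) ----------------------------------------------
    if "evaluate" in stages and report is not None:
        t0 = time.time()
        e_seed = _stage_seed(seed, "evaluate")
        manifest.stage_seeds["evaluate"] = e_seed
        rows = [
            {"analysis": "S", "mean_area": report.mean_area,
             "sd_area": report.sd_area, "mean_accuracy": report.mean_accuracy}
        ]
        c_trials = es_sel.subset(condition="C")
        if len(c_trials) and report.models:
            ctrl = classify.evaluate_control(
                report.models, c_trials.data_list(), c_trials.days(), seed=e_seed
            )
            rows.append(
                {"analysis": "C", "mean_area": ctrl.mean_area,
                 "sd_area": ctrl.sd_area, "mean_accuracy": ctrl.mean_accuracy}
            )
        rt_rep = classify.rt_baseline(rts, y, n_splits=n_splits, seed=e_seed)
        rows.append(
            {"analysis": "RT", "mean_area": rt_rep.mean_area,
             "sd_area": rt_rep.sd_area, "mean_accuracy": rt_rep.mean_accuracy}
        )
        pd.DataFrame(rows).to_csv(out / "evaluation.tsv", sep="\t", index=False)
        _done("evaluate", out / "evaluation.tsv", t0)

    # ---- localization ------------------------------------------------------
    if "localize" in stages:
        t0 = time.time()
        l_seed = _stage_seed(seed, "localize")
        manifest.stage_seeds["localize"] = l_seed
        loc = localize.leave_one_array_out(
            es.subset(condition="S"), layout, q1=q1, q2=q2,
            n_splits=n_splits, seed=l_seed,
            alpha=float(config.get("alpha", 0.01)),
            baseline=report,
        )
        loc.to_frame().to_csv(out / "localization.tsv", sep="\t", index=False)
        _done("localize", out / "localization.tsv", t0)

    # ---- parameter swaps ---------------------------------------------------
    if "swap" in stages and report is not None and report.models:
        t0 = time.time()
        w_seed = _stage_seed(seed, "swap")
        manifest.stage_seeds["swap"] = w_seed
        clf = report.models[0]
        rows = []
        for which in localize.PARAMETER_SETS:
            rep = localize.swap_parameters(clf, which, X, y, seed=w_seed)
            rows.append(
                {"parameter_set": which, "n_swaps": len(rep.matchings),
                 "baseline_accuracy": rep.baseline_accuracy,
                 "mean_swap_accuracy": float(np.mean(rep.accuracies)),
                 "accuracy_drop": rep.mean_accuracy_drop,
                 "p_accuracy": rep.p_accuracy}
            )
        pd.DataFrame(rows).to_csv(out / "swap.tsv", sep="\t", index=False)
        _done("swap", out / "swap.tsv", t0)

    # ---- segmentation ------------------------------------------------------
    if "segment" in stages and report is not None and report.models:
        t0 = time.time()
        model = report.models[0].models_[0]
        rows = []
        for day in ("day1", "day2"):
            sub = es_sel.subset(day=day, condition="S")
            if not len(sub):
                continue
            seg = microstates.segment(model, sub)
            rows.append({"day": day, "mean_duration_ms": seg.grand_mean_ms,
                         "n_trials": len(seg)})
        pd.DataFrame(rows).to_csv(out / "durations.tsv", sep="\t", index=False)
        _done("segment", out / "durations.tsv", t0)

    return manifest
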