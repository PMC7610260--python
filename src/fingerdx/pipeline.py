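"""End-to-end orchestration on synthetic cohorts.

One call reproduces the full analysis shape of a fingerprint-based
case-control study: simulate a cohort, TIC-normalize, split discovery /
validation 4:1, train the fingerprint network (SN), the multi-modal variant
(CSN), a clinical-indexes-only network, and the four classical baselines,
evaluate everything with discovery-fixed Youden thresholds and DeLong
confidence intervals, select the top-k saliency feature panel, and refit a
network on the panel alone.  All stage seeds derive from one master seed and
all artifacts are plain text, so a rerun with the same configuration
reproduces every output file bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import os
import sys
import time
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .baselines import fit_opls_da, opls_predict, run_baseline
from .evaluation import auc, confusion_at, delong_ci, youden_threshold, roc_curve_points
from .fingerprints import tic_normalize_matrix
from .networks import (TrainConfig, arch_for_width, build_csn, build_model,
                       mlp_arch)
from .saliency import aggregate_saliency, refit_on_panel, saliency_map, select_panel
from .synthetic import (CohortConfig, PlantedBin, default_planted_bins,
                        generate_cohort, split_cohort, write_cohort)


class PipelineConfigError(ValueError):
    """Raised before any compute when a pipeline configuration is invalid."""


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        planted_bins=default_planted_bins(), missing_rate=0.05, tic_log_sd=0.25))
    validation_fraction: float = 0.2
    normalize: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)
    saliency_k: int = 20
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        if "cohort" not in d:
            raise PipelineConfigError("configuration missing required section 'cohort'")
        cd = dict(d["cohort"])
        planted = cd.pop("planted_bins", None)
        if planted is None:
            n_bins = cd.get("n_bins", 881)
            cd["planted_bins"] = default_planted_bins(n_bins=n_bins)
        else:
            cd["planted_bins"] = tuple(PlantedBin(**p) for p in planted)
        try:
            cohort = CohortConfig(**cd)
            train = TrainConfig(**d.get("train", {}))
        except (TypeError, ValueError) as exc:
            raise PipelineConfigError(str(exc)) from exc
        return cls(cohort=cohort,
                   validation_fraction=d.get("validation_fraction", 0.2),
                   normalize=d.get("normalize", True),
                   train=train,
                   saliency_k=d.get("saliency_k", 20),
                   master_seed=d.get("master_seed", 0))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of 'master:stage', below 2^31."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2 ** 31)


def _report_rows(name: str, input_data: str, scores_d, y_d, scores_v, y_v) -> list[dict]:
    """Two Table-style rows: discovery (threshold source) and validation."""
    thr = youden_threshold(scores_d, y_d)
    rows = []
    for cohort, s, y in (("discovery", scores_d, y_d), ("validation", scores_v, y_v)):
        a, lo, hi = delong_ci(s, y)
        sens, spec = confusion_at(s, y, thr)
        rows.append({"input_data": input_data, "algorithm": name, "cohort": cohort,
                     "auc": a, "ci_low": lo, "ci_high": hi,
                     "sensitivity": sens, "specificity": spec, "threshold": thr})
    return rows


def _write_report(rows: list[dict], path) -> None:
    cols = ["input_data", "algorithm", "cohort", "auc", "ci_low", "ci_high",
            "sensitivity", "specificity", "threshold"]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for r in rows:
            fh.write(",".join(str(r[c]) if isinstance(r[c], str) else repr(float(r[c]))
                              for c in cols) + "\n")


def _write_roc(scores, labels, path) -> None:
    thr, sens, spec = roc_curve_points(scores, labels)
    with open(path, "w") as fh:
        fh.write("threshold,sensitivity,specificity\n")
        for t, se, sp in zip(thr, sens, spec):
            fh.write(f"{t!r},{se!r},{sp!r}\n")


def _log(stage: str, t0: float) -> None:
    print(f"[fingerdx] {stage}: {time.perf_counter() - t0:.1f}s", file=sys.stderr)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns a summary dict and writes all artifacts.

    The report mirrors a clinical-comparison table: one model per block,
    discovery and validation rows, thresholds always fixed on discovery.
    """
    os.makedirs(out_dir, exist_ok=True)
    t_start = time.perf_counter()
    ms = config.master_seed

    # --- simulate ------------------------------------------------------------
    t0 = time.perf_counter()
    cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(ms, "cohort"))
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, os.path.join(out_dir, "cohort"))
    split = split_cohort(cohort, config.validation_fraction, seed=stage_seed(ms, "split"))
    d_idx, v_idx = split.discovery_indices, split.validation_indices
    _log("simulate+split", t0)

    X = cohort.fingerprints.values
    if config.normalize:
        X = tic_normalize_matrix(X)
    clin = cohort.clinical.to_numpy(dtype=float)
    y = cohort.labels
    Xd, Xv, yd, yv = X[d_idx], X[v_idx], y[d_idx], y[v_idx]
    Cd, Cv = clin[d_idx], clin[v_idx]

    rows: list[dict] = []
    val_scores: dict[str, np.ndarray] = {}

    # --- clinical-indexes-only network --------------------------------------
    t0 = time.perf_counter()
    clin_model = build_model(mlp_arch(clin.shape[1]))
    clin_model.fit(Cd, yd, cfg=dataclasses.replace(
        config.train, seed=stage_seed(ms, "clinical_sn")))
    s_d, s_v = clin_model.predict_scores(Cd), clin_model.predict_scores(Cv)
    rows += _report_rows("SN", "clinical_indexes", s_d, yd, s_v, yv)
    val_scores["clinical_sn"] = s_v
    _log("train clinical-only SN", t0)

    # --- fingerprint network (SN) --------------------------------------------
    t0 = time.perf_counter()
    sn = build_model(arch_for_width(X.shape[1]))
    sn.fit(Xd, yd, cfg=dataclasses.replace(config.train, seed=stage_seed(ms, "sn")))
    sn.save(os.path.join(out_dir, "sn_model.json"))
    s_d, s_v = sn.predict_scores(Xd), sn.predict_scores(Xv)
    rows += _report_rows("SN", "fingerprints", s_d, yd, s_v, yv)
    val_scores["sn"] = s_v
    _log("train SN", t0)

    # --- classical baselines --------------------------------------------------
    for name in ("lasso", "random_forest", "svm"):
        t0 = time.perf_counter()
        model, s_d = run_baseline(name, Xd, yd, seed=stage_seed(ms, name))
        s_v = model.predict_scores(Xv)
        rows += _report_rows(name, "fingerprints", s_d, yd, s_v, yv)
        val_scores[name] = s_v
        _log(f"baseline {name}", t0)
    t0 = time.perf_counter()
    opls = fit_opls_da(Xd, yd, n_orthogonal=1)
    s_d, s_v = opls_predict(opls, Xd), opls_predict(opls, Xv)
    rows += _report_rows("opls_da", "fingerprints", s_d, yd, s_v, yv)
    val_scores["opls_da"] = s_v
    _log("baseline opls_da", t0)

    # --- multi-modal network (CSN) --------------------------------------------
    t0 = time.perf_counter()
    csn = build_csn(arch_for_width(X.shape[1], clinical_width=clin.shape[1]))
    csn.fit(Xd, yd, clinical=Cd,
            cfg=dataclasses.replace(config.train, seed=stage_seed(ms, "csn")))
    csn.save(os.path.join(out_dir, "csn_model.json"))
    s_d = csn.predict_scores(Xd, Cd)
    s_v = csn.predict_scores(Xv, Cv)
    rows += _report_rows("CSN", "multi_modal", s_d, yd, s_v, yv)
    val_scores["csn"] = s_v
    _log("train CSN", t0)

    # --- saliency panel --------------------------------------------------------
    t0 = time.perf_counter()
    maps = saliency_map(sn, Xd)
    agg = aggregate_saliency(maps)
    panel = select_panel(agg, config.saliency_k, Xd, yd,
                         bin_centers=cohort.fingerprints.bin_centers)
    panel.to_csv(os.path.join(out_dir, "panel.csv"))
    np.savetxt(os.path.join(out_dir, "saliency_aggregate.tsv"), agg, delimiter="\t")
    _log("saliency panel", t0)

    # --- panel refit ------------------------------------------------------------
    t0 = time.perf_counter()
    refit = refit_on_panel(panel, Xd, yd, Xv, yv, seed=stage_seed(ms, "panel_refit"),
                           max_epochs=config.train.max_epochs)
    s_d = refit["model"].predict_scores(Xd[:, panel.bin_indices])
    s_v = refit["model"].predict_scores(Xv[:, panel.bin_indices])
    rows += _report_rows("SN", "metabolite_panel", s_d, yd, s_v, yv)
    val_scores["panel_sn"] = s_v
    _log("panel refit", t0)

    # --- artifacts ----------------------------------------------------------------
    _write_report(rows, os.path.join(out_dir, "report.csv"))
    for name, s in val_scores.items():
        _write_roc(s, yv, os.path.join(out_dir, f"roc_validation_{name}.csv"))
        with open(os.path.join(out_dir, f"scores_validation_{name}.csv"), "w") as fh:
            fh.write("sample_index,score\n")
            for i, sc in zip(v_idx, s):
                fh.write(f"{int(i)},{float(sc)!r}\n")
    manifest = {
        "package_version": __version__,
        "master_seed": ms,
        "stage_seeds": {s: stage_seed(ms, s) for s in
                        ("cohort", "split", "clinical_sn", "sn", "lasso",
                         "random_forest", "svm", "csn", "panel_refit")},
        "config": {
            "cohort": {**dataclasses.asdict(cohort_cfg),
                       "planted_bins": [dataclasses.asdict(p)
                                        for p in cohort_cfg.planted_bins],
                       "clinical_spec": [dataclasses.asdict(c)
                                         for c in cohort_cfg.clinical_spec]},
            "validation_fraction": config.validation_fraction,
            "normalize": config.normalize,
            "train": dataclasses.asdict(config.train),
            "saliency_k": config.saliency_k,
        },
        "n_discovery": int(d_idx.size),
        "n_validation": int(v_idx.size),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log("total", t_start)

    return {"rows": rows, "panel": panel, "split": split, "cohort": cohort,
            "validation_scores": val_scores, "manifest": manifest}
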