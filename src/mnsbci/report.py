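"""End-to-end experiment orchestration.

``run_pipeline`` generates a synthetic cohort, preprocesses every run,
computes per-condition ERD/ERS% grand averages and ERSP summaries, runs the
four classifiers on the two headline paradigms, and emits a reproducible
bundle (JSON summary + tidy CSV tables, optional figures).  Everything is
deterministic given the config seeds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import classify as clf
from . import erders, preprocess, synth, tfr
from .containers import CONDITIONS, MI, MI_MNS, MNS, RM


class PipelineConfig(BaseModel):
    """Schema-validated configuration; defaults mirror the study protocol."""

    n_subjects: int = Field(16, ge=1)
    n_trials_per_condition: int = Field(52, ge=4)
    seed: int = 0
    generation_rate: float = Field(512.0, ge=128.0)
    target_rate: float = Field(128.0, ge=32.0)
    erd_window: tuple[float, float] = (-2.0, 7.0)
    classify_window: tuple[float, float] = (-3.0, 7.0)
    erd_bands: dict[str, tuple[float, float]] = {
        "mu": (7.0, 13.0), "beta": (15.0, 30.0), "mu+beta": (8.0, 30.0)}
    classifier_band: tuple[float, float] = clf.CLASSIFIER_BAND
    methods: tuple[str, ...] = clf.METHODS
    paradigms: tuple[str, ...] = (clf.MI_VS_REST, clf.MNS_PAIR)
    cv_folds: int = Field(4, ge=2)
    emg_ratio: float = 3.0
    outlier_sd: float = 2.5
    n_permutations: int = Field(500, ge=1)
    topography_frames: tuple[float, ...] = (1.0, 1.5, 2.5)
    effect_sigma: float = 0.2
    amplitude_sigma: float = 0.15
    fraction_sigma: float = 0.05
    output_dir: Optional[str] = None
    make_figures: bool = False

    @field_validator("classifier_band", "erd_window", "classify_window")
    @classmethod
    def _ordered(cls, v):
        if v[1] <= v[0]:
            raise ValueError("interval must be increasing")
        return v


def _subject_summary(subject: dict, config: PipelineConfig) -> dict:
    """Preprocess one subject and compute every per-subject quantity."""
    criteria = preprocess.RejectionCriteria(emg_ratio=config.emg_ratio,
                                            outlier_sd=config.outlier_sd)
    # referencing + resampling once, then the two epochings
    runs = [preprocess.resample_to(preprocess.common_average_reference(r),
                                   config.target_rate)
            for r in subject["runs"]]
    from .containers import concat_epochs

    erd_epochs = concat_epochs(
        [preprocess.epoch(r, window=config.erd_window) for r in runs])
    erd_epochs, rejection = preprocess.reject_trials(erd_epochs,
                                                     criteria=criteria)
    cls_epochs = concat_epochs(
        [preprocess.epoch(r, window=config.classify_window) for r in runs])
    cls_epochs, _ = preprocess.reject_trials(cls_epochs, criteria=criteria)

    curves = {}
    for band_name, band in config.erd_bands.items():
        filtered = preprocess.bandpass(erd_epochs, band, order=4)
        for cond in CONDITIONS:
            sub = filtered.select_condition(cond)
            if sub.n_trials:
                curves[(band_name, cond)] = erders.erd_ers_curve(sub)

    ersp_maps = {}
    for cond in (MI_MNS, MNS):
        sub = erd_epochs.select_condition(cond)
        if sub.n_trials:
            ersp_maps[cond] = tfr.ersp(sub)

    cls_filtered = preprocess.bandpass(cls_epochs, config.classifier_band,
                                       order=clf.CLASSIFIER_FILTER_ORDER)
    accuracies = []
    subject_seed = subject["params"].seed
    for paradigm in config.paradigms:
        windows = clf.extract_windows(cls_filtered, paradigm)
        for method in config.methods:
            res = clf.train_eval_cv(windows, method, k=config.cv_folds,
                                    seed=subject_seed % (2 ** 31))
            res.subject = subject["subject"]
            accuracies.append(res)
    return {"rejection": rejection, "curves": curves, "ersp": ersp_maps,
            "accuracies": accuracies, "cls_epochs": cls_filtered}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run generate -> preprocess -> ERD/ERS -> ERSP -> classify -> compare."""
    cohort = synth.simulate_cohort(
        config.n_subjects,
        variability=synth.CohortVariability(config.effect_sigma,
                                            config.amplitude_sigma,
                                            config.fraction_sigma),
        seed=config.seed,
        n_trials_per_condition=config.n_trials_per_condition,
        rate=config.generation_rate)

    per_subject = []
    accuracy_rows = []
    grand_curves: dict[tuple, list] = {}
    rejection_fracs: dict[str, list] = {c: [] for c in CONDITIONS}
    topo_example = None
    for subject in cohort:
        s = _subject_summary(subject, config)
        per_subject.append(s)
        for key, curve in s["curves"].items():
            grand_curves.setdefault(key, []).append(curve)
        for cond, frac in s["rejection"].fractions.items():
            rejection_fracs[cond].append(frac)
        for res in s["accuracies"]:
            accuracy_rows.append({
                "subject": res.subject, "method": res.method,
                "paradigm": res.paradigm,
                "band": f"{config.classifier_band[0]:g}-{config.classifier_band[1]:g}",
                "accuracy": res.accuracy,
                **{f"fold{i}": a for i, a in enumerate(res.fold_accuracies)},
            })
        if topo_example is None:
            # stimulation-locked topography contrast on the first subject
            ep = s["cls_epochs"]
            try:
                topo_example = tfr.compare_topographies(
                    ep.select_condition(MI_MNS), ep.select_condition(MNS),
                    band=config.classifier_band,
                    frame_times=config.topography_frames,
                    n_perm=config.n_permutations,
                    seed=config.seed)
            except ValueError:
                topo_example = None
        s.pop("cls_epochs")

    grand = {key: erders.grand_average(cs) for key, cs in grand_curves.items()}

    def method_mean(method: str, paradigm: str) -> float:
        vals = [r["accuracy"] for r in accuracy_rows
                if r["method"] == method and r["paradigm"] == paradigm]
        return float(np.mean(vals)) if vals else float("nan")

    summary: dict = {
        "config": json.loads(config.model_dump_json()),
        "rejection_fraction_mean": {
            c: float(np.mean(v)) if v else 0.0
            for c, v in rejection_fracs.items()},
        "mean_accuracy": {
            p: {m: method_mean(m, p) for m in config.methods}
            for p in config.paradigms},
    }

    # the headline contrast: stimulation-pair vs imagery-vs-rest (TS+LR)
    if {clf.MI_VS_REST, clf.MNS_PAIR} <= set(config.paradigms):
        acc_mi = [r["accuracy"] for r in accuracy_rows
                  if r["method"] == "TS+LR" and r["paradigm"] == clf.MI_VS_REST]
        acc_mns = [r["accuracy"] for r in accuracy_rows
                   if r["method"] == "TS+LR" and r["paradigm"] == clf.MNS_PAIR]
        t, p = clf.paired_ttest(acc_mns, acc_mi)
        summary["comparison"] = {
            "mns_pair_mean": float(np.mean(acc_mns)),
            "mi_vs_rest_mean": float(np.mean(acc_mi)),
            "t": t, "p": p,
            "mns_pair_better": bool(np.mean(acc_mns) > np.mean(acc_mi)),
        }

    # grand-average ERD/ERS landmarks at the C3-like channel
    landmarks = {}
    for (band_name, cond), curve in grand.items():
        c3 = curve.channel("C3")
        sel_task = (curve.times >= 0.3) & (curve.times <= 2.0)
        sel_late = (curve.times >= 3.5) & (curve.times <= 5.5)
        landmarks[f"{band_name}/{cond}"] = {
            "task_min_pct": float(c3[sel_task].min()),
            "late_max_pct": float(c3[sel_late].max()),
        }
    summary["erd_landmarks_c3"] = landmarks

    bundle = {"summary": summary, "accuracy_rows": accuracy_rows,
              "grand_curves": grand, "per_subject": per_subject,
              "topography": topo_example}
    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    import pandas as pd

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(
        json.dumps(bundle["summary"], indent=2, sort_keys=True))
    pd.DataFrame(bundle["accuracy_rows"]).to_csv(
        out / "accuracies.csv", index=False)
    frames = [erders.to_frame(curve).assign(condition=cond, band_name=bn)
              for (bn, cond), curve in bundle["grand_curves"].items()]
    if frames:
        pd.concat(frames).to_csv(out / "grand_average_erders.csv",
                                 index=False)
    if config.make_figures:
        _write_figures(bundle, out)


def _write_figures(bundle: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for band_name in {bn for bn, _ in bundle["grand_curves"]}:
        fig, ax = plt.subplots(figsize=(7, 4))
        curves = {cond: c for (bn, cond), c in bundle["grand_curves"].items()
                  if bn == band_name}
        erders.plot_curves(curves, channel="C3", ax=ax)
        ax.set_title(f"grand average ERD/ERS% at C3 ({band_name})")
        fig.savefig(out / f"erders_{band_name.replace('+', '_')}.png",
                    dpi=120)
        plt.close(fig)
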