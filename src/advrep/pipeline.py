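"""End-to-end orchestration: synthesize -> train -> attack -> simulate ->
RSA + selection + encoding -> machine-readable report.

``run_pipeline`` executes the whole experiment from a single seeded
:class:`RunConfig`; every stage derives its own seed from the global one, so
identical configs reproduce identical numeric outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adversarial, encoding, rsa, selection as vsel, synth
from .model import ConfigurationError, train_surrogate

log = logging.getLogger("advrep")


@dataclass
class RunConfig:
    """All knobs of one simulated experiment, defaulting to the reference
    condition counts (40 classes, 2 sessions x 5 runs, 2 repetitions, 9
    blanks per run, 5 ROIs x 2 hemispheres, 80%/1000 resampling)."""

    seed: int = 0
    # stimuli
    n_classes: int = 40
    image_size: int = 32
    train_images_per_class: int = 25
    # surrogate training
    epochs: int = 50
    # design
    sessions: int = 2
    runs_per_session: int = 5
    reps_per_image: int = 2
    blanks_per_run: int = 9
    # cortical sheet / responses
    n_vertices_per_roi_per_hemi: int = 150
    rois: tuple[str, ...] = synth.ROIS
    sparsity_k: int = 3
    rho_AI: float = 0.8
    rho_AN: float = 0.0
    rep_noise_sd: float = 0.5
    # analysis
    frac: float = 0.8
    n_boot: int = 1000
    n_perm: int = 1000
    radius: float = 3.0
    n_per_hemisphere: int = 100
    sparsity_s: int | None = None
    rdm_metric: str = "correlation"

    def stage_seed(self, offset: int) -> int:
        return int((self.seed + 7919 * offset) % (2**31 - 1))


def validate_config(config: dict | RunConfig | None) -> RunConfig:
    """Fill defaults, check ranges; report every violation with its field."""
    if config is None:
        config = {}
    if isinstance(config, RunConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(config) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = RunConfig(**config)
    errors = []
    positive = ("n_classes", "image_size", "train_images_per_class", "epochs",
                "sessions", "runs_per_session", "reps_per_image",
                "n_vertices_per_roi_per_hemi", "sparsity_k", "n_boot", "n_perm",
                "n_per_hemisphere")
    for name in positive:
        if getattr(cfg, name) < 1:
            errors.append(f"{name}: must be >= 1, got {getattr(cfg, name)}")
    if cfg.blanks_per_run < 0:
        errors.append(f"blanks_per_run: must be >= 0, got {cfg.blanks_per_run}")
    if not 0.0 < cfg.frac <= 1.0:
        errors.append(f"frac: must lie in (0, 1], got {cfg.frac}")
    for name in ("rho_AI", "rho_AN"):
        if not 0.0 <= getattr(cfg, name) <= 1.0:
            errors.append(f"{name}: must lie in [0, 1], got {getattr(cfg, name)}")
    if cfg.rep_noise_sd < 0:
        errors.append(f"rep_noise_sd: must be >= 0, got {cfg.rep_noise_sd}")
    if cfg.radius <= 0:
        errors.append(f"radius: must be > 0, got {cfg.radius}")
    if cfg.n_per_hemisphere > cfg.n_vertices_per_roi_per_hemi:
        errors.append(
            "n_per_hemisphere: cannot exceed n_vertices_per_roi_per_hemi "
            f"({cfg.n_per_hemisphere} > {cfg.n_vertices_per_roi_per_hemi})"
        )
    if cfg.reps_per_image != 2:
        errors.append("reps_per_image: split-half selection requires exactly 2")
    if errors:
        raise ConfigurationError("invalid config: " + "; ".join(errors))
    return cfg


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunReport:
    config: dict
    stimuli: dict
    surrogate: dict
    layer_profile: dict
    roi_rsa: dict
    searchlight: dict
    selection: dict
    encoding: list
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Deterministic serialization: wall-clock timings are excluded so
        identical configs produce byte-identical reports."""
        payload = dataclasses.asdict(self)
        payload.pop("timings", None)
        return json.dumps(payload, indent=1, sort_keys=True)


def _summary_dict(s: rsa.SimilaritySummary) -> dict:
    return {
        "r_re_an": s.r_re_an, "r_re_ai": s.r_re_ai, "diff": s.diff,
        "boot_ci": list(s.boot_ci), "boot_p": s.boot_p,
        "perm_p_an": s.perm_p_an, "perm_p_ai": s.perm_p_ai,
        "n_boot": s.n_boot, "n_perm": s.n_perm, "n_units": s.n_units,
    }


def run_pipeline(config: dict | RunConfig | None = None,
                 out_dir: str | Path | None = None) -> RunReport:
    """Execute all stages in order and return (and optionally write) the report.

    With ``out_dir`` set, writes report.json, CSV tables (searchlight map,
    selection, encoding accuracies, layer profile), the stimulus PNGs, the
    response HDF5 container and the trained model.  Stage failures abort
    with a stage-named error; outputs written so far are preserved.
    """
    cfg = validate_config(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_t):
                log.info("stage %s ...", name)
                self_t.t0 = time.perf_counter()

            def __exit__(self_t, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_t.t0, 3)
                log.info("stage %s done in %.1fs", name, timings[name])
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc

        return _Timer()

    with stage("synthesize_stimuli"):
        train_set = synth.generate_image_classes(
            cfg.n_classes, cfg.train_images_per_class, cfg.image_size,
            seed=cfg.stage_seed(1),
        )
        re_set = synth.generate_image_classes(
            cfg.n_classes, 1, cfg.image_size, seed=cfg.stage_seed(2)
        )
        design = synth.build_design(
            n_images_per_session=(3 * cfg.n_classes) // cfg.sessions,
            reps_per_image=cfg.reps_per_image, blanks_per_run=cfg.blanks_per_run,
            runs_per_session=cfg.runs_per_session, sessions=cfg.sessions,
            seed=cfg.stage_seed(3),
        )
        conditions = synth.enumerate_conditions(design)

    with stage("train_surrogate"):
        model = train_surrogate(
            train_set.pixel_array(), train_set.class_ids,
            epochs=cfg.epochs, seed=cfg.stage_seed(4),
        )

    with stage("generate_adversarials"):
        an_set, ai_set, adv_diags = adversarial.generate_adversarial_sets(
            model, re_set, seed=cfg.stage_seed(5)
        )

    with stage("layer_rsa"):
        profile = rsa.layer_profile(
            model, re_set, an_set, ai_set, frac=cfg.frac, n_boot=cfg.n_boot,
            n_perm=cfg.n_perm, seed=cfg.stage_seed(6), metric=cfg.rdm_metric,
        )

    with stage("simulate_responses"):
        sheet = synth.make_sheet(
            cfg.n_vertices_per_roi_per_hemi, cfg.rois, seed=cfg.stage_seed(7)
        )
        re_acts = encoding.stack_activations(model, re_set)
        responses = synth.simulate_vertex_responses(
            re_acts, sheet, sparsity_k=cfg.sparsity_k, rho_AI=cfg.rho_AI,
            rho_AN=cfg.rho_AN, rep_noise_sd=cfg.rep_noise_sd,
            seed=cfg.stage_seed(8), n_reps=cfg.reps_per_image,
        )

    with stage("searchlight"):
        sl_map = rsa.searchlight_map(responses, radius=cfg.radius,
                                     metric=cfg.rdm_metric)

    with stage("vertex_selection"):
        consistency = vsel.splithalf_consistency(responses, radius=cfg.radius,
                                                 metric=cfg.rdm_metric)
        selected = vsel.select_vertices(consistency, cfg.n_per_hemisphere)

    with stage("roi_rsa"):
        id_to_row = {
            int(v): i for i, v in enumerate(sheet.table["vertex_id"].to_numpy())
        }
        mean_betas = {k: responses.mean_over_reps(k) for k in ("RE", "AN", "AI")}
        roi_summaries = {}
        for i, (roi, vids) in enumerate(vsel.selected_ids_by_roi(selected).items()):
            sel_rows = [id_to_row[int(v)] for v in vids]
            roi_summaries[roi] = rsa.summarize_similarity(
                mean_betas["RE"][sel_rows].T, mean_betas["AN"][sel_rows].T,
                mean_betas["AI"][sel_rows].T, frac=cfg.frac, n_boot=cfg.n_boot,
                n_perm=cfg.n_perm, seed=cfg.stage_seed(9) + i, metric=cfg.rdm_metric,
            )

    with stage("encoding"):
        re_stacks = [encoding.forward_with_activations(model, im.pixels)
                     for im in re_set.images]
        an_stacks = [encoding.forward_with_activations(model, im.pixels)
                     for im in an_set.images]
        ai_stacks = [encoding.forward_with_activations(model, im.pixels)
                     for im in ai_set.images]
        bank = encoding.train_models(responses, re_stacks, selected,
                                     sparsity_s=cfg.sparsity_s)
        acc_ai = encoding.test_generalization(
            bank, ai_stacks, responses, "AI", frac=cfg.frac, n_boot=cfg.n_boot,
            n_perm=cfg.n_perm, seed=cfg.stage_seed(10),
        )
        acc_an = encoding.test_generalization(
            bank, an_stacks, responses, "AN", frac=cfg.frac, n_boot=cfg.n_boot,
            n_perm=cfg.n_perm, seed=cfg.stage_seed(11),
        )
        accuracies = pd.concat([acc_ai, acc_an], ignore_index=True)

    valid_sl = sl_map.dropna(subset=["r_re_an", "r_re_ai"])
    report = RunReport(
        config=dataclasses.asdict(cfg),
        stimuli={
            "n_re": len(re_set), "n_an": len(an_set), "n_ai": len(ai_set),
            "n_total": len(re_set) + len(an_set) + len(ai_set),
            "trials_per_run": design.trials_per_run,
            "n_conditions": len(conditions),
            "an_converged": int(sum(d["converged"] for d in adv_diags["AN"])),
            "ai_converged": int(sum(d["converged"] for d in adv_diags["AI"])),
            "an_min_final_prob": float(min(d["final_prob"] for d in adv_diags["AN"])),
            "ai_min_final_prob": float(min(d["final_prob"] for d in adv_diags["AI"])),
        },
        surrogate={"val_accuracy": model.val_accuracy_},
        layer_profile={
            "stages": {s: _summary_dict(v) for s, v in profile.summaries.items()},
            "trend_re_an": dataclasses.asdict(profile.trend_re_an),
            "trend_re_ai": dataclasses.asdict(profile.trend_re_ai),
        },
        roi_rsa={roi: _summary_dict(s) for roi, s in roi_summaries.items()},
        searchlight={
            "n_valid": int(len(valid_sl)),
            "mean_r_re_an": float(valid_sl["r_re_an"].mean()),
            "mean_r_re_ai": float(valid_sl["r_re_ai"].mean()),
        },
        selection={
            roi: int(n) for roi, n in selected.groupby("roi", sort=False).size().items()
        },
        encoding=accuracies.to_dict("records"),
        timings=timings,
    )

    if out is not None:
        with stage("write_outputs"):
            (out / "report.json").write_text(report.to_json())
            sl_map.to_csv(out / "searchlight_map.csv", index=False)
            selected.to_csv(out / "selected_vertices.csv", index=False)
            accuracies.to_csv(out / "encoding_accuracy.csv", index=False)
            prof_rows = [
                {"stage": s, **_summary_dict(v)} for s, v in profile.summaries.items()
            ]
            pd.DataFrame(prof_rows).to_csv(out / "layer_profile.csv", index=False)
            sheet.to_csv(out / "sheet.csv")
            synth.save_responses(responses, out / "responses.h5")
            model.save(out / "surrogate.npz")
            for name, sset in (("re", re_set), ("an", an_set), ("ai", ai_set)):
                synth.save_stimulus_set(sset, out / f"stimuli_{name}")
            (out / "adversarial_diagnostics.json").write_text(
                json.dumps(adv_diags, indent=1)
            )
            from . import figures

            figures.plot_layer_profile(pd.DataFrame(prof_rows), out / "layer_profile.png")
            figures.plot_roi_summary(report.roi_rsa, out / "roi_similarity.png")
            figures.plot_searchlight(sl_map, sheet.table, out / "searchlight.png")
    return report
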