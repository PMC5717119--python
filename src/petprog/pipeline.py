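"""End-to-end orchestration: simulate -> segment -> extract -> model -> validate.

One :class:`PipelineConfig` drives all stages.  A single global seed fans out
to per-stage seeds (stable CRC hashing of the stage name), so any stage can
be rerun in isolation and reproduce its outputs byte-for-byte.  Every run
writes a ``manifest.json`` listing each artifact with its SHA-256 content
hash, the seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io
from .exceptions import ValidationError
from .features import extract_all
from .segmentation import (
    BoundingBox,
    MethodSelector,
    dice,
    eligibility_filter,
    select_and_segment,
    train_selector,
)
from .survival import (
    PrognosticModel,
    aic,
    assign_quartiles,
    backward_eliminate,
    compare_models,
    events_per_variable,
    hazard_ratios,
    interaction_test,
    km_estimate,
    logrank_test,
    prognostic_score,
    transform_features,
    validate_model,
)
from .synthetic import (
    MODEL_VARIABLES,
    SimulationConfig,
    generate_cohort,
    generate_phantom,
    phantom_suite,
    _model_matrix,
)

VERSION = "0.1.0"
STAGES = ("simulate", "segment", "extract", "model", "validate")


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed: stable hash of the stage name mixed with the
    global seed; always below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (seed * 2654435761)) % (2**31 - 1)


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_train_phantoms: int = 30
    n_eval_phantoms: int = 10
    n_development: int = 302
    n_validation: int = 101
    bin_width: float = 0.5
    alpha_remove: float = 0.05
    selector_file: str | None = None  # default: written by the segment stage
    make_plots: bool = True

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValidationError(f"unknown stages {unknown}; valid: {STAGES}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _finite(x: float):
    """JSON-safe number: None when the estimate is undefined/unreached
    (e.g. a KM median above the last observed time)."""
    return float(x) if np.isfinite(x) else None


def _km_plot(groups: dict, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in sorted(groups.items()):
        ax.step(curve.times, curve.survival, where="post", label=f"Q{label}")
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def demo_config(output_dir: str, seed: int = 5, make_plots: bool = True) -> PipelineConfig:
    """The bundled demonstration configuration: a full simulate-to-validate
    run at the study's cohort sizes with a small phantom suite."""
    return PipelineConfig(
        output_dir=output_dir,
        seed=seed,
        n_train_phantoms=30,
        n_eval_phantoms=8,
        n_development=302,
        n_validation=101,
        make_plots=make_plots,
    )


def run(config: PipelineConfig) -> dict:
    """Execute the toggled stages and return the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # config errors surface before any stage does work
    if config.selector_file is not None and not Path(config.selector_file).exists():
        raise ValidationError(
            f"selector file {config.selector_file!r} does not exist"
        )
    if "segment" in config.stages and "simulate" not in config.stages:
        if not (_phantom_dir(out) / "case00_suv.nii").exists():
            raise ValidationError(
                "segmentation enabled but no simulated phantoms found in "
                f"{out}; run the simulate stage first"
            )

    if "simulate" in config.stages:
        artifacts += _stage_simulate(config, out)
    if "segment" in config.stages:
        artifacts += _stage_segment(config, out)
    if "extract" in config.stages:
        artifacts += _stage_extract(config, out)
    if "model" in config.stages:
        artifacts += _stage_model(config, out)
    if "validate" in config.stages:
        artifacts += _stage_validate(config, out)

    manifest = {
        "version": VERSION,
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _phantom_dir(out: Path) -> Path:
    d = out / "phantoms"
    d.mkdir(exist_ok=True)
    return d


def _eval_specs(config: PipelineConfig):
    seed = derive_seed(config.seed, "simulate")
    return phantom_suite(config.n_eval_phantoms, seed=seed + 1)


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    seed = derive_seed(config.seed, "simulate")
    written = []
    pdir = _phantom_dir(out)
    for i, spec in enumerate(_eval_specs(config)):
        vol, mask = generate_phantom(spec)
        vp, mp = pdir / f"case{i:02d}_suv.nii", pdir / f"case{i:02d}_truth.nii"
        io.write_volume(vol, vp)
        io.write_mask(mask, mp)
        written += [vp, mp]
    dev = generate_cohort(SimulationConfig(n=config.n_development, seed=seed + 2))
    val = generate_cohort(SimulationConfig(n=config.n_validation, seed=seed + 3))
    for name, table in (("development", dev), ("validation", val)):
        path = out / f"cohort_{name}.csv"
        io.write_cohort_table(table, path)
        written.append(path)
    return written


def _stage_segment(config: PipelineConfig, out: Path) -> list[Path]:
    seed = derive_seed(config.seed, "segment")
    written = []
    selector_path = Path(config.selector_file or out / "selector.json")
    if not selector_path.exists():
        from .experiments import crop_to_lesion

        train = [
            crop_to_lesion(*generate_phantom(sp))
            for sp in phantom_suite(config.n_train_phantoms, seed=seed)
        ]
        train_selector(train).save(selector_path)
    written.append(selector_path)
    selector = MethodSelector.load(selector_path)

    pdir = _phantom_dir(out)
    rows = []
    for i in range(config.n_eval_phantoms):
        vol = io.read_volume(pdir / f"case{i:02d}_suv.nii")
        truth = io.read_mask(pdir / f"case{i:02d}_truth.nii")
        # snug box around the lesion stands in for the manual bounding box
        result = select_and_segment(vol, BoundingBox.around_mask(truth), selector)
        mp = pdir / f"case{i:02d}_mask.nii"
        io.write_mask(result.mask, mp)
        written.append(mp)
        elig = eligibility_filter(result)
        rows.append(
            {
                "id": f"case{i:02d}",
                "method": result.method,
                "mtv_ml": result.mtv_ml,
                "suv_max": result.suv_max,
                "dice_vs_truth": dice(result.mask, truth),
                "eligible": elig.eligible,
                "exclusion_reason": elig.reason or "",
                "qc_flags": ";".join(result.qc_flags),
            }
        )
    seg_path = out / "segmentation_report.csv"
    pd.DataFrame(rows).to_csv(seg_path, index=False)
    written.append(seg_path)
    return written


def _stage_extract(config: PipelineConfig, out: Path) -> list[Path]:
    pdir = _phantom_dir(out)
    report = pd.read_csv(out / "segmentation_report.csv")
    rows = []
    for _, rec in report.iterrows():
        if not rec["eligible"]:
            continue
        vol = io.read_volume(pdir / f"{rec['id']}_suv.nii")
        mask = io.read_mask(pdir / f"{rec['id']}_mask.nii")
        fv = extract_all(vol, mask, bin_width=config.bin_width)
        rows.append({"id": rec["id"], **fv.as_row()})
    path = out / "features.csv"
    io.write_feature_table(pd.DataFrame(rows), path)
    return [path]


def _stage_model(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    dev = io.read_cohort_table(out / "cohort_development.csv")
    dev_t = transform_features(dev)
    work = pd.concat(
        [dev_t[["os_months", "event"]], _model_matrix(dev)], axis=1
    )
    epv = events_per_variable(dev, len(MODEL_VARIABLES))
    elim = backward_eliminate(work, MODEL_VARIABLES, alpha_remove=config.alpha_remove)
    hr = hazard_ratios(elim.fit)
    hr_path = out / "model_coefficients.csv"
    hr.to_csv(hr_path, index=False)
    written.append(hr_path)

    weights = dict(zip(elim.fit.variables, (float(b) for b in elim.fit.beta)))
    scores = prognostic_score(dev_t, PrognosticModel(weights=weights, cutoffs=None))
    labels, cutoffs = assign_quartiles(scores.to_numpy())
    model = PrognosticModel(weights=weights).with_cutoffs(cutoffs)
    model_path = out / "model.json"
    model.save(model_path)
    written.append(model_path)

    km = {
        int(q): km_estimate(
            dev.loc[labels == q, "os_months"], dev.loc[labels == q, "event"]
        )
        for q in np.unique(labels)
    }
    lr = logrank_test(dev["os_months"], dev["event"], labels)
    inter = interaction_test(dev, scores)
    aics = compare_models(work)
    summary = {
        "n": int(len(dev)),
        "events": int(dev["event"].sum()),
        "epv": epv,
        "retained_variables": list(elim.fit.variables),
        "removed_variables": [v for v, _ in elim.removed],
        "quartile_cutoffs": list(cutoffs),
        "quartile_sizes": [int((labels == q).sum()) for q in (1, 2, 3, 4)],
        "quartile_median_os": {f"Q{q}": _finite(km[q].median) for q in km},
        "logrank": {"chi2": lr.statistic, "df": lr.df, "p": lr.p},
        "interaction_test": {"chi2": inter.statistic, "df": inter.df, "p": inter.p},
        "aic": {r["model"]: r["aic"] for r in aics.to_dict("records")},
    }
    sum_path = out / "model_summary.json"
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    written.append(sum_path)

    if config.make_plots:
        plot = out / "km_development.png"
        _km_plot(km, plot, "development cohort: OS by score quartile")
        written.append(plot)
    return written


def _stage_validate(config: PipelineConfig, out: Path) -> list[Path]:
    written = []
    model = PrognosticModel.load(out / "model.json")
    val = io.read_cohort_table(out / "cohort_validation.csv")
    report = validate_model(model, transform_features(val))
    summary = {
        "n": int(len(val)),
        "n_missing_score": report.n_missing_score,
        "group_sizes": {
            f"Q{q}": int((report.labels == q).sum())
            for q in sorted(set(report.labels[report.labels > 0]))
        },
        "group_median_os": {
            f"Q{q}": _finite(c.median) for q, c in report.km_by_group.items()
        },
        "logrank": {
            "chi2": report.logrank.statistic,
            "df": report.logrank.df,
            "p": report.logrank.p,
        },
    }
    path = out / "validation_summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    written.append(path)
    if config.make_plots:
        plot = out / "km_validation.png"
        _km_plot(report.km_by_group, plot, "validation cohort: OS by score quartile")
        written.append(plot)
    return written
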