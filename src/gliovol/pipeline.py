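"""End-to-end orchestration: cohort → change metrics → labels → models → report.

Two entry modes share all statistics code:

* **table mode** runs the analysis directly on the generator's volume
  table (fast; exercises change metrics, consensus and modelling);
* **image mode** first renders every scan as 3D phantom images, segments
  both compartments semi-automatically, rigidly registers consecutive
  pairs and computes regional subtractions from the actual masks, then
  feeds the measured volumes into the same statistics.

Every output file embeds the config hash and the seed, and a rerun with
identical config and seed reproduces all numbers bit-identically in table
mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change_metrics import LscParams, build_change_table, regional_subtraction
from .consensus import cohens_kappa, label_change_table
from .phantoms import PhantomSpec, render_patient, simulate_cohort_table
from .progression_model import ModelSpec, compare_models, fit_glmm
from .registration import register_rigid, resample_mask
from .segmentation import seeds_from_mask, segment_semiauto

logger = logging.getLogger("gliovol")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (loadable from YAML; example in the README).

    ``phantom`` and ``lsc`` hold keyword overrides for
    :class:`~gliovol.phantoms.PhantomSpec` and
    :class:`~gliovol.change_metrics.LscParams`.
    """

    mode: str = "table"  # "table" | "image"
    out_dir: str = "gliovol_out"
    seed: int = 0
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    lsc: dict = field(default_factory=dict)  # LscParams overrides
    progression_categories: tuple[int, ...] = (5,)
    n_folds: int = 5
    grouping: str = "patient"
    tolerance_k: float = 2.5
    closing_radius: int = 1
    registration_threshold: float = 0.5
    write_nifti: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "progression_categories" in raw:
            raw["progression_categories"] = tuple(raw["progression_categories"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def _write_csv(df: pd.DataFrame, path: str, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# gliovol {__version__} config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _measure_image_mode(spec: PhantomSpec, truth, table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Replace tabular volumes/subtractions with measurements from rendered
    images: segmentation, registration and voxel-wise mask subtraction."""
    from .grids import save_image, save_mask

    table = table.set_index(["patient_id", "scan_index"], drop=False)
    nifti_dir = os.path.join(cfg.out_dir, "nifti")
    if cfg.write_nifti:
        os.makedirs(nifti_dir, exist_ok=True)

    for patient in truth.patients:
        prev = None  # (rendered, seg_cv, seg_fv)
        for rendered in render_patient(spec, truth, patient.patient_id):
            pid, t = rendered.patient_id, rendered.scan_index
            seg = {}
            for comp, img, ref in (
                ("CV", rendered.mprage, rendered.cv_mask),
                ("FV", rendered.flair, rendered.fv_mask),
            ):
                ax, co = seeds_from_mask(ref.grid)
                seg[comp] = segment_semiauto(
                    img, ax, co, tolerance_k=cfg.tolerance_k,
                    closing_radius=cfg.closing_radius, compartment=comp,
                )
            table.loc[(pid, t), "cv_ml"] = seg["CV"].volume_ml
            table.loc[(pid, t), "fv_ml"] = max(seg["FV"].volume_ml, seg["CV"].volume_ml)
            table.loc[(pid, t), "scv_ml"] = np.nan
            table.loc[(pid, t), "sfv_ml"] = np.nan

            if cfg.write_nifti:
                base = os.path.join(nifti_dir, f"p{pid:03d}_s{t:02d}")
                save_image(rendered.mprage, base + "_mprage.nii.gz")
                save_image(rendered.flair, base + "_flair.nii.gz")
                save_mask(seg["CV"], base + "_cv_seg.nii.gz")
                save_mask(seg["FV"], base + "_fv_seg.nii.gz")

            if prev is not None:
                # register on FLAIR: the larger FV compartment constrains the
                # rigid fit far better than a possibly tiny enhancing lesion
                fixed_img = prev[0].flair
                reg = register_rigid(
                    fixed_img, rendered.flair,
                    accept_threshold=cfg.registration_threshold,
                )
                if reg.accepted:
                    for comp, col in (("CV", "scv_ml"), ("FV", "sfv_ml")):
                        follow = resample_mask(seg[comp], reg.transform, fixed_img)
                        _, s_ml = regional_subtraction(prev[1][comp], follow)
                        table.loc[(pid, t), col] = s_ml
                else:
                    logger.warning(
                        "registration rejected for patient %s pair %s->%s (score %.3f); "
                        "pair excluded from regional subtraction", pid, t - 1, t, reg.score,
                    )
            prev = (rendered, seg)
    return table.reset_index(drop=True)


def _descriptive_table(scans: pd.DataFrame, changes: pd.DataFrame) -> pd.DataFrame:
    """Median (25th–75th percentile, linear interpolation) per determinant."""
    rows = []
    for name, series in (
        ("CV in ml", scans["cv_ml"]),
        ("dCV in ml", changes["dcv_ml"]),
        ("sCV in ml", changes["scv_ml"]),
        ("FV in ml", scans["fv_ml"]),
        ("dFV in ml", changes["dfv_ml"]),
        ("sFV in ml", changes["sfv_ml"]),
    ):
        s = series.dropna()
        rows.append(
            {
                "quantity": name,
                "n": int(s.size),
                "median": s.median(),
                "p25": s.quantile(0.25),
                "p75": s.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and write the report bundle into ``cfg.out_dir``.

    Returns a summary dict (also written as ``summary.json``) with the
    descriptive medians, full-model coefficients, cross-validated AUCs and
    their comparison, accuracies with exact binomial tests, and the
    inter-rater agreement."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logger.info("gliovol %s starting in %s mode (seed %d)", __version__, cfg.mode, cfg.seed)
    if cfg.mode not in ("table", "image"):
        raise ValueError("mode must be 'table' or 'image'")

    spec = PhantomSpec(**{"seed": cfg.seed, **cfg.phantom})
    table, truth = simulate_cohort_table(spec)
    if cfg.mode == "image":
        table = _measure_image_mode(spec, truth, table, cfg)

    lsc = LscParams(**cfg.lsc)
    changes = build_change_table(table, lsc)
    labelled = label_change_table(changes, cfg.progression_categories)
    modelled = labelled.dropna(subset=["label", "scv_ml", "sfv_ml"])

    desc = _descriptive_table(table, labelled)
    fit, coef = fit_glmm(modelled, ModelSpec(
        n_folds=cfg.n_folds, fold_seed=cfg.seed, grouping=cfg.grouping))
    comparison = compare_models(
        modelled, n_folds=cfg.n_folds, fold_seed=cfg.seed, grouping=cfg.grouping
    )
    res_d, res_s = comparison["model_a"], comparison["model_b"]
    dl = comparison["delong"]

    mc_kappa = cohens_kappa(labelled["rating"].astype(int), labelled["mc"].astype(int))
    rater_kappa = cohens_kappa(table["rater_a"].astype(int), table["rater_b"].astype(int))

    summary = {
        "gliovol_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n_patients": int(table["patient_id"].nunique()),
        "n_scans": int(len(table)),
        "n_follow_up_pairs": int(len(labelled)),
        "n_modelled": int(len(modelled)),
        "descriptive": {
            r["quantity"]: {"median": r["median"], "p25": r["p25"], "p75": r["p75"]}
            for r in desc.to_dict("records")
        },
        "kappa_raters": rater_kappa,
        "kappa_rc_mc": mc_kappa,
        "full_model": {
            "coefficients": coef.reset_index().rename(columns={"index": "term"}).to_dict("records"),
            "random_intercept_sd": fit.sigma,
            "converged": fit.converged,
        },
        "delta_model": {
            "auc": res_d.auc,
            "auc_ci": list(res_d.auc_ci),
            "auc_mean_folds": res_d.auc_mean_folds,
            "accuracy": res_d.accuracy,
            "accuracy_ci": list(res_d.accuracy_ci),
            "binomial_p": res_d.binomial_p,
        },
        "subtraction_model": {
            "auc": res_s.auc,
            "auc_ci": list(res_s.auc_ci),
            "auc_mean_folds": res_s.auc_mean_folds,
            "accuracy": res_s.accuracy,
            "accuracy_ci": list(res_s.accuracy_ci),
            "binomial_p": res_s.binomial_p,
        },
        "no_information_rate": res_d.nir,
        "delong": {"z": dl["z"], "p": dl["p"]},
    }

    _write_csv(table, os.path.join(cfg.out_dir, "cohort.csv"), cfg)
    _write_csv(labelled, os.path.join(cfg.out_dir, "changes.csv"), cfg)
    _write_csv(desc, os.path.join(cfg.out_dir, "descriptive.csv"), cfg)
    _write_csv(
        coef.reset_index().rename(columns={"index": "term"}),
        os.path.join(cfg.out_dir, "coefficients.csv"), cfg,
    )
    preds = pd.DataFrame(
        {
            "label": res_d.cv_labels,
            "fold": res_d.cv_fold,
            "prob_delta": res_d.cv_probabilities,
            "prob_subtraction": res_s.cv_probabilities,
        }
    )
    _write_csv(preds, os.path.join(cfg.out_dir, "predictions.csv"), cfg)
    roc = pd.concat(
        [res_d.roc_points.assign(model="delta"), res_s.roc_points.assign(model="subtraction")]
    )
    _write_csv(roc, os.path.join(cfg.out_dir, "roc_points.csv"), cfg)
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    if cfg.make_plots:
        _plots(res_d, res_s, cfg)
    logger.info("report bundle written to %s", cfg.out_dir)
    return summary


def _plots(res_d, res_s, cfg: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(res_d.roc_points.fpr, res_d.roc_points.tpr,
            label=f"delta (AUC {res_d.auc:.2f})")
    ax.plot(res_s.roc_points.fpr, res_s.roc_points.tpr,
            label=f"subtraction (AUC {res_s.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("Cross-validated ROC: volumetric determinants")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(os.path.join(cfg.out_dir, "roc_curves.png"), dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(7, 4), sharey=True)
    for ax, res, title in ((axes[0], res_d, "delta volumes"),
                           (axes[1], res_s, "regional subtractions")):
        groups = [res.cv_probabilities[res.cv_labels == 0],
                  res.cv_probabilities[res.cv_labels == 1]]
        ax.boxplot(groups, tick_labels=["no progression", "progression"])
        ax.set_title(title)
    axes[0].set_ylabel("predicted probability of progression")
    fig.tight_layout()
    fig.savefig(os.path.join(cfg.out_dir, "predicted_probabilities.png"), dpi=120)
    plt.close(fig)
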