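"""End-to-end workflow: preprocess -> color call -> per-color z -> records.

Mirrors the intended analysis of a two-dye localization-microscopy session:
molecules are localized in 2D and cropped, dim molecules are filtered by a
photon threshold, the color classifier assigns each remaining molecule a dye
(or rejects it when the posterior confidence falls below the threshold
delta), and accepted molecules are routed to the axial regressor trained for
their called dye.  The merged localization list carries (x, y, z, color,
photons, confidence) per molecule.

`run_full_benchmark` reproduces the simulated arms of this workflow from
scratch — simulator, spline models, MLE baseline, both network types — and
emits a machine-readable report.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, GridConfig, OpticalConfig
from . import mle_fitter as mf
from . import networks as nw
from . import preprocess as pp
from . import psf_sim as ps
from . import spline_model as sm

__all__ = [
    "LocalizationRecord",
    "EvaluationSummary",
    "ModelBundle",
    "BenchmarkConfig",
    "molecules_from_patches",
    "run_inference_pipeline",
    "evaluate_classification",
    "evaluate_axial",
    "run_full_benchmark",
]

REJECTED = "rejected"


@dataclass
class LocalizationRecord:
    """One row of the final multidimensional localization table."""

    frame: int
    x_nm: float
    y_nm: float
    z_nm: float | None
    color: str
    photons: float
    confidence: float
    method: str = "ann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0 + 1e-9:
            raise ValueError("confidence must lie in [0, 1]")
        if self.color == REJECTED and self.z_nm is not None:
            raise ValueError("rejected molecules carry no z estimate")


@dataclass
class EvaluationSummary:
    """Accuracy / rejection / axial-error tables for one evaluation run."""

    overall: pd.DataFrame
    by_photons: pd.DataFrame | None = None
    by_z: pd.DataFrame | None = None


@dataclass
class ModelBundle:
    """Trained classifier plus one axial regressor per dye."""

    classifier: nw.Network
    class_names: tuple[str, ...]
    axial_regressors: dict[str, nw.Network]

    def __post_init__(self) -> None:
        missing = [c for c in self.class_names if c not in self.axial_regressors]
        if missing:
            raise ConfigurationError(
                f"missing axial regressor for class(es): {missing}"
            )


def molecules_from_patches(
    patches: Sequence[np.ndarray],
    pixel_size_nm: float = 100.0,
    provenance: str = "simulated",
) -> list[pp.MoleculeImage]:
    """Wrap pre-cropped patches as molecule records with simple photometry.

    Photons are estimated as the sum above the 20th-percentile background —
    the same heuristic the MLE initializer uses — so downstream photon
    filters never peek at simulation ground truth.
    """
    out = []
    for i, patch in enumerate(patches):
        patch = np.asarray(patch, dtype=float)
        bg = float(np.percentile(patch, 20))
        photons = float(np.clip(patch - bg, 0, None).sum())
        h = patch.shape[0]
        out.append(
            pp.MoleculeImage(
                patch=patch,
                frame_index=i,
                x0_px=h // 2,
                y0_px=h // 2,
                x_px=h / 2.0,
                y_px=h / 2.0,
                photons=photons,
                sigma2_nm=0.0,
                provenance=provenance,
            )
        )
    return out


def run_inference_pipeline(
    molecules: Sequence[pp.MoleculeImage],
    bundle: ModelBundle,
    delta_threshold: float = 0.0,
    photon_threshold: float = 0.0,
    pixel_size_nm: float = 100.0,
) -> tuple[list[LocalizationRecord], dict]:
    """Color-call and axially localize every molecule.

    Returns the record list plus a log with per-stage counters; the counters
    always satisfy ``accepted + rejected + filtered == len(molecules)``.
    Rejected and filtered molecules appear as records with
    ``color='rejected'`` / no z, so nothing silently disappears.
    """
    log = {
        "n_input": len(molecules),
        "n_filtered_photons": 0,
        "n_rejected_confidence": 0,
        "n_accepted": 0,
        "delta_threshold": delta_threshold,
        "photon_threshold": photon_threshold,
    }
    records: list[LocalizationRecord] = []
    if not molecules:
        return records, log

    bright = [m for m in molecules if m.photons >= photon_threshold]
    log["n_filtered_photons"] = len(molecules) - len(bright)
    if not bright:
        return records, log

    X = nw.patches_to_inputs([m.patch for m in bright])
    calls = nw.infer_color(bundle.classifier, X, delta_threshold)
    # group accepted molecules per called color for batched regression
    z_values: dict[int, float] = {}
    for color_idx, name in enumerate(bundle.class_names):
        rows = [
            i
            for i, c in enumerate(calls)
            if c.accepted and c.map_class == color_idx
        ]
        if rows:
            zs = nw.infer_axial(bundle.axial_regressors[name], X[rows])
            z_values.update({r: float(z) for r, z in zip(rows, zs)})
    for i, (m, call) in enumerate(zip(bright, calls)):
        accepted = call.accepted
        records.append(
            LocalizationRecord(
                frame=m.frame_index,
                x_nm=m.x_px * pixel_size_nm,
                y_nm=m.y_px * pixel_size_nm,
                z_nm=z_values[i] if accepted else None,
                color=bundle.class_names[call.map_class] if accepted else REJECTED,
                photons=m.photons,
                confidence=abs(call.delta),
                method="ann",
            )
        )
        log["n_accepted" if accepted else "n_rejected_confidence"] += 1
    return records, log


def records_to_frame(records: Sequence[LocalizationRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# evaluation summaries
# ---------------------------------------------------------------------------

def _accuracy_rejection(
    map_class: np.ndarray, delta: np.ndarray, truth: np.ndarray, thr: float
) -> tuple[float, float, int]:
    accepted = np.abs(delta) >= thr
    n_acc = int(accepted.sum())
    rejection = 1.0 - n_acc / len(truth)
    accuracy = (
        float(np.mean(map_class[accepted] == truth[accepted])) if n_acc else np.nan
    )
    return accuracy, rejection, n_acc


def evaluate_classification(
    calls: Sequence[nw.ColorCall],
    truths: Sequence[int],
    photon_counts: Sequence[float] | None = None,
    z_positions: Sequence[float] | None = None,
    thresholds: Sequence[float] = (0.0, 0.4, 0.8),
    photon_bins: Sequence[float] | None = None,
    z_bins: Sequence[float] | None = None,
) -> EvaluationSummary:
    """Accuracy among accepted molecules and rejection rate, per threshold.

    Optionally stratified by photon count and by true z.  Empty strata
    report NaN accuracy (undefined), never zero.
    """
    truth = np.asarray(truths)
    map_class = np.array([c.map_class for c in calls])
    delta = np.array([c.delta for c in calls])
    rows = []
    for thr in thresholds:
        acc, rej, n_acc = _accuracy_rejection(map_class, delta, truth, thr)
        rows.append(
            {
                "threshold": thr,
                "accuracy": acc,
                "rejection_rate": rej,
                "n_accepted": n_acc,
                "n_total": len(truth),
            }
        )
    overall = pd.DataFrame(rows)

    def stratify(values, bins, label):
        values = np.asarray(values, dtype=float)
        edges = np.asarray(bins, dtype=float)
        out = []
        which = np.digitize(values, edges) - 1
        for b in range(len(edges) - 1):
            sel = which == b
            for thr in thresholds:
                if sel.sum():
                    acc, rej, n_acc = _accuracy_rejection(
                        map_class[sel], delta[sel], truth[sel], thr
                    )
                else:
                    acc, rej, n_acc = np.nan, np.nan, 0
                out.append(
                    {
                        label: 0.5 * (edges[b] + edges[b + 1]),
                        "threshold": thr,
                        "accuracy": acc,
                        "rejection_rate": rej,
                        "n": int(sel.sum()),
                        "n_accepted": n_acc,
                    }
                )
        return pd.DataFrame(out)

    by_photons = (
        stratify(photon_counts, photon_bins, "photons")
        if photon_counts is not None and photon_bins is not None
        else None
    )
    by_z = (
        stratify(z_positions, z_bins, "z_nm")
        if z_positions is not None and z_bins is not None
        else None
    )
    return EvaluationSummary(overall=overall, by_photons=by_photons, by_z=by_z)


def evaluate_axial(
    z_estimates: Sequence[float],
    z_truths: Sequence[float],
    z_bins: Sequence[float] | None = None,
    crlb_model: sm.SplinePSFModel | None = None,
    crlb_theta: sm.FitParameters | None = None,
) -> pd.DataFrame:
    """Per-true-z bias (mean error) and precision (std), optionally with CRLB."""
    z_est = np.asarray(z_estimates, dtype=float)
    z_true = np.asarray(z_truths, dtype=float)
    if z_est.shape != z_true.shape:
        raise ValueError("estimates and truths must pair one-to-one")
    if z_bins is None:
        z_bins = np.unique(z_true)
        centers = z_bins
        which = np.searchsorted(z_bins, z_true)
    else:
        edges = np.asarray(z_bins, dtype=float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        which = np.digitize(z_true, edges) - 1
    rows = []
    for b, center in enumerate(centers):
        sel = which == b
        if not sel.sum():
            continue
        err = z_est[sel] - z_true[sel]
        row = {
            "z_nm": float(center),
            "bias_nm": float(err.mean()),
            "std_nm": float(err.std()),
            "n": int(sel.sum()),
        }
        if crlb_model is not None:
            theta = crlb_theta or sm.FitParameters()
            row["crlb_nm"] = sm.crlb(
                crlb_model,
                sm.FitParameters(
                    z_nm=float(center),
                    photons=theta.photons,
                    background=theta.background,
                ),
            ).z_nm
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full simulated benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkConfig:
    """Problem sizes and conditions of the simulated two-color benchmark.

    Defaults follow the reference study conditions: 600/700 nm dyes,
    10 photons/pixel background, training photons in the 4500-5500 band,
    classification over +-400 nm defocus, regression over +-600 nm, and the
    4096-4096-2048-1024 architecture.  ``reduced()`` gives the desk-scale
    variant (smaller sets, narrower layers, same physics) used by the test
    suite and the acceptance script.
    """

    wavelengths_nm: tuple[float, float] = (600.0, 700.0)
    background: float = 10.0
    train_photon_band: tuple[float, float] = (4500.0, 5500.0)
    eval_photons: tuple[float, ...] = (5000.0, 2000.0)
    z_class_range_nm: float = 400.0
    z_reg_range_nm: float = 600.0
    n_train_per_color: int = 10000
    n_val_per_color: int = 1000
    n_test_per_color: int = 500
    n_axial_train: int = 6000
    n_axial_val: int = 600
    n_mle_test_per_color: int = 200
    classifier_hidden: tuple[int, ...] = (4096, 4096, 2048, 1024)
    regressor_hidden: tuple[int, ...] = (4096, 4096, 2048, 1024)
    classifier_epochs: int = 10
    regressor_epochs: int = 10
    regressor_decay_interval: int = 1000
    thresholds: tuple[float, ...] = (0.0, 0.4, 0.8)
    photon_threshold: float = 3000.0
    n_pipeline: int = 1000

    @staticmethod
    def reduced() -> "BenchmarkConfig":
        return BenchmarkConfig(
            n_train_per_color=3000,
            n_val_per_color=400,
            n_test_per_color=250,
            n_axial_train=6000,
            n_axial_val=600,
            n_mle_test_per_color=200,
            classifier_hidden=(256, 256, 128, 64),
            regressor_hidden=(512, 256, 128, 64),
            classifier_epochs=12,
            regressor_epochs=30,
            regressor_decay_interval=2000,
            n_pipeline=1000,
        )


def _dataset_arrays(dataset, label: str):
    X = nw.patches_to_inputs([img for img, _ in dataset])
    truths = [t for _, t in dataset]
    if label == "color":
        y = np.array([t.color_label for t in truths])
    elif label == "z":
        y = np.array([t.z_nm for t in truths])
    else:
        raise ValueError(label)
    return X, y, truths


def run_full_benchmark(
    config: BenchmarkConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
    grid: GridConfig | None = None,
) -> dict:
    """Simulate, build models, train networks, run both arms, summarize.

    Single top-level ``seed`` governs every random stream; two runs with the
    same config and seed produce identical reports.  If ``out_dir`` is given
    the report (JSON), the localization table (CSV) and diagnostic plots are
    written there.
    """
    t_start = time.time()
    grid = grid or GridConfig()
    report: dict = {
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in asdict(config).items()
        },
        "seed": seed,
        "grid": asdict(grid),
        "stages": {},
    }

    def stage(name):
        report["stages"][name] = {"t_start_s": round(time.time() - t_start, 2)}
        return report["stages"][name]

    # --- stage 1: PSF stacks and spline models -----------------------------
    st = stage("simulate")
    optics = [
        OpticalConfig(emission_wavelength_nm=wl) for wl in config.wavelengths_nm
    ]
    stacks = [ps.generate_psf_stack_cached(o, grid) for o in optics]
    models = [
        sm.build_spline_model(
            ps.roi_normalized(ps.downsample_to_detector(s, grid), grid),
            source_stack_id=f"sim{int(o.emission_wavelength_nm)}",
        )
        for s, o in zip(stacks, optics)
    ]
    st["n_colors"] = len(stacks)

    def make(n_per_color, photons, z_range, sub_seed, colors=None):
        sel = list(range(len(optics))) if colors is None else colors
        return ps.generate_benchmark_dataset(
            [optics[i] for i in sel],
            grid,
            n_per_color,
            photon_distribution=photons,
            background=config.background,
            z_distribution=(-z_range, z_range),
            rng_seed=sub_seed,
            stacks=[stacks[i] for i in sel],
        )

    # --- stage 2: MLE color arm --------------------------------------------
    st = stage("mle_color")
    mle_set = make(
        config.n_mle_test_per_color,
        config.eval_photons[0],
        config.z_class_range_nm,
        seed * 131 + 1,
    )
    correct = 0
    for img, truth in mle_set:
        call = mf.classify_color_mle(img, models)
        correct += call.color == truth.color_label
    st["accuracy"] = correct / len(mle_set)
    st["n"] = len(mle_set)

    # --- stage 3: color network --------------------------------------------
    st = stage("color_network")
    train = make(
        config.n_train_per_color,
        config.train_photon_band,
        config.z_class_range_nm,
        seed * 131 + 2,
    )
    val = make(
        config.n_val_per_color,
        config.train_photon_band,
        config.z_class_range_nm,
        seed * 131 + 3,
    )
    Xtr, ytr, _ = _dataset_arrays(train, "color")
    Xv, yv, _ = _dataset_arrays(val, "color")
    clf = nw.build_network(
        nw.NetworkSpec(
            hidden_layers=config.classifier_hidden,
            n_classes=len(optics),
            dropout_rate=0.5,
        ),
        seed=seed * 131 + 4,
    )
    clf, clf_log = nw.train_color_network(
        clf,
        (Xtr, ytr),
        (Xv, yv),
        nw.TrainingConfig(
            initial_learning_rate=1e-4,
            batch_size=64,
            max_epochs=config.classifier_epochs,
            seed=seed * 131 + 5,
        ),
    )
    st["epochs"] = clf_log.stopped_epoch
    st["val_accuracy"] = clf_log.val_metric[-1]
    st["ann_accuracy"] = {}
    for photons in config.eval_photons:
        test = make(
            config.n_test_per_color, photons, config.z_class_range_nm,
            seed * 131 + 6 + int(photons),
        )
        Xt, yt, truths = _dataset_arrays(test, "color")
        calls = nw.infer_color(clf, Xt, 0.0)
        summary = evaluate_classification(
            calls, yt, thresholds=config.thresholds
        )
        st["ann_accuracy"][str(int(photons))] = summary.overall.to_dict("records")

    # --- stage 4: axial networks -------------------------------------------
    st = stage("axial_networks")
    regressors: dict[str, nw.Network] = {}
    class_names = tuple(f"dye{int(wl)}" for wl in config.wavelengths_nm)
    st["per_color"] = {}
    for i, name in enumerate(class_names):
        atrain = make(
            config.n_axial_train, config.train_photon_band,
            config.z_reg_range_nm, seed * 131 + 20 + i, colors=[i],
        )
        aval = make(
            config.n_axial_val, config.train_photon_band,
            config.z_reg_range_nm, seed * 131 + 40 + i, colors=[i],
        )
        Xa, za, _ = _dataset_arrays(atrain, "z")
        Xav, zav, _ = _dataset_arrays(aval, "z")
        reg = nw.build_network(
            nw.NetworkSpec(
                hidden_layers=config.regressor_hidden, weight_decay=0.01
            ),
            seed=seed * 131 + 60 + i,
        )
        reg, reg_log = nw.train_axial_network(
            reg,
            (Xa, za),
            (Xav, zav),
            nw.TrainingConfig(
                initial_learning_rate=1e-3,
                batch_size=32,
                max_epochs=config.regressor_epochs,
                decay_interval=config.regressor_decay_interval,
                plateau_patience=5,
                seed=seed * 131 + 80 + i,
            ),
        )
        regressors[name] = reg
        st["per_color"][name] = {
            "epochs": reg_log.stopped_epoch,
            "val_rmse_nm": reg_log.val_metric[-1],
        }

    # --- stage 5: axial evaluation vs CRLB (reference dye: longest λ) ------
    st = stage("axial_eval")
    ref = len(optics) - 1
    sweep = make(
        config.n_test_per_color, config.eval_photons[0],
        config.z_class_range_nm, seed * 131 + 100, colors=[ref],
    )
    Xs, zs, _ = _dataset_arrays(sweep, "z")
    zhat = nw.infer_axial(regressors[class_names[ref]], Xs)
    slope = float(np.polyfit(zs, zhat, 1)[0])
    edges = np.arange(
        -config.z_class_range_nm, config.z_class_range_nm + 1e-9, 100.0
    )
    table = evaluate_axial(
        zhat, zs, z_bins=edges, crlb_model=models[ref],
        crlb_theta=sm.FitParameters(
            photons=config.eval_photons[0], background=config.background
        ),
    )
    st["calibration_slope"] = slope
    st["by_z"] = table.to_dict("records")

    # --- stage 6: mixed pipeline run ---------------------------------------
    st = stage("pipeline")
    bundle = ModelBundle(
        classifier=clf, class_names=class_names, axial_regressors=regressors
    )
    mixed = make(
        max(config.n_pipeline // len(optics), 1),
        config.eval_photons[0],
        config.z_class_range_nm,
        seed * 131 + 120,
    )
    molecules = molecules_from_patches([img for img, _ in mixed])
    records, log = run_inference_pipeline(
        molecules,
        bundle,
        delta_threshold=config.thresholds[-1],
        photon_threshold=config.photon_threshold,
        pixel_size_nm=grid.pixel_size_nm,
    )
    truth_labels = np.array([t.color_label for _, t in mixed])
    kept = [
        (r, truth_labels[i])
        for i, (r, (_, t)) in enumerate(zip(records, mixed))
    ]
    st["log"] = log
    acc_rows = [
        r.color == class_names[lbl] for r, lbl in kept if r.color != REJECTED
    ]
    st["end_to_end_color_accuracy"] = (
        float(np.mean(acc_rows)) if acc_rows else None
    )
    st["conservation_ok"] = (
        log["n_accepted"] + log["n_rejected_confidence"] + log["n_filtered_photons"]
        == log["n_input"]
    )

    report["total_runtime_s"] = round(time.time() - t_start, 2)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        records_to_frame(records).to_csv(
            out_dir / "localizations.csv", index=False
        )
        _benchmark_plots(report, table, out_dir)
    return report


def _benchmark_plots(report: dict, axial_table: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    stage = report["stages"]["color_network"]
    for photons, rows in stage["ann_accuracy"].items():
        thr = [r["threshold"] for r in rows]
        acc = [r["accuracy"] for r in rows]
        axes[0].plot(thr, acc, "o-", label=f"{photons} photons")
    axes[0].set_xlabel("confidence threshold δ")
    axes[0].set_ylabel("accuracy (accepted)")
    axes[0].legend()
    if len(axial_table):
        axes[1].plot(axial_table["z_nm"], axial_table["std_nm"], "o-", label="ANN std")
        if "crlb_nm" in axial_table:
            axes[1].plot(
                axial_table["z_nm"], axial_table["crlb_nm"], "k--", label="CRLB"
            )
        axes[1].set_xlabel("true z (nm)")
        axes[1].set_ylabel("z precision (nm)")
        axes[1].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "benchmark.png", dpi=120)
    plt.close(fig)
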