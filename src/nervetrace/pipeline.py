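"""End-to-end study orchestration.

``run_study`` reproduces the structure of a manual-vs-CNN nerve morphometry
study on synthetic phantoms: generate a dataset with ground truth, resize
to the network input, split train/validation/test, flip-augment the
training set, train U-Net and SegNet, predict the test masks, and report

* per-image and summary segmentation metrics plus the IoU histogram,
* morphometry of predicted, ground-truth and simulated-manual masks,
* Spearman correlations and Bland-Altman agreement per measurement and
  model, and a t-test comparing the two models' metric samples.

Every random draw traces to a named seed in the config; re-running with
the same config reproduces all outputs bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import morphometry, segmetrics
from .errors import NerveTraceError
from .phantoms import generate_dataset, is_hard, perturb_annotation
from .preprocess import augment_flips, crop_and_resize, split_dataset
from .segnets import SegModelConfig, build_model
from .training import TrainConfig, train

__all__ = ["Seeds", "RunConfig", "StudyReport", "run_study"]

MEASUREMENTS = ("mncsa", "circumference", "d1", "d2")
ARCHITECTURES = ("unet", "segnet")


@dataclass
class Seeds:
    data: int = 11
    split: int = 22
    model: int = 33
    train: int = 44
    annotation: int = 55


@dataclass
class RunConfig:
    """One flat config drives the whole study."""

    n_images: int = 600
    frame_size: tuple[int, int] = (300, 300)
    input_size: int = 256
    covariate_ranges: dict | None = None
    hard_ranges: dict | None = None
    hard_fraction: float = 0.25
    depth: int = 5
    base_channels: int = 16
    epochs: int = 20
    n_batches: int = 5
    batch_size: int | None = None  # overrides n_batches when set
    learning_rate: float | dict = 1e-3  # scalar, or per-architecture dict
    clip_norm: float | None = None
    threshold: float = 0.5
    mm_per_pixel: float = 1.0
    annotation_magnitude: float = 2.0  # px; 0 uses pristine ground truth
    seeds: Seeds = field(default_factory=Seeds)
    outdir: str | None = None

    def manifest(self) -> dict:
        d = asdict(self)
        d["frame_size"] = list(self.frame_size)
        return d


@dataclass
class StudyReport:
    per_image: pd.DataFrame      # one row per test image x architecture
    summaries: dict              # arch -> summarize_metrics output
    histories: dict              # arch -> LossHistory
    morphometry: pd.DataFrame    # long table: image, source, measures
    agreement: pd.DataFrame      # 4 measurements x 2 models
    model_comparison: pd.DataFrame  # t-tests between architectures
    manifest: dict
    models: dict = field(default_factory=dict, repr=False)


def _predict_batch(model, frames, threshold):
    x = np.stack([np.asarray(f.pixels, dtype=model.config.dtype) / 255.0
                  for f in frames])[..., None]
    prob = model.predict_proba(x)
    return [(prob[i, :, :, 0] >= threshold).astype(np.uint8)
            for i in range(prob.shape[0])]


def _measure_safe(mask, mmpp):
    """Morphometry of a possibly-empty model output; NaNs when unmeasurable."""
    clean = morphometry.principal_component_mask(mask)
    try:
        return morphometry.measure(clean, mm_per_pixel=mmpp).as_dict()
    except NerveTraceError:
        return {m: np.nan for m in MEASUREMENTS} | {"rect_angle": np.nan}


def run_study(config: RunConfig) -> StudyReport:
    """Run the full synthetic study; see the module docstring."""
    s = config.seeds

    # -- data ------------------------------------------------------------
    try:
        raw = generate_dataset(config.n_images, config.covariate_ranges,
                               seed=s.data, frame_size=config.frame_size,
                               hard_fraction=config.hard_fraction,
                               hard_ranges=config.hard_ranges)
    except NerveTraceError as e:
        raise NerveTraceError(f"stage generate failed: {e}") from e
    frames, masks, specs = [], [], []
    for i, (frame, mask, spec) in enumerate(raw):
        try:
            f, m = crop_and_resize(frame, target=config.input_size, mask=mask)
        except NerveTraceError as e:
            raise NerveTraceError(f"stage prepare failed on image {i}: {e}") from e
        frames.append(f)
        masks.append(m)
        specs.append(spec)

    split = split_dataset(list(range(config.n_images)), seed=s.split)
    train_pairs = augment_flips([(frames[i], masks[i]) for i in split.train],
                                seed=s.split + 1)
    val_pairs = [(frames[i], masks[i]) for i in split.validation]
    test_ids = list(split.test)

    # -- models ----------------------------------------------------------
    histories, models, preds = {}, {}, {}
    for arch in ARCHITECTURES:
        lr = (config.learning_rate[arch]
              if isinstance(config.learning_rate, dict)
              else config.learning_rate)
        tcfg = TrainConfig(epochs=config.epochs, n_batches=config.n_batches,
                           batch_size=config.batch_size, learning_rate=lr,
                           clip_norm=config.clip_norm, seed=s.train)
        mcfg = SegModelConfig(architecture=arch, input_size=config.input_size,
                              depth=config.depth,
                              base_channels=config.base_channels, seed=s.model)
        model = build_model(mcfg)
        try:
            model, hist = train(model, train_pairs, val_pairs, tcfg)
        except NerveTraceError as e:
            raise NerveTraceError(f"stage train({arch}) failed: {e}") from e
        models[arch] = model
        histories[arch] = hist
        preds[arch] = _predict_batch(model, [frames[i] for i in test_ids],
                                     config.threshold)

    # -- segmentation metrics -------------------------------------------
    rows, summaries = [], {}
    for arch in ARCHITECTURES:
        per_img = []
        for j, i in enumerate(test_ids):
            c, met = segmetrics.evaluate_pair(preds[arch][j], masks[i])
            per_img.append(met)
            rows.append({"image_id": i, "architecture": arch,
                         "stratum": "hard" if is_hard(specs[i]) else "easy",
                         "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                         **met.as_dict()})
        summaries[arch] = segmetrics.summarize_metrics(per_img)
    per_image = pd.DataFrame(rows)

    # -- morphometry -----------------------------------------------------
    mmpp = config.mm_per_pixel
    morph_rows = []
    manual = {}
    for j, i in enumerate(test_ids):
        truth = masks[i]
        man = (perturb_annotation(truth, config.annotation_magnitude,
                                  seed=s.annotation + i)
               if config.annotation_magnitude > 0 else truth)
        manual[i] = man
        morph_rows.append({"image_id": i, "source": "truth",
                           **_measure_safe(truth, mmpp)})
        morph_rows.append({"image_id": i, "source": "manual_sim",
                           **_measure_safe(man, mmpp)})
        for arch in ARCHITECTURES:
            morph_rows.append({"image_id": i, "source": arch,
                               **_measure_safe(preds[arch][j], mmpp)})
    morph = pd.DataFrame(morph_rows)

    # -- agreement -------------------------------------------------------
    wide = morph.pivot(index="image_id", columns="source")
    agree_rows = []
    for arch in ARCHITECTURES:
        for meas in MEASUREMENTS:
            ref = wide[(meas, "manual_sim")].to_numpy()
            tst = wide[(meas, arch)].to_numpy()
            ok = np.isfinite(ref) & np.isfinite(tst)
            row = {"measurement": meas, "architecture": arch,
                   "n": int(ok.sum())}
            # too few measurable predictions: report NaNs rather than abort
            if ok.sum() >= 3 and np.ptp(ref[ok]) > 0 and np.ptp(tst[ok]) > 0:
                corr = agr.spearman(ref[ok], tst[ok])
                ba = agr.bland_altman(ref[ok], tst[ok])
                row.update(rs=corr.rs, p=corr.p, band=corr.band,
                           mean_diff=ba.mean_diff, sd_diff=ba.sd_diff,
                           loa_low=ba.loa_low, loa_high=ba.loa_high,
                           coverage=ba.coverage)
            else:
                row.update(rs=np.nan, p=np.nan, band="other",
                           mean_diff=np.nan, sd_diff=np.nan,
                           loa_low=np.nan, loa_high=np.nan,
                           coverage=np.nan)
            agree_rows.append(row)
    agreement_df = pd.DataFrame(agree_rows)

    comp_rows = []
    u = per_image[per_image.architecture == "unet"]
    g = per_image[per_image.architecture == "segnet"]
    for met in segmetrics.METRIC_NAMES:
        t, p = agr.two_sample_t(u[met].to_numpy(), g[met].to_numpy())
        comp_rows.append({"metric": met, "t": t, "p": p})
    comparison = pd.DataFrame(comp_rows)

    report = StudyReport(per_image=per_image, summaries=summaries,
                         histories=histories, morphometry=morph,
                         agreement=agreement_df, model_comparison=comparison,
                         manifest=config.manifest(), models=models)
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_image.to_csv(outdir / "per_image_metrics.csv", index=False)
    report.morphometry.to_csv(outdir / "morphometry.csv", index=False)
    report.agreement.to_csv(outdir / "agreement.csv", index=False)
    report.model_comparison.to_csv(outdir / "model_comparison.csv", index=False)
    summary_rows = []
    for arch, s in report.summaries.items():
        for met, row in s["table"].iterrows():
            summary_rows.append({"architecture": arch, "metric": met,
                                 "mean": row["mean"], "sd": row["sd"]})
        summary_rows.append({"architecture": arch, "metric": "iou_mode",
                             "mean": s["iou_mode"], "sd": 0.0})
        summary_rows.append({"architecture": arch, "metric": "iou_min",
                             "mean": s["iou_min"], "sd": 0.0})
    pd.DataFrame(summary_rows).to_csv(outdir / "summary_metrics.csv", index=False)
    loss_rows = []
    for arch, h in report.histories.items():
        for e, (tl, vl) in enumerate(zip(h.train_loss, h.val_loss), start=1):
            loss_rows.append({"architecture": arch, "epoch": e,
                              "train_loss": tl, "val_loss": vl})
    pd.DataFrame(loss_rows).to_csv(outdir / "loss_curves.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True))
    _plot_report(report, outdir)


def _plot_report(report: StudyReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for arch, h in report.histories.items():
        epochs = np.arange(1, len(h.train_loss) + 1)
        ax.plot(epochs, h.train_loss, label=f"{arch} train")
        if h.val_loss:
            ax.plot(epochs, h.val_loss, "--", label=f"{arch} val")
    ax.set_xlabel("epoch")
    ax.set_ylabel("binary cross-entropy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "loss_curves.png", dpi=120)
    plt.close(fig)

    n_meas = len(MEASUREMENTS)
    fig, axes = plt.subplots(n_meas, 2, figsize=(9, 3 * n_meas))
    wide = report.morphometry.pivot(index="image_id", columns="source")
    for r, meas in enumerate(MEASUREMENTS):
        for c, arch in enumerate(ARCHITECTURES):
            ax = axes[r, c]
            ref = wide[(meas, "manual_sim")].to_numpy()
            tst = wide[(meas, arch)].to_numpy()
            ok = np.isfinite(ref) & np.isfinite(tst)
            d = ref[ok] - tst[ok]
            m = (ref[ok] + tst[ok]) / 2
            ax.scatter(m, d, s=10)
            row = report.agreement.query(
                "measurement == @meas and architecture == @arch").iloc[0]
            for yv, st in ((row.mean_diff, "-"), (row.loa_low, "--"),
                           (row.loa_high, "--")):
                ax.axhline(yv, color="k", linestyle=st, linewidth=0.8)
            ax.set_title(f"{meas} vs {arch}")
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.png", dpi=120)
    plt.close(fig)
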