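"""Dataset assembly: feature/flow alignment, time normalization and fixed-
length resampling, bounded random augmentation, and patient-wise train/
validation splitting.

Augmentation follows the bounded-perturbation rule V'(t) = |V(t) + A*rand(t)|
with rand uniform on [-1, 1] i.i.d. per sample and 0 < A < 0.05*max V; one
hundred copies per event by default.  For the pattern classifier every curve
is normalized to [0, 1] on both axes and resampled to exactly 246 points, so
classification depends only on curve shape, not flow magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .psychoacoustics import FeatureSeries
from .uroflow import LABELS, FlowrateCurve

#: Fixed sequence length of normalized curves.
RESAMPLE_LENGTH = 246


@dataclass
class AugmentConfig:
    """Bounded-perturbation augmentation settings.

    ``amplitude`` fixes A in mL/s when given; otherwise A is drawn per copy
    uniformly from (0, amplitude_fraction * max V).
    """

    amplitude: float | None = None
    amplitude_fraction: float = 0.05
    n_copies: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude is None and not 0.0 < self.amplitude_fraction <= 0.05:
            raise ValueError("amplitude_fraction must be in (0, 0.05]")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class NormalizedSequence:
    """A flow curve normalized to [0, 1] on both axes at fixed length.

    ``source_scale`` = (t_min, t_max, v_max) permits inversion back to
    physical units.
    """

    values: np.ndarray
    length: int = RESAMPLE_LENGTH
    source_scale: tuple = (0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.length:
            raise ValueError("values length must equal declared length")
        if np.any(self.values < -1e-12) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("normalized values must lie in [0, 1]")


@dataclass
class Example:
    """One training example.

    For regression ``inputs`` is a (T, d) feature matrix and ``target`` the
    length-T flowrate; for classification ``inputs`` is a length-246
    normalized curve and ``label`` the pattern letter.
    """

    patient_id: str
    inputs: np.ndarray
    target: np.ndarray | None = None
    label: str | None = None


@dataclass
class TrainingSet:
    """Patient-wise split dataset with train-only standardization statistics."""

    task: str  # "regression" or "classification"
    inputs_train: list
    targets_train: list
    inputs_val: list
    targets_val: list
    patients_train: list
    patients_val: list
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    target_mean: float = 0.0
    target_std: float = 1.0
    classes: tuple = LABELS

    def standardize_inputs(self, x: np.ndarray) -> np.ndarray:
        """Apply the train-set z-score to a (T, d) feature matrix."""
        return (x - self.feature_mean) / self.feature_std


def align_features_to_flow(fs: FeatureSeries, fc: FlowrateCurve):
    """Resample a feature series and a flow curve onto one uniform grid.

    The grid spans the intersection of both supports with the coarser of the
    two native steps; both signals are linearly interpolated.  Returns
    (times, features (n, 2), flow (n,)).
    """
    t0 = max(fs.times[0], fc.times[0])
    t1 = min(fs.times[-1], fc.times[-1])
    if t1 <= t0:
        raise ValueError("feature and flow supports do not overlap")
    step_fs = float(np.median(np.diff(fs.times))) if fs.times.size > 1 else t1 - t0
    step_fc = float(np.median(np.diff(fc.times))) if fc.times.size > 1 else t1 - t0
    step = max(step_fs, step_fc)
    n = int(np.floor((t1 - t0) / step)) + 1
    times = t0 + step * np.arange(n)
    feats = np.column_stack(
        [
            np.interp(times, fs.times, fs.loudness),
            np.interp(times, fs.times, fs.roughness),
        ]
    )
    flow = np.interp(times, fc.times, fc.flowrate)
    return times, feats, flow


def normalize_resample(fc: FlowrateCurve, length: int = RESAMPLE_LENGTH) -> NormalizedSequence:
    """Normalize a flow curve to [0, 1] on both axes and resample to
    ``length`` points by linear interpolation.  Invertible via the stored
    (t_min, t_max, v_max) scale; idempotent."""
    if fc.times.size < 2:
        raise ValueError("need at least 2 samples")
    vmax = float(fc.flowrate.max())
    if vmax <= 0:
        raise ValueError("all-zero curve cannot be normalized")
    t0, t1 = float(fc.times[0]), float(fc.times[-1])
    s = (fc.times - t0) / (t1 - t0)
    grid = np.linspace(0.0, 1.0, length)
    vals = np.interp(grid, s, fc.flowrate / vmax)
    # renormalize after resampling so the output max is exactly 1 (the true
    # peak may fall between grid points); fold the factor into the stored
    # scale to keep inversion exact and normalization idempotent
    peak = vals.max()
    return NormalizedSequence(vals / peak, length, (t0, t1, vmax * peak))


def denormalize(ns: NormalizedSequence) -> FlowrateCurve:
    """Invert :func:`normalize_resample` using the stored source scale."""
    t0, t1, vmax = ns.source_scale
    times = t0 + (t1 - t0) * np.linspace(0.0, 1.0, ns.length)
    return FlowrateCurve(times, ns.values * vmax)


def augment(fc: FlowrateCurve, cfg: AugmentConfig | None = None) -> list[FlowrateCurve]:
    """Generate ``n_copies`` bounded random perturbations of a flow curve.

    Each copy is V'(t) = |V(t) + A*rand(t)| with rand ~ U[-1, 1] i.i.d. per
    sample and A drawn per copy from (0, amplitude_fraction * max V) unless
    fixed.  The max perturbation of any copy is strictly below A, hence below
    5% of the curve maximum; bit-reproducible from the seed.
    """
    cfg = cfg or AugmentConfig()
    vmax = float(fc.flowrate.max())
    if vmax <= 0:
        raise ValueError("cannot augment an all-zero curve")
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_copies):
        a = cfg.amplitude if cfg.amplitude is not None else float(
            rng.uniform(0.0, cfg.amplitude_fraction * vmax)
        )
        r = rng.uniform(-1.0, 1.0, fc.flowrate.size)
        out.append(FlowrateCurve(fc.times.copy(), np.abs(fc.flowrate + a * r)))
    return out


def build_training_set(
    examples: list[Example],
    task: str = "regression",
    split_fraction: float = 0.8,
    seed: int = 0,
) -> TrainingSet:
    """Assemble a patient-wise split training set.

    Patients (not curves) are assigned to train or validation, so augmented
    copies of one patient never leak across the split.  Regression inputs
    and targets are z-scored with train-set statistics only; classification
    inputs are already normalized shapes and targets are pattern labels.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    patients = sorted({ex.patient_id for ex in examples})
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for a split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(split_fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_p = {patients[i] for i in order[:n_train]}
    val_p = {patients[i] for i in order[n_train:]}

    def collect(pool):
        ins, tgt, pid = [], [], []
        for ex in examples:
            if ex.patient_id not in pool:
                continue
            ins.append(np.asarray(ex.inputs, dtype=float))
            if task == "regression":
                if ex.target is None or len(ex.target) != len(ex.inputs):
                    raise ValueError("regression examples need matching targets")
                tgt.append(np.asarray(ex.target, dtype=float))
            else:
                if ex.label not in LABELS:
                    raise ValueError(f"classification examples need labels in {LABELS}")
                tgt.append(ex.label)
            pid.append(ex.patient_id)
        return ins, tgt, pid

    ins_tr, tgt_tr, pid_tr = collect(train_p)
    ins_va, tgt_va, pid_va = collect(val_p)

    ts = TrainingSet(
        task=task,
        inputs_train=ins_tr,
        targets_train=tgt_tr,
        inputs_val=ins_va,
        targets_val=tgt_va,
        patients_train=sorted(train_p),
        patients_val=sorted(val_p),
    )
    if task == "classification":
        if len(set(tgt_tr)) < 2:
            raise ValueError("training split contains a single class")
        return ts

    stacked = np.concatenate([np.atleast_2d(x) for x in ins_tr], axis=0)
    ts.feature_mean = stacked.mean(axis=0)
    ts.feature_std = np.maximum(stacked.std(axis=0), 1e-9)
    all_t = np.concatenate(tgt_tr)
    ts.target_mean = float(all_t.mean())
    ts.target_std = float(max(all_t.std(), 1e-9))
    return ts


# --------------------------------------------------------------------------
# On-disk form: directory of delimited text sequences plus a JSON manifest
# --------------------------------------------------------------------------


def save_training_set(ts: TrainingSet, outdir) -> None:
    """Serialize a training set as delimited-text sequences + JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "task": ts.task,
        "patients_train": ts.patients_train,
        "patients_val": ts.patients_val,
        "classes": list(ts.classes),
        "feature_mean": None if ts.feature_mean is None else ts.feature_mean.tolist(),
        "feature_std": None if ts.feature_std is None else ts.feature_std.tolist(),
        "target_mean": ts.target_mean,
        "target_std": ts.target_std,
        "examples": [],
    }
    for split, ins, tgts in (
        ("train", ts.inputs_train, ts.targets_train),
        ("val", ts.inputs_val, ts.targets_val),
    ):
        for k, (x, t) in enumerate(zip(ins, tgts)):
            name = f"{split}_{k:05d}"
            np.savetxt(outdir / f"{name}_x.csv", np.atleast_2d(x), delimiter=",")
            entry = {"name": name, "split": split}
            if ts.task == "regression":
                np.savetxt(outdir / f"{name}_y.csv", np.asarray(t), delimiter=",")
            else:
                entry["label"] = t
            manifest["examples"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_training_set(indir) -> TrainingSet:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    task = manifest["task"]
    parts = {"train": ([], []), "val": ([], [])}
    for entry in manifest["examples"]:
        x = np.loadtxt(indir / f"{entry['name']}_x.csv", delimiter=",", ndmin=2)
        ins, tgts = parts[entry["split"]]
        ins.append(x)
        if task == "regression":
            tgts.append(np.loadtxt(indir / f"{entry['name']}_y.csv", delimiter=","))
        else:
            tgts.append(entry["label"])
    fm = manifest["feature_mean"]
    fs = manifest["feature_std"]
    return TrainingSet(
        task=task,
        inputs_train=parts["train"][0],
        targets_train=parts["train"][1],
        inputs_val=parts["val"][0],
        targets_val=parts["val"][1],
        patients_train=manifest["patients_train"],
        patients_val=manifest["patients_val"],
        feature_mean=None if fm is None else np.asarray(fm),
        feature_std=None if fs is None else np.asarray(fs),
        target_mean=manifest["target_mean"],
        target_std=manifest["target_std"],
        classes=tuple(manifest["classes"]),
    )
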