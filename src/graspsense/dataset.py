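"""Build labeled per-sample datasets from simulated grasp closures.

The acquisition protocol lists how many closures to perform per object and
with which control reference (bench sinusoid or EMG-like).  Each closure is
simulated, its samples labeled by the 300 mA void rule (0 void, 1 rigid,
2 soft), and the rows concatenated into a flat table.  Splitting is done at
the closure level (80/20 by default, stratified by stiffness class) so no
closure leaks samples across splits, and the feature normalization is
fitted on the training rows only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .errors import InsufficientData, UnlabeledTrace
from .simulator import GraspTrace, StiffnessClass, simulate_closure

#: Motor-side current gate (mA) below which a sample is labeled void.
VOID_CURRENT_THRESHOLD = 300.0

FEATURE_COLUMNS = ["current_mA", "theta_ref_deg", "theta_out_deg"]
CSV_COLUMNS = FEATURE_COLUMNS + ["label", "closure_id", "split"]

#: Factor by which traces are decimated when flattened into feature rows
#: (1 kHz control rate -> 100 Hz logged rows, a typical acquisition rate).
DEFAULT_DOWNSAMPLE = 10


@dataclass(frozen=True)
class ProtocolRow:
    """One line of the acquisition plan."""

    n_closures: int
    object_name: str
    stiffness_label: str
    control_signal: str  # 'sinusoidal' or 'emg'

    def __post_init__(self) -> None:
        if self.n_closures < 1:
            raise ValueError("n_closures must be >= 1")


def load_protocol(path) -> List[ProtocolRow]:
    """Read an acquisition protocol from YAML (``protocol:`` list of rows)."""
    if hasattr(path, "read_text"):
        raw = yaml.safe_load(path.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [ProtocolRow(**row) for row in raw["protocol"]]


@dataclass(frozen=True)
class Normalization:
    """Per-feature z-scoring state (fitted on training rows only)."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalization":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalization":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


@dataclass
class LabeledDataset:
    """Flat per-sample table plus normalization state and provenance.

    ``frame`` columns: current_mA, theta_ref_deg, theta_out_deg, label,
    closure_id, split ('train' | 'validation' | 'test' | 'unassigned').
    """

    frame: pd.DataFrame
    normalization: Optional[Normalization] = None
    provenance: dict = field(default_factory=dict)

    def rows(self, split: Optional[str] = None) -> pd.DataFrame:
        if split is None:
            return self.frame
        return self.frame[self.frame["split"] == split]

    def features(self, split: Optional[str] = None) -> np.ndarray:
        return self.rows(split)[FEATURE_COLUMNS].to_numpy(float)

    def labels(self, split: Optional[str] = None) -> np.ndarray:
        return self.rows(split)["label"].to_numpy(int)

    def closure_ids(self, split: Optional[str] = None) -> np.ndarray:
        return np.unique(self.rows(split)["closure_id"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def read_csv(cls, path) -> "LabeledDataset":
        frame = pd.read_csv(path)
        ds = cls(frame=frame[CSV_COLUMNS])
        if (frame["split"] == "train").any():
            ds.normalization = Normalization.fit(ds.features("train"))
        return ds


def label_samples(
    trace: GraspTrace,
    rule: str = "per_sample",
    void_threshold: float = VOID_CURRENT_THRESHOLD,
) -> np.ndarray:
    """Per-sample stiffness labels for one closure.

    ``per_sample`` (default): a sample is void (0) whenever its motor-side
    current is below ``void_threshold`` — this also masks the pre-contact
    phase of object closures, which is physically indistinguishable from a
    void closure; at or above the gate the sample takes the object's class
    (1 rigid, 2 soft).  ``per_closure``: every sample takes the closure's
    object class regardless of current.
    """
    if trace.object_meta is None:
        raise UnlabeledTrace("trace carries no object metadata")
    obj_label = trace.object_meta.label
    if rule == "per_closure":
        return np.full(len(trace), obj_label, dtype=int)
    if rule != "per_sample":
        raise ValueError(f"unknown labeling rule: {rule!r}")
    labels = np.zeros(len(trace), dtype=int)
    if obj_label != 0:
        labels[trace.current >= void_threshold] = obj_label
    return labels


def build_protocol_dataset(
    protocol: Sequence[ProtocolRow],
    sim_config: SimConfig,
    seed: int,
    labeling: str = "per_sample",
    downsample: int = DEFAULT_DOWNSAMPLE,
) -> LabeledDataset:
    """Simulate every closure of the protocol and flatten into sample rows.

    Per-closure seeds are spawned deterministically from the master seed;
    the commanded amplitude is jittered per closure
    (sd = ``sim_config.amplitude_jitter_sd``) to emulate trial-to-trial
    variability of the operator/user command.  The returned dataset is
    unsplit (``split == 'unassigned'``) and carries no normalization yet.
    """
    protocol = list(protocol)
    if not protocol:
        raise InsufficientData("empty protocol")
    root = np.random.SeedSequence(seed)
    row_seqs = root.spawn(len(protocol))
    frames = []
    closure_id = 0
    for row, row_seq in zip(protocol, row_seqs):
        obj = sim_config.object(row.object_name)
        base_profile = sim_config.reference(row.control_signal)
        for closure_seq in row_seq.spawn(row.n_closures):
            rng = np.random.default_rng(closure_seq)
            amp = base_profile.amplitude + sim_config.amplitude_jitter_sd * rng.standard_normal()
            amp = float(np.clip(amp, 0.0, 110.0))
            profile = dataclasses.replace(
                base_profile,
                amplitude=amp,
                seed=int(closure_seq.generate_state(1)[0] % (2**31)),
            )
            trace = simulate_closure(
                sim_config.motor, sim_config.gains, obj, profile, sim_config.duration
            )
            labels = label_samples(trace, rule=labeling)
            sl = slice(None, None, max(1, int(downsample)))
            frames.append(
                pd.DataFrame(
                    {
                        "current_mA": trace.current[sl],
                        "theta_ref_deg": trace.theta_ref[sl],
                        "theta_out_deg": trace.theta_out[sl],
                        "label": labels[sl],
                        "closure_id": closure_id,
                        "split": "unassigned",
                    }
                )
            )
            closure_id += 1
    frame = pd.concat(frames, ignore_index=True)
    return LabeledDataset(
        frame=frame,
        provenance={
            "seed": int(seed),
            "n_closures": closure_id,
            "labeling": labeling,
            "downsample": int(downsample),
        },
    )


def _closure_classes(frame: pd.DataFrame) -> pd.Series:
    """Stiffness class of each closure (max label over its samples: a rigid
    closure contains void-labeled pre-contact samples, never vice versa)."""
    return frame.groupby("closure_id")["label"].max()


def split_dataset(
    ds: LabeledDataset, train_frac: float = 0.8, seed: int = 0
) -> LabeledDataset:
    """Assign closures to train/validation splits, stratified by class.

    Splitting is closure-level: all samples of a closure land in the same
    split, avoiding temporal leakage between adjacent samples.  Within each
    stiffness class ``round((1 - train_frac)·n)`` closures (at least 1) go
    to validation.  Normalization is (re)fitted on the training rows.
    """
    classes = _closure_classes(ds.frame)
    if len(classes) < 5:
        raise InsufficientData("need at least 5 closures to split")
    rng = np.random.default_rng(seed)
    split_of = {}
    for cls_label in sorted(classes.unique()):
        ids = classes.index[classes == cls_label].to_numpy()
        if len(ids) < 2:
            raise InsufficientData(
                f"class {cls_label} has {len(ids)} closure(s); need >= 2 to stratify"
            )
        ids = ids[rng.permutation(len(ids))]
        n_val = int(np.clip(round((1.0 - train_frac) * len(ids)), 1, len(ids) - 1))
        for cid in ids[:n_val]:
            split_of[cid] = "validation"
        for cid in ids[n_val:]:
            split_of[cid] = "train"
    frame = ds.frame.copy()
    frame["split"] = frame["closure_id"].map(split_of)
    out = LabeledDataset(frame=frame, provenance=dict(ds.provenance))
    out.provenance.update({"train_frac": train_frac, "split_seed": int(seed)})
    out.normalization = Normalization.fit(out.features("train"))
    return out
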