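"""Closed-loop evaluation: session protocol, F1 scoring, simulated users.

A test session presents 6 objects (3 rigid + 3 soft) three times each plus
3 void closures — 21 trials in seeded random order.  For each trial the
hand closes on the scheduled object, the classifier decides, the feedback
encoder turns the decision into a vibration command, and a *simulated
responder* (a synthetic stand-in for a human participant — no responder
parameter here is measured from people) answers with a stiffness guess and
a response time.  Per-session confusion matrices and F1 scores, aggregated
over many Monte-Carlo sessions, compare the four feedback conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import OvAClassifier, predict_closure
from .config import SimConfig
from .errors import InvalidLabel
from .feedback import (
    CONDITIONS,
    FeedbackCommand,
    VibrationCalibration,
    encode,
)
from .simulator import simulate_closure

N_CLASSES = 3


@dataclass(frozen=True)
class SessionProtocol:
    """Composition of one 21-trial test session."""

    rigid_objects: tuple = ("hand_dynam", "4xS2", "4xS3")
    soft_objects: tuple = ("4xS1", "2xS1", "2xS1-2xS4")
    presentations_per_object: int = 3
    n_void: int = 3

    @property
    def n_trials(self) -> int:
        return (
            (len(self.rigid_objects) + len(self.soft_objects))
            * self.presentations_per_object
            + self.n_void
        )


@dataclass
class TrialRecord:
    trial_index: int
    condition: str
    object_name: str
    true_class: int
    classifier_class: int
    user_answer: int
    response_time: float

    def __post_init__(self) -> None:
        if self.response_time < 0:
            raise ValueError("response_time must be >= 0")
        for v in (self.true_class, self.classifier_class, self.user_answer):
            if v not in (0, 1, 2):
                raise InvalidLabel(f"class {v} outside {{0,1,2}}")


def make_session(
    protocol: SessionProtocol, seed: int
) -> List[tuple]:
    """Seeded random trial order: list of (object_name, true_class)."""
    trials = []
    for name in protocol.rigid_objects:
        trials += [(name, 1)] * protocol.presentations_per_object
    for name in protocol.soft_objects:
        trials += [(name, 2)] * protocol.presentations_per_object
    trials += [("void", 0)] * protocol.n_void
    rng = np.random.default_rng(seed)
    return [trials[i] for i in rng.permutation(len(trials))]


def confusion(true_classes, predicted_classes) -> np.ndarray:
    """3x3 contingency table, rows = truth, columns = prediction."""
    t = np.asarray(true_classes, int)
    p = np.asarray(predicted_classes, int)
    if t.size == 0:
        raise ValueError("no records to score")
    if ((t < 0) | (t >= N_CLASSES) | (p < 0) | (p >= N_CLASSES)).any():
        raise InvalidLabel("classes must lie in {0, 1, 2}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def f1_score(cm: np.ndarray, averaging: str = "macro"):
    """F1 from a confusion matrix, in percent.

    ``per_class`` returns one value per class (NaN where the class appears
    in neither truth nor prediction); ``macro`` averages the defined
    per-class values; ``micro`` pools counts (equal to accuracy for
    single-label multi-class data).
    """
    cm = np.asarray(cm)
    if cm.sum() == 0:
        raise ValueError("cannot score an empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore"):
        per_class = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), np.nan)
    if averaging == "per_class":
        return 100.0 * per_class
    if averaging == "macro":
        return 100.0 * float(np.nanmean(per_class))
    if averaging == "micro":
        return 100.0 * float(2 * tp.sum() / (2 * tp.sum() + fp.sum() + fn.sum()))
    raise ValueError(f"unknown averaging: {averaging!r}")


def accuracy(cm: np.ndarray) -> float:
    """Fraction of correct decisions, in percent."""
    cm = np.asarray(cm)
    return 100.0 * float(np.diag(cm).sum() / cm.sum())


def chance_level(n_classes: int = 3) -> float:
    """Uniform-guessing accuracy, in percent."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 100.0 / n_classes


@dataclass
class ResponderModel:
    """Synthetic user answering from the cues each condition provides.

    NoFB: uniform guess.  AFB: motor sound reveals void vs object with
    ``afb_motion_accuracy``, rigid/soft is a coin flip.  1FB: vibration
    presence reveals the classifier's void decision exactly; rigid vs soft
    is guessed from the physical vibration-onset latency cue with
    ``onefb_onset_accuracy``.  2FB: the duty level is decoded, confusing
    rigid and soft with probability ``twofb_confusion``.  Response times
    are lognormal per condition (median seconds, sigma in log space).
    All values are invented defaults chosen to exercise the expected
    condition ordering, not to reproduce any human measurement.
    """

    afb_motion_accuracy: float = 0.9
    onefb_onset_accuracy: float = 0.6
    twofb_confusion: float = 0.05
    rt_median_s: Dict[str, float] = field(
        default_factory=lambda: {"NoFB": 3.5, "AFB": 3.7, "1FB": 4.3, "2FB": 2.8}
    )
    rt_sigma: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.afb_motion_accuracy, self.onefb_onset_accuracy, self.twofb_confusion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("responder probabilities must lie in [0, 1]")

    def answer(
        self,
        condition: str,
        true_class: int,
        command: FeedbackCommand,
        rng: np.random.Generator,
    ) -> tuple[int, float]:
        if condition == "NoFB":
            ans = int(rng.integers(0, 3))
        elif condition == "AFB":
            judged_object = (true_class != 0) == (rng.random() < self.afb_motion_accuracy)
            ans = int(rng.integers(1, 3)) if judged_object else 0
        elif condition == "1FB":
            if not command.active:
                ans = 0
            elif true_class == 0:
                # vibration on a truly void closure: onset cue is meaningless
                ans = int(rng.integers(1, 3))
            elif rng.random() < self.onefb_onset_accuracy:
                ans = true_class
            else:
                ans = 3 - true_class
        elif condition == "2FB":
            if not command.active:
                ans = 0
            else:
                decoded = command.class_encoded
                ans = 3 - decoded if rng.random() < self.twofb_confusion else decoded
        else:
            raise ValueError(f"invalid condition: {condition!r}")
        rt = float(rng.lognormal(np.log(self.rt_median_s[condition]), self.rt_sigma))
        return ans, rt


DEFAULT_CALIBRATION = VibrationCalibration(pwm_min=20.0, pwm_max=80.0)


@dataclass
class ClosurePool:
    """Pre-classified closure bank for Monte-Carlo session studies.

    Simulating and classifying every trial of hundreds of sessions repeats
    identical physics; the pool instead holds ``n_per_object`` independent
    seeded closures per object, each already run through the per-closure
    classifier, and sessions draw uniformly from it.
    """

    decisions: Dict[str, List[int]]

    @classmethod
    def generate(
        cls,
        model: OvAClassifier,
        sim_config: SimConfig,
        object_names: Sequence[str],
        n_per_object: int = 12,
        seed: int = 0,
        profile_kind: str = "emg_like",
    ) -> "ClosurePool":
        root = np.random.SeedSequence(seed)
        decisions: Dict[str, List[int]] = {}
        for name, obj_seq in zip(object_names, root.spawn(len(object_names))):
            obj = sim_config.object(name)
            base = sim_config.reference(profile_kind)
            decs = []
            for closure_seq in obj_seq.spawn(n_per_object):
                rng = np.random.default_rng(closure_seq)
                amp = base.amplitude + sim_config.amplitude_jitter_sd * rng.standard_normal()
                profile = dataclasses.replace(
                    base,
                    amplitude=float(np.clip(amp, 0.0, 110.0)),
                    seed=int(closure_seq.generate_state(1)[0] % (2**31)),
                )
                trace = simulate_closure(
                    sim_config.motor, sim_config.gains, obj, profile, sim_config.duration
                )
                decs.append(predict_closure(model, trace))
            decisions[name] = decs
        return cls(decisions=decisions)

    def draw(self, object_name: str, rng: np.random.Generator) -> int:
        decs = self.decisions[object_name]
        return decs[int(rng.integers(0, len(decs)))]


def run_closed_loop_session(
    model: OvAClassifier,
    sim_config: SimConfig,
    condition: str,
    responder: ResponderModel,
    protocol: SessionProtocol,
    seed: int,
    calibration: VibrationCalibration = DEFAULT_CALIBRATION,
    pool: Optional[ClosurePool] = None,
) -> List[TrialRecord]:
    """One full 21-trial session under one feedback condition.

    Without a pool each trial simulates a fresh closure (EMG-like
    reference); with a pool the classifier decision is drawn from the
    pre-classified bank.  Everything downstream of the decision — feedback
    encoding, responder answer, response time — is drawn per trial from the
    session's seeded generator either way.
    """
    root = np.random.SeedSequence(seed)
    order_seq, resp_seq, sim_seq = root.spawn(3)
    trials = make_session(protocol, seed=int(order_seq.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(resp_seq)
    sim_rng = np.random.default_rng(sim_seq)
    records = []
    for idx, (object_name, true_class) in enumerate(trials):
        if pool is not None:
            decision = pool.draw(object_name, sim_rng)
        else:
            obj = sim_config.object(object_name)
            base = sim_config.reference("emg_like")
            amp = base.amplitude + sim_config.amplitude_jitter_sd * sim_rng.standard_normal()
            profile = dataclasses.replace(
                base,
                amplitude=float(np.clip(amp, 0.0, 110.0)),
                seed=int(sim_rng.integers(0, 2**31)),
            )
            trace = simulate_closure(
                sim_config.motor, sim_config.gains, obj, profile, sim_config.duration
            )
            decision = predict_closure(model, trace)
        command = encode(decision, condition, calibration)
        user_answer, rt = responder.answer(condition, true_class, command, rng)
        records.append(
            TrialRecord(
                trial_index=idx,
                condition=condition,
                object_name=object_name,
                true_class=true_class,
                classifier_class=decision,
                user_answer=user_answer,
                response_time=rt,
            )
        )
    return records


def records_to_frame(records: Sequence[TrialRecord], session: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session": session,
            "trial": [r.trial_index for r in records],
            "condition": [r.condition for r in records],
            "object_name": [r.object_name for r in records],
            "true_class": [r.true_class for r in records],
            "classifier_class": [r.classifier_class for r in records],
            "user_answer": [r.user_answer for r in records],
            "response_time_s": [r.response_time for r in records],
        }
    )


def run_study(
    model: OvAClassifier,
    sim_config: SimConfig,
    responder: Optional[ResponderModel] = None,
    conditions: Sequence[str] = CONDITIONS,
    n_sessions: int = 200,
    protocol: Optional[SessionProtocol] = None,
    seed: int = 0,
    calibration: VibrationCalibration = DEFAULT_CALIBRATION,
    pool_size: int = 12,
) -> pd.DataFrame:
    """Monte-Carlo comparison of feedback conditions over many sessions.

    Builds one pre-classified closure pool (``pool_size`` closures per
    object) and runs ``n_sessions`` independent seeded sessions per
    condition.  Returns the tidy trial-level table.
    """
    responder = responder or ResponderModel()
    protocol = protocol or SessionProtocol()
    root = np.random.SeedSequence(seed)
    pool_seq, sessions_seq = root.spawn(2)
    names = list(protocol.rigid_objects) + list(protocol.soft_objects) + ["void"]
    pool = ClosurePool.generate(
        model,
        sim_config,
        names,
        n_per_object=pool_size,
        seed=int(pool_seq.generate_state(1)[0] % (2**31)),
    )
    frames = []
    session_id = 0
    for cond_seq, condition in zip(sessions_seq.spawn(len(conditions)), conditions):
        for sess_seq in cond_seq.spawn(n_sessions):
            records = run_closed_loop_session(
                model,
                sim_config,
                condition,
                responder,
                protocol,
                seed=int(sess_seq.generate_state(1)[0] % (2**31)),
                calibration=calibration,
                pool=pool,
            )
            frames.append(records_to_frame(records, session=session_id))
            session_id += 1
    return pd.concat(frames, ignore_index=True)


@dataclass
class EvaluationReport:
    """Per-condition aggregation of session-level scores."""

    per_condition: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_condition.to_csv(path)

    def to_json(self, path) -> None:
        self.per_condition.to_json(path, orient="index", indent=1)


def session_scores(frame: pd.DataFrame, answer_column: str = "user_answer") -> pd.DataFrame:
    """Macro-F1 (%), accuracy (%) and mean response time per session."""
    rows = []
    for (session, condition), grp in frame.groupby(["session", "condition"]):
        cm = confusion(grp["true_class"], grp[answer_column])
        rows.append(
            {
                "session": session,
                "condition": condition,
                "f1_macro_pct": f1_score(cm, "macro"),
                "accuracy_pct": accuracy(cm),
                "response_time_s": float(grp["response_time_s"].mean()),
            }
        )
    return pd.DataFrame(rows)


def summarize(frame: pd.DataFrame, answer_column: str = "user_answer") -> EvaluationReport:
    """Mean ± SD of session macro-F1, accuracy and response time per condition."""
    scores = session_scores(frame, answer_column)
    agg = scores.groupby("condition").agg(
        f1_macro_mean_pct=("f1_macro_pct", "mean"),
        f1_macro_sd_pct=("f1_macro_pct", "std"),
        accuracy_mean_pct=("accuracy_pct", "mean"),
        response_time_mean_s=("response_time_s", "mean"),
        response_time_sd_s=("response_time_s", "std"),
        n_sessions=("session", "nunique"),
    )
    return EvaluationReport(per_condition=agg.fillna(0.0))
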