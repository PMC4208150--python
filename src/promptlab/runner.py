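"""End-to-end orchestration: script -> stream -> classify -> smooth ->
prompt -> respond -> log -> evaluate, from one config and one master seed.

Every stage draws its randomness from a sub-seed derived by hashing the
master seed with the stage name, so a run is fully reproducible (byte-
identical log and report) from the config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ar_module, eval_stats, plm, synth_streams, user_model
from .labels import STANDING
from .synth_streams import ActivityScript, SensorStream, SignalModel


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class ExperimentConfig:
    """One experiment: which script, which classifier, which respondent."""

    name: str = "experiment"
    script: str = "task1"  # task1 | task2 | free_living | path to YAML
    task2_durations: tuple[float, ...] = (60.0,) * 10
    noiseless: bool = False
    classifier: str = "ideal"  # "ideal" (oracle labels) | "gmm"
    gmm_components: int = 2
    use_speed: bool = True
    respondent: user_model.RespondentProfile = field(
        default_factory=user_model.RespondentProfile)
    timeout: float = plm.DEFAULT_TIMEOUT
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        resp = user_model.RespondentProfile(**doc.pop("respondent", {}))
        if "task2_durations" in doc:
            doc["task2_durations"] = tuple(float(d) for d in doc["task2_durations"])
        return cls(respondent=resp, **doc)


@dataclass
class RunResult:
    """Artifacts of one protocol run."""

    script: ActivityScript
    stream: SensorStream
    window_labels: list
    states: list
    transitions: list
    prompts: list
    segments: list
    report: dict
    log_path: str | None = None
    report_path: str | None = None


def _build_script(config: ExperimentConfig) -> ActivityScript:
    if config.script == "task1":
        return synth_streams.make_task1_script()
    if config.script == "task2":
        return synth_streams.make_task2_script(config.task2_durations)
    if config.script == "free_living":
        return synth_streams.make_free_living_script(
            derive_seed(config.master_seed, "script"))
    return ActivityScript.from_yaml(config.script)


def _oracle_labels(script: ActivityScript, n_windows: int) -> list[ar_module.WindowLabel]:
    truth = synth_streams.window_truth_labels(script, n_windows)
    return [ar_module.WindowLabel(index=i, label=lbl) for i, lbl in enumerate(truth)]


def _train_default_classifier(model: SignalModel, k: int,
                              seed: int) -> ar_module.ClassifierModel:
    """Fit the mixture classifier on scripted streams generated in-process."""
    feats: dict[str, list] = {}
    for i, script in enumerate([synth_streams.make_task1_script(),
                                synth_streams.make_task2_script((60.0,) * 10)]):
        for rep in range(2):
            stream = synth_streams.synthesize_stream(script, model,
                                                     seed=seed + 10 * i + rep)
            fv, windows = ar_module.extract_features_stream(stream)
            truth = synth_streams.window_truth_labels(script, len(windows))
            boundary = synth_streams.boundary_windows(script, len(windows))
            for w, f, lbl in zip(windows, fv, truth):
                if w.index in boundary:
                    continue
                feats.setdefault(lbl, []).append(f)
    arrays = {lbl: np.array(v) for lbl, v in feats.items()}
    return ar_module.train_classifier(arrays, k=k, seed=seed)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RuntimeError):
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_protocol(config: ExperimentConfig, out_dir=None) -> RunResult:
    """Run one full protocol; optionally write the device log and JSON report.

    Deterministic for a fixed config and master seed: identical reruns
    produce byte-identical artifacts.
    """
    with _stage("script"):
        script = _build_script(config)
    with _stage("synthesize"):
        model = SignalModel.default()
        if config.noiseless:
            model = model.noiseless()
        stream = synth_streams.synthesize_stream(
            script, model, seed=derive_seed(config.master_seed, "stream"))
    with _stage("classify"):
        n_windows = stream.n_samples // ar_module.WINDOW_SAMPLES
        if config.classifier == "ideal":
            window_labels = _oracle_labels(script, n_windows)
        elif config.classifier == "gmm":
            clf = _train_default_classifier(
                model, config.gmm_components, derive_seed(config.master_seed, "train"))
            window_labels = ar_module.classify_stream(clf, stream,
                                                      use_speed=config.use_speed)
        else:
            raise ValueError(f"unknown classifier mode {config.classifier!r}")
    with _stage("smooth"):
        states = plm.smooth_detections(window_labels)
        transitions = plm.detect_transitions(states)
    with _stage("prompt"):
        observer = user_model.make_observer_log(script)
        rng = np.random.default_rng(derive_seed(config.master_seed, "respondent"))

        def responder(ev: plm.TransitionEvent):
            mid = (ev.prev_start_window + ev.prev_end_window + 1) / 2 * ar_module.WINDOW_SECONDS
            truth = observer.lookup(min(mid, observer.total_duration - 1e-9))
            return user_model.respond(ev, truth, config.respondent, rng)

        prompts = plm.run_prompt_session(transitions, responder, timeout=config.timeout)
    with _stage("segment"):
        segments = []
        for ev, pr in zip(transitions, prompts):
            seg = plm.extract_segment(stream, ev, pr)
            seg.observer_label = observer.label_for_span(seg.t[0],
                                                         seg.t[-1] + 1 / stream.sample_rate)
            segments.append(seg)
    with _stage("evaluate"):
        summary = eval_stats.summarize_prompts(prompts)["total"]
        report = {
            "name": config.name,
            "script": script.name,
            "master_seed": config.master_seed,
            "n_windows": n_windows,
            "prompts": {"delivered": summary.delivered, "missed": summary.missed,
                        "mean_latency": summary.mean_latency},
            "agreement": eval_stats.agreement_table(
                [s.ar_label for s in segments],
                [s.user_label for s in segments],
                [s.observer_label for s in segments]) if segments else {},
        }

    log_path = report_path = None
    if out_dir is not None:
        with _stage("write"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            log_path = str(out / f"{config.name}_log.txt")
            report_path = str(out / f"{config.name}_report.json")
            plm.write_log(segments, log_path)
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
    return RunResult(script=script, stream=stream, window_labels=window_labels,
                     states=states, transitions=transitions, prompts=prompts,
                     segments=segments, report=report,
                     log_path=log_path, report_path=report_path)
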