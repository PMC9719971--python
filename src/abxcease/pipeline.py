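"""End-to-end experiment orchestration: simulate -> preprocess -> train ->
estimate -> evaluate, with file artefacts, a content-hash manifest and
seeded reproducibility.  Each stage can be re-run independently from the
artefacts of the previous one, so credentialed real data can replace the
simulator at the preprocess boundary.
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
from .autoencoder import SequenceAutoencoder
from .evaluation import evaluate_estimates, report_to_frame, whatif_stop_after
from .preprocess import (
    FeatureNormalizer,
    SplitSpec,
    StayTimeline,
    build_timelines,
    compute_treatment_course,
    filter_cohort,
    oversample_positive_mortality,
    split_by_stay,
)
from .simulate import SimConfig, simulate_cohort
from .synthetic_control import SyntheticControlEstimator

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "run_stage", "STAGES"]

STAGES = ("simulate", "preprocess", "train", "estimate", "evaluate")


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    encoder_los: dict = field(default_factory=dict)
    encoder_mortality: dict = field(default_factory=dict)
    k: int = 10
    ridge_lambda: float = 1.0
    normalize_weights: bool = True
    segregate: bool = True
    donor_mode: str = "full"  # 'full' (leave-one-out over everyone) or 'test-only'
    eval_population: str = "test"
    n_boot: int = 1000
    alpha: float = 0.05
    whatif_cutoffs: tuple[int, ...] = (7,)
    seed: int = 0
    out_dir: str = "runs/experiment"

    def __post_init__(self):
        if self.donor_mode not in ("full", "test-only"):
            raise ValueError("donor_mode must be 'full' or 'test-only'")
        if self.eval_population not in ("test", "all"):
            raise ValueError("eval_population must be 'test' or 'all'")

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["whatif_cutoffs"] = list(self.whatif_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "split" in d and isinstance(d["split"], dict):
            d["split"] = SplitSpec(**d["split"])
        if "whatif_cutoffs" in d:
            d["whatif_cutoffs"] = tuple(d["whatif_cutoffs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------- utilities
def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: str, config: ExperimentConfig) -> str:
    entries = {}
    for root, _, files in os.walk(outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            entries[os.path.relpath(p, outdir)] = _sha256(p)
    manifest = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "files": entries,
    }
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def save_timelines(timelines: list[StayTimeline], split: dict[str, list[int]], outdir: str) -> None:
    rows = []
    stays = []
    for tl in timelines:
        for t in range(tl.n_days):
            row = {"stay_id": tl.stay_id, "day": t + 1, "abx": int(tl.abx_status[t])}
            for j, name in enumerate(tl.feature_names):
                row[name] = tl.features[t, j]
                row[f"miss_{name}"] = int(tl.missing_mask[t, j])
            rows.append(row)
        stays.append(
            {
                "stay_id": tl.stay_id,
                "age": tl.age_at_admission,
                "los_days": tl.los_label,
                "mortality": tl.mortality_label,
            }
        )
    # %.17g keeps doubles bit-exact through the CSV round trip
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "timelines.csv"), index=False, float_format="%.17g")
    sdf = pd.DataFrame(stays)
    assignment = {sid: name for name, ids in split.items() for sid in ids}
    sdf["split"] = sdf["stay_id"].map(assignment)
    sdf.to_csv(os.path.join(outdir, "stays.csv"), index=False, float_format="%.17g")


def load_timelines(outdir: str) -> tuple[list[StayTimeline], dict[str, list[int]]]:
    tdf = pd.read_csv(os.path.join(outdir, "timelines.csv"), float_precision="round_trip")
    sdf = pd.read_csv(os.path.join(outdir, "stays.csv"), float_precision="round_trip").set_index("stay_id")
    feat_names = [c for c in tdf.columns if c not in ("stay_id", "day", "abx") and not c.startswith("miss_")]
    out = []
    for sid, grp in tdf.groupby("stay_id", sort=True):
        grp = grp.sort_values("day")
        flags = grp["abx"].to_numpy(dtype=int)
        cum, course = compute_treatment_course(flags)
        meta = sdf.loc[int(sid)]
        out.append(
            StayTimeline(
                stay_id=int(sid),
                features=grp[feat_names].to_numpy(dtype=float),
                missing_mask=grp[[f"miss_{n}" for n in feat_names]].to_numpy(dtype=np.uint8),
                feature_names=list(feat_names),
                abx_status=flags,
                cum_treatment_len=cum,
                course=course,
                age_at_admission=float(meta["age"]),
                los_label=float(meta["los_days"]),
                mortality_label=int(meta["mortality"]),
                normalised=True,
            )
        )
    split = {
        name: sorted(int(s) for s in sdf.index[sdf["split"] == name])
        for name in ("train", "val", "test")
    }
    return out, split


# ------------------------------------------------------------------- stages
def stage_simulate(config: ExperimentConfig, outdir: str):
    cohort = simulate_cohort(config.sim)
    cohort.write(os.path.join(outdir, "cohort"), fmt="csv")
    return cohort


def stage_preprocess(config: ExperimentConfig, outdir: str, cohort=None):
    cdir = os.path.join(outdir, "cohort")
    if cohort is None:
        events = pd.read_csv(os.path.join(cdir, "events.csv"), float_precision="round_trip")
        abx = pd.read_csv(os.path.join(cdir, "abx.csv"))
        labels = pd.read_csv(os.path.join(cdir, "labels.csv"), float_precision="round_trip")
    else:
        events, abx, labels = cohort.events, cohort.abx, cohort.labels
    raw = build_timelines(events, abx, labels)
    kept, removed = filter_cohort(raw)
    split = split_by_stay([tl.stay_id for tl in kept], config.split)
    by_id = {tl.stay_id: tl for tl in kept}
    train = [by_id[s] for s in split["train"]]
    norm = FeatureNormalizer().fit(train)
    processed = norm.transform(kept)
    pdir = os.path.join(outdir, "processed")
    os.makedirs(pdir, exist_ok=True)
    save_timelines(processed, split, pdir)
    norm.save(os.path.join(pdir, "normalizer.json"))
    with open(os.path.join(pdir, "meta.json"), "w") as fh:
        json.dump(
            {"removed": removed, "n_kept": len(kept), "split_sizes": {k: len(v) for k, v in split.items()},
             "seed": config.split.seed},
            fh, indent=1,
        )
    return processed, split


def _split_lists(processed, split):
    by_id = {tl.stay_id: tl for tl in processed}
    return {name: [by_id[s] for s in ids if s in by_id] for name, ids in split.items()}


def stage_train(config: ExperimentConfig, outdir: str, processed=None, split=None):
    if processed is None:
        processed, split = load_timelines(os.path.join(outdir, "processed"))
    parts = _split_lists(processed, split)
    models = {}
    mdir = os.path.join(outdir, "models")
    os.makedirs(mdir, exist_ok=True)
    for task in ("los", "mortality"):
        overrides = config.encoder_los if task == "los" else config.encoder_mortality
        kwargs = {"task": task, "seed": config.seed + (0 if task == "los" else 1), **overrides}
        model = SequenceAutoencoder(**kwargs)
        sample_index = None
        if task == "mortality" and config.split.oversample_factor > 0:
            sample_index = oversample_positive_mortality(
                [tl.mortality_label for tl in parts["train"]], config.split.oversample_factor
            )
        model.fit(parts["train"], validation_data=parts["val"], sample_index=sample_index)
        model.save(os.path.join(mdir, f"{task}.npz"))
        with open(os.path.join(mdir, f"{task}_history.jsonl"), "w") as fh:
            for rec in model.loss_history_:
                fh.write(json.dumps(rec) + "\n")
        models[task] = model
        logger.info("trained %s model: best epoch %d, val %s %.4f",
                    task, model.best_epoch_, model.selection_metric_, model.best_val_metric_)
    return models


def stage_estimate(config: ExperimentConfig, outdir: str, processed=None, split=None, models=None):
    if processed is None:
        processed, split = load_timelines(os.path.join(outdir, "processed"))
    if models is None:
        mdir = os.path.join(outdir, "models")
        models = {t: SequenceAutoencoder.load(os.path.join(mdir, f"{t}.npz")) for t in ("los", "mortality")}
    parts = _split_lists(processed, split)
    donors = processed if config.donor_mode == "full" else parts["test"]
    subjects = parts["test"] if config.eval_population == "test" else processed
    frames = []
    for task in ("los", "mortality"):
        emb_donor = models[task].transform(donors)
        emb_subj = emb_donor if donors is subjects else models[task].transform(subjects)
        sc = SyntheticControlEstimator(
            k=config.k,
            ridge_lambda=config.ridge_lambda,
            normalize_weights=config.normalize_weights,
            segregate=config.segregate,
            outcome=task,
        ).fit(emb_donor)
        frames.append(sc.predict(emb_subj))
    estimates = pd.concat(frames, ignore_index=True)
    estimates.to_csv(os.path.join(outdir, "estimates.csv"), index=False)
    return estimates


def stage_evaluate(config: ExperimentConfig, outdir: str, processed=None, split=None, estimates=None):
    if processed is None:
        processed, split = load_timelines(os.path.join(outdir, "processed"))
    if estimates is None:
        estimates = pd.read_csv(os.path.join(outdir, "estimates.csv"), float_precision="round_trip")
        estimates["no_estimate"] = estimates["no_estimate"].astype(bool)
    courses = {tl.stay_id: tl.course for tl in processed}
    labels = pd.DataFrame(
        {
            "stay_id": [tl.stay_id for tl in processed],
            "los_days": [tl.los_label for tl in processed],
            "mortality": [tl.mortality_label for tl in processed],
        }
    )
    report = evaluate_estimates(
        estimates, labels, courses, alpha=config.alpha, n_boot=config.n_boot, seed=config.seed
    )
    whatif = {
        str(c): whatif_stop_after(estimates, labels, courses, c, alpha=config.alpha)
        for c in config.whatif_cutoffs
    }
    out = {"report": report, "whatif": whatif}
    with open(os.path.join(outdir, "eval_report.json"), "w") as fh:
        json.dump(out, fh, indent=1, default=float)
    report_to_frame(report).to_csv(os.path.join(outdir, "eval_report.csv"), index=False)
    return out


def run_experiment(config: ExperimentConfig, outdir: str | None = None) -> str:
    """Run all stages; returns the artefact directory.

    Re-running with an identical config reproduces every deterministic
    artefact bit-identically.
    """
    outdir = outdir or config.out_dir
    os.makedirs(outdir, exist_ok=True)
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    fh = logging.FileHandler(os.path.join(outdir, "run.log"))
    fh.setLevel(logging.INFO)
    root = logging.getLogger("abxcease")
    root.addHandler(fh)
    try:
        cohort = stage_simulate(config, outdir)
        processed, split = stage_preprocess(config, outdir, cohort=cohort)
        models = stage_train(config, outdir, processed=processed, split=split)
        estimates = stage_estimate(config, outdir, processed=processed, split=split, models=models)
        stage_evaluate(config, outdir, processed=processed, split=split, estimates=estimates)
    except Exception:
        with open(os.path.join(outdir, "FAILED"), "w") as f:
            f.write("experiment failed; partial artefacts retained\n")
        raise
    finally:
        root.removeHandler(fh)
        fh.close()
    _write_manifest(outdir, config)
    return outdir


def run_stage(stage: str, config: ExperimentConfig, outdir: str):
    os.makedirs(outdir, exist_ok=True)
    if stage == "simulate":
        return stage_simulate(config, outdir)
    if stage == "preprocess":
        return stage_preprocess(config, outdir)
    if stage == "train":
        return stage_train(config, outdir)
    if stage == "estimate":
        return stage_estimate(config, outdir)
    if stage == "evaluate":
        return stage_evaluate(config, outdir)
    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
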