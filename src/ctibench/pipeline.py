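"""Pipeline driver and run manifests.

A run executes the requested stages in order
simulate -> build -> split -> featurize -> train -> eval from one YAML/dict
config.  Every run writes a single manifest (toolkit version, config hash,
seeds, input digests, per-stage record counts) sufficient to reproduce it;
featurization results are cached on disk keyed by the config digest, so an
unchanged rerun hits the cache and reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dataset_builder import NegativeSamplingSpec, build_negative_set, filter_lrb, filter_rrb
from .evaluation import aggregate_reports, compute_metrics, cross_validate
from .features_compound import encode_2dfp
from .features_target import encode_physchem, fit_physchem_pca
from .io_data import InteractionRecord, write_interaction_table
from .models.train import TrainConfig, fp2d_pair_model, standardize_features, train
from .splitters import cold_split, warm_split
from .synthetic import SyntheticSpec, gen_compounds, gen_interactions, gen_targets, synthetic_property_table

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "split", "featurize", "train", "eval"],
    "simulate": {"n_compounds": 30, "n_targets": 10, "n_pairs": 150},
    "build": {"negatives": False, "filter": None, "k_ratio": 2.5},
    "split": {"scenario": "warm-compound", "n_folds": 5},
    "train": {"lr": 0.01, "momentum": 0.9, "batch_size": 32, "epochs": 30},
}

_SCENARIOS = {"warm-compound", "warm-target", "cold-compound", "cold-target"}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    merged = {**DEFAULT_CONFIG, **(config or {})}
    unknown = set(merged) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section in ("simulate", "build", "split", "train"):
        base = DEFAULT_CONFIG[section]
        merged[section] = {**base, **(merged.get(section) or {})}
        bad = set(merged[section]) - set(base)
        if bad:
            raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
    if merged["split"]["scenario"] not in _SCENARIOS:
        raise ConfigError(
            f"unknown scenario {merged['split']['scenario']!r}; choose from {sorted(_SCENARIOS)}"
        )
    return merged


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages and write artifacts + one manifest."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(version=__version__, config_hash=config_hash(config), seed=seed)
    stages = config["stages"]

    sim = config["simulate"]
    spec = SyntheticSpec(
        n_compounds=sim["n_compounds"],
        n_targets=sim["n_targets"],
        n_pairs=sim["n_pairs"],
        seed=seed,
    )
    compounds = gen_compounds(spec.n_compounds, seed=seed)
    targets = gen_targets(spec.n_targets, length_range=spec.length_range, seed=seed)
    records = gen_interactions(compounds, targets, spec)
    manifest.stage_counts["simulate"] = len(records)
    if "simulate" in stages:
        table = out / "interactions.tsv"
        write_interaction_table(records, table)
        manifest.input_digests["interactions.tsv"] = file_digest(table)

    if "build" in stages:
        build = config["build"]
        if build["negatives"]:
            positives = [r for r in records if r.label == 1]
            all_cmpds = sorted({(r.compound_id, r.smiles) for r in records})
            negs = build_negative_set(
                positives, all_cmpds, NegativeSamplingSpec(k_ratio=build["k_ratio"])
            )
            records = positives + negs
        if build["filter"] == "lrb":
            records = filter_lrb(records)
        elif build["filter"] == "rrb":
            records = filter_rrb(records)
        manifest.stage_counts["build"] = len(records)

    split_cfg = config["split"]
    entity = "compound" if "compound" in split_cfg["scenario"] else "target"
    if split_cfg["scenario"].startswith("warm"):
        assignment = warm_split(records, entity, split_cfg["n_folds"], seed=seed)
    else:
        assignment = cold_split(records, entity, split_cfg["n_folds"])
    if "split" in stages:
        np.savetxt(
            out / "folds.tsv",
            np.column_stack([np.arange(len(records)), assignment.fold_of]),
            fmt="%d",
            delimiter="\t",
            header="record_index\tfold",
            comments="",
        )
        (out / "folds.json").write_text(
            json.dumps(
                {
                    "scenario": assignment.scenario.value,
                    "n_folds": assignment.n_folds,
                    "seed": assignment.seed,
                    "capacity": assignment.capacity,
                },
                indent=2,
            )
        )
    manifest.stage_counts["split"] = len(records)

    reports_agg: dict = {}
    if {"featurize", "train", "eval"} & set(stages):
        cache = out / f"features-{manifest.config_hash}.npz"
        if cache.exists():
            data = np.load(cache)
            xc, xt, y = data["xc"], data["xt"], data["y"]
        else:
            fps = {r.compound_id: encode_2dfp(r.smiles).vector for r in records}
            table = synthetic_property_table(seed=seed)
            projection = fit_physchem_pca(table)
            tmats: dict[str, np.ndarray] = {}
            for r in records:
                if r.target_id not in tmats:
                    m = encode_physchem(r.sequence, projection)
                    body = m.matrix[: m.true_length]
                    tmats[r.target_id] = np.concatenate(
                        [body.mean(axis=0), body.max(axis=0)]
                    )
            xc = standardize_features(np.stack([fps[r.compound_id] for r in records]))
            xt = standardize_features(np.stack([tmats[r.target_id] for r in records]))
            y = np.array([r.label for r in records], dtype=np.int64)
            np.savez(cache, xc=xc, xt=xt, y=y)
        manifest.stage_counts["featurize"] = len(y)
        manifest.input_digests["feature_cache"] = file_digest(cache)

        if "train" in stages or "eval" in stages:
            tcfg = config["train"]
            train_config = TrainConfig(
                lr=tcfg["lr"],
                momentum=tcfg["momentum"],
                batch_size=tcfg["batch_size"],
                epochs=tcfg["epochs"],
                seed=seed,
            )
            if "eval" in stages:
                reports, agg, flagged = cross_validate(
                    xc,
                    xt,
                    y,
                    assignment.fold_of,
                    model_factory=lambda fold: fp2d_pair_model(
                        xt.shape[1], seed=seed + fold
                    ),
                    train_fn=train,
                    train_config=train_config,
                )
                reports_agg = {
                    "per_fold": [r.as_dict() for r in reports],
                    "aggregate": {k: {"mean": m, "sd": s} for k, (m, s) in agg.items()},
                    "flagged_folds": flagged,
                }
                (out / "eval.json").write_text(json.dumps(reports_agg, indent=2))
            else:
                model = fp2d_pair_model(xt.shape[1], seed=seed)
                history = train(model, xc, xt, y, train_config)
                reports_agg = {"final_train_loss": history["loss"][-1] if history["loss"] else None}
            manifest.metrics = reports_agg

    manifest.write(out / "manifest.json")
    return manifest
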