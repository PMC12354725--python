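"""End-to-end orchestration: validate → impute → features → split → fit →
evaluate, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import ReactionRecord
from .dataset_io import Dialect, read_dataset, validate_dataset
from .errors import ConfigError
from .evaluation import binarize_yield, regression_metrics, stratified_split
from .linear import fit_mlr, forward_stepwise, expert_guided_selection, predict
from .pto import FeatureRecipe, SCHEMES, assemble_features, published_recipe
from .preprocess import impute_group_mean
from .preprocess import restore_catalyst_variable


@dataclass
class RunConfig:
    dataset_path: str
    out_dir: str
    dialect_path: str | None = None
    scheme_id: str = "PTML3"
    recipe_id: str = "eq6"  # built-in recipe id, or a JSON recipe file path
    fit_population: str = "all"  # "all" | "train"
    threshold: float = 79.0
    max_steps: int = 10
    enter_p: float = 0.05
    forced_terms: list[str] = dc_field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def _resolve_recipe(recipe_id: str) -> FeatureRecipe:
    if recipe_id in ("eq5", "eq6"):
        return published_recipe(recipe_id)
    path = Path(recipe_id)
    if not path.exists():
        raise ConfigError(f"recipe {recipe_id!r}: not a built-in id or existing file")
    return FeatureRecipe.from_json(path.read_text())


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest.  A stage failure raises
    with the failing stage named; artifacts written so far are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(config.dataset_path).exists():
        raise ConfigError(f"dataset {config.dataset_path!r} does not exist")
    if config.scheme_id not in SCHEMES:
        raise ConfigError(f"unknown scheme {config.scheme_id!r}")
    recipe = _resolve_recipe(config.recipe_id)

    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    current = {"name": None}

    def stage(name):
        current["name"] = name
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **extra}

        return done

    try:
        done = stage("read")
        dialect = Dialect.from_json(config.dialect_path) if config.dialect_path else None
        records, descriptors, variables = read_dataset(config.dataset_path, dialect)
        done(records=len(records))

        done = stage("validate")
        report = validate_dataset(records, descriptors, variables)
        (out / "validation.json").write_text(report.to_json())
        done(findings=len(report.findings))

        done = stage("impute")
        records, log = impute_group_mean(records, "catalyst_quantity")
        restore_catalyst_variable(records, variables)
        done(imputed=len(log))

        done = stage("split")
        records = stratified_split(records)
        done(
            train=sum(r.split_label == "t" for r in records),
            validation=sum(r.split_label == "v" for r in records),
        )

        done = stage("features")
        train_ids = [r.reaction_id for r in records if r.split_label == "t"]
        fit_pop = None if config.fit_population == "all" else train_ids
        features = assemble_features(
            records, descriptors, variables, config.scheme_id, recipe, fit_population=fit_pop
        )
        features.to_csv(out / "features.csv")
        done(rows=len(features), terms=len(recipe.terms))

        done = stage("fit")
        yields = pd.Series(
            {r.reaction_id: r.yield_pct for r in records}, name="yield"
        )
        train_feat = features.loc[train_ids]
        selected = forward_stepwise(
            train_feat, yields.loc[train_ids], config.max_steps, config.enter_p
        )
        selected = expert_guided_selection(
            selected, config.forced_terms, known_terms=list(features.columns)
        )
        model, diag = fit_mlr(train_feat, yields.loc[train_ids], terms=selected or None)
        (out / "model.json").write_text(model.to_json())
        done(selected=selected, R_train=diag.R)

        done = stage("evaluate")
        metrics = {}
        for name, ids in (("train", train_ids), ("test", [r.reaction_id for r in records if r.split_label == "v"])):
            if not ids:
                continue
            pred = predict(model, features.loc[ids])
            rep = regression_metrics(
                yields.loc[ids], pred, threshold=config.threshold, subset=name
            )
            metrics[name] = rep.to_dict()
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
        done(**{k: round(v["R"], 4) for k, v in metrics.items() if v.get("R") is not None})
    except Exception as exc:
        manifest["failed_stage"] = current["name"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        exc.add_note(f"pipeline stage {current['name']!r} failed")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
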