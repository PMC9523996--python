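"""Configuration assembly: YAML file + CLI flag overrides → PipelineConfig.

Unknown keys are rejected so typos fail loudly. Flags always win over
file values. The position/per-tree-bootstrap invariant is enforced
here: an explicit ``per_tree_bootstrap`` that contradicts the bootstrap
position is a configuration error, not a silent override.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .elimination import EliminationConfig
from .errors import ConfigurationError
from .importance import ForestConfig
from .pipeline import PipelineConfig
from .resampling import BootstrapPosition, BootstrapSpec

__all__ = ["parse_config", "write_manifest"]

_KNOWN_KEYS = {
    "position", "per_tree_bootstrap", "runs", "trees", "criterion",
    "min_samples_leaf", "max_features_per_split", "threshold", "rfe_target",
    "rfe_step", "cv_folds", "C", "max_iterations", "tolerance",
    "classifiers", "evaluate_on", "seed",
}


def _merge(file_values: Mapping[str, Any], flags: Mapping[str, Any]) -> dict:
    merged = dict(file_values)
    for key, value in flags.items():
        if value is not None:
            merged[key] = value
    return merged


def parse_config(
    config_path: str | Path | None = None, **flags: Any
) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file and flags.

    With no file and no flags, the defaults materialize: 20 runs,
    100-tree entropy forest with min_samples_leaf=100, logistic RFE
    estimator (C=0.05, 100 iterations, tol 1e-4), 10 CV folds.
    """
    file_values: dict[str, Any] = {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must hold a mapping")
        file_values = loaded
    merged = _merge(file_values, flags)
    unknown = set(merged) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {sorted(unknown)}"
        )
    try:
        position = BootstrapPosition.parse(str(merged.get("position", "outer")))
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from None

    seed = int(merged.get("seed", 0))
    per_tree = position.per_tree_bootstrap
    if "per_tree_bootstrap" in merged:
        explicit = bool(merged["per_tree_bootstrap"])
        if explicit != per_tree:
            raise ConfigurationError(
                f"per_tree_bootstrap={explicit} contradicts position="
                f"{position.value}: inner/outer_inner require per-tree "
                f"resampling on, outer/none require it off"
            )

    target: int | str = merged.get("rfe_target", "cv")
    if isinstance(target, str) and target != "cv":
        try:
            target = int(target)
        except ValueError:
            raise ConfigurationError(
                f"rfe_target must be 'cv' or an integer, got {target!r}"
            ) from None

    classifiers = merged.get("classifiers", ("lr", "svm", "rf", "bagging"))
    if isinstance(classifiers, str):
        classifiers = tuple(c.strip() for c in classifiers.split(",") if c.strip())

    try:
        forest = ForestConfig(
            n_trees=int(merged.get("trees", 100)),
            criterion=str(merged.get("criterion", "entropy")),
            min_samples_leaf=int(merged.get("min_samples_leaf", 100)),
            per_tree_bootstrap=per_tree,
            max_features_per_split=merged.get("max_features_per_split", "sqrt"),
            seed=seed,
        )
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from None
    elimination = EliminationConfig(
        C=float(merged.get("C", 0.05)),
        max_iterations=int(merged.get("max_iterations", 100)),
        tolerance=float(merged.get("tolerance", 1e-4)),
        step=merged.get("rfe_step"),
        target_size=target,
        cv_folds=int(merged.get("cv_folds", 10)),
        seed=seed,
    )
    return PipelineConfig(
        bootstrap=BootstrapSpec(position=position, seed=seed),
        forest=forest,
        elimination=elimination,
        n_runs=int(merged.get("runs", 20)),
        classifiers=tuple(classifiers),
        threshold_rule=str(merged.get("threshold", "mean")),
        evaluate_on=str(merged.get("evaluate_on", "original")),
        master_seed=seed,
    )


def config_as_dict(config: PipelineConfig) -> dict:
    return {
        "position": config.bootstrap.position.value,
        "seed": config.master_seed,
        "runs": config.n_runs,
        "trees": config.forest.n_trees,
        "criterion": config.forest.criterion,
        "min_samples_leaf": config.forest.min_samples_leaf,
        "per_tree_bootstrap": config.forest.per_tree_bootstrap,
        "max_features_per_split": config.forest.max_features_per_split,
        "threshold": config.threshold_rule,
        "C": config.elimination.C,
        "max_iterations": config.elimination.max_iterations,
        "tolerance": config.elimination.tolerance,
        "rfe_step": config.elimination.step,
        "rfe_target": config.elimination.target_size,
        "cv_folds": config.elimination.cv_folds,
        "classifiers": list(config.classifiers),
        "evaluate_on": config.evaluate_on,
    }


def write_manifest(
    out_dir: str | Path,
    config: PipelineConfig,
    input_path: str | Path | None,
    timings: Mapping[str, float],
) -> Path:
    """Write a replayable run manifest (config echo, version, input digest)."""
    from . import __version__

    out_dir = Path(out_dir)
    digest = None
    if input_path is not None:
        digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
    manifest = {
        "tool_version": __version__,
        "config": config_as_dict(config),
        "input_file": str(input_path) if input_path else None,
        "input_sha256": digest,
        "timings_s": dict(timings),
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(path)  # atomic on POSIX
    config_echo = out_dir / "config.yaml"
    config_echo.write_text(yaml.safe_dump(config_as_dict(config)))
    return path
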