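"""Experiment configuration schema, run manifests, and the end-to-end runner.

A run config is a flat YAML/JSON mapping with three groups of keys::

    data:   either {kind: synthetic, <SynthSpec fields>} or
            {kind: files, combo: ..., ppi: ..., targets: ..., mono: ..., smiles: ...}
    split:  {mode: uniform|weak, n_weak: int, fractions: [tr, va, te]}
    model:  {variant: <name>} and/or explicit SimVec parameters
    seed:   one integer driving every source of randomness

``run_experiment`` executes build -> split -> train -> eval and writes a
manifest (config snapshot, seeds, realized split statistics, metrics) plus the
evaluation report under the run directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem_features import morgan_profiles
from .estimator import SimVec, variant_params
from .kg_store import load_kg, uniform_split, weak_nodes_split
from .synthetic_data import SynthSpec, generate, profiles_from_features

_SYNTH_KEYS = set(SynthSpec.__dataclass_fields__)
_SPLIT_KEYS = {"mode", "n_weak", "fractions"}
_MODEL_KEYS = {"variant"} | set(SimVec().get_params())


class ConfigError(ValueError):
    pass


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text) or {}


def validate_config(cfg: dict) -> dict:
    """Normalize and check a config mapping; raises ConfigError naming bad keys."""
    bad = set(cfg) - {"data", "split", "model", "seed", "out_dir"}
    if bad:
        raise ConfigError(f"unknown top-level keys: {sorted(bad)}")
    data = dict(cfg.get("data") or {"kind": "synthetic"})
    kind = data.pop("kind", "synthetic")
    if kind == "synthetic":
        bad = set(data) - _SYNTH_KEYS
    elif kind == "files":
        bad = set(data) - {"combo", "ppi", "targets", "mono", "smiles"}
    else:
        raise ConfigError(f"data.kind must be 'synthetic' or 'files', got {kind!r}")
    if bad:
        raise ConfigError(f"unknown data keys: {sorted(bad)}")
    split = dict(cfg.get("split") or {})
    if bad := set(split) - _SPLIT_KEYS:
        raise ConfigError(f"unknown split keys: {sorted(bad)}")
    if split.get("mode", "weak") not in ("weak", "uniform"):
        raise ConfigError("split.mode must be 'weak' or 'uniform'")
    model = dict(cfg.get("model") or {})
    if bad := set(model) - _MODEL_KEYS:
        raise ConfigError(f"unknown model keys: {sorted(bad)}")
    return {
        "data": {"kind": kind, **data},
        "split": {"mode": split.get("mode", "weak"),
                  "n_weak": split.get("n_weak", 10),
                  "fractions": tuple(split.get("fractions", (0.8, 0.1, 0.1)))},
        "model": model,
        "seed": int(cfg.get("seed", 0)),
        "out_dir": cfg.get("out_dir"),
    }


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def build_inputs(cfg: dict) -> tuple:
    """Deterministically rebuild (kg, profiles, digests) from a validated config."""
    digests = {}
    if cfg["data"]["kind"] == "synthetic":
        spec = SynthSpec(**{**{k: v for k, v in cfg["data"].items() if k != "kind"},
                            "seed": cfg["seed"]})
        tables = generate(spec)
        kg = load_kg(tables.combo, tables.ppi, tables.targets, tables.mono)
        profiles = profiles_from_features(kg, tables.features)
    else:
        paths = {k: cfg["data"].get(k) for k in ("combo", "ppi", "targets", "mono", "smiles")}
        digests = {k: _file_digest(Path(p)) for k, p in paths.items() if p}
        kg = load_kg(paths["combo"], paths["ppi"], paths["targets"], paths["mono"],
                     smiles_table=paths["smiles"])
        smiles = {e.entity_id: e.smiles for e in kg.entities if e.kind == "drug"}
        profiles = morgan_profiles(smiles) if any(smiles.values()) else None
    return kg, profiles, digests


def build_split(cfg: dict, kg):
    if cfg["split"]["mode"] == "weak":
        return weak_nodes_split(kg, cfg["split"]["n_weak"], seed=cfg["seed"])
    return uniform_split(kg, cfg["split"]["fractions"], seed=cfg["seed"])


def run_experiment(config, out_dir: str | Path | None = None) -> dict:
    """Execute a full build -> split -> train -> eval run from one config."""
    cfg = validate_config(load_config(config))
    seed = cfg["seed"]
    out_dir = Path(out_dir or cfg["out_dir"] or "runs/run")
    out_dir.mkdir(parents=True, exist_ok=True)

    kg, profiles, digests = build_inputs(cfg)
    if cfg["split"]["mode"] == "weak":
        split = weak_nodes_split(kg, cfg["split"]["n_weak"], seed=seed)
    else:
        split = uniform_split(kg, cfg["split"]["fractions"], seed=seed)

    params = dict(cfg["model"])
    variant = params.pop("variant", None)
    if variant:
        params = {**variant_params(variant), **params}
    est = SimVec(random_state=seed, **params).fit(kg, split, profiles)
    report = est.evaluate(split.test, seed=seed)

    manifest = {
        "package_version": __version__,
        "config": {**cfg, "model": {**cfg["model"]}},
        "variant": variant,
        "seed": seed,
        "input_digests": digests,
        "split_stats": {
            "n_weak_drugs": split.n_weak_drugs,
            "n_weak_triples": split.n_weak_triples,
            "train": len(split.train), "valid": len(split.valid), "test": len(split.test),
        },
        "metrics": report.as_dict(),
        "n_epochs": len(est.history_),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    pd.DataFrame(
        [{"relation": r, **m} for r, m in report.per_relation.items()]
    ).to_csv(out_dir / "eval_report.tsv", sep="\t", index=False)
    split.save(out_dir / "split")
    est.model_.save(out_dir / "model.npz")
    return manifest
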