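"""Run configuration: YAML schema, defaults, and deterministic seed fan-out."""

from __future__ import annotations

import hashlib

import yaml


class ConfigError(ValueError):
    pass


def derive_seed(master: int, name: str) -> int:
    """Stable per-component seed from the global seed and a component name.

    Hash-based fan-out means toggling one stage never reshuffles the
    randomness of the others.  Always < 2**31.
    """
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


DEFAULTS: dict = {
    "seed": 0,
    "outdir": "runs/default",
    "synth": {
        "sentences": {"train": 800, "dev": 100, "test": 200},
        "corruption_rate": 0.1,
    },
    "kge": {
        "dim": 64,
        "gamma": 1.0,
        "norm_order": 2,
        "epochs": 200,
        "lr": 0.01,
        "batch_size": 64,
        "negatives": 1,
    },
    "encoder": {
        "layers": 2,
        "heads": 2,
        "dim": 64,
        "ff_dim": 128,
        "max_len": 512,
        "dropout": 0.1,
    },
    "features": {
        "feature_dim": 32,
        "use_features": True,
    },
    "fusion": {
        "unlinked": "placeholder",
        "finetune_kg": False,
    },
    "labeler": {
        "hidden": 256,
        "bilstm_layers": 2,
        "dropout": 0.5,
        "constrain_decoding": False,
    },
    "training": {
        "batch_size": 16,
        "lr": 1.0e-4,
        "epochs": 100,
    },
}

_EXTRA_KEYS = {
    "synth": {"entities_per_type", "triples_per_relation", "surface_len_probs",
              "type_alphabet_size", "type_alphabet_stride",
              "distractor_alphabet_size", "entities_per_sentence",
              "distractor_run", "max_sentence_len", "type_map"},
    "kge": {"filtered_negatives"},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults and key not in _EXTRA_KEYS.get(path, set()):
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(val, dict) and isinstance(defaults.get(key), dict) and path == "":
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML run config; unknown keys are rejected."""
    user: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("top-level config must be a mapping")
    cfg = _merge(DEFAULTS, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, allow_unicode=True, sort_keys=True)
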