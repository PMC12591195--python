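"""Flat key-value run configuration with dotted namespaces.

The experiment config file is plain text, one ``key = value`` per line,
``#`` comments allowed.  Keys are validated against a fixed schema — unknown
keys are rejected — and the effective config (defaults merged with the
file) is what every CLI run echoes to its log before computing anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["RunConfig", "SCHEMA", "parse_config_file"]


def _int_list(s: str) -> list[int]:
    return [int(v) for v in str(s).replace(",", " ").split()]


def _str_list(s: str) -> list[str]:
    return [v for v in str(s).replace(",", " ").split() if v]


# key -> (parser, default)
SCHEMA: dict[str, tuple[Any, Any]] = {
    "seed": (int, 0),
    "uma.n1": (int, 2),
    "uma.n2": (int, 2),
    "uma.d": (int, 4),
    "uma.ssim_window": (int, 11),
    "uma.ssim_sigma": (float, 1.5),
    "model.stage_depths": (_int_list, [1, 1]),
    "model.stage_channels": (_int_list, [8, 16]),
    "model.memory_channels": (_int_list, [4, 4]),
    "model.num_classes": (int, 2),
    "model.j": (int, 2),
    "model.ffn_ratio": (float, 4.0),
    "model.loss_mode": (str, "memory_head"),
    "model.memory_loss_weight": (float, 0.5),
    "train.epochs": (int, 30),
    "train.batch_size": (int, 8),
    "train.learning_rate": (float, 3e-3),
    "train.weight_decay": (float, 0.01),
    "train.augmentations": (_str_list, []),
    "train.prior_policy": (str, "recompute_after_augment"),
    "data.size": (int, 32),
    "data.classes": (int, 2),
    "data.per_class": (int, 32),
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        merged = {k: default for k, (_, default) in SCHEMA.items()}
        for k, v in self.values.items():
            if k not in SCHEMA:
                raise ValueError(f"unknown config key {k!r}")
            merged[k] = v
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def snapshot(self) -> dict[str, Any]:
        return dict(self.values)


def parse_config_file(path) -> RunConfig:
    raw: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in SCHEMA:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        parser, _ = SCHEMA[key]
        raw[key] = parser(value)
    return RunConfig(raw)
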