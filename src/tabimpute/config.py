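"""Run configuration: a YAML file merged with command-line overrides.

Every CLI command echoes the effective configuration into a provenance JSON
in its output directory, which is sufficient to re-run the command
bit-identically.  All seeds are explicit; nothing is seeded from the clock.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .imputation import ImputerSpec
from .tabular_io import DEFAULT_MISSING_TOKENS


@dataclass
class RunConfig:
    input: str | None = None
    output_dir: str = "tabimpute_out"
    missing_tokens: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_MISSING_TOKENS)
    )
    type_hints: dict[str, str] = field(default_factory=dict)
    delimiter: str | None = None

    # imputer
    method: str = "boosted"
    imputer_params: dict = field(default_factory=dict)
    init: str = "mean"
    seed: int = 0

    # evaluation
    rates: list[float] = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 10)])
    n_replicates: int = 10
    eval_methods: list[str] = field(default_factory=lambda: ["mean", "boosted"])
    base_seed: int = 0

    # exploration
    embedding: str = "pca"
    embedding_params: dict = field(default_factory=dict)
    k: int | None = None
    k_min: int = 1
    k_max: int = 9

    # modeling
    response: str | None = None
    predictor: str = "penalized_linear"
    ranking_method: str = "lasso"
    top_n: int | None = None
    n_folds: int = 5

    def imputer_spec(self) -> ImputerSpec:
        return ImputerSpec(self.method, dict(self.imputer_params), self.init)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None, overrides: dict) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus CLI overrides
    (override values of ``None`` are ignored)."""
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig(**data)


def write_provenance(config: RunConfig, out_dir: Path, command: str, extra: dict | None = None) -> None:
    from . import __version__

    payload = {
        "tool": "tabimpute",
        "version": __version__,
        "command": command,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
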