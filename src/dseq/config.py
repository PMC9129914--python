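"""Layered run configuration with per-parameter provenance.

Parameters resolve as shipped defaults < config file < command-line flags,
and every resolved parameter records where its value came from.  Each CLI
run writes the resolved configuration (the "config echo") as JSON next to
its outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

__all__ = ["load_defaults", "RunConfig", "setup_logging"]

_DEFAULTS_CACHE: dict | None = None


def load_defaults() -> dict:
    """The versioned defaults file shipped with the package (includes the
    published per-class score cutoffs)."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        text = resources.files("dseq").joinpath("defaults.json").read_text()
        _DEFAULTS_CACHE = json.loads(text)
    return json.loads(json.dumps(_DEFAULTS_CACHE))  # defensive copy


@dataclass
class RunConfig:
    """Merged parameter set with provenance (default | file | flag)."""

    params: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    output_prefix: str = "dseq"

    @classmethod
    def build(cls, *, defaults: Mapping[str, Any] | None = None,
              config_file: str | None = None,
              flags: Mapping[str, Any] | None = None,
              seed: int | None = None,
              output_prefix: str = "dseq") -> "RunConfig":
        cfg = cls(seed=seed, output_prefix=output_prefix)
        for k, v in (defaults if defaults is not None else load_defaults()).items():
            cfg._set(k, v, "default")
        if config_file:
            with open(config_file) as fh:
                for k, v in json.load(fh).items():
                    cfg._set(k, v, "file")
        for k, v in (flags or {}).items():
            if v is not None:
                cfg._set(k, v, "flag")
        return cfg

    def _set(self, key: str, value: Any, source: str) -> None:
        self.params[key] = value
        self.provenance[key] = source

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)

    def echo(self, path: str) -> None:
        """Write the resolved configuration and provenance as JSON."""
        payload = {
            "seed": self.seed,
            "output_prefix": self.output_prefix,
            "params": self.params,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")

    def log_parameters(self, logger: logging.Logger) -> None:
        for k in sorted(self.params):
            logger.info("param %s = %r (%s)", k, self.params[k],
                        self.provenance[k])


def setup_logging(log_path: str | None = None,
                  level: int = logging.INFO) -> logging.Logger:
    logger = logging.getLogger("dseq")
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if log_path:
        fh = logging.FileHandler(log_path, mode="w")
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger
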