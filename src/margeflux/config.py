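"""Run configuration: a small versioned YAML schema with strict keys.

Unknown keys are errors so parameter-name typos cannot silently fall
back to defaults.  Numeric defaults follow the package's standard
settings: u_min 0.001, epsilon 0.1, growth fractions 0.8, deviation
tolerance tau 0.5, activation fraction phi 0.01, 10,000 permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .exo import DEFAULT_PHI, DEFAULT_TAU
from .solver import MargeParams

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "model", "expression", "exomet", "out_dir", "verbosity",
             "marge", "exo", "reporter"}
_MARGE_KEYS = {"u_min", "epsilon", "step2_tol", "growth_frac_a", "growth_frac_b",
               "total_flux_budget", "unit_ratio_for_unmeasured", "ratio_method"}
_EXO_KEYS = {"tau", "phi"}
_REPORTER_KEYS = {"n_perm", "seed"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    model: str | None = None
    expression: str | None = None
    exomet: str | None = None
    out_dir: str = "."
    verbosity: str = "info"
    marge: MargeParams = field(default_factory=MargeParams)
    tau: float = DEFAULT_TAU
    phi: float = DEFAULT_PHI
    n_perm: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model": self.model,
            "expression": self.expression,
            "exomet": self.exomet,
            "out_dir": self.out_dir,
            "verbosity": self.verbosity,
            "marge": self.marge.to_dict(),
            "exo": {"tau": self.tau, "phi": self.phi},
            "reporter": {"n_perm": self.n_perm, "seed": self.seed},
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        cfg = cls()
        for key in ("model", "expression", "exomet", "out_dir", "verbosity"):
            if d.get(key) is not None:
                setattr(cfg, key, d[key])
        marge_block = dict(d.get("marge") or {})
        unknown = set(marge_block) - _MARGE_KEYS
        if unknown:
            raise ConfigError(f"unknown marge keys: {sorted(unknown)}")
        if "step2_tol" in marge_block:  # printed-call alias for epsilon
            marge_block["epsilon"] = marge_block.pop("step2_tol")
        cfg.marge = MargeParams(**{**MargeParams().to_dict(), **marge_block})
        exo_block = dict(d.get("exo") or {})
        unknown = set(exo_block) - _EXO_KEYS
        if unknown:
            raise ConfigError(f"unknown exo keys: {sorted(unknown)}")
        cfg.tau = float(exo_block.get("tau", cfg.tau))
        cfg.phi = float(exo_block.get("phi", cfg.phi))
        rep_block = dict(d.get("reporter") or {})
        unknown = set(rep_block) - _REPORTER_KEYS
        if unknown:
            raise ConfigError(f"unknown reporter keys: {sorted(unknown)}")
        cfg.n_perm = int(rep_block.get("n_perm", cfg.n_perm))
        cfg.seed = int(rep_block.get("seed", cfg.seed))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(data)
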