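"""Layered run configuration: built-in defaults < config file < CLI flags.

Every numeric default mirrors the threshold its module documents (activity
cut-offs, screen thresholds, solver hyperparameters, evaluation and
sensitivity cut-offs), so a run with no configuration reproduces the
standard analysis conditions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any, Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # activity standardization (µM unless noted)
    ic50_active_um: float = 10.0
    ki_active_um: float = 5.0
    pki_active: float = 5.0
    min_confidence: int = 9
    # structure screen
    p_cut: float = 2.0e-3
    score_cut: float = -7.5
    imputed_value: float = 1.0
    confidence_weight: float = 0.5
    uniform_imputation_value: float = 0.1
    # solver
    rank: int = 100
    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 0.1
    w_obs: float = 1.0
    w_imp: float = 0.5
    w_zero: float = 0.01
    max_iter: int = 500
    tol: float = 1.0e-6
    seed: int = 42
    # evaluation
    truth_pct_control: float = 30.0
    top_fraction: float = 0.025
    # sensitivity analysis
    sensitive_min_aa: float = 1.95
    resistant_max_aa: float = 1.3
    q_cut: float = 1.0e-3
    extra: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: Optional[str] = None, **overrides: Any) -> "RunConfig":
        """Defaults overlaid with a YAML file, then keyword overrides."""
        values: dict[str, Any] = {}
        if path:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must hold a mapping")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        extra = {k: values.pop(k) for k in list(values) if k not in known}
        cfg = cls(**values)
        cfg.extra = extra
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d.pop("extra", None)
        return yaml.safe_dump(d, sort_keys=True)
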