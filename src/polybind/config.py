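"""Experiment configuration: flat key-value files with dotted section keys.

Config files are plain text, one ``key = value`` per line, ``#`` comments
allowed.  Values are parsed as int, float, bool or string.  CLI flags
override file keys.  A fixed master seed makes the full run reproducible;
per-role child seeds (wiring, each test trial, each training presentation)
are derived with a counter scheme so adding trials never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "ExperimentConfig",
    "two_layer_defaults",
    "two_layer_reduced",
    "four_layer_defaults",
    "child_seed",
]

# seed roles for the counter scheme
ROLE_WIRING = 0
ROLE_TEST = 1
ROLE_TRAIN = 2


def child_seed(master_seed: int, role: int, index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), int(role), int(index)))


def two_layer_defaults() -> dict:
    """The published two-layer polychronization experiment."""
    return {
        "architecture.model": "two_layer",
        "architecture.n_per_layer": 1000,
        "architecture.p_input_l1": 0.2,
        "architecture.p_l1_l2": 0.02,
        "architecture.input_delay_low_ms": 1.0,
        "architecture.input_delay_high_ms": 10.0,
        "architecture.l2_delay_low_ms": 1.0,
        "architecture.l2_delay_high_ms": 30.0,
        "architecture.uniform_l2_delay_ms": "",  # set (e.g. 1.0) for control
        "plasticity.alpha_c": 0.5,
        "plasticity.alpha_d": 0.5,
        "plasticity.tau_c_ms": 100.0,
        "plasticity.tau_d_ms": 150.0,
        "plasticity.rho": 0.1,
        "plasticity.stdp_enabled": True,
        "stimulus.rate_hz": 50.0,
        "stimulus.duration_ms": 200.0,
        "schedule.n_pretest": 10,
        "schedule.n_training": 10,
        "schedule.n_posttest": 10,
        "integration.dt_ms": 0.02,
        "seed": 1,
    }


def two_layer_reduced(n_per_layer: int = 300, dt_ms: float = 0.1) -> dict:
    """Reduced desk-scale configuration: 300 neurons per layer, dt = 0.1 ms,
    all other conditions identical to the published experiment."""
    cfg = two_layer_defaults()
    cfg["architecture.n_per_layer"] = n_per_layer
    cfg["integration.dt_ms"] = dt_ms
    return cfg


def four_layer_defaults(scale: float = 0.25) -> dict:
    """Scaled four-layer ventral-stream experiment (scale 1.0 = published
    64 x 64 grids; 0.25 = 16 x 16 desk default)."""
    return {
        "architecture.model": "four_layer",
        "architecture.scale": scale,
        "architecture.include_fb": True,
        "architecture.include_lat": True,
        "architecture.m_contacts": 1,
        "plasticity.alpha_c": 0.5,
        "plasticity.alpha_d": 0.5,
        "plasticity.tau_c_ms": 5.0,
        "plasticity.tau_d_ms": 5.0,
        "plasticity.rho": 0.1,
        "plasticity.stdp_enabled": True,
        "stimulus.labels": "circle,heart,star",
        "stimulus.max_rate_hz": 100.0,
        "stimulus.duration_ms": 200.0,
        "schedule.n_training_sweeps": 50,
        "schedule.n_test_transforms": 10,
        "schedule.pretest": True,
        "analysis.n_rate_bins": 10,
        "integration.dt_ms": 0.1,
        "seed": 1,
    }


class ExperimentConfig(dict):
    """A validated flat configuration (dotted keys -> typed values)."""

    @classmethod
    def from_defaults(cls, defaults: dict, overrides: dict | None = None
                      ) -> "ExperimentConfig":
        cfg = cls(defaults)
        if overrides:
            for key, value in overrides.items():
                if key not in cfg:
                    raise KeyError(f"unknown config key: {key!r}")
                cfg[key] = _coerce_like(cfg[key], value)
        cfg._validate()
        return cfg

    @classmethod
    def from_file(cls, path, defaults: dict) -> "ExperimentConfig":
        overrides = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            overrides[key.strip()] = value.strip()
        return cls.from_defaults(defaults, overrides)

    def _validate(self) -> None:
        for key, value in self.items():
            if key.startswith("schedule.") and int(value) < 0:
                raise ValueError(f"{key} must be >= 0")
        if float(self["integration.dt_ms"]) <= 0:
            raise ValueError("integration.dt_ms must be positive")

    def write(self, path) -> None:
        with Path(path).open("w") as fh:
            for key in sorted(self):
                fh.write(f"{key} = {self[key]}\n")


def _coerce_like(template, raw):
    if isinstance(raw, str):
        raw = raw.strip()
        if isinstance(template, bool):
            if raw.lower() in ("true", "1", "yes", "on"):
                return True
            if raw.lower() in ("false", "0", "no", "off"):
                return False
            raise ValueError(f"cannot parse boolean from {raw!r}")
        if isinstance(template, int) and not isinstance(template, bool):
            return int(raw)
        if isinstance(template, float):
            return float(raw)
        return raw
    return raw
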