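"""YAML configuration loading for simulations.

A config file has (all sections optional, defaults as in the modules):

.. code-block:: yaml

    population:
      mode: marginal-independent      # or joint-fixture
      proportions: {rural: 0.59, ...} # marginal mode
      fixture: {correlation: 0.2, size: 100000}
    rewards:
      call_success: {intercept: -0.25, magnitude_main: 0.5}
    policies:
      enabled: [cyclic, single_best, oracle, lin_ts]
      lin_ts: {v: 0.5, ridge: 1.0}
    simulation:
      horizon: 3000
      replications: 100
      master_seed: 0
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .engine import POLICIES, RunConfig

__all__ = ["load_config", "run_config_from_dict"]


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML config file into a plain dictionary."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def run_config_from_dict(
    raw: dict[str, Any], dataset_mode: str, outcome: str
) -> RunConfig:
    """Build a :class:`RunConfig` for one scenario from a parsed config."""
    sim = raw.get("simulation", {})
    pol = raw.get("policies", {})
    ts = pol.get("lin_ts", {})
    fixture = raw.get("population", {}).get("fixture", {})
    return RunConfig(
        dataset_mode=dataset_mode,
        outcome=outcome,
        horizon=int(sim.get("horizon", 3000)),
        replications=int(sim.get("replications", 100)),
        master_seed=int(sim.get("master_seed", 0)),
        policies=tuple(pol.get("enabled", POLICIES)),
        ts_v=(None if ts.get("v") is None else float(ts["v"])),
        ts_ridge=float(ts.get("ridge", 1.0)),
        fixture_size=int(fixture.get("size", 100_000)),
        latent_correlation=float(fixture.get("correlation", 0.2)),
        fixture_seed=int(fixture.get("seed", 0)),
        model_seed=int(raw.get("rewards", {}).get("seed", 0)),
    )
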