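"""Configuration files, result tables, run manifests and test fixtures."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import DGPConfig, config_from_dict, config_to_dict
from .cohort_sim import Cohort, generate_cohort
from .exceptions import ConfigError

logger = logging.getLogger("ciesim")

FLOAT_FORMAT = "%.10g"


def load_config(path: Union[str, Path], kind: Optional[str] = None):
    """Load and validate a YAML or JSON config file.

    The config type is taken from an explicit ``kind`` key or inferred from
    the fields; defaults are filled by the dataclass; unknown keys are
    rejected with a message naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(data, kind=kind)


def save_config(config, path: Union[str, Path]) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_results(records, path: Union[str, Path], format: Optional[str] = None):
    """Write result records as long-format CSV or JSON.

    ``records`` is a DataFrame or a list of dicts.  Floats are written with
    10 significant digits so a read-back reproduces values to ~1e-9
    relative.  An empty record list yields a header-only CSV.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", double_precision=10, indent=1))
    else:
        raise ConfigError(f"unknown results format {fmt!r}")
    logger.info("wrote %d records to %s", len(df), path)
    return path


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config: dict
    root_seed: int
    child_seeds: Dict[str, int] = field(default_factory=dict)
    version: str = __version__
    runtimes: Dict[str, float] = field(default_factory=dict)
    dropped: Dict[str, int] = field(default_factory=dict)
    _t0: Dict[str, float] = field(default_factory=dict, repr=False)

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.runtimes[stage] = time.perf_counter() - self._t0.pop(stage)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        if stage not in self.child_seeds:
            idx = len(self.child_seeds)
            ss = np.random.SeedSequence(entropy=self.root_seed, spawn_key=(idx,))
            self.child_seeds[stage] = int(ss.generate_state(1)[0] % (2**31))
        return self.child_seeds[stage]

    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            "config": self.config,
            "root_seed": self.root_seed,
            "child_seeds": self.child_seeds,
            "version": self.version,
            "runtimes": self.runtimes,
            "dropped": self.dropped,
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            config=data["config"], root_seed=data["root_seed"],
            child_seeds=data.get("child_seeds", {}), version=data.get("version", ""),
            runtimes=data.get("runtimes", {}), dropped=data.get("dropped", {}),
        )


def make_fixtures(seed: int = 90210) -> Dict[str, Cohort]:
    """Small deterministic cohorts for tests and examples.

    One n=200 cohort per outcome family under a moderately confounded,
    error-contaminated DGP, plus degenerate sets (zero-variance covariate;
    single-class binary outcome) for error-path tests.
    """
    fixtures: Dict[str, Cohort] = {}
    for i, family in enumerate(("binary", "continuous", "survival")):
        cfg = DGPConfig(
            n=200, outcome_family=family, beta=0.1, gamma=0.1, rho=0.4,
            err_var_x=0.25, err_var_z=1.0, seed=seed + i,
        )
        fixtures[family] = generate_cohort(cfg)

    base = fixtures["continuous"]
    fixtures["zero_variance_covariate"] = Cohort(
        x_true=base.x_true, z_true=np.zeros(base.n),
        x_obs=base.x_obs, z_obs=np.zeros(base.n),
        outcome=base.outcome, family="continuous", config=None,
    )
    binary = fixtures["binary"]
    fixtures["single_class_outcome"] = Cohort(
        x_true=binary.x_true, z_true=binary.z_true,
        x_obs=binary.x_obs, z_obs=binary.z_obs,
        outcome=np.zeros(binary.n), family="binary", config=None,
    )
    return fixtures
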