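"""Configuration dataclasses for the simulators, calibration and planning.

All stochastic components of the package are parameterized through these
objects.  Each carries an integer ``seed``; everything downstream derives
child streams from it via :class:`numpy.random.SeedSequence`, so a config
uniquely determines every simulated number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Optional, Sequence

from .exceptions import ConfigError, InvalidParameterError

FAMILIES = ("binary", "continuous", "survival")

#: Strategy labels for the five empirical confounder-identification rules:
#: significance of the covariate at p<=0.05 / p<=0.20, the fixed 10 %
#: change-in-estimate rule, and the two simulation-calibrated CIE rules.
STRATEGIES = ("p05", "p20", "cie10", "cie_sim_type1", "cie_sim_type2")

DEFAULT_BINARY_INTERCEPT = math.log(1.0 / 9.0)  # 10 % baseline prevalence


@dataclass
class DGPConfig:
    """Data-generating process for one synthetic cohort study.

    The exposure X and confounder Z are standard bivariate normal with
    correlation ``rho``; observed versions carry classical additive error
    with variances ``err_var_x`` / ``err_var_z``; the outcome follows
    g(Y) = intercept + beta*X + gamma*Z for the configured family.
    """

    n: int
    outcome_family: str
    beta: float = 0.1
    gamma: float = 0.1
    rho: float = 0.0
    err_var_x: float = 0.0
    err_var_z: float = 0.0
    intercept: float = DEFAULT_BINARY_INTERCEPT
    resid_var_y: float = 1.0
    censor_time: float = 0.1
    #: exponential parameter reading for the survival recipe: the shifted
    #: linear predictor is the distribution's "mean" or "rate".
    survival_param: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_family not in FAMILIES:
            raise InvalidParameterError(
                f"outcome_family must be one of {FAMILIES}, got {self.outcome_family!r}"
            )
        if self.n < 10:
            raise InvalidParameterError(f"n must be >= 10, got {self.n}")
        if not abs(self.rho) < 1:
            raise InvalidParameterError(f"|rho| must be < 1, got {self.rho}")
        if self.err_var_x < 0:
            raise InvalidParameterError(f"err_var_x must be >= 0, got {self.err_var_x}")
        if self.err_var_z < 0:
            raise InvalidParameterError(f"err_var_z must be >= 0, got {self.err_var_z}")
        if self.resid_var_y <= 0:
            raise InvalidParameterError(f"resid_var_y must be > 0, got {self.resid_var_y}")
        if self.censor_time <= 0:
            raise InvalidParameterError(f"censor_time must be > 0, got {self.censor_time}")
        if self.survival_param not in ("mean", "rate"):
            raise InvalidParameterError(
                f"survival_param must be 'mean' or 'rate', got {self.survival_param!r}"
            )

    def replace(self, **kwargs) -> "DGPConfig":
        d = asdict(self)
        d.update(kwargs)
        return DGPConfig(**d)


@dataclass
class CutoffSpec:
    """Specification of one simulated CIE cutoff calibration.

    ``error_type`` selects the null calibration (type1: adjustment for an
    independent pseudo-confounder) or the alternative calibration (type2:
    adjustment for the mis-measured confounder under the assumed
    confounded structure).  ``level`` is the target error rate: the type-I
    cutoff is the (1-level) quantile of the null deltas, the type-II
    cutoff the level quantile of the alternative deltas.
    """

    error_type: str = "type1"
    level: float = 0.05
    replicates: int = 10_000
    mode: str = "design"
    alt_structure: Optional[DGPConfig] = None

    def __post_init__(self) -> None:
        if self.error_type not in ("type1", "type2"):
            raise InvalidParameterError(f"error_type must be type1|type2, got {self.error_type!r}")
        if not 0 < self.level < 1:
            raise InvalidParameterError(f"level must be in (0,1), got {self.level}")
        if self.replicates < 100:
            raise InvalidParameterError(f"replicates must be >= 100, got {self.replicates}")
        if self.mode not in ("design", "data"):
            raise InvalidParameterError(f"mode must be design|data, got {self.mode!r}")


@dataclass
class EvalConfig:
    """One cell of the Monte Carlo strategy-comparison study."""

    dgp: DGPConfig
    n_reps: int = 10_000
    strategies: Sequence[str] = STRATEGIES
    calib_reps: int = 10_000
    screen_alpha: float = 0.05
    theta_true: Optional[float] = None
    oracle_n: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 100:
            raise InvalidParameterError(f"n_reps must be >= 100, got {self.n_reps}")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise InvalidParameterError(f"unknown strategies: {sorted(unknown)}")
        if not 0 < self.screen_alpha < 1:
            raise InvalidParameterError(f"screen_alpha must be in (0,1), got {self.screen_alpha}")
        if self.theta_true is not None and not math.isfinite(self.theta_true):
            raise InvalidParameterError("theta_true must be finite")


@dataclass
class PlanningConfig:
    """Study-planning scenario: how well must a confounder be measured?

    Emulates a cohort in which a latent confounder F (fish intake in the
    motivating application) drives both the exposure E (blood mercury,
    assumed error-free) and a dichotomized latent outcome D (depression),
    while the analyst can only adjust for W = F + noise.
    """

    n_study: int = 6911
    rho_FE: float = 0.39
    rho_FD: float = -0.35
    direct_effect: float = 0.0
    outcome_prevalence: float = 0.2295
    noise_grid: Sequence[float] = (0.10, 0.25, 0.50, 0.55, 0.60, 1.00, 10.0)
    reps: int = 10_000
    fixed_study: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_study < 10:
            raise InvalidParameterError(f"n_study must be >= 10, got {self.n_study}")
        for name in ("rho_FE", "rho_FD"):
            if not abs(getattr(self, name)) < 1:
                raise InvalidParameterError(f"|{name}| must be < 1")
        if not 0 < self.outcome_prevalence < 1:
            raise InvalidParameterError("outcome_prevalence must be in (0,1)")
        if any(s2 < 0 for s2 in self.noise_grid):
            raise InvalidParameterError("noise-to-signal ratios must be >= 0")
        if self.reps < 10:
            raise InvalidParameterError(f"reps must be >= 10, got {self.reps}")


_CONFIG_TYPES = {
    "dgp": DGPConfig,
    "eval": EvalConfig,
    "planning": PlanningConfig,
    "cutoff": CutoffSpec,
}


def config_from_dict(data: dict, kind: Optional[str] = None):
    """Build a validated config object from a plain mapping.

    The mapping may carry an explicit ``kind`` key (dgp | eval | planning |
    cutoff); otherwise the type is inferred from the field names.  Unknown
    keys are rejected with a message naming the offender.
    """
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping, got {type(data).__name__}")
    data = dict(data)
    declared = data.pop("kind", None)
    if kind is not None and declared is not None and kind != declared:
        raise ConfigError(f"config declares kind {declared!r} but {kind!r} was requested")
    kind = kind or declared
    if kind is None:
        if "outcome_family" in data:
            kind = "dgp"
        elif "dgp" in data:
            kind = "eval"
        elif "noise_grid" in data or "rho_FE" in data:
            kind = "planning"
        elif "error_type" in data:
            kind = "cutoff"
        else:
            raise ConfigError(
                "cannot infer config type; supply a 'kind' key "
                "(dgp | eval | planning | cutoff)"
            )
    if kind not in _CONFIG_TYPES:
        raise ConfigError(f"unknown config kind {kind!r}")
    cls = _CONFIG_TYPES[kind]
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) for {kind} config: {sorted(unknown)}")
    if kind == "eval" and isinstance(data.get("dgp"), dict):
        data["dgp"] = config_from_dict(data["dgp"], kind="dgp")
    if kind == "cutoff" and isinstance(data.get("alt_structure"), dict):
        data["alt_structure"] = config_from_dict(data["alt_structure"], kind="dgp")
    try:
        return cls(**data)
    except TypeError as exc:  # missing required field
        raise ConfigError(str(exc)) from exc


def config_to_dict(config) -> dict:
    """Serialize a config object to a plain dict with its ``kind`` tag."""
    for kind, cls in _CONFIG_TYPES.items():
        if isinstance(config, cls):
            d = asdict(config)
            d["kind"] = kind
            if kind == "eval":
                d["dgp"].pop("kind", None)
                d["strategies"] = list(d["strategies"])
            if kind == "planning":
                d["noise_grid"] = list(d["noise_grid"])
            return d
    raise ConfigError(f"not a config object: {type(config).__name__}")
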