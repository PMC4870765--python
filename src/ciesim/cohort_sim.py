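"""Synthetic cohort generation under confounding and classical measurement error.

A cohort consists of a standard-bivariate-normal exposure/confounder pair
(X, Z) with correlation rho, their error-contaminated observations
X* = X + eps_x and Z* = Z + eps_z (classical additive error, independent
of everything else), and an outcome generated from the true variables:

* binary      Y ~ Bernoulli(expit(alpha + beta*X + gamma*Z))
* continuous  Y = beta*X + gamma*Z + eps_y,  eps_y ~ N(0, resid_var_y)
* survival    exponential event times driven by the linear predictor
              L = beta*X + gamma*Z shifted to be non-negative within the
              cohort, administratively censored at ``censor_time``.

Classical error attenuates the observed exposure-confounder correlation to
rho / sqrt((1+sigma_x^2)(1+sigma_z^2)), which is what makes a truly
confounded covariate hard to recognise with fixed change-in-estimate rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DGPConfig, config_from_dict, config_to_dict
from .exceptions import InvalidParameterError, UnsupportedFamilyError

RandomSource = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _as_generator(rng: RandomSource) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class Cohort:
    """One simulated study: true and observed covariates plus outcome."""

    x_true: np.ndarray
    z_true: np.ndarray
    x_obs: np.ndarray
    z_obs: np.ndarray
    outcome: np.ndarray          # y, or column-stacked (time, event)
    family: str
    config: Optional[DGPConfig] = None

    @property
    def n(self) -> int:
        return len(self.x_true)

    @property
    def y(self) -> np.ndarray:
        if self.family == "survival":
            raise AttributeError("survival outcome is (time, event); use .time/.event")
        return self.outcome

    @property
    def time(self) -> np.ndarray:
        return self.outcome[:, 0]

    @property
    def event(self) -> np.ndarray:
        return self.outcome[:, 1]

    @property
    def event_fraction(self) -> float:
        """Realized event (or case) fraction, reported as cohort metadata."""
        if self.family == "survival":
            return float(self.event.mean())
        if self.family == "binary":
            return float(self.outcome.mean())
        return float("nan")

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "x_true": self.x_true,
            "z_true": self.z_true,
            "x_obs": self.x_obs,
            "z_obs": self.z_obs,
        }
        if self.family == "survival":
            cols["time"] = self.time
            cols["event"] = self.event
        else:
            cols["y"] = self.outcome
        return pd.DataFrame(cols)

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the cohort as CSV with a JSON sidecar carrying the config."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        if self.config is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            sidecar.write_text(json.dumps(config_to_dict(self.config), indent=2))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Cohort":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        config = None
        if sidecar.exists():
            config = config_from_dict(json.loads(sidecar.read_text()))
        if "time" in df.columns:
            family = "survival"
            outcome = np.column_stack([df["time"].to_numpy(), df["event"].to_numpy()])
        else:
            family = config.outcome_family if config is not None else "continuous"
            if family == "survival":
                family = "continuous"
            outcome = df["y"].to_numpy()
            if set(np.unique(outcome)) <= {0.0, 1.0}:
                family = "binary" if config is None else family
        return cls(
            x_true=df["x_true"].to_numpy(),
            z_true=df["z_true"].to_numpy(),
            x_obs=df["x_obs"].to_numpy(),
            z_obs=df["z_obs"].to_numpy(),
            outcome=outcome,
            family=family,
            config=config,
        )


def draw_confounded_pair(
    n: int, rho: float, rng: RandomSource = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw (X, Z) jointly Gaussian with N(0,1) marginals and correlation rho."""
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    if not abs(rho) < 1:
        raise InvalidParameterError(f"|rho| must be < 1, got {rho}")
    g = _as_generator(rng)
    x = g.standard_normal(n)
    z = rho * x + np.sqrt(1.0 - rho * rho) * g.standard_normal(n)
    return x, z


def add_classical_error(
    v: np.ndarray, err_var: float, rng: RandomSource = None
) -> np.ndarray:
    """Return v + eps with eps ~ N(0, err_var), independent of v."""
    if err_var < 0:
        raise InvalidParameterError(f"err_var must be >= 0, got {err_var}")
    v = np.asarray(v, dtype=float)
    if err_var == 0:
        return v.copy()
    g = _as_generator(rng)
    return v + g.normal(0.0, np.sqrt(err_var), size=v.shape)


def generate_outcome(
    x: np.ndarray, z: np.ndarray, config: DGPConfig, rng: RandomSource = None
) -> np.ndarray:
    """Generate the outcome for the configured family from true X and Z."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise InvalidParameterError("x and z must have the same length")
    g = _as_generator(rng)
    lp = config.beta * x + config.gamma * z
    family = config.outcome_family
    if family == "binary":
        p = expit(config.intercept + lp)
        return (g.random(len(x)) < p).astype(float)
    if family == "continuous":
        return lp + g.normal(0.0, np.sqrt(config.resid_var_y), size=len(x))
    if family == "survival":
        shifted = lp - lp.min()
        e = g.exponential(1.0, size=len(x))
        if config.survival_param == "mean":
            # shifted predictor is the exponential mean; a zero mean gives an
            # immediate event for the subject attaining the cohort minimum
            t_raw = shifted * e
        else:
            # shifted predictor is the rate; zero rate => infinite time, censored
            with np.errstate(divide="ignore"):
                t_raw = np.where(shifted > 0, e / np.where(shifted > 0, shifted, 1.0), np.inf)
        event = (t_raw <= config.censor_time).astype(float)
        time = np.minimum(t_raw, config.censor_time)
        return np.column_stack([time, event])
    raise UnsupportedFamilyError(f"unknown outcome family {family!r}")


def generate_cohort(config: DGPConfig, seed: Optional[int] = None) -> Cohort:
    """Generate a full cohort reproducibly from ``config.seed`` (or ``seed``).

    Four child RNG streams (pair, eps_x, eps_z, outcome noise) are derived
    from the root seed so that, e.g., switching an error variance on or off
    does not perturb any of the other draws.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_pair, s_ex, s_ez, s_out = root.spawn(4)
    x, z = draw_confounded_pair(config.n, config.rho, s_pair)
    x_obs = add_classical_error(x, config.err_var_x, s_ex)
    z_obs = add_classical_error(z, config.err_var_z, s_ez)
    outcome = generate_outcome(x, z, config, s_out)
    return Cohort(
        x_true=x, z_true=z, x_obs=x_obs, z_obs=z_obs,
        outcome=outcome, family=config.outcome_family, config=config,
    )


def attenuated_correlation(rho: float, err_var_x: float, err_var_z: float) -> float:
    """Closed-form observed correlation rho/sqrt((1+sx2)(1+sz2))."""
    return rho / np.sqrt((1.0 + err_var_x) * (1.0 + err_var_z))
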