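"""Generative models for ordinal outcomes under confounded binary treatment.

The generator draws a single continuous confounder ``Z ~ U(0, 1)``, assigns a
binary treatment ``X`` with probability ``tau_i = Z_i`` (scenario 1) or
``tau_i = Z_i**2`` (scenario 2), and draws an ordinal outcome ``Y`` in
``1..J`` from a proportional-odds cumulative-logit model

    logit P(Y_i <= j) = alpha_j - (beta * X_i + gamma * Z_i)        (scenario 1)
    logit P(Y_i <= j) = alpha_j - (beta * X_i + gamma * Z_i**2)     (scenario 2)

Sign convention
---------------
The linear predictor enters with a *minus* sign, as in mainstream
proportional-odds implementations: positive ``beta`` (or ``gamma``) shifts
probability mass toward *higher* outcome categories.  Because treatment
probability increases with Z in both scenarios, positive ``gamma`` induces
positive (upward) confounding on the unadjusted treatment estimate.

Thresholds ``alpha_j`` are derived from a baseline category-probability
vector so that at zero linear predictor the outcome has exactly those
marginal probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

__all__ = [
    "DEFAULT_BASELINE_PROBS",
    "SimulationDesign",
    "OrdinalDataset",
    "derive_intercepts",
    "category_probs",
    "assign_treatment",
    "simulate_dataset",
    "load_grid_config",
]

#: Symmetric 5-category baseline used throughout the simulation study.
DEFAULT_BASELINE_PROBS: tuple[float, ...] = (0.15, 0.20, 0.30, 0.20, 0.15)

_PROB_TOL = 1e-12


def _validate_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("baseline_probs must be a 1-d vector of length >= 2")
    if np.any(p <= 0):
        raise ValueError("baseline_probs entries must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"baseline_probs must sum to 1, got {p.sum()!r}")
    # renormalise away float dust so downstream cumulative sums end at 1
    return p / p.sum()


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation grid.

    Parameters
    ----------
    scenario : {1, 2}
        1 = linear confounder (correct specification for a linear-in-Z
        analysis model); 2 = quadratic confounder in both the treatment
        and the outcome model (misspecified for a linear-in-Z analysis).
    n : int
        Sample size per replicate.
    beta : float
        Treatment-to-outcome log odds ratio (the estimand).
    gamma : float
        Confounder-to-outcome strength.
    n_categories : int
        Number of outcome categories J (default 5).
    baseline_probs : sequence of float
        Marginal category probabilities at zero linear predictor.
    seed : int or None
        Root seed for this design; ``None`` draws fresh OS entropy.
    """

    scenario: int
    n: int
    beta: float
    gamma: float
    n_categories: int = 5
    baseline_probs: tuple[float, ...] = DEFAULT_BASELINE_PROBS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        p = _validate_probs(self.baseline_probs)
        if p.size != self.n_categories:
            raise ValueError(
                "baseline_probs length must equal n_categories "
                f"({p.size} != {self.n_categories})"
            )
        object.__setattr__(self, "baseline_probs", tuple(float(v) for v in p))

    @property
    def intercepts(self) -> np.ndarray:
        """Thresholds alpha_1..alpha_{J-1} implied by ``baseline_probs``."""
        return derive_intercepts(self.baseline_probs)


@dataclass
class OrdinalDataset:
    """Unit records: ordinal outcome, binary treatment, one confounder."""

    y: np.ndarray
    x: np.ndarray
    z: np.ndarray
    sampling_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.x = np.asarray(self.x, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        n = self.y.size
        if not (self.x.size == n and self.z.size == n):
            raise ValueError("y, x, z must have the same length")
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("x must be binary 0/1")
        if self.y.min() < 1:
            raise ValueError("y labels must start at 1")
        if self.sampling_weight is None:
            self.sampling_weight = np.ones(n)
        else:
            self.sampling_weight = np.asarray(self.sampling_weight, dtype=float)
            if self.sampling_weight.size != n:
                raise ValueError("sampling_weight length mismatch")
            if np.any(self.sampling_weight <= 0):
                raise ValueError("sampling weights must be positive")

    def __len__(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y": self.y, "x": self.x, "z": self.z,
             "sampling_weight": self.sampling_weight}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrdinalDataset":
        w = df["sampling_weight"].to_numpy() if "sampling_weight" in df else None
        return cls(df["y"].to_numpy(), df["x"].to_numpy(),
                   df["z"].to_numpy(), w)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "OrdinalDataset":
        return cls.from_frame(pd.read_csv(path))


def derive_intercepts(baseline_probs: Sequence[float]) -> np.ndarray:
    """Thresholds alpha_j = logit(p_1 + ... + p_j), j = 1..J-1.

    At zero linear predictor the cumulative-logit model with these
    thresholds reproduces ``baseline_probs`` exactly; for a symmetric
    probability vector the thresholds are antisymmetric.
    """
    p = _validate_probs(baseline_probs)
    cum = np.cumsum(p)[:-1]
    alpha = logit(cum)
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("derived thresholds are not strictly increasing")
    return alpha


def category_probs(intercepts: Sequence[float], linear_predictor) -> np.ndarray:
    """Category probabilities at a given linear predictor.

    ``P(Y = j) = sigmoid(alpha_j - eta) - sigmoid(alpha_{j-1} - eta)`` with
    the conventions ``sigmoid(alpha_0 - eta) = 0`` and
    ``sigmoid(alpha_J - eta) = 1``.  Broadcasts over ``linear_predictor``;
    the returned array has one trailing axis of length J.
    """
    alpha = np.asarray(intercepts, dtype=float)
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("intercepts must be strictly increasing")
    eta = np.asarray(linear_predictor, dtype=float)
    cum = expit(alpha - eta[..., None])
    shape = eta.shape + (1,)
    full = np.concatenate(
        [np.zeros(shape), cum, np.ones(shape)], axis=-1
    )
    return np.diff(full, axis=-1)


def _treatment_prob(z: np.ndarray, scenario: int) -> np.ndarray:
    return z if scenario == 1 else z**2


def assign_treatment(
    z: Sequence[float], scenario: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw X_i ~ Bernoulli(tau_i) with tau_i = Z_i (1) or Z_i^2 (2)."""
    z = np.asarray(z, dtype=float)
    if np.any((z < 0) | (z > 1)):
        raise ValueError("z must lie in [0, 1]")
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tau = _treatment_prob(z, scenario)
    return (rng.random(z.size) < tau).astype(int)


def simulate_dataset(design: SimulationDesign) -> OrdinalDataset:
    """Simulate one dataset from a design cell.

    Uses three independent sub-streams (Z, X, Y) spawned from the design
    seed, so the three draws are separately reproducible; the contract is
    reproducibility at fixed ``(design, seed)``, not prefix stability
    across different ``n``.
    """
    ss = np.random.SeedSequence(design.seed)
    rng_z, rng_x, rng_y = (np.random.default_rng(s) for s in ss.spawn(3))
    z = rng_z.random(design.n)
    x = assign_treatment(z, design.scenario, rng_x)
    z_out = _treatment_prob(z, design.scenario)  # confounder term in the outcome
    eta = design.beta * x + design.gamma * z_out
    alpha = design.intercepts
    cum = expit(alpha[None, :] - eta[:, None])
    u = rng_y.random(design.n)
    y = (u[:, None] > cum).sum(axis=1) + 1  # inverse-CDF draw
    return OrdinalDataset(y=y, x=x, z=z)


def load_grid_config(path: str | Path) -> dict:
    """Read a simulation-grid config (YAML or JSON).

    Expected keys: ``scenario``, ``n``, ``beta``, ``gamma`` (scalars or
    lists, crossed into a full grid), optional ``n_categories``,
    ``baseline_probs``, and run-level ``K`` and ``seed``.  Returns a dict
    with ``designs`` (list of :class:`SimulationDesign`, unseeded), ``K``
    and ``seed``.
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)

    def as_list(key, default=None):
        v = cfg.get(key, default)
        if v is None:
            raise ValueError(f"grid config missing required key {key!r}")
        return v if isinstance(v, (list, tuple)) else [v]

    extra = {}
    if "n_categories" in cfg:
        extra["n_categories"] = int(cfg["n_categories"])
    if "baseline_probs" in cfg:
        extra["baseline_probs"] = tuple(cfg["baseline_probs"])
    designs = [
        SimulationDesign(scenario=int(s), n=int(n), beta=float(b),
                         gamma=float(g), **extra)
        for s in as_list("scenario")
        for n in as_list("n")
        for b in as_list("beta")
        for g in as_list("gamma")
    ]
    return {
        "designs": designs,
        "K": int(cfg.get("K", 1000)),
        "seed": cfg.get("seed"),
    }
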