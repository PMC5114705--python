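"""Presence-only maximum-entropy niche model.

The model assigns each landscape cell x a Gibbs probability mass

    q(x) = exp(lambda . f(x)) / Z,      Z = sum_background exp(lambda . f(b)),

with features f built from the environmental variables (linear, quadratic,
pairwise-product and hinge classes on background-scaled values).  The
coefficients maximize the L1-penalized mean presence log-mass

    l(lambda) = (1/m) sum_i lambda . f(x_i) - ln Z(lambda)
                - sum_j beta_j |lambda_j|,

a concave objective whose penalty weights beta_j = r * s_j / sqrt(m) grow
with the presence-sample spread of each feature and shrink with sample
size.  The optimum is found by splitting lambda into non-negative parts and
running a quasi-Newton solver; first-order (subgradient) optimality is
verified before the model is accepted.

Outputs: raw mass q (sums to 1 over the background), the logistic
suitability s = q e^H / (1 + q e^H) in (0, 1) — where H is the entropy of
the fitted distribution, so a cell of "typical" suitability scores 0.5 —
and the training gain, the mean log improvement of q over the uniform
baseline.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "FeatureConfig",
    "FeatureExpansion",
    "MaxentModel",
    "ConvergenceError",
    "fit_maxent",
]

DEFAULT_CLASSES = ("linear", "quadratic", "product", "hinge")
_KNOWN_CLASSES = frozenset(DEFAULT_CLASSES)


class ConvergenceError(RuntimeError):
    """Solver failed the first-order optimality contract."""

    def __init__(self, message: str, last_objective: float | None = None):
        super().__init__(message)
        self.last_objective = last_objective


@dataclass(frozen=True)
class FeatureConfig:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    hinge_knots: int = 5

    def __post_init__(self) -> None:
        unknown = set(self.classes) - _KNOWN_CLASSES
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")


@dataclass
class FeatureExpansion:
    """Deterministic mapping from raw environment rows to feature rows.

    Scaling bounds and hinge knots are frozen from the background sample at
    construction time, so projecting onto new layers reuses the training
    frame of reference (with optional clamping to [0, 1]).
    """

    variables: list[str]
    config: FeatureConfig
    lo: np.ndarray  # per-variable background minimum
    hi: np.ndarray  # per-variable background maximum
    knots: list[np.ndarray]  # per-variable hinge knots in scaled (0,1) space
    feature_names: list[str] = field(default_factory=list)
    feature_classes: list[str] = field(default_factory=list)

    @classmethod
    def from_background(
        cls,
        env: np.ndarray,
        variables: Sequence[str],
        config: FeatureConfig = FeatureConfig(),
    ) -> "FeatureExpansion":
        env = np.asarray(env, float)
        lo = env.min(axis=0)
        hi = env.max(axis=0)
        keep = hi > lo
        dropped = [v for v, k in zip(variables, keep) if not k]
        if dropped:
            import warnings

            warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        variables = [v for v, k in zip(variables, keep) if k]
        if not variables:
            raise ValueError("no non-constant variables to expand")
        env = env[:, keep]
        lo, hi = lo[keep], hi[keep]
        knots: list[np.ndarray] = []
        if "hinge" in config.classes:
            k = config.hinge_knots
            probs = np.arange(1, k + 1) / (k + 1)
            for j in range(env.shape[1]):
                v = (env[:, j] - lo[j]) / (hi[j] - lo[j])
                kn = np.unique(np.quantile(v, probs))
                kn = kn[(kn > 1e-12) & (kn < 1 - 1e-12)]
                knots.append(kn)
        else:
            knots = [np.empty(0) for _ in variables]
        exp = cls(list(variables), config, lo, hi, knots)
        exp._build_names()
        return exp

    def _build_names(self) -> None:
        names: list[str] = []
        classes: list[str] = []
        v = self.variables
        if "linear" in self.config.classes:
            names += v
            classes += ["linear"] * len(v)
        if "quadratic" in self.config.classes:
            names += [f"{a}^2" for a in v]
            classes += ["quadratic"] * len(v)
        if "product" in self.config.classes:
            for a, b in itertools.combinations(v, 2):
                names.append(f"{a}*{b}")
                classes.append("product")
        if "hinge" in self.config.classes:
            for j, a in enumerate(v):
                for t in self.knots[j]:
                    names.append(f"hinge({a},{t:.6g})")
                    classes.append("hinge")
                for t in self.knots[j]:
                    names.append(f"rhinge({a},{t:.6g})")
                    classes.append("hinge")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        self.feature_names = names
        self.feature_classes = classes

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def scale(self, env: np.ndarray, clamp: bool = False) -> np.ndarray:
        env = np.asarray(env, float)
        v = (env - self.lo) / (self.hi - self.lo)
        if clamp:
            v = np.clip(v, 0.0, 1.0)
        return v

    def transform(self, env: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Expand raw environment rows (n × variables) into features (n × p)."""
        env = np.atleast_2d(np.asarray(env, float))
        if env.shape[1] != len(self.variables):
            raise ValueError(
                f"expected {len(self.variables)} variables, got {env.shape[1]}"
            )
        v = self.scale(env, clamp=clamp)
        blocks: list[np.ndarray] = []
        if "linear" in self.config.classes:
            blocks.append(v)
        if "quadratic" in self.config.classes:
            blocks.append(v**2)
        if "product" in self.config.classes:
            pairs = list(itertools.combinations(range(v.shape[1]), 2))
            if pairs:
                blocks.append(np.column_stack([v[:, a] * v[:, b] for a, b in pairs]))
        if "hinge" in self.config.classes:
            cols = []
            for j in range(v.shape[1]):
                for t in self.knots[j]:
                    cols.append(np.maximum(0.0, (v[:, j] - t) / (1.0 - t)))
                for t in self.knots[j]:
                    cols.append(np.maximum(0.0, (t - v[:, j]) / t))
            if cols:
                blocks.append(np.column_stack(cols))
        return np.hstack([b for b in blocks if b.size]) if blocks else np.empty((env.shape[0], 0))

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "classes": list(self.config.classes),
            "hinge_knots": self.config.hinge_knots,
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "knots": [k.tolist() for k in self.knots],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureExpansion":
        exp = cls(
            variables=list(d["variables"]),
            config=FeatureConfig(tuple(d["classes"]), int(d["hinge_knots"])),
            lo=np.asarray(d["lo"], float),
            hi=np.asarray(d["hi"], float),
            knots=[np.asarray(k, float) for k in d["knots"]],
        )
        exp._build_names()
        return exp


@dataclass
class MaxentModel:
    expansion: FeatureExpansion
    lam: np.ndarray  # coefficient per feature
    beta: np.ndarray  # L1 weight per feature
    log_Z: float  # log normalizer over the defining background
    entropy: float  # H of the fitted distribution, nats
    m: int  # presence count
    n_background: int
    r: float  # global regularization multiplier
    converged: bool = True

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    # -- outputs ------------------------------------------------------------

    def raw_output(self, features: np.ndarray) -> np.ndarray:
        """Gibbs mass q(x) = exp(lambda . f(x)) / Z per row of ``features``."""
        features = np.atleast_2d(np.asarray(features, float))
        return np.exp(features @ self.lam - self.log_Z)

    def logistic_output(self, features: np.ndarray) -> np.ndarray:
        """Suitability s = q e^H / (1 + q e^H) in (0, 1)."""
        q = self.raw_output(features)
        return self.logistic_from_raw(q)

    def logistic_from_raw(self, q: np.ndarray) -> np.ndarray:
        # computed in log space to survive very large q e^H
        log_qe = np.log(np.maximum(q, 1e-300)) + self.entropy
        return np.where(
            log_qe > 0,
            1.0 / (1.0 + np.exp(-log_qe)),
            np.exp(log_qe) / (1.0 + np.exp(log_qe)),
        )

    def gain(self, presence_features: np.ndarray) -> float:
        """Mean log improvement over the uniform model, (1/m) sum ln(q N_b)."""
        presence_features = np.atleast_2d(np.asarray(presence_features, float))
        log_q = presence_features @ self.lam - self.log_Z
        return float(np.mean(log_q) + np.log(self.n_background))

    def penalized_objective(self, presence_features: np.ndarray) -> float:
        presence_features = np.atleast_2d(presence_features)
        return float(
            np.mean(presence_features @ self.lam)
            - self.log_Z
            - np.sum(self.beta * np.abs(self.lam))
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "expansion": self.expansion.to_dict(),
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "log_Z": self.log_Z,
            "entropy": self.entropy,
            "m": self.m,
            "n_background": self.n_background,
            "r": self.r,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxentModel":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            expansion=FeatureExpansion.from_dict(d["expansion"]),
            lam=np.asarray(d["lam"], float),
            beta=np.asarray(d["beta"], float),
            log_Z=float(d["log_Z"]),
            entropy=float(d["entropy"]),
            m=int(d["m"]),
            n_background=int(d["n_background"]),
            r=float(d["r"]),
        )


def _kkt_violation(grad: np.ndarray, lam: np.ndarray, beta: np.ndarray) -> float:
    """Max violation of the L1 subgradient conditions at ``lam``.

    grad is the gradient of the smooth part (mean presence feature minus
    background expectation); at the optimum grad_j = beta_j sign(lam_j) for
    active features and |grad_j| <= beta_j for zero ones.
    """
    active = np.abs(lam) > 0
    v_active = np.abs(grad[active] - beta[active] * np.sign(lam[active]))
    v_zero = np.maximum(np.abs(grad[~active]) - beta[~active], 0.0)
    parts = np.concatenate([v_active, v_zero]) if lam.size else np.empty(0)
    return float(parts.max()) if parts.size else 0.0


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    expansion: FeatureExpansion | None = None,
    r: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    Parameters
    ----------
    presence_features, background_features
        Feature matrices (m × p) and (N_b × p) from one
        :class:`FeatureExpansion`.
    r
        Global regularization multiplier scaling every beta_j.
    tol
        First-order optimality tolerance (max subgradient violation).
    """
    F_p = np.atleast_2d(np.asarray(presence_features, float))
    F_b = np.atleast_2d(np.asarray(background_features, float))
    m, p = F_p.shape
    if m < 2:
        raise ValueError("need at least 2 presence records")
    if F_b.shape[0] < m:
        raise ValueError("background must be at least as large as the presence sample")
    if F_b.shape[1] != p:
        raise ValueError("presence/background feature dimension mismatch")
    if not (np.isfinite(F_p).all() and np.isfinite(F_b).all()):
        raise ValueError("features must be finite")

    f_bar = F_p.mean(axis=0)
    s = F_p.std(axis=0)  # population (ddof=0) spread of each feature
    beta = np.maximum(r * s / np.sqrt(m), 1e-6 * r)

    def smooth_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative smooth objective -(lambda.f_bar - ln Z) and its gradient."""
        eta = F_b @ lam
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        g = F_b.T @ w - f_bar  # gradient of (ln Z - lambda . f_bar)
        return float(lz - lam @ f_bar), g

    def objective_split(u: np.ndarray) -> tuple[float, np.ndarray]:
        lam = u[:p] - u[p:]
        val, g = smooth_grad(lam)
        val += float(beta @ (u[:p] + u[p:]))
        grad = np.concatenate([g + beta, -g + beta])
        return val, grad

    u0 = np.zeros(2 * p)
    last_val: float | None = None
    lam = np.zeros(p)
    for attempt, (pgtol, factr_like) in enumerate([(tol * 0.05, 1e-15), (tol * 0.005, 1e-16)]):
        res = minimize(
            objective_split,
            u0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * p),
            options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": factr_like, "gtol": pgtol},
        )
        u = res.x
        lam = u[:p] - u[p:]
        # shrink the overlap of the split (both halves positive) to zero
        overlap = np.minimum(u[:p], u[p:])
        if overlap.any():
            lam = np.where(np.abs(lam) < 1e-12, 0.0, lam)
        last_val = float(res.fun)
        _, g_smooth = smooth_grad(lam)
        # gradient of the maximized objective's smooth part is -g_smooth
        if _kkt_violation(-g_smooth, lam, beta) <= tol:
            break
        u0 = u
    else:
        raise ConvergenceError(
            f"maxent solver missed the optimality tolerance {tol}", last_objective=last_val
        )

    lam = np.where(np.abs(lam) < 1e-12, 0.0, lam)
    eta = F_b @ lam
    log_Z = float(logsumexp(eta))
    log_q = eta - log_Z
    entropy = float(-np.sum(np.exp(log_q) * log_q))
    return MaxentModel(
        expansion=expansion if expansion is not None else _bare_expansion(p),
        lam=lam,
        beta=beta,
        log_Z=log_Z,
        entropy=entropy,
        m=m,
        n_background=F_b.shape[0],
        r=r,
    )


def _bare_expansion(p: int) -> FeatureExpansion:
    """Placeholder expansion for models fit on pre-built feature matrices."""
    exp = FeatureExpansion(
        variables=[f"f{j}" for j in range(p)],
        config=FeatureConfig(classes=("linear",)),
        lo=np.zeros(p),
        hi=np.ones(p),
        knots=[np.empty(0)] * p,
    )
    exp._build_names()
    return exp
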