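"""Single-response partial least squares with Monte-Carlo component selection.

The core is a bespoke NIPALS PLS1 with X (and y) deflation, exposing weights,
loadings and scores explicitly so downstream target projection can be built
from them. The number of components is chosen by repeated random 50/50
train/validation splits: the component count minimizing the across-repetition
median validation RMSEP wins, ties resolved toward fewer components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScalingParams",
    "PLSModel",
    "SelectionResult",
    "DegenerateMatrixError",
    "SelectionConfigError",
    "autoscale",
    "apply_scaling",
    "fit_pls1",
    "predict",
    "monte_carlo_splits",
    "select_components",
    "fit_autoscaled",
]

_TOL = 1e-12


class DegenerateMatrixError(ValueError):
    """Raised when a data matrix cannot be autoscaled or decomposed."""


class SelectionConfigError(ValueError):
    """Raised for infeasible resampling configurations."""


@dataclass
class ScalingParams:
    """Centering/unit-variance parameters for X columns and y (SD uses n-1)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float


def autoscale(
    X: np.ndarray, y: np.ndarray, labels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, ScalingParams]:
    """Center and scale X columns and y to unit variance; params are stored."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise DegenerateMatrixError("need at least 2 samples to autoscale")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(x_sd <= _TOL)
    if zero.size:
        names = [labels[i] for i in zero] if labels else list(zero)
        raise DegenerateMatrixError(f"zero-variance column(s): {names}")
    y_sd = y.std(ddof=1)
    if y_sd <= _TOL:
        raise DegenerateMatrixError("outcome has zero variance")
    params = ScalingParams(x_mean=x_mean, x_sd=x_sd, y_mean=float(y.mean()), y_sd=float(y_sd))
    return (X - x_mean) / x_sd, (y - params.y_mean) / y_sd, params


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(params.x_mean):
        raise ValueError(
            f"column-count mismatch: got {X.shape[1]}, expected {len(params.x_mean)}"
        )
    return (X - params.x_mean) / params.x_sd


@dataclass
class PLSModel:
    """Fitted PLS1 model on autoscaled data.

    ``b`` is the regression vector on the standardized scale, so training
    predictions are ``X_std @ b`` (plus un-scaling of y).
    """

    n_components: int
    weights: np.ndarray       # p x A
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A
    scores: np.ndarray        # n x A
    b: np.ndarray             # p
    scaling: ScalingParams
    r2_cumulative: np.ndarray  # training R^2 of y per cumulative component
    status: str = "ok"        # "ok" or "early_stop"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_components": int(self.n_components),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "b": self.b.tolist(),
            "scaling": {
                "x_mean": self.scaling.x_mean.tolist(),
                "x_sd": self.scaling.x_sd.tolist(),
                "y_mean": self.scaling.y_mean,
                "y_sd": self.scaling.y_sd,
            },
            "r2_cumulative": self.r2_cumulative.tolist(),
            "status": self.status,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PLSModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        scaling = ScalingParams(
            x_mean=np.asarray(d["scaling"]["x_mean"]),
            x_sd=np.asarray(d["scaling"]["x_sd"]),
            y_mean=d["scaling"]["y_mean"],
            y_sd=d["scaling"]["y_sd"],
        )
        return cls(
            n_components=d["n_components"],
            weights=np.asarray(d["weights"]),
            x_loadings=np.asarray(d["x_loadings"]),
            y_loadings=np.asarray(d["y_loadings"]),
            scores=np.empty((0, d["n_components"])),
            b=np.asarray(d["b"]),
            scaling=scaling,
            r2_cumulative=np.asarray(d["r2_cumulative"]),
            status=d["status"],
        )


def _nipals_pls1(Xs: np.ndarray, ys: np.ndarray, n_components: int):
    """NIPALS recursion for PLS1 with X and y deflation.

    Returns (W, P, q, T, status) with possibly fewer columns than requested
    when the residual covariance vanishes.
    """
    X = np.array(Xs, dtype=float)
    y = np.array(ys, dtype=float)
    n, p = X.shape
    W, P, T, q = [], [], [], []
    status = "ok"
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _TOL * max(1.0, np.abs(X).max(initial=0.0)):
            status = "early_stop"
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _TOL:
            status = "early_stop"
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        W.append(w)
        P.append(p_a)
        T.append(t)
        q.append(q_a)
    if not W:
        raise DegenerateMatrixError("no PLS component could be extracted")
    return (
        np.column_stack(W),
        np.column_stack(P),
        np.asarray(q),
        np.column_stack(T),
        status,
    )


def fit_pls1(Xs: np.ndarray, ys: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model on autoscaled inputs.

    Preconditions: ``Xs`` and ``ys`` centered/scaled, and
    ``1 <= n_components <= min(n-1, p)``.
    """
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, p = Xs.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    W, P, q, T, status = _nipals_pls1(Xs, ys, n_components)
    A = W.shape[1]
    # b = W (P'W)^-1 q ; P'W is upper-triangular with unit-ish diagonal
    b = W @ np.linalg.solve(P.T @ W, q)
    ss_y = float(ys @ ys)
    fitted = np.cumsum(T * q, axis=1)  # n x A, cumulative fitted values
    resid_ss = ((ys[:, None] - fitted) ** 2).sum(axis=0)
    r2 = 1.0 - resid_ss / ss_y if ss_y > 0 else np.zeros(A)
    scaling = ScalingParams(
        x_mean=np.zeros(p), x_sd=np.ones(p), y_mean=0.0, y_sd=1.0
    )
    return PLSModel(
        n_components=A,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        b=b,
        scaling=scaling,
        r2_cumulative=r2,
        status=status,
    )


def fit_autoscaled(
    X: np.ndarray, y: np.ndarray, n_components: int, labels: list[str] | None = None
) -> PLSModel:
    """Autoscale raw X, y then fit; the model carries the scaling parameters."""
    Xs, ys, params = autoscale(X, y, labels)
    model = fit_pls1(Xs, ys, n_components)
    model.scaling = params
    return model


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict in original y units for raw (unscaled) X_new."""
    Xs = apply_scaling(np.atleast_2d(np.asarray(X_new, dtype=float)), model.scaling)
    return Xs @ model.b * model.scaling.y_sd + model.scaling.y_mean


@dataclass
class SelectionResult:
    """Monte-Carlo validation curve and the chosen component count."""

    n_components: int
    median_rmsep: np.ndarray     # length A_max
    rmsep: np.ndarray            # repetitions x A_max
    rmsep_null: np.ndarray       # per-repetition RMSEP of the mean-only predictor
    seed: int | None
    predictive: bool = True      # False when no A beats the mean-only predictor

    @property
    def median_rmsep_null(self) -> float:
        return float(np.median(self.rmsep_null))

    def to_frame(self) -> pd.DataFrame:
        reps, a_max = self.rmsep.shape
        return pd.DataFrame(
            {
                "repetition": np.repeat(np.arange(reps), a_max),
                "n_components": np.tile(np.arange(1, a_max + 1), reps),
                "rmsep": self.rmsep.ravel(),
            }
        )


def monte_carlo_splits(
    n: int, repetitions: int, holdout_fraction: float, seed: int | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic list of (train_idx, validation_idx) random splits."""
    if not (0.0 < holdout_fraction < 1.0):
        raise SelectionConfigError("holdout_fraction must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    splits = []
    for child in ss.spawn(repetitions):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        n_val = int(round(n * holdout_fraction))
        n_val = min(max(n_val, 1), n - 2)
        splits.append((perm[n_val:], perm[:n_val]))
    return splits


def _validation_curve(
    X_tr: np.ndarray, y_tr: np.ndarray, X_va: np.ndarray, y_va: np.ndarray, a_max: int
) -> tuple[np.ndarray, float]:
    """RMSEP (original y units) for 1..a_max components, plus the mean-only RMSEP.

    Runs a single NIPALS pass, co-deflating the validation block, so nested
    models share all computation.
    """
    Xs, ys, params = autoscale(X_tr, y_tr)
    Xv = apply_scaling(X_va, params)
    yt = ys.copy()
    Xt = Xs.copy()
    pred = np.zeros(len(y_va))
    y_va_s = (y_va - params.y_mean) / params.y_sd
    out = np.empty(a_max)
    rmsep_null = float(np.sqrt(np.mean(y_va_s**2))) * params.y_sd
    last = rmsep_null
    for a in range(a_max):
        w = Xt.T @ yt
        nw = np.linalg.norm(w)
        if nw <= _TOL:
            out[a:] = last
            break
        w /= nw
        t = Xt @ w
        tt = float(t @ t)
        if tt <= _TOL:
            out[a:] = last
            break
        p_a = Xt.T @ t / tt
        q_a = float(yt @ t) / tt
        tv = Xv @ w
        pred += q_a * tv
        Xt -= np.outer(t, p_a)
        yt -= q_a * t
        Xv -= np.outer(tv, p_a)
        last = float(np.sqrt(np.mean((y_va_s - pred) ** 2))) * params.y_sd
        out[a] = last
    return out, rmsep_null


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    repetitions: int = 100,
    holdout_fraction: float = 0.5,
    a_max: int | None = None,
    seed: int | None = None,
) -> SelectionResult:
    """Choose the component count by minimum median validation RMSEP.

    Scaling is re-estimated on each training half. The result also flags
    whether the chosen model beats the mean-only (zero-component) predictor;
    if not, no predictive model should be reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise SelectionConfigError("need n >= 10 for Monte-Carlo selection")
    a_cap = min(n - int(round(n * holdout_fraction)) - 1, p)
    if a_max is None:
        a_max = min(10, a_cap)
    if not (1 <= a_max <= a_cap):
        raise SelectionConfigError(f"a_max must be in [1, {a_cap}]")
    splits = monte_carlo_splits(n, repetitions, holdout_fraction, seed)
    rmsep = np.empty((repetitions, a_max))
    rmsep_null = np.empty(repetitions)
    for i, (tr, va) in enumerate(splits):
        rmsep[i], rmsep_null[i] = _validation_curve(X[tr], y[tr], X[va], y[va], a_max)
    median_curve = np.median(rmsep, axis=0)
    chosen = int(np.argmin(median_curve)) + 1  # first minimum -> fewest components
    predictive = bool(median_curve[chosen - 1] < np.median(rmsep_null))
    return SelectionResult(
        n_components=chosen,
        median_rmsep=median_curve,
        rmsep=rmsep,
        rmsep_null=rmsep_null,
        seed=seed,
        predictive=predictive,
    )
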