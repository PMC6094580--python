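"""Predictive-component signatures: target projection and selectivity ratios.

A fitted multi-component PLS1 model is collapsed onto the single component
spanned by its regression vector (target projection). Each predictor's
importance is then the ratio of its variance explained by that component to
its residual variance, signed by the target-projection loading. Confidence
intervals reuse the Monte-Carlo half-sample machinery of the component
selection step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pls import (
    PLSModel,
    ScalingParams,
    autoscale,
    fit_pls1,
    monte_carlo_splits,
)

__all__ = [
    "TargetProjection",
    "SignatureProfile",
    "NullModelError",
    "target_projection",
    "selectivity_ratios",
    "sr_confidence_intervals",
    "weighted_loadings",
    "compare_patterns",
    "univariate_profile",
    "r_significance_threshold",
    "sed_sensitivity",
    "build_signature",
]


_ABS_FLOOR = 1e-300


class NullModelError(ValueError):
    """Raised when the regression vector is zero and no direction exists."""


@dataclass
class TargetProjection:
    """Rank-1 rotation of a PLS model onto its regression-vector direction."""

    w_tp: np.ndarray      # unit direction, length p
    t_tp: np.ndarray      # scores, length n
    p_tp: np.ndarray      # loadings, length p
    v_expl: np.ndarray    # per-variable variance explained by the TP component
    v_res: np.ndarray     # per-variable residual variance


def target_projection(model: PLSModel, Xs: np.ndarray) -> TargetProjection:
    """Project a fitted model onto its single predictive direction.

    ``Xs`` must be the standardized training matrix. The rank-1 model
    preserves the full model's fitted values exactly (Xs @ b is unchanged;
    only the basis is rotated).
    """
    Xs = np.asarray(Xs, dtype=float)
    norm_b = np.linalg.norm(model.b)
    if norm_b <= 0:
        raise NullModelError("zero regression vector: no predictive direction")
    w_tp = model.b / norm_b
    t_tp = Xs @ w_tp
    tt = float(t_tp @ t_tp)
    if tt <= 0:
        raise NullModelError("degenerate target-projection scores")
    p_tp = Xs.T @ t_tp / tt
    n = Xs.shape[0]
    explained = np.outer(t_tp, p_tp)
    v_expl = explained.var(axis=0, ddof=1) if n > 1 else np.zeros(Xs.shape[1])
    v_res = (Xs - explained).var(axis=0, ddof=1) if n > 1 else np.zeros(Xs.shape[1])
    return TargetProjection(w_tp=w_tp, t_tp=t_tp, p_tp=p_tp, v_expl=v_expl, v_res=v_res)


def selectivity_ratios(tp: TargetProjection, rel_tol: float = 1e-12) -> np.ndarray:
    """Signed per-variable SR: sign(p_tp) * v_expl / v_res.

    Variables whose residual variance is (numerically) zero are flagged with
    an infinite SR.
    """
    total = tp.v_expl + tp.v_res
    degenerate = tp.v_res <= rel_tol * np.maximum(total, _ABS_FLOOR)
    magnitude = np.where(degenerate, np.inf, tp.v_expl / np.where(degenerate, 1.0, tp.v_res))
    return np.sign(tp.p_tp) * magnitude


def _sr_for_subset(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    Xs, ys, _ = autoscale(X, y)
    model = fit_pls1(Xs, ys, n_components)
    return selectivity_ratios(target_projection(model, Xs))


def sr_confidence_intervals(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    repetitions: int = 100,
    holdout_fraction: float = 0.5,
    seed: int | None = None,
    levels: tuple[float, float] = (2.5, 97.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CIs for signed SRs over Monte-Carlo training halves.

    Returns ``(ci, sr_matrix)`` where ``ci`` is p x 2 (low, high) and
    ``sr_matrix`` is repetitions x p. A variable is "significant" when its
    interval excludes zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    splits = monte_carlo_splits(len(y), repetitions, holdout_fraction, seed)
    srs = np.empty((repetitions, X.shape[1]))
    for i, (tr, _) in enumerate(splits):
        srs[i] = _sr_for_subset(X[tr], y[tr], n_components)
    finite = np.where(np.isfinite(srs), srs, np.nan)
    ci = np.nanpercentile(finite, levels, axis=0).T
    return ci, srs


def weighted_loadings(
    tp: TargetProjection, scaling: ScalingParams
) -> tuple[np.ndarray, np.ndarray]:
    """(weighted, unweighted) TP loadings.

    The weighted form multiplies each loading by the variable's original-unit
    SD, giving a covariance-scale importance per minute/day; the unweighted
    form is the raw TP loading.
    """
    return tp.p_tp * scaling.x_sd, tp.p_tp.copy()


def compare_patterns(loadings_a: np.ndarray, loadings_b: np.ndarray) -> float:
    """Pearson correlation between two loading patterns."""
    a = np.asarray(loadings_a, dtype=float)
    b = np.asarray(loadings_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("patterns must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("pattern correlation undefined for constant vectors")
    return float(stats.pearsonr(a, b).statistic)


def r_significance_threshold(n: int, alpha: float = 0.05) -> float:
    """|r| at the two-sided significance boundary for a Pearson correlation."""
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def univariate_profile(
    X: np.ndarray,
    outcomes: pd.DataFrame,
    bin_labels: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin Pearson r against each (already adjusted) outcome.

    Returns a frame indexed by bin label with MultiIndex columns
    (outcome, {r, p, significant}); p-values are two-sided via the
    t-transform, with no multiplicity adjustment.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    cols = {}
    for name in outcomes.columns:
        y = outcomes[name].to_numpy(dtype=float)
        r = np.empty(X.shape[1])
        p = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            res = stats.pearsonr(X[:, j], y)
            r[j], p[j] = res.statistic, res.pvalue
        cols[(name, "r")] = r
        cols[(name, "p")] = p
        cols[(name, "significant")] = p < alpha
    out = pd.DataFrame(cols, index=list(bin_labels))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["outcome", "stat"])
    out.attrs["n"] = n
    out.attrs["r_threshold"] = r_significance_threshold(n, alpha)
    return out


@dataclass
class SignatureProfile:
    """Signed SRs with CIs and SD-weighted loadings for one fitted model."""

    labels: tuple[str, ...]
    sr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_tp: np.ndarray
    weighted_loading: np.ndarray
    unweighted_loading: np.ndarray
    n_components: int
    r2: float
    predictive: bool = True

    @property
    def significant(self) -> np.ndarray:
        return (self.ci_low > 0) | (self.ci_high < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.labels),
                "sr": self.sr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
                "weighted_loading": self.weighted_loading,
                "unweighted_loading": self.unweighted_loading,
            }
        )


def build_signature(
    X: np.ndarray,
    y: np.ndarray,
    labels: Sequence[str],
    n_components: int,
    repetitions: int = 100,
    holdout_fraction: float = 0.5,
    seed: int | None = None,
    predictive: bool = True,
) -> SignatureProfile:
    """Fit at a fixed component count and assemble the full SR profile."""
    Xs, ys, params = autoscale(X, y, list(labels))
    model = fit_pls1(Xs, ys, n_components)
    model.scaling = params
    tp = target_projection(model, Xs)
    sr = selectivity_ratios(tp)
    ci, _ = sr_confidence_intervals(
        X, y, n_components, repetitions, holdout_fraction, seed
    )
    weighted, unweighted = weighted_loadings(tp, params)
    return SignatureProfile(
        labels=tuple(labels),
        sr=sr,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        p_tp=tp.p_tp,
        weighted_loading=weighted,
        unweighted_loading=unweighted,
        n_components=model.n_components,
        r2=float(model.r2_cumulative[-1]),
        predictive=predictive,
    )


def sed_sensitivity(
    streams: Sequence,
    y: pd.Series,
    base_scheme=None,
    alt_first_edges: Sequence[int] = (50, 100, 150, 250),
    criteria=None,
    n_components: int | None = None,
    repetitions: int = 100,
    holdout_fraction: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """|SR| of the lowest-intensity bin under alternative SED upper cut points.

    Rebuilds the spectrum from epoch streams for each first-bin edge variant
    (keeping the partition contiguous), refits the pipeline, and reports the
    SED bin's absolute SR. ``y`` must be indexed by subject_id.
    """
    from .accel import BinScheme, WearCriteria, process_stream
    from .pls import select_components

    base_scheme = base_scheme or BinScheme.default()
    criteria = criteria or WearCriteria()
    rows = []
    for edge in alt_first_edges:
        scheme = base_scheme.with_first_edge(edge)
        feats = {}
        for stream in streams:
            spectrum, _, _ = process_stream(stream, criteria, scheme)
            if spectrum is not None and spectrum.subject_id in y.index:
                feats[spectrum.subject_id] = spectrum.minutes_per_day
        if len(feats) < 10:
            raise ValueError(f"too few valid subjects ({len(feats)}) for edge {edge}")
        ids = [sid for sid in y.index if sid in feats]
        X = np.asarray([feats[sid] for sid in ids])
        yv = y.loc[ids].to_numpy(dtype=float)
        if n_components is None:
            sel = select_components(
                X, yv, repetitions=repetitions,
                holdout_fraction=holdout_fraction, seed=seed,
            )
            a = sel.n_components
        else:
            a = n_components
        sr = _sr_for_subset(X, yv, a)
        rows.append(
            {
                "sed_upper": edge,
                "n_bins": scheme.n_bins,
                "n_components": a,
                "sed_abs_sr": float(abs(sr[0])),
                "sed_sr": float(sr[0]),
                "n_subjects": len(ids),
            }
        )
    return pd.DataFrame(rows)
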