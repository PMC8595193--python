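"""Sensitivity-analysis machinery: one-at-a-time screening index, Latin
hypercube sampling, and (partial) rank correlation coefficients.

With ψ = k+1 samples per trial, full partialling of the other k−1 inputs
leaves zero residual degrees of freedom, so the default coefficient is the
plain correlation formula applied to ranks (Spearman); a proper partial
mode is available when ψ > k+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["OATResult", "LHSDesign", "PRCCResult", "oat_index", "lhs_sample",
           "prcc", "run_sensitivity"]


@dataclass
class OATResult:
    """One-at-a-time screening record for a single parameter adjustment."""

    parameter: str
    p_ref: float
    p_adj: float
    Q_ref: float
    Q_adj: float
    S: float


@dataclass
class LHSDesign:
    """One Latin hypercube trial: a (psi × k) sample matrix."""

    names: list[str]
    ranges: dict[str, tuple[float, float]]
    samples: np.ndarray  # (psi, k)
    seed: int

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def psi(self) -> int:
        return self.samples.shape[0]


@dataclass
class PRCCResult:
    """Per-trial coefficients and their across-trial mean."""

    names: list[str]
    per_trial: np.ndarray = field(default=None)  # (n_trials, k)

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.per_trial, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_trial, columns=self.names)
        df.index.name = "trial"
        return df


def oat_index(Q_ref: float, Q_adj: float, p_ref: float, p_adj: float) -> float:
    """Normalized flow change over normalized parameter change.

    S = [(Q̄_ref − Q̄_adj)/Q̄_ref] / [(p_ref − p_adj)/p_ref]
    """
    if p_ref == p_adj:
        raise ZeroDivisionError("parameter change must be nonzero")
    if Q_ref == 0:
        raise ZeroDivisionError("reference flow must be nonzero")
    if p_ref == 0:
        raise ZeroDivisionError("reference parameter must be nonzero")
    return ((Q_ref - Q_adj) / Q_ref) / ((p_ref - p_adj) / p_ref)


def lhs_sample(ranges: dict[str, tuple[float, float]], n_trials: int,
               seed: int, psi: int | None = None) -> list[LHSDesign]:
    """Latin hypercube designs: ψ = k+1 strata per parameter by default,
    one uniform draw per stratum, stratum order randomly permuted per
    column.  Deterministic given ``seed``."""
    names = list(ranges)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 parameters")
    if psi is None:
        psi = k + 1
    rng = np.random.default_rng(seed)
    designs = []
    for _ in range(n_trials):
        samples = np.empty((psi, k))
        for j, name in enumerate(names):
            lo, hi = ranges[name]
            strata = (np.arange(psi) + rng.uniform(size=psi)) / psi
            samples[:, j] = lo + (hi - lo) * rng.permutation(strata)
        designs.append(LHSDesign(names=names, ranges=dict(ranges),
                                 samples=samples, seed=seed))
    return designs


def _partial_residuals(R: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Residuals of column j of X and of Y after projecting out the other
    columns (with intercept); R = [X | Y] rank-transformed."""
    X = R[:, :-1]
    Y = R[:, -1]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(Y)), others])
    coef_x, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return X[:, j] - A @ coef_x, Y - A @ coef_y


def prcc(X: np.ndarray, Y: np.ndarray, mode: str = "rank") -> np.ndarray:
    """Per-parameter correlation coefficients in [−1, 1].

    ``mode="rank"`` (default): the covariance/variance correlation
    applied to rank-transformed data.  ``mode="partial"``: classical PRCC
    (requires ψ > k+1); ``mode="literal"``: the same formula on raw
    values.  Degenerate (constant) columns yield NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    psi, k = X.shape
    out = np.empty(k)
    if mode in ("rank", "literal"):
        Xw = np.column_stack([rankdata(X[:, j]) for j in range(k)]) \
            if mode == "rank" else X
        Yw = rankdata(Y) if mode == "rank" else Y
        yc = Yw - Yw.mean()
        vy = (yc @ yc) / (psi - 1)
        for j in range(k):
            xc = Xw[:, j] - Xw[:, j].mean()
            vx = (xc @ xc) / (psi - 1)
            if vx == 0 or vy == 0:
                out[j] = np.nan
                continue
            cov = (xc @ yc) / (psi - 1)
            out[j] = cov / np.sqrt(vx * vy)
    elif mode == "partial":
        if psi <= k + 1:
            raise ValueError("partial mode needs psi > k+1 samples")
        R = np.column_stack([rankdata(X[:, j]) for j in range(k)]
                            + [rankdata(Y)])
        for j in range(k):
            rx, ry = _partial_residuals(R, j)
            denom = np.linalg.norm(rx) * np.linalg.norm(ry)
            out[j] = np.nan if denom == 0 else float(rx @ ry) / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.clip(out, -1.0, 1.0, out=out, where=np.isfinite(out))


def run_sensitivity(model, ranges: dict[str, tuple[float, float]],
                    n_trials: int, seed: int, mode: str = "rank",
                    on_error: str = "flag") -> PRCCResult:
    """LHS campaign: ψ = k+1 model calls per trial, one coefficient vector
    per trial, across-trial mean as the overall measure.

    ``model`` maps a {name: value} dict to a scalar output.  Failed model
    calls flag the whole trial (its coefficients become NaN) and are
    logged; with ``on_error="raise"`` they propagate.
    """
    if not ranges:
        raise ValueError("empty campaign: no parameters given")
    designs = lhs_sample(ranges, n_trials, seed)
    names = designs[0].names
    k = len(names)
    per_trial = np.full((n_trials, k), np.nan)
    for t, design in enumerate(designs):
        Y = np.empty(design.psi)
        failed = False
        for i in range(design.psi):
            point = dict(zip(names, design.samples[i]))
            try:
                Y[i] = float(model(point))
            except Exception as exc:  # noqa: BLE001 - model runs may fail
                if on_error == "raise":
                    raise
                import logging
                logging.getLogger(__name__).warning(
                    "trial %d sample %d failed: %s", t, i, exc)
                failed = True
                break
        if not failed:
            per_trial[t] = prcc(design.samples, Y, mode=mode)
    return PRCCResult(names=names, per_trial=per_trial)
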