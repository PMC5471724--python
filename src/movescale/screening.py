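"""Two-step predictor screening under multicollinearity.

Step 1 ranks candidate predictors by out-of-bag permutation importance from
a bagged regression-tree ensemble.  Step 2 walks the ranking greedily and
keeps a predictor only if its absolute Pearson correlation with every
already-kept predictor is below the threshold (default 0.5); categorical
predictors are exempt from the correlation filter.  A cross-validated
predictive-accuracy rule then truncates the kept list where adding the next
predictor no longer improves CV R² by at least ``epsilon`` (default 0.01).

Permutation (rather than impurity) importance is used because it is robust
to predictor scale and cardinality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ScreeningResult",
    "rank_importance",
    "decorrelate",
    "accuracy_stop",
    "screen_predictors",
]


@dataclass
class ScreeningResult:
    ranking: pd.DataFrame  # predictor, importance (sorted descending)
    kept: list[str]
    dropped: list[dict]  # {"predictor", "reason", "blocking", "r"}
    final: list[str]
    cv_r2_trace: list[float] = field(default_factory=list)
    constant_response: bool = False

    def to_dict(self) -> dict:
        return {
            "ranking": self.ranking.to_dict(orient="records"),
            "kept": self.kept,
            "dropped": self.dropped,
            "final": self.final,
            "cv_r2_trace": self.cv_r2_trace,
            "constant_response": self.constant_response,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _encode(X: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in X.columns:
        s = X[c]
        if s.dtype.kind in "OUb" or isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(pd.factorize(s)[0].astype(float))
        else:
            cols.append(s.to_numpy(dtype=float))
    return np.column_stack(cols)


def rank_importance(
    y,
    X: pd.DataFrame,
    weights=None,
    n_trees: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, bool]:
    """Out-of-bag permutation importance from a bagged tree ensemble.

    Importance is the mean increase in out-of-bag MSE when the predictor is
    permuted within each tree's OOB sample.  Deterministic under ``seed``.
    Returns (ranking DataFrame sorted by importance, constant_response flag).
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    Xm = _encode(X)
    ok &= np.isfinite(Xm).all(axis=1)
    y, Xm = y[ok], Xm[ok]
    w = None if weights is None else np.asarray(weights, dtype=float)[ok]
    names = list(X.columns)
    if len(y) < 30:
        raise ValueError("rank_importance requires >= 30 records")
    if np.ptp(y) == 0.0:
        ranking = pd.DataFrame({"predictor": names, "importance": 0.0})
        return ranking, True

    ens = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_features=max(1, Xm.shape[1] // 3)),
        n_estimators=n_trees,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    ens.fit(Xm, y, sample_weight=w)
    rng = np.random.default_rng(seed)
    n = len(y)
    imp = np.zeros(Xm.shape[1])
    used = np.zeros(Xm.shape[1])
    for tree, samples in zip(ens.estimators_, ens.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples, assume_unique=False)
        if len(oob) < 2:
            continue
        Xo = Xm[oob]
        base = np.mean((tree.predict(Xo) - y[oob]) ** 2)
        for jcol in range(Xm.shape[1]):
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, jcol] = Xo[perm, jcol]
            imp[jcol] += np.mean((tree.predict(Xp) - y[oob]) ** 2) - base
            used[jcol] += 1
    imp = imp / np.maximum(used, 1)
    ranking = (
        pd.DataFrame({"predictor": names, "importance": imp})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ranking, False


def decorrelate(
    ranking: pd.DataFrame,
    X: pd.DataFrame,
    threshold: float = 0.5,
    method: str = "pearson",
) -> tuple[list[str], list[dict]]:
    """Greedy de-correlation scan in importance order.

    A predictor is kept iff its |r| with every already-kept numeric
    predictor is strictly below the threshold; categorical predictors are
    always eligible.  Dropped entries record the blocking predictor.
    """
    kept: list[str] = []
    dropped: list[dict] = []
    numeric = {
        c for c in X.columns
        if X[c].dtype.kind in "fiu" and not isinstance(X[c].dtype, pd.CategoricalDtype)
    }
    for name in ranking["predictor"]:
        if name not in numeric:
            kept.append(name)
            continue
        blocker = None
        r_block = 0.0
        for prev in kept:
            if prev not in numeric:
                continue
            if X[name].std() == 0 or X[prev].std() == 0:
                continue
            r = X[name].corr(X[prev], method=method)
            if np.isfinite(r) and abs(r) >= threshold:
                blocker, r_block = prev, float(r)
                break
        if blocker is None:
            kept.append(name)
        else:
            dropped.append(
                {"predictor": name, "reason": "correlated",
                 "blocking": blocker, "r": r_block}
            )
    return kept, dropped


def accuracy_stop(
    candidates: list[str],
    y,
    X: pd.DataFrame,
    weights=None,
    epsilon: float = 0.01,
    cv: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> tuple[list[str], list[float]]:
    """Forward inclusion in importance order with a CV-R² plateau rule.

    Predictors are added one at a time; when a step improves cross-validated
    R² by less than ``epsilon`` the scan stops and the set before the
    plateau is returned.  A single candidate is returned as-is.
    """
    if len(candidates) <= 1:
        return list(candidates), []
    y = np.asarray(y, dtype=float)
    trace: list[float] = []
    best = -np.inf
    final = [candidates[0]]
    for i in range(1, len(candidates) + 1):
        cols = candidates[:i]
        r2 = _cv_r2(y, X[cols], weights, cv, seed, n_trees)
        trace.append(r2)
        if i == 1:
            best = r2
            continue
        if r2 - best < epsilon:
            break
        best = r2
        final = cols
    return final, trace


def _cv_r2(y, X: pd.DataFrame, weights, cv: int, seed: int, n_trees: int) -> float:
    Xm = _encode(X)
    ok = np.isfinite(y) & np.isfinite(Xm).all(axis=1)
    y, Xm = y[ok], Xm[ok]
    w = None if weights is None else np.asarray(weights, dtype=float)[ok]
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    num = 0.0
    den = 0.0
    for tr, te in kf.split(Xm):
        model = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            max_features=max(1, Xm.shape[1] // 3),
        )
        model.fit(Xm[tr], y[tr], sample_weight=None if w is None else w[tr])
        pred = model.predict(Xm[te])
        num += float(np.sum((y[te] - pred) ** 2))
        den += float(np.sum((y[te] - np.mean(y[tr])) ** 2))
    return 1.0 - num / den if den > 0 else 0.0


def screen_predictors(
    y,
    X: pd.DataFrame,
    weights=None,
    threshold: float = 0.5,
    epsilon: float = 0.01,
    n_trees: int = 200,
    seed: int = 0,
    apply_accuracy_stop: bool = True,
) -> ScreeningResult:
    """Full two-step screen: rank -> de-correlate -> accuracy plateau."""
    ranking, const = rank_importance(y, X, weights, n_trees=n_trees, seed=seed)
    if const:
        return ScreeningResult(ranking=ranking, kept=[], dropped=[], final=[],
                               constant_response=True)
    kept, dropped = decorrelate(ranking, X, threshold=threshold)
    if apply_accuracy_stop and len(kept) > 1:
        final, trace = accuracy_stop(kept, y, X, weights, epsilon=epsilon, seed=seed)
    else:
        final, trace = list(kept), []
    return ScreeningResult(
        ranking=ranking, kept=kept, dropped=dropped, final=final, cv_r2_trace=trace
    )
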