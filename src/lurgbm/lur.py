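"""Land-use regression: multivariate OLS and bidirectional stepwise selection.

The regression is the classical LUR form
``y = a0 + a1 x1 + ... + an xn + eps`` fitted by ordinary least squares.
Its role in the hybrid pipeline is variable selection only: the selected
covariate *set* feeds the boosted-tree stage, the fitted linear values do not.

Stepwise selection is the textbook bidirectional procedure: repeatedly add
the candidate with the smallest entry p-value below ``p_enter``, then drop
any retained variable whose p-value exceeds ``p_remove``, until a fixed
point.  Ties break on larger |t|, then name order, so the procedure is
deterministic for a given candidate table.  An AIC mode (greedy add/drop by
largest AIC decrease) is available as an alternative criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

logger = logging.getLogger(__name__)


@dataclass
class LURModel:
    """Fitted land-use regression: selected names, coefficients and fit stats."""

    selected: list[str]
    coefficients: pd.Series        # "const" + one per selected covariate
    residual_sd: float
    r_squared: float
    tvalues: pd.Series
    pvalues: pd.Series
    aic: float

    def __post_init__(self):
        if len(self.coefficients) != len(self.selected) + 1:
            raise ValueError("coefficient count must be number of selected + 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be ≥ 0")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.coefficients["const"], dtype=float)
        for name in self.selected:
            out += self.coefficients[name] * X[name].to_numpy(dtype=float)
        return out

    def to_yaml(self, path) -> None:
        doc = {
            "selected": list(self.selected),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "residual_sd": float(self.residual_sd),
            "r_squared": float(self.r_squared),
            "aic": float(self.aic),
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _collinear_sets(X: pd.DataFrame) -> list[str]:
    """Columns exactly expressible from the others (R² against the rest ≈ 1)."""
    bad = []
    cols = list(X.columns)
    xv = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        others = np.delete(xv, j, axis=1)
        a = np.column_stack([np.ones(len(xv)), others])
        resid = xv[:, j] - a @ np.linalg.lstsq(a, xv[:, j], rcond=None)[0]
        denom = np.var(xv[:, j])
        if denom == 0 or np.var(resid) / denom < 1e-10:
            bad.append(name)
    return bad


def fit_ols(X: pd.DataFrame, y) -> LURModel:
    """Ordinary least squares with intercept.

    Raises on rank deficiency, naming the collinear columns (e.g. the road sum
    ``hm`` entered alongside both of its addends).
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more rows than columns + 1")
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {_collinear_sets(X)}")
    res = sm.OLS(y, design).fit()
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return LURModel(
        selected=list(X.columns),
        coefficients=res.params,
        residual_sd=resid_sd,
        r_squared=float(res.rsquared),
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        aic=float(res.aic),
    )


@dataclass
class StepwiseCriteria:
    """Entry/removal thresholds for p-value stepwise, or AIC mode."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    criterion: str = "pvalue"      # "pvalue" | "aic"

    def __post_init__(self):
        if self.criterion not in ("pvalue", "aic"):
            raise ValueError("criterion must be 'pvalue' or 'aic'")
        if self.p_remove < self.p_enter:
            raise ValueError("p_remove must be ≥ p_enter to avoid cycling")


def _fit_quiet(X: pd.DataFrame, y) -> "sm.regression.linear_model.RegressionResultsWrapper":
    return sm.OLS(np.asarray(y, dtype=float), sm.add_constant(X.astype(float), has_constant="add")).fit()


def _rank_ok(X: pd.DataFrame) -> bool:
    d = sm.add_constant(X.astype(float), has_constant="add").to_numpy()
    return np.linalg.matrix_rank(d) == d.shape[1]


def stepwise_select(
    candidates: pd.DataFrame,
    y,
    criteria: StepwiseCriteria | None = None,
    max_iter: int | None = None,
) -> tuple[list[str], LURModel]:
    """Bidirectional stepwise variable selection over screened candidates.

    The road-length sum ``hm`` is dropped from the candidate pool whenever both
    of its addends ``hig`` and ``maj`` are candidates (exact collinearity).
    Candidates whose entry would make the design rank deficient (duplicated
    columns) are skipped.  If nothing passes entry, an intercept-only model is
    returned with a warning.
    """
    criteria = criteria or StepwiseCriteria()
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    if "hm" in names and "hig" in names and "maj" in names:
        logger.info("excluding 'hm' from candidates: exactly collinear with hig + maj")
        names.remove("hm")
    if not names:
        raise ValueError("no candidates to select from")
    max_iter = max_iter or 2 * len(names)

    selected: list[str] = []
    for _ in range(max_iter):
        changed = False

        # a numerically perfect fit leaves zero residual variance: every extra
        # candidate would show a spurious ~0 p-value, so selection stops here
        if selected:
            res = _fit_quiet(candidates[selected], y)
            if res.ssr <= 1e-12 * max(float(np.sum((y - y.mean()) ** 2)), 1e-300):
                break

        # entry step
        best = None   # (p, -|t|, name)
        for name in names:
            if name in selected:
                continue
            trial = candidates[selected + [name]]
            if not _rank_ok(trial):
                continue
            res = _fit_quiet(trial, y)
            p, t = float(res.pvalues[name]), float(res.tvalues[name])
            if criteria.criterion == "pvalue":
                if p < criteria.p_enter:
                    key = (p, -abs(t), name)
                    if best is None or key < best[0]:
                        best = (key, name)
            else:
                cur_aic = _fit_quiet(candidates[selected], y).aic if selected else _fit_quiet(
                    pd.DataFrame(index=candidates.index), y
                ).aic
                if res.aic < cur_aic - 1e-9:
                    key = (res.aic, -abs(t), name)
                    if best is None or key < best[0]:
                        best = (key, name)
        if best is not None:
            selected.append(best[1])
            logger.info("stepwise: entered %s", best[1])
            changed = True

        # removal step
        if selected:
            res = _fit_quiet(candidates[selected], y)
            if criteria.criterion == "pvalue":
                worst = None
                for name in selected:
                    p, t = float(res.pvalues[name]), float(res.tvalues[name])
                    if p > criteria.p_remove:
                        key = (-p, -abs(t), name)
                        if worst is None or key < worst[0]:
                            worst = (key, name)
                if worst is not None:
                    selected.remove(worst[1])
                    logger.info("stepwise: removed %s", worst[1])
                    changed = True
            else:
                cur_aic = res.aic
                worst = None
                for name in selected:
                    rest = [s for s in selected if s != name]
                    a = _fit_quiet(candidates[rest], y).aic if rest else _fit_quiet(
                        pd.DataFrame(index=candidates.index), y
                    ).aic
                    if a < cur_aic - 1e-9 and (worst is None or a < worst[0]):
                        worst = (a, name)
                if worst is not None:
                    selected.remove(worst[1])
                    logger.info("stepwise: removed %s", worst[1])
                    changed = True

        if not changed:
            break

    if not selected:
        logger.warning("stepwise: no candidate passed entry; returning intercept-only model")
        res = _fit_quiet(pd.DataFrame(index=candidates.index), y)
        model = LURModel(
            selected=[],
            coefficients=res.params,
            residual_sd=float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0,
            r_squared=0.0,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            aic=float(res.aic),
        )
        return [], model
    return selected, fit_ols(candidates[selected], y)


def best_subset_aic(candidates: pd.DataFrame, y) -> tuple[list[str], float]:
    """Exhaustive best-subset search by AIC (oracle for small candidate pools)."""
    names = list(candidates.columns)
    if len(names) > 16:
        raise ValueError("best-subset enumeration limited to ≤ 16 candidates")
    y = np.asarray(y, dtype=float)
    best_names, best_aic = [], _fit_quiet(pd.DataFrame(index=candidates.index), y).aic
    for mask in range(1, 2 ** len(names)):
        subset = [names[i] for i in range(len(names)) if mask >> i & 1]
        if not _rank_ok(candidates[subset]):
            continue
        a = _fit_quiet(candidates[subset], y).aic
        if a < best_aic:
            best_aic, best_names = a, subset
    return best_names, float(best_aic)
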