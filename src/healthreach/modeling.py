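"""Covariate modeling of access: forests and mixed-effects models.

Workflow: draw random points in the study area, extract the co-registered
layers (population density, poverty, sub-region, walking minutes and
bicycle-minutes-saved per facility level), screen predictors for
collinearity (VIF), split train/test, then fit

* a tuned random-forest regressor per response (hyperparameters chosen by
  out-of-bag MAE), with permutation mean-decrease-in-accuracy importance and
  boxplot-trimmed partial dependence; and
* linear mixed-effects models with a sub-region random intercept over the
  five candidate fixed-effect sets {null, poverty, density, poverty+density,
  poverty+density+interaction}, predictors normalized by Tukey's ladder of
  powers and centered, selected by lowest BIC;

and finally compare the two families head-to-head on the held-out test set
(MAE, RMSE, predictive R²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

import statsmodels.api as sm

from .traveltime import Tier

__all__ = [
    "SampleTable",
    "ModelFitResult",
    "TukeyTransform",
    "sample_points",
    "vif_screen",
    "split",
    "fit_forest",
    "conditional_importance",
    "partial_dependence",
    "tukey_transform",
    "fit_mixed_models",
    "compare_models",
    "regression_metrics",
]

WALK_COLS = {t: f"walk_{t.name.lower()}" for t in Tier}
SAVED_COLS = {t: f"saved_{t.name.lower()}" for t in Tier}


def sample_points(scene, walk_surfaces, bike_surfaces, n: int = 5000, seed: int = 0,
                  max_retries: int = 50) -> pd.DataFrame:
    """Random points in the study area with the 15 extracted layers.

    ``walk_surfaces`` / ``bike_surfaces`` map each tier to its travel-time
    surface. Points whose extraction hits a no-data value (unreachable cell)
    are resampled, with a note, up to ``max_retries`` rounds.
    """
    rng = np.random.default_rng(seed)
    grid = scene.grid
    mask_cells = np.nonzero(scene.study_mask.ravel())[0]
    density = scene.density

    def extract(cells):
        rr, cc = np.unravel_index(cells, grid.shape)
        x, y = grid.rowcol_to_xy(rr, cc)
        cols = {
            "x": x,
            "y": y,
            "subregion": scene.subregions.labels[rr, cc],
            "density": density[rr, cc],
            "poverty": scene.poverty[rr, cc],
        }
        for t in Tier:
            w = walk_surfaces[t].minutes[rr, cc]
            b = bike_surfaces[t].minutes[rr, cc]
            cols[WALK_COLS[t]] = w
            with np.errstate(invalid="ignore"):  # inf - inf on unreachable cells
                cols[SAVED_COLS[t]] = w - b
        return pd.DataFrame(cols)

    rows = []
    need = n
    for attempt in range(max_retries):
        cells = rng.choice(mask_cells, size=need, replace=True)
        df = extract(cells)
        ok = np.isfinite(df.drop(columns=["subregion"]).to_numpy()).all(axis=1)
        rows.append(df[ok])
        dropped = int((~ok).sum())
        if dropped == 0:
            break
        warnings.warn(f"resampling {dropped} point(s) that landed on no-data cells",
                      stacklevel=2)
        need = dropped
    out = pd.concat(rows, ignore_index=True).iloc[:n].reset_index(drop=True)
    if len(out) < n:
        raise RuntimeError("could not place all points on valid cells")
    return out


# Backwards-friendly alias used in docs
SampleTable = pd.DataFrame


def vif_screen(table: pd.DataFrame, predictors: list[str], threshold: float = 10.0):
    """Iterative variance-inflation-factor screening.

    VIF_j = 1 / (1 − R²_j) from regressing predictor j on the others; the
    worst offender above ``threshold`` is dropped until all pass. Returns
    ``(retained, vif_series)``.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    retained = list(predictors)
    while True:
        X = table[retained].to_numpy(dtype=float)
        vifs = {}
        for j, name in enumerate(retained):
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(len(X)), others])
            beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            resid = X[:, j] - A @ beta
            ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
            r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        series = pd.Series(vifs)
        worst = series.idxmax()
        if series[worst] <= threshold or len(retained) <= 1:
            return retained, series
        warnings.warn(f"dropping {worst} (VIF={series[worst]:.1f})", stacklevel=2)
        retained.remove(worst)


def split(table: pd.DataFrame, train_frac: float = 0.85, seed: int = 0):
    """Disjoint exhaustive train/test split, sizes round(n·frac) / remainder."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = int(round(n * train_frac))
    perm = rng.permutation(n)
    return (
        table.iloc[perm[:n_train]].reset_index(drop=True),
        table.iloc[perm[n_train:]].reset_index(drop=True),
    )


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """MAE, RMSE and predictive R² (1 − SS_res/SS_tot; may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / ss_tot) if ss_tot > 0 else np.nan
    return {"MAE": mae, "RMSE": rmse, "R2": r2}


@dataclass
class ModelFitResult:
    """Fitted-model metadata for one (response, learner) pair."""

    kind: str  # "forest" | "mixed"
    response: str
    hyperparams: dict = field(default_factory=dict)
    importance: pd.DataFrame | None = None
    coefficients: pd.DataFrame | None = None
    variance_components: dict = field(default_factory=dict)
    bic: float | None = None
    metrics: dict = field(default_factory=dict)
    model: object = None
    extra: dict = field(default_factory=dict)


FOREST_PREDICTORS = ["density", "poverty", "subregion"]


def _forest_matrix(table: pd.DataFrame, predictors=FOREST_PREDICTORS):
    X = table[list(predictors)].copy()
    if "subregion" in X:
        X["subregion"] = X["subregion"].astype(int)  # categorical codes; trees split on them
    return X.to_numpy(dtype=float)


def fit_forest(
    train: pd.DataFrame,
    test: pd.DataFrame,
    response: str,
    mtry_grid=(1, 2, 3),
    ntree_grid=(500,),
    seed: int = 0,
    predictors=None,
) -> ModelFitResult:
    """Random forest tuned over (mtry, ntree) by out-of-bag MAE.

    mtry is the number of predictors considered at each split; ntree the
    ensemble size. The winning model is evaluated on the held-out test set.
    """
    if len(mtry_grid) == 0 or len(ntree_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if predictors is None:
        predictors = list(FOREST_PREDICTORS)
    X = _forest_matrix(train, predictors)
    y = train[response].to_numpy(dtype=float)
    best = None
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            est = RandomForestRegressor(
                n_estimators=int(ntree),
                max_features=int(mtry),
                oob_score=True,
                bootstrap=True,
                random_state=int(seed),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
                est.fit(X, y)
            oob = est.oob_prediction_
            have = np.isfinite(oob)
            oob_mae = float(np.mean(np.abs(y[have] - oob[have])))
            if best is None or oob_mae < best[0]:
                best = (oob_mae, mtry, ntree, est)
    oob_mae, mtry, ntree, est = best
    pred = est.predict(_forest_matrix(test, predictors))
    return ModelFitResult(
        kind="forest",
        response=response,
        hyperparams={"mtry": mtry, "ntree": ntree, "oob_mae": oob_mae},
        metrics=regression_metrics(test[response], pred),
        model=est,
        extra={"predictors": list(predictors)},
    )


def conditional_importance(
    result: ModelFitResult, table: pd.DataFrame, n_iter: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Out-of-bag permutation mean-decrease-in-accuracy, averaged over runs.

    For every tree, the increase in MAE on that tree's out-of-bag samples
    when one predictor column is permuted, averaged over trees and over
    ``n_iter`` random permutations; ranks by descending score. Using OOB
    samples (rather than the training rows a tree has memorized) keeps the
    score of an uninformative predictor near zero.
    """
    rng = np.random.default_rng(seed)
    est = result.model
    predictors = result.extra["predictors"]
    X = _forest_matrix(table, predictors)
    y = table[result.response].to_numpy(dtype=float)
    n = len(y)
    scores = {name: [] for name in predictors}
    for tree, inbag in zip(est.estimators_, est.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[inbag] = False
        if not oob.any():
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean(np.abs(yo - tree.predict(Xo)))
        for j, name in enumerate(predictors):
            deltas = []
            for _ in range(n_iter):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                deltas.append(np.mean(np.abs(yo - tree.predict(Xp))) - base)
            scores[name].append(np.mean(deltas))
    df = pd.DataFrame({"score": pd.Series({k: float(np.mean(v)) for k, v in scores.items()})})
    df["rank"] = df["score"].rank(ascending=False, method="first").astype(int)
    result.importance = df
    return df


def partial_dependence(
    result: ModelFitResult, table: pd.DataFrame, variable: str, n_grid: int = 25
):
    """Partial-dependence curve with boxplot-fence outlier trimming.

    The evaluation grid spans [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the training
    values (clipped to the observed range); other predictors keep their
    observed joint values.
    """
    predictors = result.extra["predictors"]
    j = predictors.index(variable)
    X = _forest_matrix(table, predictors)
    col = X[:, j]
    q1, q3 = np.percentile(col, [25, 75])
    iqr = q3 - q1
    lo = max(col.min(), q1 - 1.5 * iqr)
    hi = min(col.max(), q3 + 1.5 * iqr)
    grid = np.linspace(lo, hi, n_grid)
    curve = np.empty(n_grid)
    for g, val in enumerate(grid):
        Xg = X.copy()
        Xg[:, j] = val
        curve[g] = float(np.mean(result.model.predict(Xg)))
    return grid, curve


@dataclass
class TukeyTransform:
    """A fitted ladder-of-powers normalizing transform."""

    lmbda: float
    shift: float
    center: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if self.lmbda > 0:
            t = x**self.lmbda
        elif self.lmbda == 0:
            t = np.log(x)
        else:
            t = -(x**self.lmbda)
        return t - self.center


def tukey_transform(x, grid=None, seed: int = 0):
    """Tukey's ladder of powers toward normality, then centering.

    λ is chosen from a grid (default −2…2 in steps of 0.025) maximizing the
    Shapiro–Wilk W statistic (on a capped subsample of 5000); the transform
    is x^λ for λ>0, log x for λ=0, −x^λ for λ<0. Non-positive inputs get a
    positive shift first (with a warning). Output is centered to mean 0.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant input: transform undefined")
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.025), 6)
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
        warnings.warn(f"applying positive shift {shift:.6g} before the power ladder",
                      stacklevel=2)
    xs = x + shift
    rng = np.random.default_rng(seed)
    sub = xs if len(xs) <= 5000 else rng.choice(xs, 5000, replace=False)
    best_w, best_l = -np.inf, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in grid:
            if lam > 0:
                t = sub**lam
            elif lam == 0:
                t = np.log(sub)
            else:
                t = -(sub**lam)
            if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
                continue
            w = stats.shapiro(t).statistic
            if w > best_w:
                best_w, best_l = w, float(lam)
    tf = TukeyTransform(lmbda=best_l, shift=shift, center=0.0)
    tf.center = float(tf(x).mean())
    return tf, tf(x)


MIXED_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("poverty_t",),
    ("density_t",),
    ("poverty_t", "density_t"),
    ("poverty_t", "density_t", "interaction"),
)


def _prepare_mixed(train: pd.DataFrame, test: pd.DataFrame, seed: int = 0):
    """Transform + center poverty and density on the train set; add interaction."""
    out = {}
    for name in ("poverty", "density"):
        tf, t_train = tukey_transform(train[name].to_numpy(), seed=seed)
        out[name] = tf
        train = train.assign(**{f"{name}_t": t_train})
        test = test.assign(**{f"{name}_t": tf(test[name].to_numpy())})
    train = train.assign(interaction=train["poverty_t"] * train["density_t"])
    test = test.assign(interaction=test["poverty_t"] * test["density_t"])
    return train, test, out


def _fit_one_mixed(train, response, fixed):
    exog = sm.add_constant(train[list(fixed)]) if fixed else pd.DataFrame(
        {"const": np.ones(len(train))}, index=train.index
    )
    model = sm.MixedLM(train[response], exog, groups=train["subregion"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    n = len(train)
    k = exog.shape[1] + 2  # fixed effects + residual var + random-intercept var
    bic = -2.0 * res.llf + k * np.log(n)
    return res, bic


def _mixed_predict(res, exog, groups):
    fe = np.asarray(exog @ res.fe_params)
    re = res.random_effects
    offsets = np.array([float(re[g].iloc[0]) if g in re else 0.0 for g in groups])
    return fe + offsets


def fit_mixed_models(
    train: pd.DataFrame, test: pd.DataFrame, response: str, seed: int = 0
):
    """All candidate mixed models for one response; best chosen by BIC.

    Candidates are the five fixed-effect sets (interaction only with both
    mains), each with a sub-region random intercept. The null model doubles
    as the check that the grouping variable carries variance (reported via
    its ICC and a likelihood-ratio test against plain OLS). Returns
    ``(best ModelFitResult, list of all candidates)``.
    """
    train, test, transforms = _prepare_mixed(train, test, seed=seed)
    results = []
    for fixed in MIXED_CANDIDATES:
        try:
            res, bic = _fit_one_mixed(train, response, fixed)
        except Exception as exc:  # singular fit: drop the candidate
            warnings.warn(f"candidate {fixed or ('null',)} dropped: {exc}", stacklevel=2)
            continue
        sigma2 = float(res.scale)
        tau00 = float(res.cov_re.iloc[0, 0])
        icc = tau00 / (tau00 + sigma2)
        exog_t = sm.add_constant(test[list(fixed)], has_constant="add") if fixed else pd.DataFrame(
            {"const": np.ones(len(test))}, index=test.index
        )
        pred = _mixed_predict(res, exog_t, test["subregion"].to_numpy())
        names = list(res.fe_params.index)
        ci = res.conf_int().loc[names]
        coef = pd.DataFrame(
            {
                "Estimate": res.fe_params,
                "SE": res.bse.loc[names],
                "CI_low": ci[0],
                "CI_high": ci[1],
                "t": res.tvalues.loc[names],
                "p": res.pvalues.loc[names],
            }
        )
        results.append(
            ModelFitResult(
                kind="mixed",
                response=response,
                hyperparams={"fixed_effects": fixed},
                coefficients=coef,
                variance_components={"sigma2": sigma2, "tau00": tau00, "ICC": icc},
                bic=float(bic),
                metrics=regression_metrics(test[response], pred),
                model=res,
                extra={"transforms": transforms},
            )
        )
    if not results:
        raise RuntimeError("all mixed-model candidates failed to fit")
    # null-model grouping check: LRT of the random intercept vs pooled OLS
    null = next((r for r in results if r.hyperparams["fixed_effects"] == ()), None)
    if null is not None:
        ols = sm.OLS(train[response], np.ones(len(train))).fit()
        lr = 2.0 * (null.model.llf - ols.llf)
        # boundary-corrected chi²₁ p-value, halved
        null.extra["grouping_lrt_p"] = float(0.5 * stats.chi2.sf(max(lr, 0.0), 1))
    best = min(results, key=lambda r: r.bic)
    return best, results


def compare_models(forest_results, mixed_results) -> pd.DataFrame:
    """Per-response accuracy deltas, forest as the reference.

    Positive ΔR² (= forest − mixed) and negative ΔMAE/ΔRMSE mean the forest
    predicts better.
    """
    fmap = {r.response: r for r in forest_results}
    mmap = {r.response: r for r in mixed_results}
    if set(fmap) != set(mmap):
        raise ValueError("forest and mixed results cover different responses")
    rows = []
    for resp in fmap:
        f, m = fmap[resp].metrics, mmap[resp].metrics
        rows.append(
            {
                "response": resp,
                "dMAE": f["MAE"] - m["MAE"],
                "dRMSE": f["RMSE"] - m["RMSE"],
                "dR2": f["R2"] - m["R2"],
            }
        )
    return pd.DataFrame(rows)
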