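"""Elastic-net immune-age model with leave-one-out cross-validation.

The model regresses gestational age (weeks) on the standardized immune
feature matrix with an elastic-net penalty

    (1/2n) ||y - X b||^2 + lam * (alpha ||b||_1 + (1 - alpha)/2 ||b||_2^2)

using the glmnet parameterization: ``alpha`` is the L1/L2 mixing weight and
``lam`` the overall penalty strength.  Hyperparameters are chosen on a
(alpha x lam) grid by leave-one-out cross-validation (LOOCV): every sample
is predicted exactly once by a model trained entirely without it, the grid
point minimizing the LOOCV mean squared error is selected (ties broken
toward stronger regularization), and the reported predictions are those
blinded LOOCV predictions at the selected grid point.  Standardization
(feature centering/scaling, response centering) is recomputed inside every
training fold so no statistic of the held-out sample leaks into training.

Reported performance is the Spearman correlation between the blinded
predictions and the true GA.  Note that because the same LOOCV errors both
choose the hyperparameters and assess the model, the performance estimate
is mildly optimistic; ``nested=True`` runs an inner LOOCV per outer fold to
remove that optimism at ~n-fold extra cost.

`ImmuneAgeResults.bootstrap` runs stability selection: the elastic net is
refit on ``B`` resamples (n samples drawn with replacement), and the number
of resamples in which each feature receives a nonzero coefficient is
tallied.  By default the resample fits use *stability hyperparameters*
rather than the prediction-optimal pair: the mixing parameter is fixed at
the smallest grid value (the ridge-leaning end, whose grouping effect
selects correlated feature blocks together instead of arbitrary single
representatives) and the penalty is the one-standard-error LOOCV choice at
that mixing (the sparser model whose cross-validated error is within one
standard error of the minimum — the standard parsimony rule for penalized
selection).  Features selected in at least ``threshold_frac * B`` resamples
(default 0.6, inside the usual stability-selection threshold range) form
the *informative* set; passing ``threshold=1`` recovers the most inclusive
"ever selected" reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path

from .errors import ValidationError
from .features import FeatureMatrix

__all__ = [
    "ImmuneAgeModel",
    "ImmuneAgeResults",
    "BootstrapTally",
    "fit_en_loocv",
    "model_performance",
    "bootstrap_en",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
DEFAULT_N_LAMBDA = 50
DEFAULT_LAMBDA_MIN_RATIO = 1e-3
DEFAULT_THRESHOLD_FRAC = 0.6


def _standardize(X: np.ndarray, y: np.ndarray):
    """Column-standardize X and center y; zero-variance columns are frozen."""
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=0)
    xs = np.where(xs == 0.0, 1.0, xs)
    ym = y.mean()
    return (X - xm) / xs, y - ym, xm, xs, ym


def _lambda_path(Xs, yc, alpha, n_lambda, min_ratio):
    """glmnet-style log-spaced penalty path from the maximal absolute
    feature-response covariance."""
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def _spearman(pred, y):
    if np.all(pred == pred[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(pred, y)
    return float(rho), float(p)


@dataclass
class BootstrapTally:
    """Outcome of elastic-net bootstrap stability selection."""

    B: int
    counts: pd.Series
    threshold: float
    skipped: int = 0

    @property
    def informative(self) -> list:
        """Feature ids selected in at least ``threshold`` resamples."""
        return list(self.counts.index[self.counts >= self.threshold])

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("count").to_frame()
        df["frequency"] = df["count"] / max(self.B, 1)
        df["informative"] = df["count"] >= self.threshold
        return df


class ImmuneAgeModel:
    """Penalized linear model of gestational age on immune features.

    Parameters
    ----------
    X : FeatureMatrix or pandas.DataFrame
        Samples x features (pre-processed).
    ga : array-like
        Gestational age at sampling, weeks, aligned with the rows of ``X``.
    alpha_grid : sequence of float
        Elastic-net mixing values in (0, 1] to search.
    n_lambda, lambda_min_ratio : int, float
        Penalty path resolution and dynamic range.
    penalty_weights : ignored features
        Optional per-feature multiplicative penalty factors; features with
        weight ``inf`` are excluded from the design (hard penalization).

    Examples
    --------
    >>> model = ImmuneAgeModel(X, cohort["ga_weeks"])
    >>> res = model.fit()
    >>> res.rho, res.alpha, res.lam
    """

    def __init__(
        self,
        X,
        ga,
        alpha_grid=DEFAULT_ALPHA_GRID,
        n_lambda: int = DEFAULT_N_LAMBDA,
        lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
        lambda_grid=None,
        penalty_weights=None,
    ):
        values = X.values if isinstance(X, FeatureMatrix) else X
        self.feature_matrix = X if isinstance(X, FeatureMatrix) else None
        self.feature_ids = list(values.columns)
        self.sample_ids = list(values.index)
        self.X = values.to_numpy(float)
        self.y = np.asarray(ga, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValidationError("X and ga are misaligned")
        if self.X.shape[0] < 5:
            raise ValidationError("need at least 5 samples")
        if np.all(self.y == self.y[0]):
            raise ValidationError("GA is constant; nothing to model")
        self.alpha_grid = tuple(float(a) for a in alpha_grid)
        if len(self.alpha_grid) == 0:
            raise ValidationError("alpha grid is empty")
        if any(a <= 0 or a > 1 for a in self.alpha_grid):
            raise ValidationError("alpha values must lie in (0, 1]")
        if lambda_grid is not None and len(lambda_grid) == 0:
            raise ValidationError("lambda grid is empty")
        self.lambda_grid = None if lambda_grid is None else np.asarray(lambda_grid, float)
        self.n_lambda = int(n_lambda)
        self.lambda_min_ratio = float(lambda_min_ratio)
        if penalty_weights is not None:
            w = pd.Series(penalty_weights).reindex(self.feature_ids).fillna(1.0)
            keep = ~np.isinf(w.to_numpy())
            self.X = self.X[:, keep]
            self.feature_ids = list(np.asarray(self.feature_ids, object)[keep])

    # -- internals ----------------------------------------------------------

    def _grids(self):
        Xs, yc, *_ = _standardize(self.X, self.y)
        grids = {}
        for alpha in self.alpha_grid:
            if self.lambda_grid is not None:
                grids[alpha] = np.sort(self.lambda_grid)[::-1]
            else:
                grids[alpha] = _lambda_path(
                    Xs, yc, alpha, self.n_lambda, self.lambda_min_ratio
                )
        return grids

    def _loocv_predictions(self, alpha, lams):
        """Blinded LOOCV predictions for every lambda on the path."""
        n = self.X.shape[0]
        preds = np.empty((n, lams.size))
        for i in range(n):
            tr = np.arange(n) != i
            Xs, yc, xm, xs, ym = _standardize(self.X[tr], self.y[tr])
            _, coefs, _ = enet_path(
                Xs, yc, l1_ratio=alpha, alphas=lams, check_input=True,
                tol=1e-3, max_iter=2000,
            )
            xi = (self.X[i] - xm) / xs
            preds[i] = xi @ coefs + ym
        return preds

    # -- fitting ------------------------------------------------------------

    def fit(self, nested: bool = False) -> "ImmuneAgeResults":
        """Grid-search hyperparameters by LOOCV and fit the final model.

        Returns an :class:`ImmuneAgeResults` carrying the blinded LOOCV
        predictions at the selected grid point, the selected
        hyperparameters, the full-data coefficient vector at those
        hyperparameters, and Spearman performance.
        """
        grids = self._grids()
        n = len(self.y)
        best = None  # (mse, lam, alpha, preds_column)
        cv_table = []
        for alpha in self.alpha_grid:
            lams = grids[alpha]
            preds = self._loocv_predictions(alpha, lams)
            err = (preds - self.y[:, None]) ** 2
            mse = err.mean(axis=0)
            se = err.std(axis=0, ddof=1) / np.sqrt(n)
            for k, lam in enumerate(lams):
                cv_table.append((alpha, float(lam), float(mse[k]), float(se[k])))
                cand = (mse[k], -lam, -alpha)
                if best is None or cand < best[0]:
                    best = (cand, alpha, float(lam), preds[:, k].copy())
        _, alpha, lam, predictions = best

        # stability hyperparameters: smallest mixing value; 1-SE penalty there
        cv = pd.DataFrame(cv_table, columns=["alpha", "lam", "loocv_mse", "loocv_se"])
        a_st = min(self.alpha_grid)
        row = cv[cv["alpha"] == a_st].reset_index(drop=True)  # lam descending
        k_min = int(row["loocv_mse"].idxmin())
        limit = row.loc[k_min, "loocv_mse"] + row.loc[k_min, "loocv_se"]
        lam_st = float(row.loc[(row["loocv_mse"] <= limit).idxmax(), "lam"])

        if nested:
            predictions = self._nested_predictions()

        Xs, yc, xm, xs, ym = _standardize(self.X, self.y)
        final = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False, max_iter=5000)
        final.fit(Xs, yc)
        coef = pd.Series(final.coef_, index=self.feature_ids, name="coef_std")
        if (coef == 0.0).all():
            # Empty (intercept-only) model: the LOOCV predictions are the
            # training fold means, which are anti-monotone in the held-out
            # response by construction and say nothing about the features.
            # The association is undefined, not negative.
            rho, p = float("nan"), float("nan")
        else:
            rho, p = _spearman(predictions, self.y)
        return ImmuneAgeResults(
            model=self,
            predictions=pd.Series(predictions, index=self.sample_ids, name="ga_pred"),
            alpha=alpha,
            lam=lam,
            coef=coef,
            rho=rho,
            pvalue=p,
            cv_table=cv,
            stability_alpha=a_st,
            stability_lam=lam_st,
            nested=nested,
        )

    def _nested_predictions(self):
        """Outer-LOOCV predictions with hyperparameters re-tuned per fold."""
        n = self.X.shape[0]
        preds = np.empty(n)
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            inner = ImmuneAgeModel(
                pd.DataFrame(self.X[tr], columns=self.feature_ids),
                self.y[tr],
                alpha_grid=self.alpha_grid,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
            )
            res = inner.fit(nested=False)
            Xs, yc, xm, xs, ym = _standardize(self.X[tr], self.y[tr])
            est = ElasticNet(
                alpha=res.lam, l1_ratio=res.alpha, fit_intercept=False, max_iter=5000
            )
            est.fit(Xs, yc)
            preds[i] = ((self.X[i] - xm) / xs) @ est.coef_ + ym
        return preds


@dataclass
class ImmuneAgeResults:
    """Fitted immune-age model: blinded predictions, hyperparameters,
    coefficients and performance."""

    model: ImmuneAgeModel
    predictions: pd.Series
    alpha: float
    lam: float
    coef: pd.Series
    rho: float
    pvalue: float
    cv_table: pd.DataFrame = field(repr=False, default=None)
    stability_alpha: float = None
    stability_lam: float = None
    nested: bool = False

    @property
    def selected_features(self) -> list:
        """Features with nonzero coefficients in the full-data fit."""
        return list(self.coef.index[self.coef != 0.0])

    def performance(self) -> dict:
        return {"rho": self.rho, "p": self.pvalue}

    def summary(self) -> str:
        lines = [
            "Immune-age elastic-net model (LOOCV)",
            "=" * 44,
            f"samples                {len(self.predictions)}",
            f"features               {len(self.coef)}",
            f"mixing alpha           {self.alpha:.2f}",
            f"penalty lambda         {self.lam:.4g}",
            f"nonzero coefficients   {len(self.selected_features)}",
            f"Spearman rho (blinded) {self.rho:.3f}",
            f"two-sided p            {self.pvalue:.3g}",
            f"nested CV              {self.nested}",
        ]
        return "\n".join(lines)

    # -- downstream analyses -------------------------------------------------

    def bootstrap(
        self,
        B: int = 1000,
        threshold: float | None = None,
        threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
        seed: int = 0,
        retune: bool = False,
        hyperparams: str = "stability",
    ) -> BootstrapTally:
        """Stability selection; see :func:`bootstrap_en`.

        ``hyperparams`` chooses the fixed resample-fit hyperparameters:
        ``"stability"`` (default; smallest-mixing / 1-SE penalty) or
        ``"selected"`` (the prediction-optimal LOOCV pair).
        """
        if hyperparams == "stability":
            a, l = self.stability_alpha, self.stability_lam
        elif hyperparams == "selected":
            a, l = self.alpha, self.lam
        else:
            raise ValidationError("hyperparams must be 'stability' or 'selected'")
        return bootstrap_en(
            self.model,
            B=B,
            alpha=a,
            lam=l,
            threshold=threshold,
            threshold_frac=threshold_frac,
            seed=seed,
            retune=retune,
        )

    def confounder_analysis(self, cohort: pd.DataFrame, covariates=None) -> pd.DataFrame:
        from .confounders import run_all_confounders

        return run_all_confounders(cohort, self, covariates=covariates)


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------


def fit_en_loocv(
    X,
    ga,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=None,
    seed: int = 0,
    nested: bool = False,
) -> ImmuneAgeResults:
    """Fit the elastic-net GA model with LOOCV hyperparameter selection.

    ``seed`` is accepted for interface uniformity; the fit itself is
    deterministic (cyclic coordinate descent on a fixed grid).
    """
    model = ImmuneAgeModel(X, ga, alpha_grid=alpha_grid, lambda_grid=lambda_grid)
    return model.fit(nested=nested)


def model_performance(result: ImmuneAgeResults, ga) -> dict:
    """Spearman rho and two-sided p of blinded predictions versus GA."""
    ga = np.asarray(ga, float)
    pred = result.predictions.to_numpy()
    if pred.size != ga.size:
        raise ValidationError("predictions and GA are misaligned")
    rho, p = _spearman(pred, ga)
    return {"rho": rho, "p": p}


def bootstrap_en(
    model: ImmuneAgeModel,
    B: int = 1000,
    alpha: float = 0.5,
    lam: float = 0.1,
    threshold: float | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    seed: int = 0,
    retune: bool = False,
) -> BootstrapTally:
    """Bootstrap stability selection for the elastic net.

    Each of the ``B`` iterations resamples the cohort with replacement,
    refits the elastic net (at the supplied hyperparameters, or re-tuned
    per iteration when ``retune=True``) and increments the tally of every
    feature with a nonzero coefficient.  A resample with constant GA cannot
    be fit; it is skipped, recorded in ``skipped``, and excluded from the
    effective ``B``.  The per-iteration RNG stream is split from ``seed``,
    so tallies are reproducible.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    n, p = model.X.shape
    counts = np.zeros(p, dtype=int)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=B)
    skipped = 0
    effective = 0
    for b in range(B):
        it_rng = np.random.default_rng(seeds[b])
        idx = it_rng.integers(0, n, size=n)
        yb = model.y[idx]
        if np.all(yb == yb[0]):
            skipped += 1
            continue
        Xb = model.X[idx]
        Xs, yc, *_ = _standardize(Xb, yb)
        if retune:
            inner = ImmuneAgeModel(
                pd.DataFrame(Xb, columns=model.feature_ids),
                yb,
                alpha_grid=model.alpha_grid,
                n_lambda=model.n_lambda,
                lambda_min_ratio=model.lambda_min_ratio,
            )
            res = inner.fit()
            a_b, l_b = res.alpha, res.lam
        else:
            a_b, l_b = alpha, lam
        est = ElasticNet(alpha=l_b, l1_ratio=a_b, fit_intercept=False, max_iter=5000)
        est.fit(Xs, yc)
        counts += est.coef_ != 0.0
        effective += 1
    if threshold is None:
        threshold = max(1.0, threshold_frac * effective)
    return BootstrapTally(
        B=effective,
        counts=pd.Series(counts, index=model.feature_ids, name="count"),
        threshold=float(threshold),
        skipped=skipped,
    )
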