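"""Phylogenetic generalized least squares with Pagel's lambda, all-subsets
AIC ranking and model averaging.

``PGLS`` follows the statsmodels model/results idiom: build the model from a
response, a design and a tree (or from a DataFrame), call :meth:`PGLS.fit`
and read estimates, standard errors, AIC and a text ``summary()`` from the
returned :class:`PGLSResults`.  The multimodel machinery — all predictor
subsets, Akaike weights, the 95% cumulative-weight confidence set, and
conditional (natural) model averaging with Burnham–Anderson unconditional
standard errors — lives in :func:`fit_model_set` /
:class:`ModelSelectionResults`.

The GLS error covariance is ``sigma^2 * V(lambda)`` with V the
Brownian-motion tip covariance of the tree and lambda scaling its
off-diagonal.  lambda may be fixed or jointly profiled by maximum
likelihood per model (default); under joint ML the AIC parameter count is
``#coefficients + 2`` (sigma^2 and lambda).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylosignal import apply_lambda
from .trees import covariance_for_labels

__all__ = [
    "PGLS",
    "PGLSResults",
    "enumerate_models",
    "akaike_weights",
    "confidence_set",
    "model_average",
    "fit_model_set",
    "ModelSelectionResults",
]

MAX_SUBSET_PREDICTORS = 12


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name columns whose removal restores full rank
    collinear = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            collinear.append(names[j])
    raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


class PGLS:
    """Phylogenetic GLS regression model.

    Parameters
    ----------
    endog
        Response vector (one value per species).
    exog
        Design matrix *without* intercept; a constant column is prepended.
    tree / V
        Phylogeny (dendropy) or a precomputed Brownian covariance matrix
        aligned with ``species``.
    species
        Species labels aligning rows with tree tips (required with
        ``tree``).
    exog_names
        Column names for ``exog``.
    """

    def __init__(self, endog, exog, tree=None, V=None, species=None, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("endog and exog lengths differ")
        if V is None:
            if tree is None:
                raise ValueError("provide either tree or V")
            if species is None:
                raise ValueError("species labels are required with a tree")
            V = covariance_for_labels(tree, list(species))
        V = np.asarray(V, dtype=float)
        if V.shape != (y.size, y.size):
            raise ValueError("covariance dimension does not match data")
        names = list(exog_names) if exog_names is not None else [
            f"x{j+1}" for j in range(X.shape[1])
        ]
        X = np.column_stack([np.ones(y.size), X])
        names = ["intercept"] + names
        _check_full_rank(X, names)
        self.endog = y
        self.exog = X
        self.exog_names = names
        self.V = V
        self.nobs = y.size

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors, tree=None, V=None):
        """Build from a species-indexed DataFrame (index = species labels)."""
        predictors = list(predictors)
        if response in predictors:
            raise ValueError("response cannot appear among predictors")
        y = data[response]
        X = data[predictors] if predictors else pd.DataFrame(index=data.index)
        return cls(
            y.to_numpy(),
            X.to_numpy(dtype=float) if predictors else np.empty((len(data), 0)),
            tree=tree,
            V=V,
            species=list(data.index),
            exog_names=predictors,
        )

    # -- GLS core -------------------------------------------------------
    def _gls(self, lam: float):
        V = apply_lambda(self.V, lam)
        y, X = self.endog, self.exog
        n, p = X.shape
        c, low = linalg.cho_factor(V)
        ViX = linalg.cho_solve((c, low), X)
        Viy = linalg.cho_solve((c, low), y)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, X.T @ Viy)
        r = y - X @ beta
        Vir = linalg.cho_solve((c, low), r)
        rss = float(r @ Vir)
        sigma2_ml = rss / n
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        if sigma2_ml <= 0:
            sigma2_ml = np.finfo(float).tiny
        llf = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
        sigma2_ub = rss / (n - p) if n > p else np.nan
        cov_params = sigma2_ub * np.linalg.inv(XtViX)
        return beta, cov_params, sigma2_ml, llf

    def loglik(self, lam: float) -> float:
        return self._gls(lam)[3]

    def fit(self, lambda_mode="ml", ci_level: float = 0.95) -> "PGLSResults":
        """Fit by GLS.

        ``lambda_mode``: ``"ml"`` profiles lambda jointly with the
        coefficients (21-point grid plus bounded refinement, boundaries
        evaluated); a float in [0, 1] fixes lambda.
        """
        if lambda_mode == "ml":
            grid = np.linspace(0.0, 1.0, 21)
            lls = [self.loglik(g) for g in grid]
            i = int(np.argmax(lls))
            lam, best = grid[i], lls[i]
            lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda l: -self.loglik(l), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > best:
                lam, best = float(res.x), float(-res.fun)
            for b in (0.0, 1.0):
                llb = self.loglik(b)
                if llb > best:
                    lam, best = b, llb
            lambda_estimated = True
        else:
            lam = float(lambda_mode)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("fixed lambda must lie in [0, 1]")
            lambda_estimated = False
        beta, cov, sigma2, llf = self._gls(lam)
        k = len(beta) + 1 + (1 if lambda_estimated else 0)  # + sigma2 (+ lambda)
        return PGLSResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            sigma2=sigma2,
            llf=llf,
            lam=lam,
            lambda_estimated=lambda_estimated,
            k_params=k,
            ci_level=ci_level,
        )


@dataclass
class PGLSResults:
    """Results of a single PGLS fit."""

    model: PGLS
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    llf: float
    lam: float
    lambda_estimated: bool
    k_params: int
    ci_level: float = 0.95

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.params)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.to_numpy()
        p = 2 * stats.t.sf(np.abs(t), df=self.df_resid)
        return pd.Series(p, index=self.params.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, df=self.df_resid)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        ci = self.conf_int()
        tbl = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "t": self.tvalues,
                "P>|t|": self.pvalues,
                "[0.025": ci["lower"],
                "0.975]": ci["upper"],
            }
        )
        head = (
            "Phylogenetic GLS (Pagel's lambda error structure)\n"
            f"n = {self.nobs}   lambda = {self.lam:.4f}"
            f" ({'ML' if self.lambda_estimated else 'fixed'})   "
            f"sigma2 = {self.sigma2:.6f}\n"
            f"logLik = {self.llf:.4f}   AIC = {self.aic:.4f}   k = {self.k_params}\n"
        )
        return head + tbl.to_string(float_format=lambda v: f"{v: .4f}")


# -- multimodel inference ----------------------------------------------


def enumerate_models(predictors, always=(), max_predictors: int = MAX_SUBSET_PREDICTORS):
    """All subsets of ``predictors``, each augmented with the ``always``
    terms, ordered by size then lexicographically (input order).

    The intercept-only (or always-terms-only) model is included.  More than
    ``max_predictors`` optional predictors is refused as a combinatorial
    guard.
    """
    predictors = list(predictors)
    always = list(always)
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictors")
    if len(predictors) > max_predictors:
        raise ValueError(
            f"{len(predictors)} predictors exceed the all-subsets limit "
            f"({max_predictors})"
        )
    models = []
    for size in range(len(predictors) + 1):
        for combo in itertools.combinations(predictors, size):
            models.append(tuple(always) + combo)
    return models


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-(AIC_i - AIC_min)/2), normalised to 1.

    Non-finite AICs receive zero weight with a warning.
    """
    aics = np.asarray(aics, dtype=float)
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("no finite AIC values")
    if not finite.all():
        warnings.warn("non-finite AIC values excluded from weights", stacklevel=2)
    w = np.zeros_like(aics)
    d = aics[finite] - aics[finite].min()
    ew = np.exp(-d / 2.0)
    w[finite] = ew / ew.sum()
    return w


def confidence_set(weights, threshold: float = 0.95, k_params=None) -> list[int]:
    """Indices of the smallest prefix of weight-ranked models whose
    cumulative Akaike weight exceeds ``threshold``.

    Ties in weight are broken by fewer parameters (when ``k_params`` is
    given), then by enumeration order.  ``threshold = 0`` returns the single
    top model.
    """
    w = np.asarray(weights, dtype=float)
    k = np.asarray(k_params) if k_params is not None else np.zeros(w.size)
    order = sorted(range(w.size), key=lambda i: (-w[i], k[i], i))
    out, cum = [], 0.0
    for i in order:
        out.append(i)
        cum += w[i]
        if cum > threshold:
            break
    return out


def model_average(fits, weights, terms=None, set_size=None) -> pd.DataFrame:
    """Conditional (natural) model averaging over a confidence set.

    For each term, the average is taken over the models containing it with
    weights renormalised over those models; the unconditional standard
    error follows Burnham & Anderson:
    ``SE = sum_i w_i * sqrt(SE_i^2 + (beta_i - beta_bar)^2)``.
    95%/90% CIs use normal quantiles (1.96 / 1.645).  Relative variable
    importance is the summed (set-renormalised) weight of containing
    models.

    Parameters
    ----------
    fits
        Sequence of :class:`PGLSResults` (the confidence set).
    weights
        Raw weights of those fits; renormalised to 1 here.
    terms
        Row order; defaults to the union of fitted terms (intercept first).

    Returns
    -------
    DataFrame indexed by term with columns estimate, se, ci95_low,
    ci95_high, ci90_low, ci90_high, importance, n_containing_models,
    significant_95, significant_90.
    """
    w = np.asarray(weights, dtype=float)
    if len(fits) != w.size or len(fits) == 0:
        raise ValueError("fits and weights must be non-empty and equal length")
    w = w / w.sum()
    if terms is None:
        terms = []
        for f in fits:
            for t in f.params.index:
                if t not in terms:
                    terms.append(t)
    rows = []
    for term in terms:
        has = np.array([term in f.params.index for f in fits])
        n_containing = int(has.sum())
        if n_containing == 0:
            rows.append(
                dict(term=term, estimate=np.nan, se=np.nan, ci95_low=np.nan,
                     ci95_high=np.nan, ci90_low=np.nan, ci90_high=np.nan,
                     importance=0.0, n_containing_models=0,
                     significant_95=False, significant_90=False)
            )
            continue
        wi = w[has]
        wt = wi / wi.sum()
        betas = np.array([f.params[term] for f, h in zip(fits, has) if h])
        ses = np.array([f.bse[term] for f, h in zip(fits, has) if h])
        bbar = float(wt @ betas)
        se = float(wt @ np.sqrt(ses**2 + (betas - bbar) ** 2))
        rows.append(
            dict(
                term=term,
                estimate=bbar,
                se=se,
                ci95_low=bbar - 1.96 * se,
                ci95_high=bbar + 1.96 * se,
                ci90_low=bbar - 1.645 * se,
                ci90_high=bbar + 1.645 * se,
                importance=float(wi.sum()),
                n_containing_models=n_containing,
                significant_95=bool(bbar - 1.96 * se > 0 or bbar + 1.96 * se < 0),
                significant_90=bool(bbar - 1.645 * se > 0 or bbar + 1.645 * se < 0),
            )
        )
    return pd.DataFrame(rows).set_index("term")


@dataclass
class ModelSelectionResults:
    """All-subsets PGLS: ranked candidates, confidence set and averages."""

    response: str
    candidates: list
    fits: list
    aics: np.ndarray
    weights: np.ndarray
    confidence_indices: list[int]
    threshold: float
    averaged: pd.DataFrame = field(repr=False)

    @property
    def n_models(self) -> int:
        return len(self.candidates)

    @property
    def confidence_set_size(self) -> int:
        return len(self.confidence_indices)

    def ranking(self) -> pd.DataFrame:
        order = np.argsort(self.aics, kind="stable")
        return pd.DataFrame(
            {
                "predictors": [" + ".join(self.candidates[i]) or "(intercept)" for i in order],
                "aic": self.aics[order],
                "delta_aic": self.aics[order] - self.aics.min(),
                "weight": self.weights[order],
            }
        )

    def summary(self) -> str:
        head = (
            f"All-subsets PGLS for response '{self.response}': "
            f"{self.n_models} candidate models, "
            f"{self.confidence_set_size} in the {self.threshold:.0%} "
            "cumulative-weight confidence set\n"
        )
        return head + self.averaged.to_string(float_format=lambda v: f"{v: .4f}")


def fit_model_set(
    data: pd.DataFrame,
    response: str,
    predictors,
    tree=None,
    V=None,
    always=(),
    lambda_mode="ml",
    threshold: float = 0.95,
) -> ModelSelectionResults:
    """Fit every predictor subset by PGLS, rank by AIC and model-average.

    ``always`` predictors are forced into every candidate model (used for
    the co-pigment term).  Weights are computed over the full candidate set,
    the >``threshold`` cumulative-weight confidence set is selected, its
    weights are renormalised, and conditional model averaging is performed.
    """
    if V is None:
        V = covariance_for_labels(tree, list(data.index))
    candidates = enumerate_models(predictors, always=always)
    fits, aics, ks = [], [], []
    for preds in candidates:
        m = PGLS.from_dataframe(data, response, list(preds), V=V)
        r = m.fit(lambda_mode=lambda_mode)
        fits.append(r)
        aics.append(r.aic)
        ks.append(r.k_params)
    aics = np.asarray(aics)
    weights = akaike_weights(aics)
    idx = confidence_set(weights, threshold=threshold, k_params=ks)
    terms = ["intercept"] + list(always) + [p for p in predictors]
    averaged = model_average(
        [fits[i] for i in idx], weights[idx], terms=terms
    )
    return ModelSelectionResults(
        response=response,
        candidates=candidates,
        fits=fits,
        aics=aics,
        weights=weights,
        confidence_indices=idx,
        threshold=threshold,
        averaged=averaged,
    )
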