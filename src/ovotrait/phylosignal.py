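"""Phylogenetic signal (Pagel's lambda) and auxiliary comparative statistics.

Pagel's lambda rescales the off-diagonal of the Brownian-motion tip
covariance V: lambda = 0 is phylogenetic independence, lambda = 1 full
Brownian covariance.  ``PagelLambda`` profiles the Gaussian likelihood over
lambda in [0, 1] — the GLS mean mu and rate sigma^2 are maximised
analytically for each lambda — and reports a profile-likelihood confidence
interval using the chi-square(1) cutoff.

Also here: the one-way-ANOVA repeatability (intraclass correlation) with a
species-bootstrap percentile interval, and Spearman's rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .trees import covariance_for_labels, tree_covariance

__all__ = [
    "apply_lambda",
    "bm_profile_loglik",
    "PagelLambda",
    "PagelLambdaResults",
    "estimate_lambda",
    "repeatability_icc",
    "RepeatabilityEstimate",
    "spearman_rho",
]


def apply_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of V by lambda (diagonal kept)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = np.asarray(V, dtype=float)
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def bm_profile_loglik(x: np.ndarray, V_lambda: np.ndarray) -> tuple[float, float, float]:
    """Profile ML of the single-mean Brownian model for a fixed covariance.

    Returns ``(mu_hat, sigma2_hat, loglik)`` where
    ``mu_hat = (1' V^-1 x) / (1' V^-1 1)``, ``sigma2_hat = r' V^-1 r / n``
    with r the residual, and the log-likelihood is the multivariate normal
    density at the maximisers.
    """
    x = np.asarray(x, dtype=float).ravel()
    V = np.asarray(V_lambda, dtype=float)
    n = x.size
    if V.shape != (n, n):
        raise ValueError("dimension mismatch between trait vector and V")
    try:
        c, low = linalg.cho_factor(V)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (condition number {cond:.3g})"
        ) from exc
    ones = np.ones(n)
    Vi1 = linalg.cho_solve((c, low), ones)
    Vix = linalg.cho_solve((c, low), x)
    mu = float(ones @ Vix / (ones @ Vi1))
    r = x - mu
    Vir = linalg.cho_solve((c, low), r)
    sigma2 = float(r @ Vir / n)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return mu, sigma2, ll


@dataclass
class PagelLambdaResults:
    """Maximum-likelihood fit of Pagel's lambda for one trait."""

    lambda_: float
    ci_low: float
    ci_high: float
    mu: float
    sigma2: float
    llf: float
    ci_level: float
    n: int
    identifiable: bool = True
    profile: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Pagel's lambda (profile maximum likelihood)",
            "-" * 45,
            f"n species            {self.n}",
            f"lambda_hat           {self.lambda_:.4f}",
            f"{int(self.ci_level * 100)}% profile CI       "
            f"[{self.ci_low:.4f}, {self.ci_high:.4f}]",
            f"mu_hat               {self.mu:.4f}",
            f"sigma2_hat           {self.sigma2:.6f}",
            f"log-likelihood       {self.llf:.4f}",
        ]
        if not self.identifiable:
            lines.append("warning: star tree; lambda not identifiable")
        return "\n".join(lines)


class PagelLambda:
    """Model object estimating Pagel's lambda for one trait on a tree.

    Parameters
    ----------
    x
        Trait values (one per species; species means for replicated data).
    tree
        A dendropy tree whose tip labels match ``species`` (or, if ``V`` is
        given, ignored).
    species
        Species labels aligning ``x`` with the tree tips.  If omitted the
        tree's own tip order is assumed.
    V
        Precomputed Brownian covariance matrix (alternative to ``tree``).
    """

    #: coarse profile grid evaluated before local refinement
    N_GRID = 21

    def __init__(self, x, tree=None, species=None, V=None):
        x = np.asarray(x, dtype=float).ravel()
        if x.size < 4:
            raise ValueError("need at least 4 species to estimate lambda")
        if np.var(x) == 0:
            raise ValueError("trait has zero variance")
        if V is None:
            if tree is None:
                raise ValueError("provide either a tree or a covariance matrix")
            if species is not None:
                V = covariance_for_labels(tree, list(species))
            else:
                V, _ = tree_covariance(tree)
        V = np.asarray(V, dtype=float)
        if V.shape != (x.size, x.size):
            raise ValueError("trait vector and covariance dimensions differ")
        self.x = x
        self.V = V
        self.nobs = x.size

    def loglik(self, lam: float) -> float:
        return bm_profile_loglik(self.x, apply_lambda(self.V, lam))[2]

    def fit(self, ci_level: float = 0.95, xatol: float = 1e-6) -> PagelLambdaResults:
        """Profile-likelihood estimate of lambda with a chi-square(1) CI.

        A 21-point coarse grid over [0, 1] brackets the optimum, which is
        refined by bounded scalar minimisation to ``xatol``; both boundaries
        are evaluated explicitly.  The CI is the set of lambda whose profile
        log-likelihood is within ``chi2.ppf(ci_level, 1) / 2`` of the
        maximum, truncated to [0, 1].
        """
        offdiag = self.V - np.diag(np.diag(self.V))
        if np.allclose(offdiag, 0.0):
            mu, s2, ll = bm_profile_loglik(self.x, self.V)
            return PagelLambdaResults(
                lambda_=0.0, ci_low=0.0, ci_high=1.0, mu=mu, sigma2=s2,
                llf=ll, ci_level=ci_level, n=self.nobs, identifiable=False,
            )
        grid = np.linspace(0.0, 1.0, self.N_GRID)
        lls = np.array([self.loglik(g) for g in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, self.N_GRID - 1)]
        best_lam, best_ll = grid[i], lls[i]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda lam: -self.loglik(lam),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": xatol},
            )
            if -res.fun > best_ll:
                best_lam, best_ll = float(res.x), float(-res.fun)
        for b in (0.0, 1.0):  # boundaries checked explicitly
            llb = self.loglik(b)
            if llb > best_ll:
                best_lam, best_ll = b, llb
        mu, s2, _ = bm_profile_loglik(self.x, apply_lambda(self.V, best_lam))

        cutoff = best_ll - stats.chi2.ppf(ci_level, df=1) / 2.0
        ci_low = self._profile_bound(0.0, best_lam, cutoff, lower=True)
        ci_high = self._profile_bound(best_lam, 1.0, cutoff, lower=False)
        return PagelLambdaResults(
            lambda_=best_lam, ci_low=ci_low, ci_high=ci_high, mu=mu,
            sigma2=s2, llf=best_ll, ci_level=ci_level, n=self.nobs,
            profile={"grid": grid, "loglik": lls},
        )

    def _profile_bound(self, a: float, b: float, cutoff: float, lower: bool) -> float:
        """Bisection for loglik(lam) = cutoff on [a, b] (monotone side)."""
        end = a if lower else b
        if self.loglik(end) >= cutoff:
            return end
        f = lambda lam: self.loglik(lam) - cutoff  # noqa: E731
        lo, hi = (a, b) if lower else (b, a)
        # f(lo) < 0 <= f(hi) by construction (hi side holds the optimum)
        try:
            return float(optimize.brentq(f, a, b, xtol=1e-6))
        except ValueError:
            return end


def estimate_lambda(x, tree=None, species=None, V=None, ci_level: float = 0.95) -> PagelLambdaResults:
    """Convenience wrapper: ``PagelLambda(x, tree, species, V).fit(ci_level)``."""
    return PagelLambda(x, tree=tree, species=species, V=V).fit(ci_level=ci_level)


@dataclass
class RepeatabilityEstimate:
    icc: float
    p5: float
    p95: float
    n_species: int
    n_boot: int

    def summary(self) -> str:
        return (
            f"ICC {self.icc:.3f} [5th {self.p5:.3f}, 95th {self.p95:.3f}] "
            f"({self.n_species} species, {self.n_boot} bootstrap draws)"
        )


def _anova_icc(groups: list[np.ndarray]) -> float:
    ni = np.array([g.size for g in groups], dtype=float)
    s = len(groups)
    N = ni.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ni * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (s - 1)
    msw = ssw / (N - s)
    k0 = (N - (ni**2).sum() / N) / (s - 1)  # harmonic-mean-adjusted group size
    if msw == 0:
        return 1.0
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return float(np.clip(icc, 0.0, 1.0))


def repeatability_icc(
    values,
    groups,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RepeatabilityEstimate:
    """One-way ANOVA repeatability with a species-bootstrap interval.

    ICC = (MS_between - MS_within) / (MS_between + (k0 - 1) * MS_within)
    with k0 the adjusted replicate count for unbalanced designs; negative
    estimates are clipped to zero.  The 5th/95th percentiles come from a
    percentile bootstrap resampling species (groups) with replacement.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValueError("values and groups must have equal length")
    uniq = np.unique(groups)
    per = [values[groups == g] for g in uniq]
    per = [g for g in per if g.size >= 1]
    if sum(g.size >= 2 for g in per) < 2 or len(per) < 2:
        raise ValueError("need at least two species with two replicates each")
    icc = _anova_icc(per)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    s = len(per)
    for b in range(n_boot):
        idx = rng.integers(s, size=s)
        sample = [per[i] for i in idx]
        if sum(g.size >= 2 for g in sample) < 2:
            boots[b] = np.nan
            continue
        boots[b] = _anova_icc(sample)
    boots = boots[~np.isnan(boots)]
    p5, p95 = np.percentile(boots, [5, 95]) if boots.size else (icc, icc)
    return RepeatabilityEstimate(
        icc=icc, p5=float(p5), p95=float(p95), n_species=s, n_boot=n_boot
    )


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation (Pearson on average ranks, ties averaged)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input; Spearman correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
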