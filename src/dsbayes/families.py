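"""Conjugate likelihood/prior pairs and their closed-form Bayes objects.

Four families are supported; in each the anchor prior ``g`` is conjugate,
so the marginal ``f_G(y)`` and posterior ``pi_G(theta | y)`` are closed
form:

=============  ==================  =======================  =============================
likelihood     prior g             marginal f_G             posterior pi_G
=============  ==================  =======================  =============================
Bin(n, theta)  Beta(a, b)          beta-binomial            Beta(a + y, b - y + n)
Poi(theta)     Gamma(a, scale b)   neg-binomial, p=1/(1+b)  Gamma(a + y, b/(1+b))
N(theta, s^2)  N(mu, tau^2)        N(mu, s^2 + tau^2)       N(lam*mu + (1-lam)*y, ...)
Exp(theta)     Gamma(a, scale b)   Lomax a*b/(1+b*y)^(a+1)  Gamma(a + 1, b/(1+b*y))
=============  ==================  =======================  =============================

with ``lam = s^2 / (s^2 + tau^2)``.  The gamma hyperparameter ``b`` is a
*scale* (prior mean a*b).

Beyond the conjugate algebra the module supplies the posterior moments of
the rank polynomials, ``E_G[T_j(Theta) | y]`` and relatives, which are the
workhorse integrals of the whole correction framework.  They are computed
by quadrature after the posterior-quantile substitution
``theta = Q_post(v)``, which turns every such moment into the integral of
the smooth bounded function ``Leg_j(G(Q_post(v)))`` over the unit
interval -- exactly normalised for any observation, however concentrated
its posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lp_basis import leg_matrix

__all__ = [
    "ConjugateFamily",
    "StudyData",
    "marginal_fG",
    "posterior_G",
    "fit_mle",
    "jeffreys",
    "posterior_expect_T",
    "posterior_expect_hT",
    "posterior_basis_moments",
    "read_study_data",
    "expand_frequency_table",
]

FAMILY_IDS = ("binomial", "poisson", "normal", "exponential")

_GAMMA_LIKE = ("poisson", "exponential")


@dataclass(frozen=True)
class ConjugateFamily:
    """A likelihood family together with hyperparameters of its conjugate prior.

    Parameters
    ----------
    family_id : str
        One of ``binomial``, ``poisson``, ``normal``, ``exponential``.
    a, b : float
        ``(alpha, beta)`` for the beta/gamma priors, ``(mu, tau2)`` for
        the normal prior (``b`` is the prior *variance* tau^2 there).
    """

    family_id: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.family_id not in FAMILY_IDS:
            raise ValueError(f"unknown family {self.family_id!r}")
        if self.family_id == "normal":
            if self.b < 0:
                raise ValueError("prior variance tau2 must be >= 0")
        elif self.a <= 0 or self.b <= 0:
            raise ValueError("hyperparameters must be positive")

    # -- aliases -------------------------------------------------------
    @property
    def alpha(self) -> float:
        return self.a

    @property
    def beta(self) -> float:
        return self.b

    @property
    def mu(self) -> float:
        return self.a

    @property
    def tau2(self) -> float:
        return self.b

    # -- the prior G ---------------------------------------------------
    @property
    def prior(self):
        """Frozen scipy distribution of the conjugate prior g."""
        if self.family_id == "binomial":
            return stats.beta(self.a, self.b)
        if self.family_id in _GAMMA_LIKE:
            return stats.gamma(self.a, scale=self.b)
        return stats.norm(self.a, np.sqrt(self.b))

    def pdf(self, theta):
        return self.prior.pdf(theta)

    def cdf(self, theta):
        return self.prior.cdf(theta)

    def ppf(self, u):
        return self.prior.ppf(u)

    @property
    def prior_mean(self) -> float:
        if self.family_id == "binomial":
            return self.a / (self.a + self.b)
        if self.family_id in _GAMMA_LIKE:
            return self.a * self.b
        return self.a

    @property
    def support(self) -> tuple[float, float]:
        if self.family_id == "binomial":
            return (0.0, 1.0)
        if self.family_id in _GAMMA_LIKE:
            return (0.0, np.inf)
        return (-np.inf, np.inf)

    # -- likelihood ----------------------------------------------------
    def likelihood(self, y, theta, exposure=None):
        """f(y | theta); ``exposure`` is n (binomial) or s (normal)."""
        theta = np.asarray(theta, dtype=float)
        if self.family_id == "binomial":
            return stats.binom.pmf(y, int(exposure), theta)
        if self.family_id == "poisson":
            return stats.poisson.pmf(y, theta)
        if self.family_id == "normal":
            return stats.norm.pdf(y, loc=theta, scale=exposure)
        return np.where(theta > 0, theta * np.exp(-theta * y), 0.0)


def _validate_obs(y, exposure, family: ConjugateFamily) -> None:
    fid = family.family_id
    if fid == "binomial":
        if exposure is None:
            raise ValueError("binomial observations need the trial count n")
        if y < 0 or y > exposure:
            raise ValueError(f"binomial y={y} outside [0, n={exposure}]")
    elif fid == "poisson":
        if y < 0 or y != int(y):
            raise ValueError("poisson observations are nonnegative integers")
    elif fid == "normal":
        if exposure is None or exposure <= 0:
            raise ValueError("normal observations need a standard error s > 0")
    else:
        if y <= 0:
            raise ValueError("exponential observations must be positive")


def marginal_fG(y, exposure=None, family: ConjugateFamily = None):
    """Marginal density/pmf of an observation under the conjugate model."""
    _validate_obs(y, exposure, family)
    a, b = family.a, family.b
    fid = family.family_id
    if fid == "binomial":
        return float(stats.betabinom.pmf(y, int(exposure), a, b))
    if fid == "poisson":
        return float(stats.nbinom.pmf(y, a, 1.0 / (1.0 + b)))
    if fid == "normal":
        return float(stats.norm.pdf(y, loc=a, scale=np.sqrt(exposure**2 + b)))
    return float(a * b / (1.0 + b * y) ** (a + 1.0))


def posterior_G(y, exposure=None, family: ConjugateFamily = None):
    """Frozen scipy distribution of the conjugate posterior pi_G(. | y)."""
    _validate_obs(y, exposure, family)
    a, b = family.a, family.b
    fid = family.family_id
    if fid == "binomial":
        return stats.beta(a + y, b - y + exposure)
    if fid == "poisson":
        return stats.gamma(a + y, scale=b / (1.0 + b))
    if fid == "normal":
        s2 = exposure**2
        lam = s2 / (s2 + b)
        return stats.norm(lam * a + (1 - lam) * y, np.sqrt((1 - lam) * s2))
    return stats.gamma(a + 1.0, scale=b / (1.0 + b * y))


# ---------------------------------------------------------------------
# study data container & text IO
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class StudyData:
    """Observations from k parallel studies.

    ``exposure`` holds n_i for binomial data, s_i for normal data, and is
    ``None`` for Poisson/exponential counts.
    """

    y: np.ndarray
    exposure: np.ndarray | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if self.exposure is not None:
            exp = np.asarray(self.exposure, dtype=float)
            if exp.shape != y.shape:
                raise ValueError("y and exposure must have equal length")
            object.__setattr__(self, "exposure", exp)
        fid = self.family_id
        if fid == "binomial":
            if self.exposure is None:
                raise ValueError("binomial data require trial counts")
            if np.any(y < 0) or np.any(y > self.exposure) or np.any(y != np.round(y)):
                raise ValueError("binomial counts must be integers in [0, n_i]")
        elif fid == "poisson":
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError("poisson counts must be nonnegative integers")
        elif fid == "normal":
            if self.exposure is None or np.any(self.exposure <= 0):
                raise ValueError("normal data require positive standard errors")
        elif fid == "exponential":
            if np.any(y <= 0):
                raise ValueError("exponential data must be positive")

    @property
    def k(self) -> int:
        return len(self.y)

    def grouped(self):
        """Unique (y, exposure) pairs with multiplicities.

        Large count data often contain massive ties (a frequency table of
        claim counts expands to thousands of identical observations);
        every per-study integral needs computing only once per unique
        pair.
        """
        if self.exposure is None:
            pairs = self.y[:, None]
        else:
            pairs = np.column_stack([self.y, self.exposure])
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        ys = uniq[:, 0]
        exps = uniq[:, 1] if self.exposure is not None else [None] * len(ys)
        return list(zip(ys, exps)), counts


def expand_frequency_table(values: Sequence[float], counts: Sequence[int]) -> np.ndarray:
    """Expand a counts-of-counts table to an individual-level vector."""
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("frequencies must be nonnegative")
    return np.repeat(np.asarray(values, dtype=float), counts)


def read_study_data(path: str | Path, family_id: str) -> StudyData:
    """Read delimited study data (comma or tab, optional header row).

    Layout by family: two columns (y, n) for binomial, (y, s) for normal;
    one column y or two columns (value, frequency) for poisson and
    exponential.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    # a non-numeric first row is a header
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype(float)
    if family_id in ("binomial", "normal"):
        if df.shape[1] < 2:
            raise ValueError(f"{family_id} data need two columns")
        return StudyData(df.iloc[:, 0].values, df.iloc[:, 1].values, family_id)
    if df.shape[1] >= 2:
        y = expand_frequency_table(df.iloc[:, 0].values, df.iloc[:, 1].values.astype(int))
    else:
        y = df.iloc[:, 0].values
    return StudyData(y, None, family_id)


# ---------------------------------------------------------------------
# hyperparameter estimation
# ---------------------------------------------------------------------


def jeffreys(family_id: str = "binomial") -> ConjugateFamily:
    """The Jeffreys Beta(1/2, 1/2) prior for binomial data."""
    if family_id != "binomial":
        raise ValueError("Jeffreys shortcut implemented for the binomial family")
    return ConjugateFamily("binomial", 0.5, 0.5)


def _neg_loglik_factory(data: StudyData, family_id: str):
    pairs, counts = data.grouped()
    y = np.array([p[0] for p in pairs])
    if family_id == "binomial":
        n = np.array([p[1] for p in pairs])

        def nll(log_ab):
            a, b = np.exp(log_ab)
            ll = stats.betabinom.logpmf(y, n.astype(int), a, b)
            return -np.sum(counts * ll)

    elif family_id == "poisson":

        def nll(log_ab):
            a, b = np.exp(log_ab)
            ll = stats.nbinom.logpmf(y, a, 1.0 / (1.0 + b))
            return -np.sum(counts * ll)

    elif family_id == "exponential":

        def nll(log_ab):
            a, b = np.exp(log_ab)
            ll = np.log(a) + np.log(b) - (a + 1.0) * np.log1p(b * y)
            return -np.sum(counts * ll)

    else:
        raise ValueError(family_id)
    return nll


def fit_mle(data: StudyData, family_id: str) -> ConjugateFamily:
    """Marginal maximum-likelihood fit of the conjugate hyperparameters.

    Maximises ``prod_i f_G(y_i)`` -- the usual empirical-Bayes type-II
    likelihood.  The normal family is profiled: for fixed tau^2 the
    optimal mu is the precision-weighted mean, leaving a 1-D bounded
    search over tau^2 (the tau^2 = 0 boundary is admissible).
    """
    if data.k < 2:
        raise ValueError("need at least two studies to fit hyperparameters")
    y = data.y
    if family_id == "normal":
        s2 = data.exposure**2

        def profile_nll(tau2):
            w = 1.0 / (s2 + tau2)
            mu = np.sum(w * y) / np.sum(w)
            return -np.sum(stats.norm.logpdf(y, mu, np.sqrt(s2 + tau2)))

        hi = max(10.0 * np.var(y), 1e-6)
        res = optimize.minimize_scalar(profile_nll, bounds=(0.0, hi), method="bounded")
        tau2 = float(res.x)
        # compare against the boundary explicitly
        if profile_nll(0.0) <= res.fun:
            tau2 = 0.0
        w = 1.0 / (s2 + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        return ConjugateFamily("normal", mu, tau2)

    if np.all(y == y[0]):
        raise ValueError(
            "all observations identical: conjugate hyperparameters are not identifiable"
        )
    nll = _neg_loglik_factory(data, family_id)

    ybar = float(np.mean(y))
    if family_id == "binomial":
        phat = np.mean(y / data.exposure)
        phat = min(max(phat, 1e-3), 1 - 1e-3)
        x0 = np.log([2.0 * phat / (1 - phat) + 0.1, 2.0])
    else:
        # moment start: mean = a*b, var = a*b^2 + a*b (poisson) or heavy-tailed
        v = max(float(np.var(y)), ybar + 1e-6)
        b0 = max((v - ybar) / max(ybar, 1e-6), 0.1)
        a0 = max(ybar / b0, 0.1)
        x0 = np.log([a0, b0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if not res.success:
        raise RuntimeError(f"hyperparameter optimisation failed: {res.message}")
    a, b = np.exp(res.x)
    return ConjugateFamily(family_id, float(a), float(b))


# ---------------------------------------------------------------------
# posterior expectations of rank polynomials
# ---------------------------------------------------------------------


@lru_cache(maxsize=8)
def _gl_nodes(n: int):
    """Gauss-Legendre nodes on (0, 1) under the cosine substitution
    v = (1 - cos(pi w))/2, which clusters nodes at the endpoints and
    restores fast convergence for integrands with endpoint power-law
    behaviour (the rank transform of a posterior quantile typically has
    one)."""
    x, w = np.polynomial.legendre.leggauss(n)
    t = 0.5 * (x + 1.0)
    v = 0.5 * (1.0 - np.cos(np.pi * t))
    gw = 0.5 * w * (np.pi / 2.0) * np.sin(np.pi * t)
    return v, gw


def _posterior_u_weights(y, exposure, family: ConjugateFamily, nodes: int):
    """Quadrature nodes of the conjugate posterior on the u = G(theta) scale.

    Substituting theta = Q_post(v) for v in (0, 1) turns any posterior
    expectation into an integral of a smooth bounded function of v against
    the uniform measure, so Gauss-Legendre nodes in v give exact
    normalisation for every observation -- including posteriors
    concentrated deep in the prior's tail, where quadrature on the
    u = G(theta) scale itself would under-resolve the mass.

    Returns (u, theta, w) with ``sum(w) == 1`` up to rounding.
    """
    v, w = _gl_nodes(nodes)
    post = posterior_G(y, exposure, family)
    theta = post.ppf(v)
    u = family.cdf(theta)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite posterior quadrature nodes")
    return u, theta, w


def posterior_expect_T(j: int, y, exposure=None, family: ConjugateFamily = None,
                       nodes: int = 128) -> float:
    """E_G[T_j(Theta; G) | y], the conjugate posterior mean of a rank polynomial."""
    if j == 0:
        return 1.0
    u, _, w = _posterior_u_weights(y, exposure, family, nodes)
    return float(leg_matrix(j, u)[j - 1] @ w)


def posterior_expect_hT(h: Callable, j: int, y, exposure=None,
                        family: ConjugateFamily = None, nodes: int = 128) -> float:
    """E_G[h(Theta) T_j(Theta; G) | y]; j = 0 gives the plain posterior mean of h."""
    u, theta, w = _posterior_u_weights(y, exposure, family, nodes)
    hv = np.asarray(h(theta), dtype=float) * np.ones_like(u)
    if j == 0:
        return float(hv @ w)
    return float((leg_matrix(j, u)[j - 1] * hv) @ w)


def posterior_basis_moments(y, exposure, family: ConjugateFamily, m: int,
                            nodes: int = 128, h: Callable | None = None):
    """All basis moments of one conjugate posterior in a single quadrature pass.

    Returns ``(t, M, hvec, h0)`` where ``t[j-1] = E_G[T_j | y]``,
    ``M[j-1, l-1] = E_G[T_j T_l | y]``, and, when ``h`` is given,
    ``hvec[j-1] = E_G[h(Theta) T_j | y]`` with ``h0 = E_G[h | y]``.
    """
    u, theta, w = _posterior_u_weights(y, exposure, family, nodes)
    L = leg_matrix(m, u)
    t = L @ w
    M = (L * w) @ L.T
    hvec = h0 = None
    if h is not None:
        hv = np.asarray(h(theta), dtype=float) * np.ones_like(u)
        hvec = L @ (hv * w)
        h0 = float(hv @ w)
    return t, M, hvec, h0
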