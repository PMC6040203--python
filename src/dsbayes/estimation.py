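"""Type-II method-of-moments estimation of the LP correction coefficients.

If the latent study effects theta_1..theta_k were observed, the Fourier
coefficients of the correction would simply be the sample means of the
rank polynomials, k^{-1} sum_i T_j(theta_i; G).  They are not observed,
so -- in the spirit of EM -- each T_j(theta_i) is replaced by its
posterior mean given y_i under the *current* DS prior:

    c_j  <-  k^{-1} sum_i E_LP[ T_j(Theta_i; G) | y_i ].

Starting from c = 0 (so the first pass uses the plain conjugate
posterior, the "ghost" estimates), the update is iterated to a fixed
point; no numerical optimisation is involved.  The conjugate
hyperparameters stay fixed throughout: g is the anchor being corrected,
not re-fit.

The converged vector is then sparsified by BIC: order coefficients by
decreasing magnitude and keep the prefix maximising

    BIC(m) = sum_{j<=m} |c_(j)|^2 - m log(k) / k,

with BIC(0) = 0, i.e. keeping nothing is always on the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ds_prior import DSPrior
from .families import ConjugateFamily, StudyData, posterior_basis_moments

__all__ = ["FitResult", "mom2_fit", "bic_select"]

DEFAULT_M_MAX = 8
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 100


@dataclass
class FitResult:
    """Outcome of a MOM-II fit.

    ``prior.coef`` is ``raw_coef`` with everything outside the
    BIC-selected index set zeroed; ``bic_table`` records the cumulative
    BIC path over the magnitude-ordered prefixes.
    """

    prior: DSPrior
    raw_coef: np.ndarray
    selected: list[int]
    bic_table: list[tuple[int, float]]
    n_iter: int
    converged: bool
    diverged: bool = False
    trajectory: np.ndarray = field(repr=False, default=None)

    @property
    def qlp(self) -> float:
        return self.prior.qlp

    def to_dict(self) -> dict:
        fam = self.prior.family
        return {
            "family_id": fam.family_id,
            "hyper": [fam.a, fam.b],
            "coef": {str(j + 1): c for j, c in enumerate(self.prior.coef)},
            "raw_coef": list(map(float, self.raw_coef)),
            "selected": self.selected,
            "m": int(np.max(self.selected)) if self.selected else 0,
            "qlp": self.qlp,
            "bic_table": [[int(m), float(b)] for m, b in self.bic_table],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "diverged": self.diverged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        fam = ConjugateFamily(d["family_id"], *d["hyper"])
        raw = np.asarray(d["raw_coef"], dtype=float)
        coef = np.zeros_like(raw)
        for j, c in d["coef"].items():
            coef[int(j) - 1] = c
        return cls(
            prior=DSPrior(fam, coef),
            raw_coef=raw,
            selected=list(d["selected"]),
            bic_table=[tuple(row) for row in d["bic_table"]],
            n_iter=d["n_iter"],
            converged=d["converged"],
            diverged=d.get("diverged", False),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))


def bic_select(raw_coef: np.ndarray, k: int):
    """BIC sparsification of a raw coefficient vector.

    Coefficients are ranked by decreasing magnitude; the retained set is
    the magnitude-prefix maximising ``sum |c|^2 - m log(k)/k`` (empty set
    allowed at BIC(0) = 0).

    Returns
    -------
    selected : list of int
        1-based orders of the retained coefficients.
    bic_table : list of (m, BIC(m)) pairs including m = 0.
    """
    if k < 2:
        raise ValueError("BIC selection needs k >= 2")
    raw_coef = np.asarray(raw_coef, dtype=float)
    order = np.argsort(-np.abs(raw_coef), kind="stable")
    penalty = np.log(k) / k
    bic_table = [(0, 0.0)]
    running = 0.0
    for m, j in enumerate(order, start=1):
        running += raw_coef[j] ** 2 - penalty
        bic_table.append((m, running))
    best_m = max(bic_table, key=lambda t: t[1])[0]
    selected = sorted(int(order[i]) + 1 for i in range(best_m))
    return selected, bic_table


def mom2_fit(
    data: StudyData,
    family: ConjugateFamily,
    m_max: int = DEFAULT_M_MAX,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    nodes: int = 128,
    smooth: bool = True,
    coef0: np.ndarray | None = None,
) -> FitResult:
    """Fit the LP correction coefficients by iterated posterior moments.

    All orders j = 1..m_max are updated simultaneously each sweep;
    convergence is declared when the largest absolute coefficient change
    drops below ``tol``.  With ``smooth`` (the default) the converged
    vector is BIC-sparsified; ``smooth=False`` returns the raw fixed
    point.

    A coefficient leaving its Fourier bound sqrt(2j+1) means the update
    has diverged (the nonparametric correction is absorbing more
    structure than the truncated series can hold); the fit rolls back to
    the last in-bound iterate, flags ``diverged``, and smooths that.
    """
    if data.k < 2:
        raise ValueError("need at least two studies")
    pairs, counts = data.grouped()
    weights = counts / counts.sum()
    # one quadrature pass per distinct observation
    t_list, M_list = [], []
    for y, expo in pairs:
        t, M, _, _ = posterior_basis_moments(y, expo, family, m_max, nodes=nodes)
        t_list.append(t)
        M_list.append(M)
    T = np.asarray(t_list)          # (u, m)  E_G[T_j | y_i]
    M = np.asarray(M_list)          # (u, m, m)  E_G[T_j T_l | y_i]
    bound = np.sqrt(2.0 * np.arange(1, m_max + 1) + 1.0)

    if coef0 is None:
        coef = np.zeros(m_max)
    else:
        coef = np.zeros(m_max)
        coef0 = np.asarray(coef0, dtype=float)
        coef[: len(coef0)] = coef0
    traj = [coef.copy()]
    converged = False
    diverged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        numer = T + M @ coef        # (u, m): E_G[T_j|y] + sum_l c_l E_G[T_j T_l|y]
        denom = 1.0 + T @ coef      # (u,)
        if np.any(denom <= 0):
            diverged = True
            break
        new = weights @ (numer / denom[:, None])
        if np.any(np.abs(new) > bound):
            diverged = True
            break
        delta = np.max(np.abs(new - coef))
        coef = new
        traj.append(coef.copy())
        if delta < tol:
            converged = True
            break

    raw = coef.copy()
    if smooth:
        selected, bic_table = bic_select(raw, data.k)
    else:
        selected, bic_table = list(range(1, m_max + 1)), [(0, 0.0)]
    final = np.zeros(m_max)
    for j in selected:
        final[j - 1] = raw[j - 1]
    return FitResult(
        prior=DSPrior(family, final),
        raw_coef=raw,
        selected=selected,
        bic_table=bic_table,
        n_iter=n_iter,
        converged=converged,
        diverged=diverged,
        trajectory=np.asarray(traj),
    )
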