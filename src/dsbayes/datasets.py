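"""Bundled study datasets and synthetic-data generators.

Three small datasets that recur throughout the examples are shipped as
code (they are tiny tables of integers):

``rat_tumor``
    Endometrial stromal polyp incidence in k = 70 groups of female rats;
    (y_i, n_i) = rats with polyps out of rats in the group.
``navy_shipyard``
    Defects found in k = 5 lots of 5 welding-material samples each:
    y = (0, 0, 0, 1, 5).
``insurance_counts``
    One year of automobile claims: the number of policyholders filing
    y = 0..7 claims, expanded to an individual-level Poisson count vector
    (k = 9461).

The generators cover the two simulation designs used for validation: a
two-component beta-mixture binomial experiment probing prior-data
conflict, and a generic DS(G, m) sampler for coefficient-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .ds_prior import DSPrior
from .families import StudyData, expand_frequency_table

__all__ = [
    "load_dataset",
    "export_dataset_csv",
    "SimulationConfig",
    "simulate_pharma",
    "simulate_ds",
    "INSURANCE_FREQ",
]

# (y_i, n_i): number of rats with endometrial stromal polyps / group size
_RAT_TUMOR = [
    # low-incidence block
    (0, 20), (0, 20), (0, 20), (0, 20), (0, 20), (0, 20), (0, 20),
    (0, 19), (0, 19), (0, 19), (0, 19), (0, 18), (0, 18), (0, 17),
    (1, 20), (1, 20), (1, 20), (1, 20), (1, 19), (1, 19), (1, 18), (1, 18),
    # higher-incidence block
    (3, 27), (2, 25), (2, 24), (2, 23), (2, 20), (2, 20), (2, 20),
    (2, 20), (2, 20), (2, 20), (1, 10),
    (5, 49), (2, 19), (5, 46), (2, 17), (7, 49), (7, 47), (3, 20),
    (3, 20), (2, 13), (9, 48), (10, 50),
    (4, 20), (4, 20), (4, 20), (4, 20), (4, 20), (4, 20), (4, 20),
    (10, 48), (4, 19), (4, 19), (4, 19),
    (5, 22), (11, 46), (12, 49), (5, 20), (5, 20), (6, 23), (5, 19),
    (6, 22), (6, 20), (6, 20), (6, 20),
    (16, 52), (15, 46), (15, 47), (9, 24),
]

_NAVY = ([0, 0, 0, 1, 5], [5, 5, 5, 5, 5])

# policyholders filing y = 0..7 claims in one year
INSURANCE_FREQ = (7840, 1317, 239, 42, 14, 4, 4, 1)


def load_dataset(name: str) -> StudyData:
    """Return one of the bundled datasets as a validated :class:`StudyData`."""
    if name == "rat_tumor":
        y, n = zip(*_RAT_TUMOR)
        return StudyData(np.array(y), np.array(n), "binomial")
    if name == "navy_shipyard":
        return StudyData(np.array(_NAVY[0]), np.array(_NAVY[1]), "binomial")
    if name == "insurance_counts":
        y = expand_frequency_table(np.arange(len(INSURANCE_FREQ)), INSURANCE_FREQ)
        return StudyData(y, None, "poisson")
    raise KeyError(f"unknown dataset {name!r}; choose from "
                   "rat_tumor, navy_shipyard, insurance_counts")


def export_dataset_csv(name: str, path: str | Path) -> Path:
    """Write a bundled dataset as CSV (y[,exposure] columns)."""
    data = load_dataset(name)
    path = Path(path)
    with open(path, "w") as fh:
        if data.exposure is not None:
            fh.write("y,n\n")
            for yi, ni in zip(data.y, data.exposure):
                fh.write(f"{int(yi)},{int(ni)}\n")
        else:
            fh.write("y\n")
            for yi in data.y:
                fh.write(f"{int(yi)}\n")
    return path


# ---------------------------------------------------------------------
# synthetic generators
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Design of the beta-mixture prior-data-conflict experiment.

    The true prior is the two-component mixture

        pi(theta) = eta * Beta(5, 45) + (1 - eta) * Beta(30, 70),

    so eta = 0 is a unimodal prior centred near 0.3 and growing eta
    injects a conflicting low-rate subpopulation.  Each replicate draws
    k = 100 study effects, observes y_i ~ Bin(60, theta_i), fits the DS
    prior, then scores estimates of a new study's rate against its
    generative truth p_new = 0.3, observed through y_new ~ Bin(50, 0.3).
    """

    eta: float = 0.0
    k: int = 100
    n_trials: int = 60
    n_new: int = 50
    p_new: float = 0.3
    reps: int = 250
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if min(self.k, self.n_trials, self.n_new, self.reps) <= 0:
            raise ValueError("all sizes must be positive")


def _draw_mixture_theta(rng: np.random.Generator, eta: float, k: int) -> np.ndarray:
    low = rng.random(k) < eta
    theta = rng.beta(30.0, 70.0, size=k)
    theta[low] = rng.beta(5.0, 45.0, size=int(low.sum()))
    return theta


def simulate_pharma(config: SimulationConfig, m_max: int = 8) -> dict:
    """Run the beta-mixture conflict experiment and accumulate MSEs.

    Per replicate the three estimators of the new study's rate are the
    frequentist MLE y_new/n_new, the parametric empirical Bayes
    (conjugate posterior mean under the beta-binomial MLE fit), and the
    LP-corrected Elastic-Bayes posterior mean.  Returns a dict with the
    per-method MSEs against p_new and their PEB-relative ratios.
    """
    from .estimation import mom2_fit
    from .families import fit_mle
    from .inference import elastic_bayes, stein_peb

    rng = np.random.default_rng(config.seed)
    errs = {"mle": [], "peb": [], "ds": []}
    n_failed = 0
    for _ in range(config.reps):
        theta = _draw_mixture_theta(rng, config.eta, config.k)
        y = rng.binomial(config.n_trials, theta)
        y_new = int(rng.binomial(config.n_new, config.p_new))
        data = StudyData(y, np.full(config.k, config.n_trials), "binomial")
        fam = fit_mle(data, "binomial")
        fit = mom2_fit(data, fam, m_max=m_max)
        if fit.diverged:
            n_failed += 1
        prior = fit.prior
        mle = y_new / config.n_new
        peb = stein_peb(y_new, config.n_new, fam)
        ds = elastic_bayes(y_new, config.n_new, prior)
        errs["mle"].append((mle - config.p_new) ** 2)
        errs["peb"].append((peb - config.p_new) ** 2)
        errs["ds"].append((ds - config.p_new) ** 2)
    mse = {k: float(np.mean(v)) for k, v in errs.items()}
    return {
        "eta": config.eta,
        "reps_used": len(errs["mle"]),
        "reps_failed": n_failed,
        "mse": mse,
        "peb_over_mle": mse["peb"] / mse["mle"],
        "peb_over_ds": mse["peb"] / mse["ds"],
    }


def simulate_ds(prior: DSPrior, k: int, exposures=None, seed=None) -> StudyData:
    """Draw a StudyData set from a DS prior and its likelihood family.

    Study effects come from :meth:`DSPrior.sample`; observations from the
    family likelihood with the given exposures (n_i for binomial, s_i for
    normal; ignored otherwise).
    """
    rng = np.random.default_rng(seed)
    theta = prior.sample(k, seed=rng.integers(2**31))
    fid = prior.family.family_id
    if fid == "binomial":
        if exposures is None:
            raise ValueError("binomial simulation needs trial counts")
        n = np.broadcast_to(np.asarray(exposures, dtype=int), (k,))
        y = rng.binomial(n, theta)
        return StudyData(y, n, "binomial")
    if fid == "poisson":
        return StudyData(rng.poisson(theta), None, "poisson")
    if fid == "normal":
        if exposures is None:
            raise ValueError("normal simulation needs standard errors")
        s = np.broadcast_to(np.asarray(exposures, dtype=float), (k,))
        return StudyData(rng.normal(theta, s), s, "normal")
    return StudyData(rng.exponential(1.0 / theta), None, "exponential")
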