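"""Bayesian liability-threshold animal model for binomial performance counts.

Model
-----
Each assayed female contributes one record of ``successes`` out of
``trials``.  A latent liability per record,

    l_i = mu + a_{animal(i)} + d_{day(i)} + m_{mother(i)} + e_i,
    e_i ~ Normal(0, Vr),   successes_i ~ Binomial(trials_i, link^{-1}(l_i)),

carries a pedigree-structured additive genetic effect ``a ~ N(0, Va A)``
(haplodiploid relationship matrix A), i.i.d. testing-day and mother
effects, and a residual whose variance Vr is fixed (1 by default) because
it is not identifiable for binomial data.  Narrow-sense heritability per
posterior draw is

    h2 = Va / (Va + Vday + Vmother + Vr + c),

with c the link variance: 1 for the probit link, pi^2/3 for the logit.

Priors and sampler
------------------
Each variance component carries a parameter-expanded prior: the effect is
written u = alpha * u_tilde with u_tilde ~ N(0, v S), alpha ~
N(alpha_mu, alpha_V), v ~ Inv-Gamma(nu/2, nu V / 2), so the implied prior
on the variance alpha^2 v approaches alpha_V times a scaled chi-square
with 1 degree of freedom for large nu (defaults V=1, nu=1000, alpha_mu=0,
alpha_V=1).  Liabilities are updated by an adaptive random-walk Metropolis
step (vectorised over records); all Gaussian blocks and the expansion
parameters are conjugate draws; v is a conjugate inverse-gamma draw.  The
genetic block is drawn in the eigenbasis of A restricted to phenotyped
animals, which makes its conditional diagonal.  Draws are reproducible
bit-for-bit given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr, ndtr, ndtri

from waspqg.mcmc_diagnostics import DiagnosticsReport, diagnostics
from waspqg.pedigree import RelatednessMatrix, phenotyped_submatrix

LINK_VARIANCE = {"probit": 1.0, "logit": np.pi**2 / 3.0}


class SamplerDivergenceError(RuntimeError):
    """A variance draw overflowed; reported with the iteration index."""


class NotPositiveDefiniteError(ValueError):
    """The phenotyped relatedness submatrix is not positive definite."""


@dataclass(frozen=True)
class PriorSpec:
    """Parameter-expanded variance prior (MCMCglmm-style parameterisation)."""

    V: float = 1.0
    nu: float = 1000.0
    alpha_mu: float = 0.0
    alpha_V: float = 1.0


@dataclass(frozen=True)
class ModelConfig:
    link: str = "probit"
    n_samples: int = 50_000  # post burn-in iterations
    burn_in: int = 10_000
    thin: int = 25
    prior: PriorSpec = field(default_factory=PriorSpec)
    residual_variance: float = 1.0
    seed: int = 0
    min_retained: int = 1000

    def __post_init__(self) -> None:
        if self.link not in LINK_VARIANCE:
            raise ValueError(f"link must be one of {sorted(LINK_VARIANCE)}")
        if self.n_samples // self.thin < self.min_retained:
            raise ValueError(
                f"n_samples/thin = {self.n_samples // self.thin} retained draws; "
                f"need at least {self.min_retained}"
            )

    @property
    def n_retained(self) -> int:
        return self.n_samples // self.thin


@dataclass(frozen=True)
class TraitDataset:
    """Per-female success/failure counts with design labels.

    One record per phenotyped animal; ``animal_id`` must resolve in the
    relatedness matrix passed to :func:`fit`.
    """

    successes: np.ndarray
    trials: np.ndarray
    day_id: np.ndarray
    mother_id: np.ndarray
    animal_id: np.ndarray

    def __post_init__(self) -> None:
        y, m = np.asarray(self.successes), np.asarray(self.trials)
        if y.shape != m.shape or y.ndim != 1:
            raise ValueError("successes and trials must be 1-d and congruent")
        if np.any((y < 0) | (y > m)):
            raise ValueError("need 0 <= successes <= trials for every record")
        if len(set(map(str, self.animal_id))) != y.size:
            raise ValueError("one record per animal: animal_id must be unique")

    def __len__(self) -> int:
        return int(np.asarray(self.successes).size)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of the variance components and derived h2."""

    va: np.ndarray
    vday: np.ndarray
    vmother: np.ndarray
    intercept: np.ndarray
    h2: np.ndarray
    vr: float
    link: str
    config: ModelConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "va": self.va,
                "vday": self.vday,
                "vmother": self.vmother,
                "intercept": self.intercept,
                "h2": self.h2,
            }
        )

    def chains(self) -> dict[str, np.ndarray]:
        return {
            "va": self.va,
            "vday": self.vday,
            "vmother": self.vmother,
            "h2": self.h2,
        }

    def diagnostics(self) -> DiagnosticsReport:
        return diagnostics(self.chains())


def heritability_from_components(
    va: float,
    vday: float = 0.0,
    vmother: float = 0.0,
    vr: float = 1.0,
    link: str = "probit",
) -> float:
    """h2 = Va / (Va + Vday + Vmother + Vr + link variance)."""
    return va / (va + vday + vmother + vr + LINK_VARIANCE[link])


def _binomial_loglik(l: np.ndarray, y, m, link: str) -> np.ndarray:
    if link == "probit":
        return y * log_ndtr(l) + (m - y) * log_ndtr(-l)
    # logit: log expit(l) = -log1p(exp(-l)), numerically stable form
    return y * -np.logaddexp(0.0, -l) + (m - y) * -np.logaddexp(0.0, l)


def inverse_link(l: np.ndarray, link: str) -> np.ndarray:
    return ndtr(l) if link == "probit" else expit(l)


def fit(
    data: TraitDataset,
    A: RelatednessMatrix,
    config: ModelConfig,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Draw from the posterior of the threshold animal model.

    With ``prior_only=True`` the likelihood is switched off and the same
    Gibbs cycle samples the joint prior of the variance components (used
    for prior-predictive checks).
    """
    n = len(data)
    if n == 0:
        raise ValueError("empty dataset")
    y = np.asarray(data.successes, dtype=float)
    m = np.asarray(data.trials, dtype=float)
    day_codes, _ = pd.factorize(np.asarray(data.day_id).astype(str))
    mom_codes, _ = pd.factorize(np.asarray(data.mother_id).astype(str))
    n_day = int(day_codes.max()) + 1
    n_mom = int(mom_codes.max()) + 1

    A_sub = phenotyped_submatrix(A, [str(a) for a in data.animal_id])
    lam, Q = np.linalg.eigh(A_sub.entries)
    if lam.min() < -1e-8:
        raise NotPositiveDefiniteError(
            f"phenotyped relatedness submatrix has eigenvalue {lam.min():.3g}"
        )
    lam = np.clip(lam, 1e-10, None)

    vr = float(config.residual_variance)
    prior = config.prior
    rng = np.random.default_rng(config.seed)
    link = config.link
    link_var = LINK_VARIANCE[link]

    # state
    l = np.zeros(n)
    mu = 0.0
    b = np.zeros(n)  # genetic effects, eigenbasis
    d = np.zeros(n_day)
    mo = np.zeros(n_mom)
    alpha = {"a": 1.0, "d": 1.0, "m": 1.0}
    v = {"a": 1.0, "d": 1.0, "m": 1.0}
    x_a = Q @ b

    step = np.full(n, 0.5)  # RW-Metropolis proposal sd, adapted in burn-in
    if not prior_only:
        # start liabilities at the empirical link scale
        phat = np.clip((y + 0.5) / (m + 1.0), 1e-3, 1 - 1e-3)
        l = ndtri(phat) if link == "probit" else np.log(phat / (1 - phat))

    def eta() -> np.ndarray:
        return (
            mu
            + alpha["a"] * x_a
            + alpha["d"] * d[day_codes]
            + alpha["m"] * mo[mom_codes]
        )

    def draw_invgamma(shape: float, rate: float) -> float:
        return float(rate / rng.gamma(shape))

    total = config.burn_in + config.n_samples
    keep = config.n_retained
    out = {
        k: np.empty(keep)
        for k in ("va", "vday", "vmother", "intercept", "h2")
    }
    kept = 0
    loglik = _binomial_loglik(l, y, m, link)

    for it in range(total):
        if not prior_only:
            # --- liability update: vectorised random-walk Metropolis
            center = eta()
            prop = l + step * rng.standard_normal(n)
            loglik_prop = _binomial_loglik(prop, y, m, link)
            logr = (
                loglik_prop
                - loglik
                + ((l - center) ** 2 - (prop - center) ** 2) / (2.0 * vr)
            )
            accept = np.log(rng.uniform(size=n)) < logr
            l = np.where(accept, prop, l)
            loglik = np.where(accept, loglik_prop, loglik)
            if it < config.burn_in:
                # Robbins-Monro drift of per-record step toward ~44% acceptance
                step *= np.exp((accept - 0.44) * 2.0 / np.sqrt(it + 10.0))
                step = np.clip(step, 0.05, 5.0)

            # --- intercept (flat prior)
            resid = l - (eta() - mu)
            mu = float(resid.mean() + np.sqrt(vr / n) * rng.standard_normal())

        # --- genetic block in the eigenbasis of A
        if prior_only:
            b = np.sqrt(v["a"] * lam) * rng.standard_normal(n)
        else:
            r = l - mu - alpha["d"] * d[day_codes] - alpha["m"] * mo[mom_codes]
            r_rot = Q.T @ r
            prec = alpha["a"] ** 2 / vr + 1.0 / (v["a"] * lam)
            sd = 1.0 / np.sqrt(prec)
            mean = (alpha["a"] / vr) * r_rot / prec
            b = mean + sd * rng.standard_normal(n)
        x_a = Q @ b
        alpha["a"] = _draw_alpha(
            rng, x_a, None if prior_only else (l - mu - alpha["d"] * d[day_codes]
                                               - alpha["m"] * mo[mom_codes]),
            vr, prior
        )
        quad = float(np.sum(b**2 / lam))
        v["a"] = draw_invgamma((prior.nu + n) / 2.0, (prior.nu * prior.V + quad) / 2.0)

        # --- day and mother blocks (i.i.d. groups)
        d = _draw_group(
            rng, day_codes, n_day, v["d"], alpha["d"], vr,
            None if prior_only else l - mu - alpha["a"] * x_a - alpha["m"] * mo[mom_codes],
        )
        alpha["d"] = _draw_alpha(
            rng, d[day_codes],
            None if prior_only else (l - mu - alpha["a"] * x_a - alpha["m"] * mo[mom_codes]),
            vr, prior,
        )
        v["d"] = draw_invgamma(
            (prior.nu + n_day) / 2.0, (prior.nu * prior.V + float(np.sum(d**2))) / 2.0
        )

        mo = _draw_group(
            rng, mom_codes, n_mom, v["m"], alpha["m"], vr,
            None if prior_only else l - mu - alpha["a"] * x_a - alpha["d"] * d[day_codes],
        )
        alpha["m"] = _draw_alpha(
            rng, mo[mom_codes],
            None if prior_only else (l - mu - alpha["a"] * x_a - alpha["d"] * d[day_codes]),
            vr, prior,
        )
        v["m"] = draw_invgamma(
            (prior.nu + n_mom) / 2.0, (prior.nu * prior.V + float(np.sum(mo**2))) / 2.0
        )

        va = alpha["a"] ** 2 * v["a"]
        vday = alpha["d"] ** 2 * v["d"]
        vmom = alpha["m"] ** 2 * v["m"]
        if not np.isfinite(va + vday + vmom) or va + vday + vmom > 1e10:
            raise SamplerDivergenceError(
                f"variance overflow at iteration {it}: "
                f"Va={va:.3g} Vday={vday:.3g} Vmother={vmom:.3g}"
            )

        post = it - config.burn_in
        if post >= 0 and post % config.thin == config.thin - 1 and kept < keep:
            out["va"][kept] = va
            out["vday"][kept] = vday
            out["vmother"][kept] = vmom
            out["intercept"][kept] = mu
            out["h2"][kept] = va / (va + vday + vmom + vr + link_var)
            kept += 1

    for k in out:
        out[k] = out[k][:kept]
    return PosteriorSamples(
        va=out["va"],
        vday=out["vday"],
        vmother=out["vmother"],
        intercept=out["intercept"],
        h2=out["h2"],
        vr=vr,
        link=link,
        config=config,
    )


def _draw_alpha(
    rng: np.random.Generator,
    x: np.ndarray,
    resid: np.ndarray | None,
    vr: float,
    prior: PriorSpec,
) -> float:
    """Conjugate draw of a scalar expansion parameter (normal prior)."""
    if resid is None:
        return float(prior.alpha_mu + np.sqrt(prior.alpha_V) * rng.standard_normal())
    prec = float(np.dot(x, x)) / vr + 1.0 / prior.alpha_V
    mean = (float(np.dot(x, resid)) / vr + prior.alpha_mu / prior.alpha_V) / prec
    return float(mean + rng.standard_normal() / np.sqrt(prec))


def _draw_group(
    rng: np.random.Generator,
    codes: np.ndarray,
    n_groups: int,
    v: float,
    alpha: float,
    vr: float,
    resid: np.ndarray | None,
) -> np.ndarray:
    """Conjugate draw of an i.i.d. random-effect block (working scale)."""
    if resid is None:
        return np.sqrt(v) * rng.standard_normal(n_groups)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.bincount(codes, weights=resid, minlength=n_groups)
    prec = alpha**2 * counts / vr + 1.0 / v
    mean = (alpha / vr) * sums / prec
    return mean + rng.standard_normal(n_groups) / np.sqrt(prec)


# ---------------------------------------------------------------------------
# Dataset assembly from assay tables


def trait_dataset_from_tables(
    trials: pd.DataFrame,
    controls: pd.DataFrame,
    trait: str = "killing",
    qc_threshold: float | None = 0.6,
    standardize: bool = True,
    mother_of: dict[str, str] | None = None,
) -> TraitDataset:
    """Build success/failure records for one index from assay tables.

    ``trait`` is an index name understood by
    :func:`waspqg.indices.standardized_counts`.  With ``standardize=False``
    the raw assay total (``n_larvae``) replaces the rounded day-control
    mean.  ``mother_of`` maps female_id -> dam label; by default the
    mother is read from a ``mother_id`` column if present, else each
    female is her own mother group.
    """
    from waspqg import indices as idx

    summaries = idx.controls_to_summaries(controls)
    if qc_threshold is not None and len(summaries) >= 2:
        retained, _ = idx.qc_filter_blocks(list(summaries.values()), qc_threshold)
        summaries = {s.day_id: s for s in retained}

    succ, tot, days, moms, animals = [], [], [], [], []
    has_mom_col = "mother_id" in trials.columns
    for row, trial in zip(
        trials.itertuples(index=False), idx.trials_to_objects(trials)
    ):
        if trial.day_id not in summaries:
            continue
        if standardize:
            pair = idx.standardized_counts(trial, summaries[trial.day_id], trait)
        else:
            surrogate = idx.DayControlSummary(
                day_id=trial.day_id, n_bar=float(trial.n_larvae), n_vials=1
            )
            pair = idx.standardized_counts(trial, surrogate, trait)
        if pair is None:
            continue
        s, f = pair
        succ.append(s)
        tot.append(s + f)
        days.append(trial.day_id)
        if mother_of is not None:
            moms.append(mother_of[trial.female_id])
        elif has_mom_col:
            moms.append(str(row.mother_id))
        else:
            moms.append(trial.female_id)
        animals.append(trial.female_id)
    return TraitDataset(
        successes=np.asarray(succ, dtype=np.int64),
        trials=np.asarray(tot, dtype=np.int64),
        day_id=np.asarray(days),
        mother_id=np.asarray(moms),
        animal_id=np.asarray(animals),
    )
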