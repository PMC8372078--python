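"""Selection-response statistics: differentials, realized heritability,
selection intensity, and breeder's-equation projections.

Per generation interval, the selection differential S is the mean of the
selected parents minus the mean of the whole parental cohort, and the
response R is the offspring-cohort mean minus the whole parental-cohort
mean, both on the day-standardized killing-rate (percent) scale.  Realized
heritability is the slope of the no-intercept regression of cumulative R
on cumulative S.  The breeder's equation R = i * sigma_a * sqrt(h2)
projects the per-generation gain on the liability scale, with a
configurable mapping from liability to observed percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri


@dataclass(frozen=True)
class ResponsePoint:
    line_id: str
    interval: str  # e.g. "F2-F3": parents F2, offspring F3
    generation: int  # parental generation index
    S: float
    R: float
    cum_S: float
    cum_R: float


@dataclass(frozen=True)
class RealizedH2Fit:
    slope: float
    se: float
    f_stat: float
    df1: int
    df2: int
    adj_r2: float
    p_value: float
    n_points: int


@dataclass(frozen=True)
class BreederProjection:
    i: float
    sigma_a: float
    h2: float
    latent_gain: float  # per generation
    mapping: str
    percent_trajectory: tuple[float, ...]  # index 0 = start


def _gen_label(t: int) -> str:
    return "P" if t == 0 else f"F{t}"


def response_points(means, line_type: str = "selection") -> list[ResponsePoint]:
    """Per-generation S and R with prefix sums, per line.

    Accepts a tidy means table (columns line_id, generation, mean_all,
    mean_selected, mean_offspring) or a
    :class:`waspqg.selection.SelectionTrajectory`.  Prefix sums are taken
    in generation order regardless of row order; a gap in the generation
    sequence is an error.
    """
    if hasattr(means, "means_table"):
        df = means.means_table(line_type)
    else:
        df = pd.DataFrame(means)
    points: list[ResponsePoint] = []
    for line, grp in df.groupby("line_id", sort=True):
        grp = grp.sort_values("generation")
        gens = grp["generation"].to_numpy()
        if gens.size < 2:
            raise ValueError(f"line {line}: need at least 2 generations")
        if not np.array_equal(gens, np.arange(gens[0], gens[0] + gens.size)):
            missing = sorted(set(range(gens[0], gens[-1] + 1)) - set(gens))
            raise ValueError(f"line {line}: missing generation(s) {missing}")
        mean_all = grp["mean_all"].to_numpy(dtype=float)
        mean_sel = grp["mean_selected"].to_numpy(dtype=float)
        if "mean_offspring" in grp.columns:
            mean_off = grp["mean_offspring"].to_numpy(dtype=float)
        else:
            mean_off = np.r_[mean_all[1:], np.nan]
        cs = cr = 0.0
        for k in range(gens.size - 1):
            off = mean_off[k] if np.isfinite(mean_off[k]) else mean_all[k + 1]
            S = mean_sel[k] - mean_all[k]
            R = off - mean_all[k]
            cs += S
            cr += R
            points.append(
                ResponsePoint(
                    line_id=str(line),
                    interval=f"{_gen_label(int(gens[k]))}-{_gen_label(int(gens[k + 1]))}",
                    generation=int(gens[k]),
                    S=S,
                    R=R,
                    cum_S=cs,
                    cum_R=cr,
                )
            )
    return points


def realized_heritability(points: list[ResponsePoint]) -> RealizedH2Fit:
    """No-intercept least squares of cumulative R on cumulative S.

    slope = sum(S_cum R_cum) / sum(S_cum^2); SE, F(1, n-1), uncentered
    adjusted R^2 and the p-value follow the no-intercept regression
    conventions.  Points from several lines may be pooled.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 response points")
    x = np.array([p.cum_S for p in points], dtype=float)
    y = np.array([p.cum_R for p in points], dtype=float)
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all cumulative selection differentials are zero")
    slope = float(np.dot(x, y)) / sxx
    n = x.size
    resid = y - slope * x
    ssr = float(np.dot(resid, resid))
    df2 = n - 1
    sigma2 = ssr / df2
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = (slope / se) ** 2
        p = float(stats.f.sf(f_stat, 1, df2))
    syy = float(np.dot(y, y))
    r2 = 1.0 - ssr / syy if syy > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * n / df2
    return RealizedH2Fit(
        slope=slope,
        se=se,
        f_stat=float(f_stat),
        df1=1,
        df2=df2,
        adj_r2=float(adj_r2),
        p_value=p,
        n_points=n,
    )


def realized_heritability_table(
    points: list[ResponsePoint], max_generations: list[int] | None = None
) -> pd.DataFrame:
    """Report-shaped table: one pooled ("Average") and per-line fit per
    generation interval P-F_t."""
    all_lines = sorted({p.line_id for p in points})
    tmax = max(p.generation for p in points) + 1
    if max_generations is None:
        max_generations = list(range(3, tmax + 1))
    rows = []
    for t in max_generations:
        subset = [p for p in points if p.generation < t]
        for label, pts in [("Average", subset)] + [
            (line, [p for p in subset if p.line_id == line]) for line in all_lines
        ]:
            if len(pts) < 2:
                continue
            fit = realized_heritability(pts)
            rows.append(
                {
                    "line": label,
                    "interval": f"P-F{t}",
                    "realized_h2": fit.slope,
                    "std_error": fit.se,
                    "F": fit.f_stat,
                    "df1": fit.df1,
                    "df2": fit.df2,
                    "adj_r2": fit.adj_r2,
                    "p_value": fit.p_value,
                }
            )
    return pd.DataFrame(rows)


def selection_intensity(p_selected: float) -> float:
    """Truncation-selection intensity i = phi(z) / p for retained fraction p."""
    if not 0.0 < p_selected <= 1.0:
        raise ValueError("retained fraction must be in (0, 1]")
    if p_selected == 1.0:
        return 0.0
    z = ndtri(1.0 - p_selected)  # upper-tail quantile
    return float(stats.norm.pdf(z) / p_selected)


def breeders_projection(
    i: float,
    sigma_a: float,
    h2: float,
    start_mean_percent: float,
    generations: int,
    mapping: str = "probit-unit",
    latent_sd: float | None = None,
) -> BreederProjection:
    """Project the mean observed percentage under R = i sigma_a sqrt(h2).

    Mappings from cumulative latent gain G_t = t R to observed percent:

    - ``probit-unit``: p_t = Phi(Phi^{-1}(p_0) + G_t) (liability in unit
      probit scale);
    - ``probit-scaled``: as above with G_t / latent_sd (latent gain scaled
      by the total liability SD, which must be supplied);
    - ``linear-local``: p_t = p_0 + G_t phi(Phi^{-1}(p_0)) (the probit
      slope frozen at the starting mean).
    """
    if min(i, sigma_a, h2) < 0:
        raise ValueError("i, sigma_a and h2 must be non-negative")
    p0 = start_mean_percent / 100.0
    if not 0.0 < p0 < 1.0:
        raise ValueError("start mean must be strictly between 0 and 100 percent")
    gain = i * sigma_a * np.sqrt(h2)
    z0 = float(ndtri(p0))
    traj = []
    for t in range(generations + 1):
        G = t * gain
        if mapping == "probit-unit":
            p = float(ndtr(z0 + G))
        elif mapping == "probit-scaled":
            if latent_sd is None or latent_sd <= 0:
                raise ValueError("probit-scaled mapping needs a positive latent_sd")
            p = float(ndtr(z0 + G / latent_sd))
        elif mapping == "linear-local":
            p = min(max(p0 + G * float(stats.norm.pdf(z0)), 0.0), 1.0)
        else:
            raise ValueError(f"unknown mapping {mapping!r}")
        traj.append(100.0 * p)
    return BreederProjection(
        i=i,
        sigma_a=sigma_a,
        h2=h2,
        latent_gain=float(gain),
        mapping=mapping,
        percent_trajectory=tuple(traj),
    )
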