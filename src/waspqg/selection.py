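"""Forward simulator of a truncation-selection experiment on killing rate.

Emulates an artificial-selection protocol on a haplodiploid parasitoid:
three selection and three control lines of 100 females each; every
generation each female is assayed on 25 host larvae, the 50 females with
the highest day-standardized killing rate (random 50 in control lines)
are bred, each contributing eight pupae, and 100 daughters of the pooled,
randomly mated offspring form the next cohort.

Genetics are genotype-explicit: ``n_loci`` additive loci with free
recombination approximate the infinitesimal model.  Females carry two
haplotypes, males one; a daughter receives her sire's entire haplotype
plus one recombined maternal gamete, a son only a maternal gamete.
Founder allelic values are i.i.d. normal, scaled so the founder female
breeding-value variance equals ``true_Va``.

The assay maps a liability l = base_mean + g + day + mother + N(0,1) to a
per-larva kill probability q = Phi(l - r_t), where r_t is a host-resistance
shift emulating laboratory adaptation of the host colony; flies emerge as
Binomial(25, s_t (1 - q)) with s_t the drifting baseline host survival.
Both trends are flat through F2 and then grow, survival linearly by
``host_survival_final_ratio`` and resistance quadratically to
``host_resistance_final_shift`` (the host colony's fitness gain
accelerated late in the year-long experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from waspqg.tables import rng_from_seed


class MatingFailureError(RuntimeError):
    """A bred generation produced no sons or too few daughters."""


@dataclass(frozen=True)
class SimConfig:
    n_lines_selected: int = 3
    n_lines_control: int = 3
    females_per_line: int = 100
    males_per_line: int = 100
    selected_per_generation: int = 50
    generations: int = 7
    n_loci: int = 100
    true_Va: float = 1.077
    true_Vday: float = 0.345
    true_Vmother: float = 0.001
    base_mean_liability: float = -1.31
    baseline_host_survival: float = 0.72
    host_survival_final_ratio: float = 1.30  # F7 relative to F2
    # liability-scale resistance gain of the host colony by F7, calibrated so
    # that under default selection it cancels the cumulative genetic gain
    # (killing rate back near its starting mean by F7, as the drifting host
    # fitness produced in the experiment this emulates)
    host_resistance_final_shift: float = 1.9
    trend_start_generation: int = 2
    larvae_per_assay: int = 25
    pupae_per_mother: int = 8
    sex_ratio: float = 0.5  # probability an offspring is a (diploid) daughter
    encapsulation_prob: float = 0.25  # capsule among surviving flies
    offspring_success_prob: float = 0.0  # wasp development on the novel host
    days_per_line: int = 3
    control_vials_per_day: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selected_per_generation > self.females_per_line:
            raise ValueError("cannot select more females than assayed")
        if min(self.true_Va, self.true_Vday, self.true_Vmother) < 0:
            raise ValueError("variances must be non-negative")
        if not 0 < self.baseline_host_survival <= 1:
            raise ValueError("baseline host survival must be in (0, 1]")
        final = self.baseline_host_survival * self.host_survival_final_ratio
        if not 0 < final <= 1:
            raise ValueError("host survival path leaves (0, 1]")

    @property
    def true_latent_h2(self) -> float:
        """Heritability on the threshold-model scale (probit link)."""
        return self.true_Va / (
            self.true_Va + self.true_Vday + self.true_Vmother + 1.0 + 1.0
        )

    def host_survival_at(self, generation: int) -> float:
        t0, tmax = self.trend_start_generation, self.generations
        s0 = self.baseline_host_survival
        if generation <= t0 or tmax <= t0:
            return s0
        frac = min(generation - t0, tmax - t0) / (tmax - t0)
        return s0 * (1.0 + (self.host_survival_final_ratio - 1.0) * frac)

    def host_resistance_at(self, generation: int) -> float:
        t0, tmax = self.trend_start_generation, self.generations
        if generation <= t0 or tmax <= t0:
            return 0.0
        frac = min(generation - t0, tmax - t0) / (tmax - t0)
        return self.host_resistance_final_shift * frac**2


@dataclass
class Population:
    """One line's cohort: female genotypes, male pool, and dam bookkeeping."""

    female_h: np.ndarray  # (n_females, 2, n_loci) allelic values
    male_h: np.ndarray  # (n_males, n_loci)
    dam_index: np.ndarray  # (n_females,) shared index for full sisters

    @property
    def n_females(self) -> int:
        return self.female_h.shape[0]

    def breeding_values(self) -> np.ndarray:
        return self.female_h.sum(axis=(1, 2))


@dataclass
class GenerationRecord:
    line_id: str
    line_type: str  # "selection" or "control"
    generation: int
    trials: pd.DataFrame  # per-female assay counts and indices
    control_nbar: dict[str, float]
    selected: np.ndarray  # indices of bred females
    mean_all: float  # standardized killing rate, all females
    mean_selected: float
    mean_latent_all: float  # liability scale
    mean_latent_selected: float
    mean_g_all: float
    mean_g_selected: float


@dataclass
class SelectionTrajectory:
    config: SimConfig
    records: list[GenerationRecord]

    def means_table(self, line_type: str | None = "selection") -> pd.DataFrame:
        """Tidy per-line, per-generation means feeding response analysis.

        ``mean_offspring`` is the next generation's whole-cohort mean and is
        NaN for the last generation.
        """
        rows = []
        by_line: dict[str, list[GenerationRecord]] = {}
        for rec in self.records:
            if line_type is not None and rec.line_type != line_type:
                continue
            by_line.setdefault(rec.line_id, []).append(rec)
        for line, recs in by_line.items():
            recs = sorted(recs, key=lambda r: r.generation)
            for k, rec in enumerate(recs):
                nxt = recs[k + 1] if k + 1 < len(recs) else None
                rows.append(
                    {
                        "line_id": line,
                        "generation": rec.generation,
                        "mean_all": rec.mean_all,
                        "mean_selected": rec.mean_selected,
                        "mean_offspring": nxt.mean_all if nxt else np.nan,
                        "mean_latent_all": rec.mean_latent_all,
                        "mean_latent_selected": rec.mean_latent_selected,
                        "mean_offspring_latent": (
                            nxt.mean_latent_all if nxt else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def trials_table(self) -> pd.DataFrame:
        frames = []
        for rec in self.records:
            df = rec.trials.copy()
            df.insert(0, "line_id", rec.line_id)
            df.insert(1, "generation", rec.generation)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def init_base_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Founder cohort with i.i.d. allelic values scaled to ``true_Va``.

    Per-locus, per-haplotype variance is Va / (2 n_loci), so a diploid
    female's breeding value has variance Va.
    """
    sd = np.sqrt(config.true_Va / (2.0 * config.n_loci))
    nf, nm, L = config.females_per_line, config.males_per_line, config.n_loci
    return Population(
        female_h=sd * rng.standard_normal((nf, 2, L)),
        male_h=sd * rng.standard_normal((nm, L)),
        dam_index=np.arange(nf),
    )


def _maternal_gametes(
    female_h: np.ndarray, rows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One freely recombining gamete per requested mother row."""
    L = female_h.shape[2]
    choice = rng.integers(0, 2, size=(rows.size, L))
    h = female_h[rows]  # (k, 2, L)
    return np.where(choice == 0, h[:, 0, :], h[:, 1, :])


def assay_cohort(
    pop: Population,
    generation: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float], np.ndarray, np.ndarray]:
    """Run the standardized assay for every female of a cohort.

    Returns (trials frame, per-day control means, liabilities, std killing
    rates).  Day and mother effects are drawn fresh; the host survival and
    resistance trends at *generation* apply to exposed and control vials
    alike.
    """
    nf = pop.n_females
    g = pop.breeding_values()
    s_t = config.host_survival_at(generation)
    r_t = config.host_resistance_at(generation)

    day_of = rng.integers(0, config.days_per_line, size=nf)
    day_effects = np.sqrt(config.true_Vday) * rng.standard_normal(config.days_per_line)
    dams, dam_pos = np.unique(pop.dam_index, return_inverse=True)
    mom_effects = np.sqrt(config.true_Vmother) * rng.standard_normal(dams.size)

    liab = (
        config.base_mean_liability
        + g
        + day_effects[day_of]
        + mom_effects[dam_pos]
        + rng.standard_normal(nf)
    )
    q = ndtr(liab - r_t)
    N = config.larvae_per_assay
    f = rng.binomial(N, s_t * (1.0 - q))
    e = rng.binomial(f, config.encapsulation_prob)
    p = rng.binomial(N - f, config.offspring_success_prob)

    nbar = {}
    for day in range(config.days_per_line):
        vials = rng.binomial(N, s_t, size=config.control_vials_per_day)
        nbar[f"d{day}"] = float(vials.mean())
    nbar_of = np.array([nbar[f"d{day}"] for day in day_of])
    killing = np.clip(100.0 * (nbar_of - f) / nbar_of, 0.0, None)

    trials = pd.DataFrame(
        {
            "female_id": [f"g{generation}_f{i}" for i in range(nf)],
            "day_id": [f"d{day}" for day in day_of],
            "n_larvae": N,
            "flies_emerged": f,
            "flies_encapsulated": e,
            "wasp_offspring": p,
            "dam_index": pop.dam_index,
            "breeding_value": g,
            "liability": liab,
            "killing_rate_std": killing,
        }
    )
    return trials, nbar, liab, killing


def assay_phenotype(
    g: float,
    day_effect: float,
    host_survival: float,
    config: SimConfig,
    rng: np.random.Generator,
    mother_effect: float = 0.0,
    resistance_shift: float = 0.0,
) -> tuple[int, int, int, float]:
    """Single-female assay: returns (flies f, encapsulated e, offspring p,
    liability).  Scalar counterpart of :func:`assay_cohort`."""
    liab = (
        config.base_mean_liability
        + g
        + day_effect
        + mother_effect
        + rng.standard_normal()
    )
    q = float(ndtr(liab - resistance_shift))
    N = config.larvae_per_assay
    f = int(rng.binomial(N, host_survival * (1.0 - q)))
    e = int(rng.binomial(f, config.encapsulation_prob))
    p = int(rng.binomial(N - f, config.offspring_success_prob))
    return f, e, p, liab


def truncation_select(
    values: np.ndarray,
    k: int,
    rng: np.random.Generator,
    random_choice: bool = False,
) -> np.ndarray:
    """Indices of the k highest values (ties uniformly random), or a random
    k-subset for control lines."""
    values = np.asarray(values, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > values.size:
        raise ValueError("cannot select more individuals than available")
    if random_choice:
        return rng.choice(values.size, size=k, replace=False)
    order = np.lexsort((rng.random(values.size), -values))
    return order[:k]


def breed_next_generation(
    pop: Population,
    mothers: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Breed selected mothers to random males; pool, sex and sample offspring.

    Each mother contributes ``pupae_per_mother`` offspring sired by one
    random male from the line's male pool; daughters get the sire haplotype
    plus a recombined maternal gamete, sons a maternal gamete only.  100
    daughters are sampled for the next assayed cohort; all sons form the
    next male pool.
    """
    mothers = np.asarray(mothers)
    if mothers.size == 0:
        raise MatingFailureError("no mothers selected")
    if pop.male_h.shape[0] == 0:
        raise MatingFailureError("no males available for mating")
    mates = rng.integers(0, pop.male_h.shape[0], size=mothers.size)

    per = config.pupae_per_mother
    mother_rows = np.repeat(mothers, per)
    sire_rows = np.repeat(mates, per)
    gametes = _maternal_gametes(pop.female_h, mother_rows, rng)
    is_daughter = rng.random(mother_rows.size) < config.sex_ratio

    d_gam = gametes[is_daughter]
    d_sire = pop.male_h[sire_rows[is_daughter]]
    daughters = np.stack([d_gam, d_sire], axis=1)  # (nd, 2, L)
    sons = gametes[~is_daughter]
    dam_of_daughter = mother_rows[is_daughter]

    if sons.shape[0] == 0:
        raise MatingFailureError("bred generation produced no male offspring")
    nf = config.females_per_line
    if daughters.shape[0] < nf:
        raise MatingFailureError(
            f"only {daughters.shape[0]} daughters produced; need {nf}"
        )
    pick = rng.choice(daughters.shape[0], size=nf, replace=False)
    return Population(
        female_h=daughters[pick],
        male_h=sons,
        dam_index=dam_of_daughter[pick],
    )


def run_line(
    config: SimConfig,
    line_id: str,
    line_type: str,
    rng: np.random.Generator,
) -> list[GenerationRecord]:
    pop = init_base_population(config, rng)
    records = []
    for t in range(config.generations + 1):
        trials, nbar, liab, killing = assay_cohort(pop, t, config, rng)
        sel = truncation_select(
            killing,
            config.selected_per_generation,
            rng,
            random_choice=(line_type == "control"),
        )
        g = trials["breeding_value"].to_numpy()
        records.append(
            GenerationRecord(
                line_id=line_id,
                line_type=line_type,
                generation=t,
                trials=trials,
                control_nbar=nbar,
                selected=sel,
                mean_all=float(killing.mean()),
                mean_selected=float(killing[sel].mean()),
                mean_latent_all=float(liab.mean()),
                mean_latent_selected=float(liab[sel].mean()),
                mean_g_all=float(g.mean()),
                mean_g_selected=float(g[sel].mean()),
            )
        )
        if t < config.generations:
            pop = breed_next_generation(pop, sel, config, rng)
    return records


def run_experiment(config: SimConfig) -> SelectionTrajectory:
    """Simulate all selection and control lines for the configured span."""
    records: list[GenerationRecord] = []
    for k in range(config.n_lines_selected):
        rng = rng_from_seed(config.seed, 1, k)
        records.extend(run_line(config, f"S{k + 1}", "selection", rng))
    for k in range(config.n_lines_control):
        rng = rng_from_seed(config.seed, 2, k)
        records.extend(run_line(config, f"C{k + 1}", "control", rng))
    return SelectionTrajectory(config=config, records=records)


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    return replace(config, **kwargs)
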