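"""Synthetic half-sib assay datasets with known genetic ground truth.

Emulates a paternal half-sib breeding design in a haplodiploid parasitoid:
each sire is mated to up to three dams and three daughters per dam are
assayed on 25 host larvae, families being spread over a small number of
testing blocks (one block = one testing day) with at least ten unexposed
control vials per day.  Daughter liabilities follow the same threshold
model the analysis assumes — additive genetic, day and mother variance
components plus a unit residual — so fits can be checked against the
generating values (parameter recovery).

Haplodiploid transmission makes a daughter's breeding value the sum of her
sire's (haploid) genotypic value and one maternal gamete; with non-inbred
founders this gives full-sister additive relatedness 0.75 and paternal
half-sister relatedness 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from waspqg.animal_model import heritability_from_components
from waspqg.tables import rng_from_seed


@dataclass(frozen=True)
class HalfSibDesign:
    n_sires: int = 68
    # how many sires achieved 1, 2 or 3 matings; counts must sum to n_sires
    dams_per_sire_distribution: dict[int, int] = field(
        default_factory=lambda: {1: 28, 2: 33, 3: 7}
    )
    daughters_per_dam: int = 3
    blocks: int = 5
    larvae_per_assay: int = 25
    control_vials_per_day: int = 10

    def __post_init__(self) -> None:
        if sum(self.dams_per_sire_distribution.values()) != self.n_sires:
            raise ValueError("dam-count distribution must cover every sire")
        if min(self.dams_per_sire_distribution) < 1:
            raise ValueError("each counted sire needs at least one dam")

    @property
    def n_dams(self) -> int:
        return sum(k * v for k, v in self.dams_per_sire_distribution.items())

    @property
    def n_daughters(self) -> int:
        return self.n_dams * self.daughters_per_dam


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters and realized effects behind one dataset."""

    va: float
    vday: float
    vmother: float
    vr: float
    base_mean: float
    baseline_survival: float
    day_effects: dict[str, float]
    mother_effects: dict[str, float]
    breeding_values: dict[str, float]
    liabilities: dict[str, float] = field(default_factory=dict)
    day_survival: dict[str, float] = field(default_factory=dict)

    @property
    def h2(self) -> float:
        return heritability_from_components(
            self.va, self.vday, self.vmother, self.vr, link="probit"
        )

    def to_dict(self) -> dict:
        return {
            "va": self.va,
            "vday": self.vday,
            "vmother": self.vmother,
            "vr": self.vr,
            "base_mean": self.base_mean,
            "baseline_survival": self.baseline_survival,
            "h2": self.h2,
        }


def generate_halfsib(
    design: HalfSibDesign,
    va: float = 1.077,
    vday: float = 0.345,
    vmother: float = 0.001,
    base_mean: float = -1.31,
    baseline_survival: float = 0.82,
    day_survival_jitter_sd: float = 0.03,
    encapsulation_prob: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (pedigree, trials, controls) tables plus the ground truth.

    Breeding values follow haplodiploid transmission: sire genotypic value
    x_s ~ N(0, Va/2) (one haplotype), dam value g_d = sum of two such
    haplotypes, daughter g = x_s + (g_d / 2 + Mendelian N(0, Va/4)).
    Kill counts are Binomial(larvae, Phi(liability)) thinned by the day's
    host survival; control vials are Binomial(larvae, day survival).
    Families are assigned to blocks round-robin; realized family totals are
    whatever the dam-count distribution yields.
    """
    rng = rng_from_seed(seed)
    ped_rows, trial_rows = [], []
    day_ids = [f"b{k + 1}" for k in range(design.blocks)]
    day_eff = {
        d: float(np.sqrt(vday) * rng.standard_normal()) for d in day_ids
    }
    day_surv = {
        d: float(
            np.clip(
                baseline_survival * (1.0 + day_survival_jitter_sd * rng.standard_normal()),
                0.05,
                1.0,
            )
        )
        for d in day_ids
    }

    N = design.larvae_per_assay
    mother_effects: dict[str, float] = {}
    breeding_values: dict[str, float] = {}
    liabilities: dict[str, float] = {}

    # control vials are drawn first: the assay bookkeeping anchors each
    # female's emergence count to the day's observed control mean, so the
    # day-standardized killing count inverts to the thinned kill count
    control_rows = []
    nbar: dict[str, float] = {}
    for d in day_ids:
        counts = rng.binomial(N, day_surv[d], size=design.control_vials_per_day)
        nbar[d] = float(counts.mean())
        for v, c in enumerate(counts):
            control_rows.append(
                {
                    "day_id": d,
                    "vial_id": f"{d}_v{v + 1}",
                    "n_larvae": N,
                    "flies_emerged": int(c),
                }
            )
    sire_counts = [
        k for k, cnt in sorted(design.dams_per_sire_distribution.items())
        for _ in range(cnt)
    ]
    rng.shuffle(sire_counts)

    dam_no = 0
    for s, n_dams in enumerate(sire_counts):
        sire_id = f"sire{s + 1}"
        block = day_ids[s % design.blocks]
        x_s = float(np.sqrt(va / 2.0) * rng.standard_normal())
        ped_rows.append({"id": sire_id, "sex": "M", "dam": "", "sire": ""})
        breeding_values[sire_id] = x_s
        for _ in range(n_dams):
            dam_no += 1
            dam_id = f"dam{dam_no}"
            g_d = float(np.sqrt(va / 2.0) * rng.standard_normal(2).sum())
            ped_rows.append({"id": dam_id, "sex": "F", "dam": "", "sire": ""})
            breeding_values[dam_id] = g_d
            mother_effects[dam_id] = float(
                np.sqrt(vmother) * rng.standard_normal()
            )
            for c in range(design.daughters_per_dam):
                daughter_id = f"{dam_id}_o{c + 1}"
                g = (
                    x_s
                    + g_d / 2.0
                    + float(np.sqrt(va / 4.0) * rng.standard_normal())
                )
                breeding_values[daughter_id] = g
                ped_rows.append(
                    {"id": daughter_id, "sex": "F", "dam": dam_id, "sire": sire_id}
                )
                liab = (
                    base_mean
                    + g
                    + day_eff[block]
                    + mother_effects[dam_id]
                    + float(rng.standard_normal())
                )
                liabilities[daughter_id] = liab
                q = float(ndtr(liab))
                # wasp kills K of the 25 larvae; only kills of larvae that
                # would have survived rearing count as excess mortality, so
                # the kill count is thinned by the day's background survival
                # and emergence is the day's expected survivor count minus
                # that excess (the structure the day-standardized killing
                # index inverts; see the module docstring)
                killed = int(rng.binomial(N, q))
                excess = int(rng.binomial(killed, day_surv[block]))
                f = max(int(math.floor(nbar[block] + 0.5)) - excess, 0)
                e = int(rng.binomial(f, encapsulation_prob))
                trial_rows.append(
                    {
                        "female_id": daughter_id,
                        "day_id": block,
                        "line_id": "halfsib",
                        "generation": 0,
                        "n_larvae": N,
                        "flies_emerged": f,
                        "flies_encapsulated": e,
                        "wasp_offspring": 0,
                        "mother_id": dam_id,
                    }
                )

    truth = TruthRecord(
        va=va,
        vday=vday,
        vmother=vmother,
        vr=1.0,
        base_mean=base_mean,
        baseline_survival=baseline_survival,
        day_effects=day_eff,
        mother_effects=mother_effects,
        breeding_values=breeding_values,
        liabilities=liabilities,
        day_survival=day_surv,
    )
    return (
        pd.DataFrame(ped_rows),
        pd.DataFrame(trial_rows),
        pd.DataFrame(control_rows),
        truth,
    )


def va_for_h2(
    h2: float, vday: float = 0.345, vmother: float = 0.001, vr: float = 1.0
) -> float:
    """Additive variance giving the requested threshold-scale heritability."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    rest = vday + vmother + vr + 1.0
    return h2 * rest / (1.0 - h2)


def generate_block_quality_scenario(
    seed: int = 0,
    targets: tuple[float, ...] = (10.8, 21.1, 20.0, 22.0, 20.0),
    n_vials: int = 10,
    n_larvae: int = 25,
) -> pd.DataFrame:
    """Control table with five blocks whose means hit the given targets.

    Vial counts are binomial draws nudged (within [0, n_larvae]) until each
    block's total matches its target mean to rounding, so the block means
    land within 1/n_vials of the targets; used to exercise the block
    quality-control filter.
    """
    rng = rng_from_seed(seed, 99)
    rows = []
    for b, target in enumerate(targets):
        counts = rng.binomial(n_larvae, min(target / n_larvae, 1.0), size=n_vials)
        want = int(round(target * n_vials))
        guard = 0
        while counts.sum() != want and guard < 10_000:
            i = rng.integers(0, n_vials)
            if counts.sum() < want and counts[i] < n_larvae:
                counts[i] += 1
            elif counts.sum() > want and counts[i] > 0:
                counts[i] -= 1
            guard += 1
        for v, c in enumerate(counts):
            rows.append(
                {
                    "day_id": f"b{b + 1}",
                    "vial_id": f"b{b + 1}_v{v + 1}",
                    "n_larvae": n_larvae,
                    "flies_emerged": int(c),
                }
            )
    return pd.DataFrame(rows)
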