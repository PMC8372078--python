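import pytest

from waspqg.indices import ControlVial, DayControlSummary, ExposureTrial
from waspqg.pedigree import PedigreeRecord, build_pedigree
from waspqg.synthetic import HalfSibDesign, generate_halfsib


@pytest.fixture
def day_control():
    return DayControlSummary(day_id="d1", n_bar=20.0, n_vials=10)


@pytest.fixture
def family_pedigree():
    """One sire, two dams, daughters and a son: the canonical relationships."""
    return build_pedigree(
        [
            PedigreeRecord("s1", "M"),
            PedigreeRecord("d1", "F"),
            PedigreeRecord("d2", "F"),
            PedigreeRecord("g1", "F", dam="d1", sire="s1"),
            PedigreeRecord("g2", "F", dam="d1", sire="s1"),
            PedigreeRecord("g3", "F", dam="d1", sire="s1"),
            PedigreeRecord("h1", "F", dam="d2", sire="s1"),
            PedigreeRecord("m1", "M", dam="d1"),
        ]
    )


@pytest.fixture(scope="session")
def small_halfsib():
    """A reduced half-sib dataset for fast end-to-end checks."""
    design = HalfSibDesign(
        n_sires=12, dams_per_sire_distribution={1: 4, 2: 4, 3: 4}, blocks=3
    )
    ped, trials, controls, truth = generate_halfsib(design, seed=123)
    return design, ped, trials, controls, truth


def make_trial(f, e=0, p=0, n_larvae=25, day_id="d1", female_id="w1"):
    return ExposureTrial(
        female_id=female_id, day_id=day_id, n_larvae=n_larvae, f=f, e=e, p=p
    )


def make_controls(day_id, emerged_counts, n_larvae=25):
    return [
        ControlVial(day_id=day_id, n_larvae=n_larvae, n_emerged=c)
        for c in emerged_counts
    ]
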