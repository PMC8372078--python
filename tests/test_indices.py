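import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waspqg.indices import (
    ControlVial,
    DayControlSummary,
    DegenerateControlError,
    EmptyDatasetError,
    ExposureTrial,
    MissingControlError,
    attack_rate,
    compute_performance_table,
    killing_rate,
    lethal_attack_rate,
    performance_record,
    qc_filter_blocks,
    standardized_counts,
    successful_parasitism,
    summarize_day_controls,
)
from tests.conftest import make_controls, make_trial


class TestDayControls:
    def test_mean_over_vials(self):
        s = summarize_day_controls(make_controls("d1", [20, 22, 18]), "d1")
        assert s.n_bar == 20.0
        assert s.n_vials == 3

    def test_single_vial_identity(self):
        s = summarize_day_controls(make_controls("d1", [25]), "d1")
        assert s.n_bar == 25.0

    def test_missing_day_raises(self):
        with pytest.raises(MissingControlError):
            summarize_day_controls(make_controls("d1", [20]), "d2")

    def test_vial_invariant(self):
        with pytest.raises(ValueError):
            ControlVial(day_id="d1", n_larvae=25, n_emerged=26)


class TestIndexFormulas:
    """Hand-verified arithmetic for the four standardized indices."""

    @pytest.mark.parametrize(
        "f,e,expected",
        [(10, 4, 70.0), (20, 0, 0.0), (12, 12, 100.0)],
    )
    def test_attack_rate(self, day_control, f, e, expected):
        assert attack_rate(make_trial(f=f, e=e), day_control) == pytest.approx(expected)

    def test_attack_rate_clamped_when_w_exceeds_control(self):
        control = DayControlSummary("d1", 18.0, 10)
        trial = make_trial(f=22, e=0)  # 22 survivors vs control mean 18
        assert attack_rate(trial, control) == 0.0
        assert performance_record(trial, control).attack_clamped

    @pytest.mark.parametrize("f,expected", [(10, 50.0), (20, 0.0)])
    def test_killing_rate(self, day_control, f, expected):
        assert killing_rate(make_trial(f=f), day_control) == pytest.approx(expected)

    def test_negative_killing_floored_to_zero(self):
        control = DayControlSummary("d1", 18.0, 10)
        assert killing_rate(make_trial(f=22), control) == 0.0

    def test_lethal_attack_rate(self, day_control):
        assert lethal_attack_rate(make_trial(f=10, e=4), day_control) == pytest.approx(
            100 * 10 / 14
        )

    def test_lethal_attack_undefined_when_none_attacked(self, day_control):
        assert lethal_attack_rate(make_trial(f=20, e=0), day_control) is None

    def test_lethal_attack_all_killed(self, day_control):
        # w = f and e = 0: every attacked fly died
        assert lethal_attack_rate(make_trial(f=12, e=0), day_control) == 100.0

    def test_successful_parasitism(self, day_control):
        assert successful_parasitism(make_trial(f=10, p=1), day_control) == 10.0
        assert successful_parasitism(make_trial(f=10, p=0), day_control) == 0.0

    def test_successful_parasitism_undefined_without_kills(self, day_control):
        assert successful_parasitism(make_trial(f=20, p=0), day_control) is None

    def test_degenerate_control_raises(self):
        control = DayControlSummary("d1", 0.0, 10)
        with pytest.raises(DegenerateControlError):
            killing_rate(make_trial(f=10), control)

    def test_trial_invariants(self):
        with pytest.raises(ValueError):
            ExposureTrial("w", "d", 25, f=26, e=0, p=0)
        with pytest.raises(ValueError):
            ExposureTrial("w", "d", 25, f=10, e=11, p=0)
        with pytest.raises(ValueError):
            ExposureTrial("w", "d", 25, f=10, e=0, p=16)  # p > n - f


class TestIndexProperties:
    @given(
        f=st.integers(0, 25),
        e=st.integers(0, 25),
        n_bar=st.floats(1.0, 25.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_killing_never_exceeds_attack(self, f, e, n_bar):
        e = min(e, f)
        control = DayControlSummary("d1", n_bar, 5)
        trial = make_trial(f=f, e=e)
        assert killing_rate(trial, control) <= attack_rate(trial, control) + 1e-9

    @given(
        f=st.integers(0, 20),
        e=st.integers(0, 20),
        n_bar=st.floats(5.0, 24.0),
        k=st.integers(2, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, f, e, n_bar, k):
        e = min(e, f)
        c1 = DayControlSummary("d1", n_bar, 5)
        c2 = DayControlSummary("d1", n_bar * k, 5)
        t1 = make_trial(f=f, e=e, n_larvae=25)
        t2 = make_trial(f=f * k, e=e * k, n_larvae=25 * k)
        assert attack_rate(t1, c1) == pytest.approx(attack_rate(t2, c2))
        assert killing_rate(t1, c1) == pytest.approx(killing_rate(t2, c2))
        lar1, lar2 = lethal_attack_rate(t1, c1), lethal_attack_rate(t2, c2)
        assert (lar1 is None) == (lar2 is None)
        if lar1 is not None:
            assert lar1 == pytest.approx(lar2)

    @given(f=st.integers(0, 19), n_bar=st.floats(5.0, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_lethal_is_total_when_no_encapsulation(self, f, n_bar):
        # with e = 0 every attacked fly died, so killing > 0 implies 100%
        control = DayControlSummary("d1", n_bar, 5)
        trial = make_trial(f=f, e=0)
        kr = killing_rate(trial, control)
        lar = lethal_attack_rate(trial, control)
        if kr > 0:
            assert lar == pytest.approx(100.0)


class TestBlockQC:
    def test_low_quality_block_excluded(self):
        blocks = [
            DayControlSummary(d, m, 10)
            for d, m in zip("abcde", [10.8, 21.1, 20.0, 22.0, 20.0])
        ]
        retained, excluded = qc_filter_blocks(blocks)
        assert len(retained) == 4
        assert [b.n_bar for b in excluded] == [10.8]

    def test_identical_means_all_retained(self):
        blocks = [DayControlSummary(d, 20.0, 10) for d in "abc"]
        retained, excluded = qc_filter_blocks(blocks)
        assert len(retained) == 3 and not excluded

    def test_rule_arithmetic(self):
        blocks = [DayControlSummary(d, m, 10) for d, m in zip("abc", [5, 20, 20])]
        retained, _ = qc_filter_blocks(blocks)
        assert len(retained) == 2

    def test_order_independent_and_idempotent(self):
        blocks = [
            DayControlSummary(d, m, 10)
            for d, m in zip("abcde", [10.8, 21.1, 20.0, 22.0, 20.0])
        ]
        r1, _ = qc_filter_blocks(blocks)
        r2, _ = qc_filter_blocks(blocks[::-1])
        assert {b.day_id for b in r1} == {b.day_id for b in r2}
        r3, e3 = qc_filter_blocks(r1)
        assert {b.day_id for b in r3} == {b.day_id for b in r1} and not e3

    def test_all_excluded_raises(self):
        # median-relative rule cannot empty the set unless threshold > 1
        blocks = [DayControlSummary(d, 20.0, 10) for d in "ab"]
        with pytest.raises(EmptyDatasetError):
            qc_filter_blocks(blocks, ratio_threshold=1.5)


class TestStandardizedCounts:
    @pytest.mark.parametrize(
        "index,n_bar,f,e,expected",
        [
            ("killing", 20.4, 10, 0, (10, 10)),
            ("killing", 20.0, 20, 0, (0, 20)),
            ("attack", 20.0, 10, 4, (14, 6)),
        ],
    )
    def test_examples(self, index, n_bar, f, e, expected):
        control = DayControlSummary("d1", n_bar, 10)
        assert standardized_counts(make_trial(f=f, e=e), control, index) == expected

    def test_undefined_pairs_are_none(self, day_control):
        assert standardized_counts(make_trial(f=20, e=0), day_control, "lethal") is None
        assert (
            standardized_counts(make_trial(f=20, p=0), day_control, "parasitism")
            is None
        )

    @given(f=st.integers(0, 25), e=st.integers(0, 25), n_bar=st.floats(1.0, 25.0))
    @settings(max_examples=200, deadline=None)
    def test_pairs_are_valid_counts(self, f, e, n_bar):
        e = min(e, f)
        control = DayControlSummary("d1", n_bar, 5)
        trial = make_trial(f=f, e=e)
        for index in ("killing", "attack", "lethal", "parasitism"):
            pair = standardized_counts(trial, control, index)
            if pair is not None:
                s, fl = pair
                assert s >= 0 and fl >= 0 and s + fl > 0


class TestTablePipeline:
    def test_performance_table(self, small_halfsib):
        _, _, trials, controls, _ = small_halfsib
        table = compute_performance_table(trials, controls)
        assert len(table) == len(trials)
        assert set(
            ["attack_rate", "killing_rate", "lethal_attack_rate",
             "successful_parasitism", "lethal_defined", "killing_clamped"]
        ) <= set(table.columns)
        assert table["killing_rate"].between(0, 100).all()
        assert table["attack_rate"].between(0, 100).all()
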