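"""Odds/probability conversions and likelihood-ratio chaining."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from omibayes import (
    EvidenceItem,
    FullPrecision,
    LikelihoodRatio,
    PrintedCheckpoint,
    ProbabilityValue,
    apply_lr,
    chain_update,
    odds_to_prob,
    prob_to_odds,
    propagate_interval,
    round_percent,
)

probs = st.floats(min_value=1e-4, max_value=0.9999, allow_nan=False)
lrs = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def ev(*values):
    return [EvidenceItem(f"e{i}", LikelihoodRatio(v)) for i, v in enumerate(values)]


class TestConversions:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, 1.0),
            (0.16, 0.16 / 0.84),  # 0.190476...
            (0.196, 0.196 / 0.804),  # 0.243781...
        ],
    )
    def test_prob_to_odds(self, p, expected):
        assert prob_to_odds(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "o,expected",
        [
            (1.0, 0.5),
            (0.16 / 0.84, 0.16),
            (3.0473, 3.0473 / 4.0473),  # 0.75292..., the high-probability regime
        ],
    )
    def test_odds_to_prob(self, o, expected):
        assert odds_to_prob(o) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_prob_domain_error_names_value(self, bad):
        with pytest.raises(ValueError, match=repr(bad)):
            prob_to_odds(bad)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_odds_domain_error(self, bad):
        with pytest.raises(ValueError):
            odds_to_prob(bad)

    @given(probs)
    @settings(derandomize=True)
    def test_round_trip(self, p):
        assert odds_to_prob(prob_to_odds(p)) == pytest.approx(p, abs=1e-12)


class TestApplyLR:
    @pytest.mark.parametrize(
        "prior,lr,expected",
        [
            # anterior ST elevation applied to a 0.8% pre-ECG probability
            (0.008, 12.5, 0.0915750915750916),
            # negative troponin pulling an intermediate probability down
            (0.27, 0.28, 0.0938430983118173),
            # millimetric pattern lifting a 19.6% pre-ECG probability
            (0.196, 12.5, 0.7529194837123541),
        ],
    )
    def test_published_updates(self, prior, lr, expected):
        assert apply_lr(prior, lr) == pytest.approx(expected, abs=1e-12)

    @given(probs)
    @settings(derandomize=True)
    def test_neutral_evidence(self, p):
        assert apply_lr(p, 1.0) == p

    @given(probs, lrs, lrs)
    @settings(derandomize=True)
    def test_monotone_in_lr(self, p, lr1, lr2):
        if lr1 == lr2:
            return
        lo, hi = sorted((lr1, lr2))
        assert apply_lr(p, lo) < apply_lr(p, hi)

    @given(probs, probs, lrs)
    @settings(derandomize=True)
    def test_monotone_in_prior(self, p1, p2, lr):
        if p1 == p2:
            return
        lo, hi = sorted((p1, p2))
        assert apply_lr(lo, lr) < apply_lr(hi, lr)

    @given(probs, lrs)
    @settings(derandomize=True)
    def test_complement_symmetry(self, p, lr):
        assert apply_lr(p, lr) + apply_lr(1.0 - p, 1.0 / lr) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rejects_nonpositive_lr(self):
        with pytest.raises(ValueError):
            apply_lr(0.5, 0.0)


class TestChainUpdate:
    def test_case1_pre_ecg_chain(self):
        # 0.17% anchor through male sex, typical pain, recent pain change
        trace = chain_update(0.0017, ev(1.3, 1.9, 2.0))
        assert trace.posterior.p == pytest.approx(0.0083421, abs=5e-7)

    def test_case5_pre_ecg_chain(self):
        trace = chain_update(0.09, ev(1.9, 1.3))
        assert trace.posterior.p == pytest.approx(0.19632, abs=5e-5)

    def test_reciprocal_lrs_cancel(self):
        trace = chain_update(0.5, ev(2.0, 0.5))
        assert trace.posterior.p == pytest.approx(0.5, abs=1e-12)

    def test_empty_evidence_returns_prior(self):
        trace = chain_update(0.3, [])
        assert trace.posterior.p == 0.3
        assert trace.steps == ()

    @given(probs, st.lists(lrs, min_size=1, max_size=5))
    @settings(derandomize=True)
    def test_collapsibility(self, prior, values):
        trace = chain_update(prior, ev(*values))
        assert trace.posterior.p == pytest.approx(
            apply_lr(prior, math.prod(values)), abs=1e-12
        )

    @given(probs, st.permutations([1.3, 1.9, 2.0, 0.23]))
    @settings(derandomize=True)
    def test_commutativity_full_precision(self, prior, order):
        base = chain_update(prior, ev(1.3, 1.9, 2.0, 0.23)).posterior.p
        assert chain_update(prior, ev(*order)).posterior.p == pytest.approx(
            base, abs=1e-12
        )

    def test_trace_steps_consistent(self):
        trace = chain_update(0.05, ev(2.0, 0.5, 3.0))
        for step in trace.steps:
            assert step.post == pytest.approx(apply_lr(step.pre, step.lr_value))
        assert trace.prior.p == 0.05
        assert trace.steps[-1].post == trace.posterior.p

    def test_printed_checkpoint_rounds_each_step(self):
        # 0.8% fed to the ECG step only after rounding the pre-ECG chain
        policy = PrintedCheckpoint(step_decimals=(None, None, 1, 1))
        trace = chain_update(0.0017, ev(1.3, 1.9, 2.0, 12.5), policy)
        assert trace.steps[2].post == pytest.approx(0.008, abs=1e-12)
        assert trace.posterior.p == pytest.approx(0.092, abs=1e-12)

    def test_printed_checkpoint_override_carries_stated_value(self):
        policy = PrintedCheckpoint(step_decimals=(0,), step_overrides=(0.17,))
        trace = chain_update(0.46, ev(0.23), policy)
        assert trace.posterior.p == 0.17

    def test_policy_length_mismatch(self):
        with pytest.raises(ValueError, match="declares"):
            chain_update(0.5, ev(2.0), PrintedCheckpoint(step_decimals=(1, 1)))


class TestRoundPercent:
    @pytest.mark.parametrize(
        "p,decimals,expected",
        [
            (0.555424, 0, 0.56),  # half-up at the integer scale
            (0.095, 0, 0.10),
            (0.0915751, 1, 0.092),
            (0.0022089, 2, 0.0022),
            (0.00834, 1, 0.008),
        ],
    )
    def test_half_up_on_percent_scale(self, p, decimals, expected):
        assert round_percent(p, decimals) == pytest.approx(expected, abs=1e-15)


class TestProbabilityValue:
    def test_odds_view_round_trip(self):
        pv = ProbabilityValue(0.37)
        assert ProbabilityValue.from_odds(pv.odds).p == pytest.approx(0.37, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0])
    def test_degenerate_rejected(self, bad):
        with pytest.raises(ValueError):
            ProbabilityValue(bad)

    def test_lr_interval_must_bracket_point(self):
        with pytest.raises(ValueError):
            LikelihoodRatio(2.0, ci_low=2.5, ci_high=3.0)

    def test_direction_consistency(self):
        assert EvidenceItem("a", LikelihoodRatio(2.0)).direction == "supports"
        assert EvidenceItem("b", LikelihoodRatio(0.5)).direction == "refutes"
        with pytest.raises(ValueError):
            EvidenceItem("c", LikelihoodRatio(2.0), direction="refutes")
        # LR exactly 1 accepts either label
        EvidenceItem("d", LikelihoodRatio(1.0), direction="supports")
        EvidenceItem("e", LikelihoodRatio(1.0), direction="refutes")


class TestPropagateInterval:
    def test_degenerate_intervals_collapse_to_point(self):
        items = [
            EvidenceItem("a", LikelihoodRatio(2.0, 2.0, 2.0)),
            EvidenceItem("b", LikelihoodRatio(0.5, 0.5, 0.5)),
        ]
        lo, hi = propagate_interval(0.1, items, n_draws=2000, seed=3)
        point = chain_update(0.1, items).posterior.p
        assert lo == pytest.approx(point, abs=1e-12)
        assert hi == pytest.approx(point, abs=1e-12)

    def test_published_chain_interval_brackets_point(self):
        # 1.4% anchor with both-arm radiation and typical pain
        items = [
            EvidenceItem("both arms", LikelihoodRatio(2.6, 1.8, 3.7)),
            EvidenceItem("typical", LikelihoodRatio(1.9, 0.94, 2.9)),
        ]
        lo, hi = propagate_interval(0.014, items, n_draws=100_000, seed=1)
        assert lo < 0.066 < hi

    def test_ci_spanning_one_spans_prior(self):
        items = [EvidenceItem("weak", LikelihoodRatio(1.0, 0.5, 2.0))]
        lo, hi = propagate_interval(0.2, items, n_draws=50_000, seed=2)
        assert lo < 0.2 < hi

    def test_missing_ci_lists_item(self):
        items = [
            EvidenceItem("has ci", LikelihoodRatio(2.0, 1.5, 2.5)),
            EvidenceItem("bare lr", LikelihoodRatio(1.3)),
        ]
        with pytest.raises(ValueError, match="bare lr"):
            propagate_interval(0.1, items, n_draws=2000, seed=0)

    def test_deterministic_for_fixed_seed(self):
        items = [EvidenceItem("a", LikelihoodRatio(2.0, 1.5, 2.7))]
        assert propagate_interval(0.1, items, 5000, seed=9) == propagate_interval(
            0.1, items, 5000, seed=9
        )

    def test_too_few_draws_rejected(self):
        items = [EvidenceItem("a", LikelihoodRatio(2.0, 1.5, 2.7))]
        with pytest.raises(ValueError, match="1000"):
            propagate_interval(0.1, items, n_draws=10, seed=0)
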