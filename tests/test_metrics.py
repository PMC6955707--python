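import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cptsim import (
    SessionCounts,
    correct_response_factor,
    engagement_factor,
    error_factor,
    impulsivity_factor,
    inattention_factor,
    mean_sd_crt,
    performance_index,
    round_percent,
    score_session,
    score_summary,
    tally,
)
from conftest import make_log
from oracle import oracle_metrics


# ---------------------------------------------------------------------------
# hypothesis strategy: arbitrary valid session logs
# ---------------------------------------------------------------------------

@st.composite
def raw_sessions(draw, max_trials: int = 10):
    """(outcomes, rts, n_trials, theta) for a valid session."""
    n_trials = draw(st.integers(1, max_trials))
    n_play = draw(st.integers(0, n_trials))
    outcomes = draw(
        st.lists(
            st.sampled_from(["correct", "commission", "omission"]),
            min_size=n_play,
            max_size=n_play,
        )
    )
    if n_play < n_trials and draw(st.booleans()):
        outcomes = outcomes + ["quit"]
    theta = 60.0
    rts = [
        draw(st.floats(0.5, theta, allow_nan=False)) if o in ("correct", "commission") else None
        for o in outcomes
    ]
    return outcomes, rts, n_trials, theta


def _build(outcomes, rts, n_trials, theta):
    return make_log(
        outcomes, rts=[r for r in rts if r is not None], n_trials=n_trials, theta=theta
    )


# ---------------------------------------------------------------------------
# tallies
# ---------------------------------------------------------------------------

class TestTally:
    def test_reference_phase_counts(self):
        log = make_log(
            ["correct"] * 3 + ["omission"] * 3 + ["commission"] * 4,
            rts=[25.0] * 7,
        )
        c = tally(log)
        assert (c.C, c.OE, c.CE, c.I, c.K) == (3, 3, 4, 7, 0)

    def test_immediate_quit_forfeits_all_tries(self, quit_first_log):
        c = tally(quit_first_log)
        assert (c.C, c.I, c.K) == (0, 0, 10)

    def test_invalid_log_is_rejected_naming_first_violation(self):
        log = make_log(["quit", "quit"])
        with pytest.raises(ValueError, match="quit"):
            tally(log)

    @given(raw_sessions())
    @settings(max_examples=200, deadline=None)
    def test_conservation_identities(self, raw):
        outcomes, rts, n_trials, theta = raw
        c = tally(_build(*raw))
        assert c.T == c.C + c.I + c.K
        assert c.I == c.OE + c.CE
        assert c.T == n_trials


# ---------------------------------------------------------------------------
# response-time summaries
# ---------------------------------------------------------------------------

class TestMeanSd:
    @pytest.mark.parametrize(
        "crts, m, sd",
        [
            ([10.0, 20.0, 30.0], 20.0, 10.0),
            ([25.13], 25.13, 0.0),
            ([7.0, 7.0, 7.0, 7.0], 7.0, 0.0),
        ],
    )
    def test_known_values(self, crts, m, sd):
        got_m, got_sd = mean_sd_crt(crts)
        assert got_m == pytest.approx(m)
        assert got_sd == pytest.approx(sd)

    def test_empty_means_absent(self):
        assert mean_sd_crt([]) == (None, 0.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mean_sd_crt([5.0, -1.0])


# ---------------------------------------------------------------------------
# individual factors
# ---------------------------------------------------------------------------

class TestFactors:
    @pytest.mark.parametrize(
        "counts, gf, iaf, imf, ef",
        [
            (SessionCounts(C=3, OE=3, CE=4, K=0), 1.0, 0.3, 0.4, 0.7),
            (SessionCounts(C=8, OE=1, CE=1, K=0), 1.0, 0.1, 0.1, 0.2),
            (SessionCounts(C=3, OE=0, CE=0, K=7), 0.3, 0.0, 0.0, 0.0),
            (SessionCounts(C=0, OE=0, CE=0, K=10), 0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_reference_values(self, counts, gf, iaf, imf, ef):
        assert engagement_factor(counts) == pytest.approx(gf)
        assert inattention_factor(counts) == pytest.approx(iaf)
        assert impulsivity_factor(counts) == pytest.approx(imf)
        assert error_factor(counts) == pytest.approx(ef)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            engagement_factor(SessionCounts(C=0, OE=0, CE=0, K=0))

    @given(
        st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_error_factor_additivity(self, c, oe, ce, k):
        counts = SessionCounts(C=c, OE=oe, CE=ce, K=k)
        assert error_factor(counts) == inattention_factor(counts) + impulsivity_factor(counts)


class TestCorrectResponseFactor:
    def test_reference_phase1(self):
        assert correct_response_factor(3 * 25.13, 3, 60.0) == pytest.approx(75.39 / 180.0)

    def test_maximal_time_saturates_at_one(self):
        assert correct_response_factor(5 * 60.0, 5, 60.0) == 1.0

    def test_no_correct_tries_is_zero(self):
        assert correct_response_factor(0.0, 0, 60.0) == 0.0

    def test_impossible_log_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            correct_response_factor(200.0, 3, 60.0)


class TestPerformanceIndex:
    @pytest.mark.parametrize(
        "crf, ef, gf, percent",
        [
            (25.13 / 60, 0.70, 1.0, 44),
            (21.62 / 60, 0.0, 1.0, 82),
            (0.0, 0.0, 1.0, 100),
        ],
    )
    def test_reference_values(self, crf, ef, gf, percent):
        assert round_percent(performance_index(crf, ef, gf)) == percent

    def test_zero_engagement_floors_everything(self):
        assert performance_index(0.9, 0.9, 0.0) == 0.0

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            performance_index(1.2, 0.0, 1.0)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0.01, 1), st.floats(0.001, 0.2)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_argument(self, crf, ef, gf, eps):
        base = performance_index(crf, ef, gf)
        if crf + eps <= 1.0:
            assert performance_index(crf + eps, ef, gf) < base
        if ef + eps <= 1.0:
            assert performance_index(crf, ef + eps, gf) < base
        if gf + eps <= 1.0 and (1 - crf) + (1 - ef) > 0:
            assert performance_index(crf, ef, gf + eps) > base

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_range(self, crf, ef, gf):
        assert 0.0 <= performance_index(crf, ef, gf) <= 1.0


# ---------------------------------------------------------------------------
# full-session scoring
# ---------------------------------------------------------------------------

class TestScoreSession:
    def test_fully_correct_session(self, all_correct_log):
        m = score_session(all_correct_log)
        assert m.GF == 1.0
        assert m.EF == 0.0
        assert m.CRF == pytest.approx(5.0 / 60.0)
        assert m.PI == pytest.approx(((55.0 / 60.0) + 1.0) / 2.0)
        assert m.GT == pytest.approx(50.0)
        assert m.ST == 600.0

    def test_immediate_quit_scores_worst(self, quit_first_log):
        m = score_session(quit_first_log)
        assert m.GF == 0.0
        assert m.PI == 0.0
        assert m.M is None

    def test_omissions_contribute_full_theta_to_game_time(self):
        log = make_log(["omission"] * 3 + ["correct"] * 7, rts=[10.0] * 7)
        assert score_session(log).GT == pytest.approx(3 * 60.0 + 70.0)

    @given(raw_sessions())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, raw):
        outcomes, rts, n_trials, theta = raw
        m = score_session(_build(*raw))
        ref = oracle_metrics(outcomes, rts, n_trials, theta)
        for key in ("GF", "IAF", "IMF", "EF", "CRF", "PI", "GT", "ST"):
            assert getattr(m, key) == pytest.approx(ref[key], abs=1e-12)
        if ref["M"] is None:
            assert m.M is None
        else:
            assert m.M == pytest.approx(ref["M"])
            assert m.SD == pytest.approx(ref["SD"])

    @given(raw_sessions())
    @settings(max_examples=150, deadline=None)
    def test_summary_mode_agrees_with_trial_mode(self, raw):
        m = score_session(_build(*raw))
        c = m.counts
        s = score_summary(C=c.C, OE=c.OE, CE=c.CE, K=c.K, M=m.M, theta=m.theta)
        for key in ("GF", "IAF", "IMF", "EF", "CRF", "PI"):
            assert getattr(s, key) == pytest.approx(getattr(m, key), abs=1e-9)
        assert s.SD is None and s.GT is None


class TestScoreSummary:
    def test_reference_phase_rows(self):
        assert round_percent(score_summary(5, 3, 2, 0, 23.71).PI) == 55
        m = score_summary(7, 0, 0, 3, 22.94)
        assert m.GF == pytest.approx(0.7)
        assert round_percent(m.PI) == 57

    def test_all_quit_summary(self):
        m = score_summary(0, 0, 0, 10, None)
        assert m.PI == 0.0

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            score_summary(0, 0, 0, 0, None)
        with pytest.raises(ValueError):
            score_summary(3, 0, 0, 7, None)  # M required when C > 0
        with pytest.raises(ValueError):
            score_summary(3, 0, 0, 7, 75.0)  # M above theta


# ---------------------------------------------------------------------------
# exhaustive small-session oracle equivalence
# ---------------------------------------------------------------------------

CRT_GRID = (5.0, 25.0, 60.0)


def _small_sessions(max_T=5):
    """Every outcome sequence with T ≤ max_T, CRTs over a 3-value grid.

    Metrics depend on the correct-CRT multiset (not its order), so CRT
    assignments enumerate combinations with replacement; commission trials
    get a fixed response time, which only GT sees.
    """
    for T in range(1, max_T + 1):
        for n_play in range(T + 1):
            for outcome_seq in itertools.product(
                ("correct", "commission", "omission"), repeat=n_play
            ):
                tails = [()] if n_play == T else [(), ("quit",)]
                for tail in tails:
                    outcomes = list(outcome_seq) + list(tail)
                    n_correct = outcome_seq.count("correct")
                    for crt_multiset in itertools.combinations_with_replacement(
                        CRT_GRID, n_correct
                    ):
                        crt_iter = iter(crt_multiset)
                        rts = [
                            next(crt_iter) if o == "correct"
                            else (10.0 if o == "commission" else None)
                            for o in outcomes
                        ]
                        yield outcomes, rts, T


def test_exhaustive_small_sessions_match_oracle():
    """Scoring equals the independent recomputation on every small session."""
    n_checked = 0
    for outcomes, rts, T in _small_sessions():
        log = make_log(outcomes, rts=[r for r in rts if r is not None], n_trials=T)
        m = score_session(log)
        ref = oracle_metrics(outcomes, rts, T, 60.0)
        for key in ("GF", "IAF", "IMF", "EF", "CRF", "PI", "GT", "ST", "SD"):
            got = getattr(m, key)
            assert got == pytest.approx(ref[key], abs=1e-12), (key, outcomes, rts)
        assert (m.counts.C, m.counts.OE, m.counts.CE, m.counts.K) == (
            ref["C"], ref["OE"], ref["CE"], ref["K"],
        )
        n_checked += 1
    assert n_checked > 3000  # the enumeration is genuinely exhaustive
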