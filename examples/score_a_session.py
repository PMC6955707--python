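"""Score a single hand-built session log.

Builds a 10-trial session (3 correct, 3 omissions, 4 commissions) and
prints every performance measure the engine computes for it.
"""

from cptsim import Outcome, SessionConfig, SessionLog, TrialRecord, score_session

trials = []
for i, (outcome, rt) in enumerate(
    [("correct", 25.13)] * 3 + [("omission", None)] * 3 + [("commission", 12.0)] * 4
):
    trials.append(TrialRecord(index=i, outcome=Outcome(outcome), response_time=rt))

log = SessionLog(
    session_id="demo",
    config=SessionConfig(n_trials=10, trial_limit=60.0),
    trials=tuple(trials),
)
m = score_session(log)

print(f"counts: C={m.counts.C} OE={m.counts.OE} CE={m.counts.CE} K={m.counts.K}")
print(f"mean correct response time M = {m.M:.2f} s (SD {m.SD:.2f} s)")
print(f"engagement GF = {m.GF:.0%}   inattention IAF = {m.IAF:.0%}   "
      f"impulsivity IMF = {m.IMF:.0%}   errors EF = {m.EF:.0%}")
print(f"correct-response factor CRF = {m.CRF:.3f}")
print(f"Performance Index PI = {m.PI:.4f}  (~{m.PI:.0%} of the best possible session)")
print(f"elapsed game time GT = {m.GT:.1f} s of at most ST = {m.ST:.0f} s")
# Seven of ten tries were errors, so the error factor dominates: despite full
# engagement (GF=100%) the composite PI lands near 44%.
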