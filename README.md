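# cptsim

Simulation and scoring of game-based continuous performance tests (CPTs)
for attention training, aimed at researchers and developers of serious
games and digital ADHD assessment tools.

A CPT session presents a fixed number of tries (*T*, default 10), each
limited to θ seconds (default 60). The patient either hits the target
stimulus (**correct**, with a correct response time, CRT), hits the
non-target (**commission error**, indexing impulsivity), lets the timer
run out (**omission error**, indexing inattention), or quits the session,
forfeiting the remaining tries (**uncompleted**, *K*). From the tallies
*C*, *OE*, *CE* (with *I = OE + CE* and *T = C + I + K*) and the CRTs,
`cptsim` computes the standard session measures:

```
M, SD  = mean and sample SD of the correct response times
GF     = (C + I) / T                      engagement factor
IAF    = OE / (C + I)                     inattention factor
IMF    = CE / (C + I)                     impulsivity factor
EF     = IAF + IMF                        error factor
CRF    = Σ CRT / (C · θ)                  correct response factor
PI     = [((1 − CRF) + (1 − EF)) / 2] · GF   performance index
```

All measures are fractions in [0, 1]; fast, accurate, engaged play scores
a high PI. Beyond scoring, the package ships a seeded trial-level
simulator (per-trial omission/commission/quit probabilities, truncated
normal response times with a linear improvement schedule), a
method-of-moments estimator that recovers the behaviour probabilities from
logs, JSONL/CSV trial-stream I/O, and a built-in two-part case study over
fixed phase parameter sets.

## Worked example

```python
>>> from cptsim import score_summary, round_percent
>>> m = score_summary(C=3, OE=3, CE=4, K=0, M=25.13, theta=60.0)
>>> round_percent(m.GF), round_percent(m.EF), round_percent(m.PI)
(100, 70, 44)
```

A session with 3 correct tries (mean CRT 25.13 s), 3 omissions and 4
commissions has full engagement (GF = 100%) but a 70% error rate, so the
composite index lands at PI = 44%. Running
`python examples/run_case_study.py` prints the full phase tables; part 1
(error variation at full engagement) yields Average PI 44 / 55 / 72 %
across its three phases, and part 2 (engagement variation with no errors)
yields 24 / 40 / 57 / 82 %.

The same pipeline is available from the shell:

```bash
cptsim simulate --sessions 20 --seed 7 --out logs.jsonl
cptsim score --in logs.jsonl --out metrics.csv
cptsim case-study --part 1 --out-dir results/ --curves
cptsim validate --in logs.jsonl
```

## Layout

- `src/cptsim/model.py` — domain types (profiles, session config, trial records) and log validation
- `src/cptsim/metrics.py` — tallies, factors and the performance index
- `src/cptsim/simulator.py` — stochastic behaviour model, seeded session generator, parameter recovery
- `src/cptsim/case_study.py` — the two-part phase experiment, PI curves, generative cross-check
- `src/cptsim/io.py`, `src/cptsim/cli.py` — JSONL/CSV/YAML I/O and the `cptsim` command
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model assumptions, conventions and limitations
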