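# physioecon

Tools for a physioeconomics study design that combines a **bribery
auction** (experimental economics) with **event-related skin-conductance
analysis** (psychophysiology).

Two firms compete for a procurement contract in front of an official.
Each firm splits a fixed budget *A* between a quality bid *Q* — which
benefits everyone through a social return *a* per unit — and a bribe
*B = A − Q* — which benefits only the official and costs the winning
firm *c* per unit. The official picks one bid; the winner also earns a
reward *R*, and every player receives an endowment *F* per period:

```
π_official = F + a·Q_w + B_w
π_winner   = F + a·Q_w − c·B_w + R
π_loser    = F + a·Q_w
```

A psychological extension charges each agent a bribery-aversion cost γ
per unit of bribe (`(1−γ_official)·B_w` for the official,
`(c+γ_winner)·B_w` for the winner). In an *Inspection* treatment the
losing firm may audit the transaction: a revealed bribe zeroes the
corrupt pair's period earnings; a false accusation zeroes the accuser's.

The package provides:

- **`physioecon.game`** — payoffs, the official's choice rule, exhaustive
  Nash enumeration on the integer bid grid (with arbitrary refinement),
  closed-form psychological equilibria, and the inspection/punishment
  transformation.
- **`physioecon.simulate`** — an agent-based generator of full sessions:
  fixed triplets (1 official + 2 firms) play 15 Baseline then 15
  Inspection periods; firms are softmax best-responders with adaptive
  beliefs, officials act on heterogeneous bribery aversion, losers
  inspect with a geometrically decaying propensity. Produces period
  records and per-subject event markers with timestamps and response
  times.
- **`physioecon.edasynth`** — synthetic 125 Hz skin-conductance traces:
  bi-exponential SCRs locked to the behavioral events, condition-
  dependent lognormal amplitudes, drifting tonic level, noise, and full
  ground truth for detector validation.
- **`physioecon.pipeline`** — the processing chain: 0.5 Hz zero-phase
  Butterworth low-pass, trough-to-peak SCR detection with a 0.02 μS
  amplitude floor, association of SCRs to decision/feedback events
  through latency windows, and baseline-corrected condition epochs.
- **`physioecon.stats`** — the sample-wise surrogate permutation test
  (200 surrogates, Benjamini–Hochberg FDR across time samples,
  significant latency intervals), tie-corrected Mann–Whitney z, Spearman
  rank correlation, and exact percentage tables.
- **`physioecon.workflow` / CLI** — `simulate`, `analyze`, `equilibria`
  and `report` verbs tying everything together with delimited-text
  artifacts and JSON run manifests.

## Worked example

The equilibrium report for the default economy
(*F*, *a*, *c*, *A*, *R*) = (10, ½, 2, 10, 10):

```
$ physioecon equilibria
parameters: (F, a, c, A, R) = (10, 0.5, 2, 10, 10)
continuous monetary equilibrium bribe: 5
psychological prediction [bribe branch]: firm1 (Q, B) = (5, 5), firm2 (Q, B) = (5, 5)
  nearest integer bids: (5, 5), (5, 5)
discrete enumeration (step 1): 3 equilibria
  firm1 (Q, B) = (7, 3), firm2 (Q, B) = (7, 3)  [strict]
  firm1 (Q, B) = (6, 4), firm2 (Q, B) = (6, 4)  [strict]
  firm1 (Q, B) = (5, 5), firm2 (Q, B) = (5, 5)  [weak]
```

Reading: with continuous bids, Bertrand-style bribe competition stops at
*B = R/c =* 5, where the bribing cost exhausts the winner's reward. On
the integer grid that profile survives only weakly (deviating down ties
the 12.5 payoff), and two strict equilibria appear at bribes 3 and 4. A
sufficiently bribery-averse official (γ ≥ 1 − *a*) flips the game to
quality-only bidding, (Q, B) = (10, 0).

Simulating a full session (31 triplets, 30 periods) and summarizing:

```python
from physioecon.simulate import SessionConfig, simulate_session, summarize_behavior

records, markers = simulate_session(SessionConfig(seed=1))
s = summarize_behavior(records)
```

prints, via the analyze report: mean bribe 1.74 in Baseline vs 0.26
under Inspection; 89.5% of the officials' 266 non-tie Baseline decisions
favour the higher bribe; losers inspect in 17.63% of the possible
instances, fading over the treatment. The full physiological pass —

```sh
physioecon simulate --out session --seed 1
physioecon analyze --in session --out results
```

— filters every subject's trace, detects and labels SCRs, and tests the
five standard condition contrasts (officials' choices and firms' bid
decisions in both treatments, plus bribing vs honest winners awaiting
the audit decision), reporting per-contrast significant latency ranges
and the arousal/response-time rank correlation.

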