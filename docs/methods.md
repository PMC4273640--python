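# Methods

This note records the models implemented in `physioecon`, the defaults
and why they were chosen, and the numerical conventions that matter when
interpreting results.

## 1. The auction game

Two firms simultaneously post bids (Q, B) with Q + B = A; an official
selects one. Monetary payoffs:

    π_official = F + a·Q_w + B_w
    π_winner   = F + a·Q_w − c·B_w + R
    π_loser    = F + a·Q_w

Defaults (F, a, c, A, R) = (10, 0.5, 2, 10, 10). The psychological
variant charges an agent-specific aversion γ ≥ 0 per bribe unit:
`(1−γ_official)·B_w` for the official and `(c+γ_winner)·B_w` for the
winner; the loser's payoff never depends on the winner's bribe. γ = 0
recovers the monetary game exactly (asserted over the full bid grid).

**Official's rule.** If a ≥ 1 − γ_official the official's utility is
non-decreasing in quality, so the higher-Q bid is chosen; otherwise the
official maximises a·Q + (1−γ)·B. The boundary a = 1 − γ is assigned to
the quality branch. Indifference is resolved uniformly (50/50) by
default; deterministic tie rules are available. Uniform is the minimal
symmetric assumption and all expected-payoff computations (including
equilibrium checks) use it.

**Equilibrium enumeration.** All (A/h + 1)² profiles on a bribe grid of
step h (default h = 1, the experimental integer grid) are checked
exhaustively: a profile is an equilibrium iff no unilateral deviation
raises the deviating firm's expected payoff by more than 1e−9; it is
*strict* iff the best response is attained uniquely at that tolerance.
Under the defaults the symmetric equilibria have bribes {3, 4, 5}, with
B = 5 weak (the downward deviation ties at 12.5). Analytically the
symmetric band is [R/c − 2(a+c)h/c, R/c]; as h → 0 it collapses onto the
continuous solution B = R/c = 5, and the refinement test verifies the
band tightens monotonically for h = 1, 1/2, 1/5, 1/10. The enumeration
is validated against an independent plain-loop deviation checker.

**Closed-form psychological equilibria.** Quality branch
(a ≥ 1 − γ_official): both firms bid (A, 0). Bribe branch: firm i bids
B_i = R/(c + γ_i), capped at A; undefined when c + γ_i = 0 (raised as an
error). The continuous prediction is returned as-is along with a
nearest-integer companion (halves rounded up).

**Inspection.** No inspection leaves payoffs unchanged. An inspection
that reveals a bribe zeroes the official's and winner's period payoffs
("loss of period earnings" is implemented as payoff = 0, with no
decomposition into endowment and surplus); an inspection of a bribe-free
transaction zeroes the denouncing loser's payoff. For any belief about
the winner's bribe the loser's expected payoff change from inspecting is
≤ 0, so equilibrium play never inspects.

Out of scope: mixed strategies and incomplete-information equilibria.

## 2. The session simulator

The generator emulates sessions of fixed triplets (1 official, 2 firms)
playing 15 Baseline (T0) then 15 Inspection (T1) periods. No behavioral
model is prescribed by the study design, so the rules below are
deliberately stylized — chosen as the simplest standard mechanisms that
reproduce the qualitative session structure, not fitted to data.

- **Bribery aversion.** Each agent draws γ from a configurable
  distribution; default Exponential(scale 0.35), shared by all roles.
  An official is pro-social (picks quality against their own interest)
  iff γ > 1 − a = 0.5; the default scale puts ≈ 24% of officials in that
  region. Agents are re-drawn at the T0→T1 boundary, mirroring the
  re-matching and fresh role assignment between treatments.
- **Firms** pick integer bribes by softmax (temperature 0.6) over
  expected utility, combining (i) a Beta(9, 1)-prior belief that the
  official is a monetary maximiser, updated by every observed non-tie
  decision, (ii) a recency-discounted (factor 0.7 per period) empirical
  distribution of the opponent's past bids, and (iii) in T1 the
  inspection hazard, which confiscates a winning briber's payoff. The
  strong prior matters: with a symmetric prior, bids cannot affect the
  perceived win probability and play degenerates to zero bribes; with
  plain (undiscounted) empirical opponent beliefs the best-response
  dynamics freeze below the equilibrium set within 15 periods. In the
  zero-noise, bribery-neutral limit the dynamics are absorbed by the
  equilibrium bribe set {3, 4, 5} (tested).
- **Officials** choose by the game-theoretic rule with their own γ and
  are myopic about the inspection hazard. Consequence: the simulator
  does not emulate a treatment-induced reversal toward pro-social
  official choices; its directional effect is carried by the firms'
  bids. Decision classes: "bribe_max" / "quality_max" for non-tie bids,
  "tie" otherwise (ties are excluded from share summaries).
- **Losers** in T1 inspect with probability 0.42 · 0.875^(t−16) — a
  geometric decay from ≈ 42% in the first Inspection period to ≈ 6% in
  the last.
- **Response times** are lognormal (median 2 s, σ = 0.4) with a +1 s
  location shift whenever the decision goes against the agent's myopic
  monetary optimum (for firms: bribing status differs from the
  monetary-EU-maximal bid; for officials: the hazard-discounted monetary
  optimum; for losers: any inspection). This makes arousal and response
  time positively coupled by construction.
- **Timestamps.** Screen sequence per period: bid screens → allocation
  screen → (T1) inspection wait/decision → feedback; inter-screen gaps
  are uniform in [0.5, 1.5] s and inter-period gaps in [4, 8] s. Only
  ordering and window containment matter downstream.

What passing tests show: determinism under a fixed seed, payoff
consistency with the game rules, the directional Inspection effect
(mean T1 bribe < mean T0 bribe, sign test over 50 seeds), and the
equilibrium absorption above. What they do not show: quantitative
agreement with any human sample — levels (e.g. mean bribes) depend on
the stylized learning rule and the γ distribution.

## 3. Synthetic electrodermal activity

A subject's trace (125 Hz) is tonic + phasic + noise:

- **Phasic.** Each stimulus-type event (screen onsets: decision screens,
  feedback, inspection wait) spawns one SCR: a bi-exponential kernel
  h(t) ∝ e^(−t/τ_d) − e^(−t/τ_r), normalised to unit peak, scaled by an
  amplitude drawn from a lognormal whose mean depends on the condition
  label. Defaults τ_r = 0.75 s, τ_d = 2.0 s, onset latency 1.5 s after
  the stimulus (plus N(0, 0.1 s) jitter) — standard electrodermal
  modeling values; the kernel peaks 1.18 s after onset
  (t* = ln(τ_d/τ_r)/(1/τ_r − 1/τ_d)). The phasic part is linear:
  superposing event subsets equals synthesizing their union.
- **Amplitude model.** Default condition means (μS): 0.45 for decisions
  against the decision-maker's monetary interest in each treatment
  (pro-social official choices and bribe-free bids in Baseline; bribing
  choices and bids under Inspection; bribing winners awaiting the audit)
  vs 0.25 for their counterparts; 0.3 otherwise; CV = 0.5.
- **Tonic.** Bounded Gaussian random walk (step SD 0.001 μS/sample,
  reflected within ±1 μS of an 8 μS level); sinusoidal and flat
  alternatives available.
- **Noise.** White Gaussian, SD 0.01 μS.

Ground truth (event id, onset, amplitude, condition) is returned for
every injected SCR. Not emulated: motion artifacts, electrode drift
discontinuities, habituation, nonlinear sweat-gland dynamics, and any
refractoriness — overlapping responses superpose linearly, so detection
on densely spaced events underestimates amplitudes by construction.

## 4. SCR pipeline

- **Filtering.** Butterworth low-pass at 0.5 Hz, zero-phase
  (forward–backward). The configured order (default 4) is the
  *effective two-pass order*: filtfilt squares the single-pass magnitude
  response, so the default is realised as a 2nd-order design run in both
  directions. A literal 4th-order single-pass design applied twice rings
  enough to bias trough-to-peak amplitudes by ≈ +8% on the default
  kernel; the two-pass reading keeps the expected "4th-order zero-phase"
  sharpness with ≈ +2% distortion (within the ±5% validation band).
- **Detection.** Rising segments of the first difference; onset = run
  start (trough), peak = run end; amplitude = peak − trough conductance.
  Responses below 0.02 μS are discarded, as are rise times outside
  [0.25 s, 5 s] — two automated criteria standing in for manual removal
  of false responses after visual inspection.
- **Association.** An SCR links to a decision if its onset falls in
  [screen onset + 1.0 s, decision time], and to a feedback event if in
  [feedback + 1.0 s, feedback + 3.0 s]; windows are closed on both
  edges, times count from session start. Each event takes at most one
  SCR (largest amplitude by default; earliest-onset selectable) and each
  SCR at most one event; overlapping windows resolve by earliest-event
  priority (logged).
- **Epochs.** 15 s windows time-locked to event onsets (long enough to
  cover response latencies past 12 s), baseline-corrected by subtracting
  the conductance at the event onset so condition averages are
  comparable across drifting tonic levels. Whether to baseline-correct
  at all is an open convention; the onset-anchored choice is exposed in
  the epoch construction and documented here as a deviation one may
  disable by pre-detrending. Events whose epoch exceeds the trace are
  dropped with a log entry.

Validation on the generator: recall 1 and amplitude error < 5% for
noise-free traces with injected amplitudes ≥ 2× the floor; spurious
detections < 3/min at the default noise and drift.

## 5. Statistics

- **Waveform permutation test.** Observed statistic: difference of
  condition means at each time sample. Surrogates (default 200): random
  relabelings of the pooled trials — label permutation preserves each
  waveform's autocorrelation and is the primary reading of "permuting
  the data points at each sample from all individual trials"; an
  alternative that shuffles values independently at each sample is
  available as `mode="samplewise"`. When subject ids are supplied,
  labels permute within subject (each subject's condition counts are
  preserved); otherwise trials pool across subjects. Per-sample
  two-sided p = (1 + #{|surrogate| ≥ |observed|}) / (1 + n_surrogates) —
  the +1 smoothing avoids zero p-values at 200 surrogates, and ties with
  the observed statistic count as extreme (a 1e−9-scaled tolerance
  protects exact mirror relabelings from float noise). Benjamini–
  Hochberg FDR across samples at q = 0.05; maximal runs of the rejection
  mask are reported as significant latency intervals. Calibration and
  power are verified by simulation: under an exchangeable null the share
  of runs with any significant sample stays within q + 2 MC standard
  errors (1000 repetitions, 16+16 trials, 40 samples); a 0.5 vs 0.1 μS
  contrast at 40 epochs per condition and 0.05 μS noise is detected at
  the response peak in ≥ 95 of 100 runs.
- **Mann–Whitney z.** Rank-sum with midrank ties; normal approximation
  z = (U − n₁n₂/2)/σ with the tie-corrected variance and no continuity
  correction (the reported statistic is a z value); two-sided normal
  p. Cross-checked against exhaustive enumeration of all label
  assignments at small n and against scipy's asymptotic path.
- **Spearman ρ** with tie handling (t-approximation p), via scipy behind
  the module surface.
- **Percentage tables** round to two decimals. One printed reference
  share (13/31) truncates rather than rounds in its source; comparisons
  are made at printed precision (±0.01).

All tests are two-sided; no directionality is assumed.

## 6. Problem sizes and determinism

Every stochastic routine takes a seed or Generator and is bit-for-bit
reproducible. The default acceptance-style checks run at desk scale:
11×11 (up to 101×101 refined) equilibrium grids; sessions of 2–31
triplets; 1000-repetition null calibration at 40 samples; 100-run power
studies at full 125 Hz, 15 s epochs. The analysis workflow derives
per-contrast seeds from the run seed, and JSON manifests snapshot the
configuration, seed, and file lists of every run.

## 7. Known limitations

- The behavioral rules are stylized; levels (mean bribes, decision
  shares) are qualitative. Officials ignore the inspection hazard.
- The detector measures overlapping SCRs trough-to-peak without
  deconvolution; dense event trains bias amplitudes downward.
- Tonic/phasic decomposition, cluster-based permutation correction, and
  mixed-effects waveform models are out of scope.
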