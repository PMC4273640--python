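"""Synthetic skin-conductance traces with known event-locked SCRs.

A trace is the sum of a slowly drifting tonic level, a phasic part built
by superposing a bi-exponential (Bateman-type) response kernel at each
stimulus event, and white Gaussian noise.  Each injected response is
returned as ground truth (onset, amplitude, condition) so the detection
pipeline can be validated with known recall and amplitude error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import EventMarker

__all__ = [
    "SCRKernelParams",
    "EDATrace",
    "SCRGroundTruth",
    "TonicParams",
    "LognormalAmplitudes",
    "scr_kernel",
    "kernel_peak_time",
    "phasic_signal",
    "synthesize_trace",
    "default_amplitude_model",
    "STIMULUS_EVENT_TYPES",
]

#: marker types that evoke a response (screen onsets, not button presses)
STIMULUS_EVENT_TYPES = frozenset(
    {"decision_screen_on", "feedback_on", "inspection_wait_on"}
)


@dataclass(frozen=True)
class SCRKernelParams:
    """Bi-exponential SCR shape parameters (seconds).

    Defaults (rise 0.75 s, decay 2.0 s, onset latency 1.5 s after the
    stimulus) are standard electrodermal modeling values.
    """

    tau_rise: float = 0.75
    tau_decay: float = 2.0
    latency: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.tau_rise < self.tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        if self.latency < 0:
            raise ValueError("latency must be nonnegative")


@dataclass
class EDATrace:
    """One subject's conductance time series (microSiemens)."""

    subject: str
    sampling_rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sampling_rate


@dataclass(frozen=True)
class SCRGroundTruth:
    """An injected response: validation target for the detector."""

    event_id: str
    onset_s: float
    amplitude: float
    condition: str


@dataclass(frozen=True)
class TonicParams:
    """Tonic (baseline) conductance model.

    ``mode="walk"`` is a bounded Gaussian random walk reflected at
    ``level +/- bound``; ``mode="sine"`` a slow sinusoid; ``mode="flat"``
    a constant.
    """

    level: float = 8.0
    mode: str = "walk"
    walk_sd: float = 0.001  # per-sample step SD, microSiemens
    bound: float = 1.0
    sine_amplitude: float = 0.5
    sine_period_s: float = 120.0

    def generate(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "flat":
            return np.full(n, self.level)
        if self.mode == "sine":
            t = np.arange(n) / fs
            return self.level + self.sine_amplitude * np.sin(
                2 * np.pi * t / self.sine_period_s
            )
        if self.mode == "walk":
            steps = rng.normal(0.0, self.walk_sd, size=n)
            walk = np.cumsum(steps)
            # reflect the excursion into [-bound, bound]
            period = 4.0 * self.bound
            x = np.mod(walk + self.bound, period)
            walk = np.abs(x - period / 2.0) - self.bound
            return self.level + walk
        raise ValueError(f"unknown tonic mode {self.mode!r}")


@dataclass(frozen=True)
class LognormalAmplitudes:
    """Condition -> right-skewed (lognormal) SCR amplitude distribution.

    ``means`` maps a condition label to its mean amplitude in
    microSiemens; conditions not listed use ``default_mean``.  ``cv`` is
    the coefficient of variation shared by all conditions (``cv=0`` makes
    amplitudes deterministic).
    """

    means: dict = field(default_factory=dict)
    default_mean: float = 0.3
    cv: float = 0.5

    def mean(self, condition: str) -> float:
        return float(self.means.get(condition, self.default_mean))

    def sample(self, condition: str, rng: np.random.Generator) -> float:
        m = self.mean(condition)
        if m <= 0:
            return 0.0
        if self.cv <= 0:
            return m
        sigma2 = math.log(1.0 + self.cv**2)
        mu = math.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))


def default_amplitude_model() -> LognormalAmplitudes:
    """Condition means emulating the observed arousal orderings: in the
    Baseline, decisions against monetary maximization respond more
    strongly; in the Inspection treatment the ordering reverses, and
    bribing winners waiting for the loser's audit decision respond more
    strongly than honest ones."""
    return LognormalAmplitudes(
        means={
            "T0:choice_quality_max": 0.45,
            "T0:choice_bribe_max": 0.25,
            "T1:choice_bribe_max": 0.45,
            "T1:choice_quality_max": 0.25,
            "T0:bid_no_bribe": 0.45,
            "T0:bid_bribe": 0.25,
            "T1:bid_bribe": 0.45,
            "T1:bid_no_bribe": 0.25,
            "T1:wait_bribed": 0.45,
            "T1:wait_honest": 0.25,
            "T1:inspect": 0.45,
            "T1:no_inspect": 0.25,
        },
        default_mean=0.3,
        cv=0.5,
    )


def kernel_peak_time(kernel: SCRKernelParams) -> float:
    """Time of the kernel maximum after onset:
    t* = (ln tau_decay - ln tau_rise) / (1/tau_rise - 1/tau_decay)."""
    return (math.log(kernel.tau_decay) - math.log(kernel.tau_rise)) / (
        1.0 / kernel.tau_rise - 1.0 / kernel.tau_decay
    )


def scr_kernel(
    kernel: SCRKernelParams,
    duration: float,
    sampling_rate: float,
) -> np.ndarray:
    """Unit-peak bi-exponential response shape sampled at ``sampling_rate``.

    h(t) is proportional to exp(-t/tau_decay) - exp(-t/tau_rise), zero at
    t = 0, normalised so max h = 1.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    h = np.exp(-t / kernel.tau_decay) - np.exp(-t / kernel.tau_rise)
    tp = kernel_peak_time(kernel)
    peak = math.exp(-tp / kernel.tau_decay) - math.exp(-tp / kernel.tau_rise)
    return h / peak


def phasic_signal(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    kernel: SCRKernelParams,
    n_samples: int,
    sampling_rate: float,
    kernel_duration: float = 40.0,
) -> np.ndarray:
    """Superpose amplitude-scaled kernels at the given onset times (s).

    Linear by construction: the phasic part of a union of event sets is
    the sum of the parts synthesized separately.
    """
    out = np.zeros(n_samples)
    h = scr_kernel(kernel, kernel_duration, sampling_rate)
    for onset, amp in zip(np.asarray(onsets), np.asarray(amplitudes)):
        if amp == 0:
            continue
        i0 = int(round(onset * sampling_rate))
        start = max(i0, 0)  # a response may begin before the trace
        koff = start - i0
        seg = min(len(h) - koff, n_samples - start)
        if seg <= 0:
            continue
        out[start : start + seg] += amp * h[koff : koff + seg]
    return out


def synthesize_trace(
    markers: list[EventMarker],
    amplitudes: LognormalAmplitudes | None = None,
    kernel: SCRKernelParams = SCRKernelParams(),
    tonic: TonicParams = TonicParams(),
    noise_sd: float = 0.01,
    latency_jitter_sd: float = 0.1,
    sampling_rate: float = 125.0,
    duration: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    respond_to: frozenset = STIMULUS_EVENT_TYPES,
) -> tuple[EDATrace, list[SCRGroundTruth]]:
    """Generate one subject's trace from their event markers.

    Every marker whose type is in ``respond_to`` spawns one SCR with
    onset ``marker.time_s + kernel.latency + jitter`` and an amplitude
    drawn from the condition's distribution.  Raises if markers from more
    than one subject are mixed.
    """
    subjects = {m.subject for m in markers}
    if len(subjects) > 1:
        raise ValueError(
            f"markers from multiple subjects mixed: {sorted(subjects)}"
        )
    subject = subjects.pop() if subjects else "anonymous"
    if amplitudes is None:
        amplitudes = default_amplitude_model()
    if rng is None:
        rng = np.random.default_rng(seed)

    stim = sorted(
        (m for m in markers if m.event_type in respond_to),
        key=lambda m: m.time_s,
    )
    if duration is None:
        t_end = max((m.time_s for m in markers), default=0.0)
        duration = t_end + 25.0
    n = int(round(duration * sampling_rate))

    onsets = []
    amps = []
    truth: list[SCRGroundTruth] = []
    for m in stim:
        onset = (
            m.time_s
            + kernel.latency
            + float(rng.normal(0.0, latency_jitter_sd))
        )
        amp = amplitudes.sample(m.condition, rng)
        onsets.append(onset)
        amps.append(amp)
        if amp > 0:
            truth.append(
                SCRGroundTruth(
                    event_id=m.event_id,
                    onset_s=onset,
                    amplitude=amp,
                    condition=m.condition,
                )
            )

    values = tonic.generate(n, sampling_rate, rng)
    values += phasic_signal(
        np.array(onsets), np.array(amps), kernel, n, sampling_rate
    )
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=n)

    return EDATrace(subject, sampling_rate, values), truth
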