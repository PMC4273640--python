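"""Waveform permutation testing with FDR, and behavioral rank statistics.

The central routine compares two condition-average SCR waveforms sample
by sample: the observed statistic is the difference of condition means at
each time sample; the null distribution is built from surrogate data
sets obtained by randomly permuting condition labels across the pooled
trials (within subject when subject identifiers are supplied).  Per-sample
two-sided p-values use the +1 smoothed estimator, are adjusted by
Benjamini-Hochberg FDR across samples, and significant samples are
reported as maximal latency intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .pipeline import EpochSet

__all__ = [
    "WaveformTestResult",
    "RankTestResult",
    "waveform_permutation_test",
    "mann_whitney_z",
    "spearman_rho",
    "inspection_arithmetic",
]


@dataclass
class WaveformTestResult:
    """Sample-wise comparison of two condition waveforms."""

    times: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # FDR-adjusted mask at level q
    intervals: list[tuple[float, float]]
    n_surrogates: int
    q: float
    seed: int | None
    mode: str
    n_a: int = 0
    n_b: int = 0

    @property
    def diff(self) -> np.ndarray:
        return self.mean_a - self.mean_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": np.arange(len(self.times)),
                "time_s": self.times,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "p": self.p_values,
                "significant": self.significant,
            }
        )

    def summary(self) -> str:
        lines = [
            "Waveform permutation test",
            f"  epochs: {self.n_a} vs {self.n_b}; "
            f"samples: {len(self.times)}; surrogates: {self.n_surrogates}; "
            f"mode: {self.mode}; FDR q = {self.q}",
            f"  significant samples: {int(self.significant.sum())}",
        ]
        if self.intervals:
            shown = self.intervals[:8]
            for lo, hi in shown:
                lines.append(f"  significant latency: {lo:.2f} - {hi:.2f} s")
            if len(self.intervals) > len(shown):
                lines.append(
                    f"  ... {len(self.intervals) - len(shown)} further "
                    "intervals"
                )
        else:
            lines.append("  no significant latencies")
        return "\n".join(lines)


@dataclass
class RankTestResult:
    """A rank-based test statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str

    def summary(self) -> str:
        name = {"mann-whitney-z": "z", "spearman-rho": "rho"}.get(
            self.method, "stat"
        )
        return (
            f"{self.method}: {name} = {self.statistic:.4f}, "
            f"p = {self.p_value:.4g}, n = {self.n}"
        )


def _mask_intervals(
    mask: np.ndarray, times: np.ndarray
) -> list[tuple[float, float]]:
    """Maximal runs of True converted to (start, end) latencies in s."""
    out = []
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return out
    edges = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    for i, j in zip(starts, ends):
        out.append((float(times[i]), float(times[j - 1])))
    return out


def waveform_permutation_test(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    n_surrogates: int = 200,
    q: float = 0.05,
    seed: int | None = None,
    subject_ids: list | None = None,
    mode: str = "labels",
) -> WaveformTestResult:
    """Sample-wise surrogate permutation test between two conditions.

    Parameters
    ----------
    epochs_a, epochs_b : EpochSet
        Trial matrices of the two conditions (equal lengths and rates).
    n_surrogates : int
        Number of surrogate data sets (default 200).
    q : float
        FDR level for the Benjamini-Hochberg adjustment across samples.
    subject_ids : sequence, optional
        One id per pooled trial (a's trials then b's); when given, labels
        are permuted within subject, preserving each subject's trial
        counts per condition.
    mode : {"labels", "samplewise"}
        "labels" permutes condition labels across whole trials (the
        default; preserves waveform autocorrelation).  "samplewise"
        permutes the pooled values independently at each time sample.
    """
    if epochs_a.data.shape[1] != epochs_b.data.shape[1]:
        raise ValueError("epoch lengths differ between conditions")
    if epochs_a.sampling_rate != epochs_b.sampling_rate:
        raise ValueError("sampling rates differ between conditions")
    na, nb = epochs_a.n_events, epochs_b.n_events
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 epochs per condition")
    if mode not in ("labels", "samplewise"):
        raise ValueError("mode must be 'labels' or 'samplewise'")

    X = np.vstack([epochs_a.data, epochs_b.data])
    n = na + nb
    rng = np.random.default_rng(seed)
    observed = epochs_a.data.mean(axis=0) - epochs_b.data.mean(axis=0)

    if subject_ids is not None and len(subject_ids) != n:
        raise ValueError("subject_ids must cover all pooled trials")

    # weight vector turning a permuted trial order into a mean difference
    w = np.empty(n)
    w[:na] = 1.0 / na
    w[na:] = -1.0 / nb

    if mode == "samplewise":
        surr = np.empty((n_surrogates, X.shape[1]))
        for k in range(n_surrogates):
            surr[k] = w @ rng.permuted(X, axis=0)
    elif subject_ids is None:
        W = np.empty((n_surrogates, n))
        idx = np.arange(n)
        for k in range(n_surrogates):
            perm = rng.permutation(idx)
            W[k, perm] = w
        surr = W @ X
    else:
        ids = np.asarray(subject_ids)
        W = np.tile(w, (n_surrogates, 1))
        for s in np.unique(ids):
            cols = np.flatnonzero(ids == s)
            for k in range(n_surrogates):
                W[k, cols] = W[k, cols[rng.permutation(len(cols))]]
        surr = W @ X

    # ties with the observed statistic count as at-least-as-extreme; the
    # tolerance keeps float noise from dropping exact mirror assignments
    tie_tol = 1e-9 * (np.abs(observed) + 1.0)
    exceed = (
        np.abs(surr) >= (np.abs(observed) - tie_tol)[None, :]
    ).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_surrogates)
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    times = epochs_a.times
    return WaveformTestResult(
        times=times,
        mean_a=epochs_a.data.mean(axis=0),
        mean_b=epochs_b.data.mean(axis=0),
        p_values=p,
        significant=reject,
        intervals=_mask_intervals(reject, times),
        n_surrogates=n_surrogates,
        q=q,
        seed=seed,
        mode=mode,
        n_a=na,
        n_b=nb,
    )


def mann_whitney_z(sample_a, sample_b) -> RankTestResult:
    """Mann-Whitney rank-sum z statistic with tie correction.

    Normal approximation without continuity correction: z = (U - mu)/sigma
    with mu = n1 n2 / 2 and the tie-corrected variance; the two-sided
    p-value comes from the standard normal.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = spstats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        z = 0.0
    else:
        z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * spstats.norm.sf(abs(z))
    return RankTestResult(
        statistic=float(z), p_value=float(p), n=(n1, n2), method="mann-whitney-z"
    )


def spearman_rho(x, y) -> RankTestResult:
    """Spearman rank correlation with tie handling (t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = spstats.spearmanr(x, y)
    return RankTestResult(
        statistic=float(rho),
        p_value=float(p),
        n=(x.size,),
        method="spearman-rho",
    )


def inspection_arithmetic(counts) -> pd.DataFrame:
    """Percentages from a count table, rounded to 2 decimals.

    ``counts`` maps a label to an (occurrences, possible instances) pair,
    or is a sequence of (label, occurrences, possible) triples.
    """
    if isinstance(counts, dict):
        items = [(k, v[0], v[1]) for k, v in counts.items()]
    else:
        items = [tuple(row) for row in counts]
    rows = []
    for label, num, den in items:
        if den <= 0:
            raise ValueError(f"zero or negative denominator for {label!r}")
        rows.append(
            {
                "label": label,
                "count": int(num),
                "possible": int(den),
                "percent": round(100.0 * num / den, 2),
            }
        )
    return pd.DataFrame(rows)
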