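"""Activation-kinetics fitting, IV assembly, and the exact rank test.

The activation model is a sum of two saturating exponentials

    y(x) = amp0 + amp1*(1 - exp(-x/tau1)) + amp2*(1 - exp(-x/tau2))

fitted over [pulse_start + exclude_initial, window_end] so that the
residual capacitive transient at the start of the pulse is excluded.
Fitted components are re-ordered so tau1 <= tau2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, rankdata

from .core_io.traces import CurrentTrace

__all__ = [
    "ActivationFit",
    "fit_activation",
    "activation_model",
    "IVCurve",
    "build_iv",
    "RankTestResult",
    "mannwhitney_exact",
]


def activation_model(x, amp0, amp1, amp2, tau1, tau2):
    return amp0 + amp1 * (1.0 - np.exp(-x / tau1)) + amp2 * (1.0 - np.exp(-x / tau2))


@dataclass
class ActivationFit:
    amp0: float
    amp1: float
    amp2: float
    tau1: float
    tau2: float
    window_ms: tuple
    residual_rms: float
    converged: bool
    taus_identifiable: bool = True

    def asdict(self) -> dict:
        return {
            "amp0": self.amp0,
            "amp1": self.amp1,
            "amp2": self.amp2,
            "tau1": self.tau1,
            "tau2": self.tau2,
            "window_ms": list(self.window_ms),
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "taus_identifiable": self.taus_identifiable,
        }


def fit_activation(
    trace: CurrentTrace,
    pulse_start_ms: float = 0.0,
    exclude_initial_ms: float = 4.0,
    window_end_ms: float | None = None,
) -> ActivationFit:
    """Nonlinear least-squares fit of the double-exponential activation model.

    ``window_end_ms`` is the time (relative to the trace clock) at which
    the current plateaus; it is a required input for real recordings and
    defaults to the end of the trace.
    """
    if not (2.0 <= exclude_initial_ms <= 6.0):
        raise ValueError("exclude_initial_ms must lie in [2, 6] ms")
    t = trace.time_ms
    y = trace.current_pA
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite samples in trace")
    if window_end_ms is None:
        window_end_ms = float(t[-1])
    t0 = pulse_start_ms + exclude_initial_ms
    if window_end_ms <= t0:
        raise ValueError("degenerate fit window")
    mask = (t >= t0) & (t <= window_end_ms)
    if mask.sum() < 20:
        raise ValueError(f"fit window contains only {int(mask.sum())} samples (need >= 20)")
    x = t[mask] - pulse_start_ms
    yy = y[mask]

    # data-driven initialization: 30/70 amplitude split, taus at 5%/50% of window
    span = float(x[-1] - x[0])
    amp0_0 = float(yy[0])
    total = float(yy[-1] - yy[0])
    p0 = np.array([amp0_0, 0.3 * total, 0.7 * total, 0.05 * span, 0.5 * span])
    lb = np.array([-np.inf, -np.inf, -np.inf, 1e-6, 1e-6])
    ub = np.full(5, np.inf)

    def resid(p):
        return activation_model(x, *p) - yy

    sol = least_squares(resid, p0, bounds=(lb, ub), max_nfev=10000)
    amp0, amp1, amp2, tau1, tau2 = sol.x
    if tau1 > tau2:
        amp1, amp2 = amp2, amp1
        tau1, tau2 = tau2, tau1
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and sol.status not in (0,)
    # flat traces leave the time constants unidentifiable
    amp_scale = max(abs(amp1), abs(amp2))
    identifiable = amp_scale > max(1e-8, 1e-6 * max(1.0, abs(amp0)))
    return ActivationFit(
        amp0=float(amp0),
        amp1=float(amp1),
        amp2=float(amp2),
        tau1=float(tau1),
        tau2=float(tau2),
        window_ms=(t0, window_end_ms),
        residual_rms=rms,
        converged=bool(converged),
        taus_identifiable=bool(identifiable),
    )


@dataclass
class IVCurve:
    voltages_mV: np.ndarray
    mean_pA: np.ndarray
    sd_pA: np.ndarray
    n: np.ndarray
    normalized_at_mV: float | None = None


def build_iv(
    traces: list,
    measure_at: str = "end-of-pulse",
    junction_correction_mV: float = 0.0,
    normalize_at_mV: float | None = None,
    ramp_bin_mV: float = 4.0,
) -> IVCurve:
    """Assemble a current-voltage relation from traces.

    End-of-pulse mode averages the last 5% of each fixed-voltage pulse;
    ramp mode bins per-sample (voltage, current) pairs by voltage.
    Voltages are shifted by ``junction_correction_mV`` (a liquid junction
    correction; the paper-style +6 mV pipette offset corresponds to
    passing -6 here).
    """
    pairs: dict[float, list[float]] = {}
    if measure_at == "end-of-pulse":
        for tr in traces:
            if not tr.voltage_is_scalar:
                raise ValueError("end-of-pulse mode needs one voltage per trace")
            k = max(1, int(np.ceil(0.05 * len(tr))))
            v = float(tr.voltage_mV) + junction_correction_mV
            pairs.setdefault(v, []).append(float(np.mean(tr.current_pA[-k:])))
    elif measure_at == "ramp":
        for tr in traces:
            if tr.voltage_is_scalar:
                raise ValueError("ramp mode needs per-sample voltages")
            v = np.asarray(tr.voltage_mV) + junction_correction_mV
            binned = np.round(v / ramp_bin_mV) * ramp_bin_mV
            for vb, i in zip(binned, tr.current_pA):
                pairs.setdefault(float(vb), []).append(float(i))
    else:
        raise ValueError("measure_at must be 'end-of-pulse' or 'ramp'")
    if not pairs:
        raise ValueError("no traces")
    volts = np.array(sorted(pairs))
    mean = np.array([np.mean(pairs[v]) for v in volts])
    sd = np.array([np.std(pairs[v], ddof=1) if len(pairs[v]) > 1 else 0.0 for v in volts])
    n = np.array([len(pairs[v]) for v in volts])
    if normalize_at_mV is not None:
        i_ref = int(np.argmin(np.abs(volts - normalize_at_mV)))
        ref = mean[i_ref]
        if ref == 0:
            raise ValueError("reference current is zero; cannot normalize")
        mean = mean / ref
        sd = sd / abs(ref)
    return IVCurve(voltages_mV=volts, mean_pA=mean, sd_pA=sd, n=n, normalized_at_mV=normalize_at_mV)


@dataclass
class RankTestResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str


def _u_statistic(ranks: np.ndarray, idx: tuple, n1: int) -> float:
    r1 = float(np.sum(ranks[list(idx)]))
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Null counts of U = 0..n1*n2 for untied samples (classic recursion)."""
    # f(n1, n2, u): number of arrangements with statistic u
    table = np.zeros((n1 + 1, n2 + 1, n1 * n2 + 1), dtype=float)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            for u in range(a * b + 1):
                v = table[a - 1, b, u - b] if u >= b else 0.0
                table[a, b, u] = v + table[a, b - 1, u]
    return table[n1, n2]


def mannwhitney_exact(x, y, enumeration_limit: int = 16, method: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact p-values come from full enumeration of rank splits when
    n1 + n2 <= ``enumeration_limit`` (midranks for ties), or from the
    classic counting recursion when the pooled sample has no ties.
    Otherwise a normal approximation with tie correction (and continuity
    correction) is used.  Two-sided p is the probability, under random
    assignment, of a U at least as far from its null mean as observed.
    ``method`` can force ``"normal-approx"`` for cross-validation.
    """
    if method not in ("auto", "normal-approx"):
        raise ValueError("method must be 'auto' or 'normal-approx'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    U = _u_statistic(ranks, tuple(range(n1)), n1)
    mu = n1 * n2 / 2.0
    dev = abs(U - mu)
    N = n1 + n2
    has_ties = len(np.unique(pooled)) < N
    if method == "normal-approx":
        has_ties = True
        enumeration_limit = 0

    if N <= enumeration_limit:
        total = 0
        hits = 0
        for idx in itertools.combinations(range(N), n1):
            total += 1
            if abs(_u_statistic(ranks, idx, n1) - mu) >= dev - 1e-9:
                hits += 1
        return RankTestResult(U=U, p_value=hits / total, n1=n1, n2=n2, method="exact")
    if not has_ties:
        counts = _exact_count_distribution(n1, n2)
        us = np.arange(len(counts))
        p = counts[np.abs(us - mu) >= dev - 1e-9].sum() / counts.sum()
        return RankTestResult(U=U, p_value=float(p), n1=n1, n2=n2, method="exact")

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return RankTestResult(U=U, p_value=1.0, n1=n1, n2=n2, method="normal-approx")
    z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(z))
    return RankTestResult(U=U, p_value=float(p), n1=n1, n2=n2, method="normal-approx")
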