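"""Sum-of-sinusoids model of a skin-conductance trace.

Real-time affect monitoring benefits from a compact parametric form of the
electrodermal signal; here an SC trace is approximated by

    f(t) = sum_i  a_i * sin(b_i * t + c_i),        i = 1..n_terms (default 8)

fitted by nonlinear least squares.  Raw fits of sinusoid sums are badly
initialization-sensitive, so the frequencies are seeded from the top
periodogram peaks (amplitudes and phases from the corresponding spectral
components) with a handful of seeded multi-start restarts.  A constant is
representable inside the family (b = 0 gives a * sin(c)), and the constant
candidate is always evaluated, so the returned RMSE never exceeds that of
the best constant fit.

This is a descriptive decomposition for tracking, not a validated
physiological model of electrodermal activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .cohort import ChannelTrace

N_RESTARTS = 5


@dataclass
class SinusoidSum:
    """Fitted parameters: amplitudes (uS), angular frequencies (rad/s),
    phases (rad), and the fit RMSE."""

    amplitudes: np.ndarray
    angular_freqs: np.ndarray
    phases: np.ndarray
    rmse: float
    converged: bool = True

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, b, c in zip(self.amplitudes, self.angular_freqs, self.phases):
            out = out + a * np.sin(b * t + c)
        return out

    @property
    def n_terms(self) -> int:
        return len(self.amplitudes)

    def params(self) -> np.ndarray:
        return np.concatenate([self.amplitudes, self.angular_freqs, self.phases])

    def to_dict(self) -> dict:
        return {"amplitudes": self.amplitudes.tolist(),
                "angular_freqs": self.angular_freqs.tolist(),
                "phases": self.phases.tolist(),
                "rmse": self.rmse, "converged": self.converged}


def _model(params: np.ndarray, t: np.ndarray, n_terms: int) -> np.ndarray:
    a = params[:n_terms]
    b = params[n_terms:2 * n_terms]
    c = params[2 * n_terms:]
    return np.sum(a[:, None] * np.sin(b[:, None] * t[None, :] + c[:, None]),
                  axis=0)


def _rmse(params: np.ndarray, t: np.ndarray, y: np.ndarray, n: int) -> float:
    return float(np.sqrt(np.mean((_model(params, t, n) - y) ** 2)))


def _greedy_init(t: np.ndarray, y: np.ndarray, fs: float,
                 n_terms: int) -> np.ndarray:
    """Peel off periodogram peaks one at a time from the residual."""
    a = np.zeros(n_terms)
    b = np.zeros(n_terms)
    c = np.zeros(n_terms)
    r = y.copy()
    for i in range(n_terms):
        mean = float(np.mean(r))
        freqs, psd = signal.periodogram(r - mean, fs=fs)
        if len(psd) > 1 and np.max(psd[1:]) > 0:
            j = 1 + int(np.argmax(psd[1:]))
            f0 = freqs[j]
            # amplitude & phase of that spectral line
            z = np.sum((r - mean) * np.exp(-2j * np.pi * f0 * t)) * 2 / len(t)
            amp, ph = np.abs(z), np.angle(z)
            peak_rms2 = amp ** 2 / 2.0
        else:
            amp = ph = f0 = 0.0
            peak_rms2 = -1.0
        if mean ** 2 >= peak_rms2:
            # residual is dominated by its offset: spend the term on a
            # (near-)constant, b ~ 0, a*sin(c) = mean
            a[i], b[i], c[i] = mean, 1e-9, np.pi / 2
            r = r - mean
        else:
            # cos convention of z -> sin(x + pi/2 + ph)
            a[i], b[i], c[i] = amp, 2 * np.pi * f0, ph + np.pi / 2
            r = r - a[i] * np.sin(b[i] * t + c[i])
    return np.concatenate([a, b, c])


def fit_sum_of_sinusoids(trace: ChannelTrace, n_terms: int = 8,
                         seed: int = 0,
                         warm_start: SinusoidSum | None = None,
                         max_nfev: int = 2000) -> SinusoidSum:
    """Least-squares fit of ``n_terms`` sinusoids to a single channel.

    ``warm_start`` (a previous fit with fewer terms, padded with
    zero-amplitude terms) is added to the candidate starts, which makes the
    RMSE non-increasing in ``n_terms`` when fits are chained.  If no restart
    converges, the best candidate found is returned with ``converged=False``.
    """
    y = np.asarray(trace.samples, dtype=float)
    if len(y) < 4 * n_terms:
        raise ValueError(f"need >= {4 * n_terms} samples to fit {n_terms} "
                         f"sinusoids, got {len(y)}")
    t = np.arange(len(y)) / trace.fs
    rng = np.random.default_rng(seed)

    starts = [_greedy_init(t, y, trace.fs, n_terms)]
    if warm_start is not None:
        pad = n_terms - warm_start.n_terms
        if pad < 0:
            raise ValueError("warm_start has more terms than requested")
        p = warm_start
        starts.append(np.concatenate([
            np.r_[p.amplitudes, np.zeros(pad)],
            np.r_[p.angular_freqs, np.full(pad, 1e-9)],
            np.r_[p.phases, np.zeros(pad)]]))
    base = starts[0]
    for _ in range(N_RESTARTS - 1):
        jitter = base.copy()
        jitter[n_terms:2 * n_terms] *= rng.lognormal(0.0, 0.15, n_terms)
        jitter[:n_terms] *= rng.lognormal(0.0, 0.15, n_terms)
        starts.append(jitter)

    best_params, best_cost, converged = None, np.inf, False
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _model(p, t, n_terms) - y, p0,
                method="lm" if len(y) >= 3 * n_terms else "trf",
                max_nfev=max_nfev)
        except Exception:
            continue
        cost = _rmse(res.x, t, y, n_terms)
        if cost < best_cost:
            best_params, best_cost, converged = res.x, cost, bool(res.success)

    # the constant candidate: a1*sin(c1) = mean(y), everything else zero
    const = np.zeros(3 * n_terms)
    const[0] = float(np.mean(y))
    const[n_terms] = 1e-9
    const[2 * n_terms] = np.pi / 2
    const_cost = _rmse(const, t, y, n_terms)
    if best_params is None or const_cost < best_cost:
        best_params, best_cost = const, min(const_cost, best_cost)
        converged = True

    return SinusoidSum(amplitudes=best_params[:n_terms].copy(),
                       angular_freqs=best_params[n_terms:2 * n_terms].copy(),
                       phases=best_params[2 * n_terms:].copy(),
                       rmse=best_cost, converged=converged)
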