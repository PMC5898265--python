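"""Numerical core: periodic mono-exponential decay model and Poisson profiling.

At a 20 MHz repetition rate the excited-state population does not fully decay
between pulses, so the steady-state emission at time ``t`` after a pulse is a
periodic sum over all previous pulses::

    g(t) = sum_{m>=0} exp(-(t + m*P)/tau) = exp(-t/tau) / (1 - exp(-P/tau))

with ``P`` the repetition period.  The measured curve is this incomplete decay
circularly convolved (period ``P``) with the instrument response ``h`` sampled
on the acquisition grid::

    conv_k = sum_j h_j * g((t_k - t_j) mod P)

Because ``g`` factorizes over the mod-P difference, ``conv`` is computed in
O(n) with two first-order recursive filters (causal part plus the wrapped
anti-causal part), with every intermediate bounded by 1 — no large
exponentials appear.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter
from scipy.special import xlogy

__all__ = [
    "periodic_exp_conv",
    "decay_shape",
    "poisson_loglik",
    "profile_amplitude_offset",
]


def periodic_exp_conv(
    tau: float,
    response: np.ndarray,
    bin_width: float,
    rep_period: float,
) -> np.ndarray:
    """Incomplete (wrap-around) exponential decay convolved with an IRF.

    ``response`` is sampled on uniform bin centers with spacing ``bin_width``;
    the returned curve is on the same grid, un-normalized.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    h = np.asarray(response, dtype=np.float64)
    n = h.size
    window = n * bin_width
    d = np.exp(-bin_width / tau)
    # causal part: a_k = sum_{j<=k} h_j exp(-(t_k - t_j)/tau)
    a = lfilter([1.0], [1.0, -d], h)
    # wrapped part: r_k = sum_{j>k} h_j exp(-(t_k + P - t_j)/tau).  Because
    # t decreases going backward, the reversed recursion GROWS by 1/d per
    # step; rescaling by exp(-(P - W)/tau) keeps every intermediate equal to
    # a partial sum bounded by 1, so the unstable-looking pole is benign:
    #   g_{k-1} = (g_k + h_k exp(-W/tau)) / d,   r_k = exp(-(P - W)/tau) g_k
    u = h * np.exp(-window / tau)
    g_rev = lfilter([0.0, 1.0 / d], [1.0, -1.0 / d], u[::-1])
    r = np.exp(-(rep_period - window) / tau) * g_rev[::-1]
    denom = -np.expm1(-rep_period / tau)  # 1 - exp(-P/tau), accurate for tau >> P
    return (a + r) / denom


def decay_shape(
    tau: float,
    response: np.ndarray,
    bin_width: float,
    rep_period: float,
) -> np.ndarray:
    """Model decay shape normalized to sum 1 over the acquisition window."""
    conv = periodic_exp_conv(tau, response, bin_width, rep_period)
    total = conv.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate decay shape (IRF empty or tau pathological)")
    return conv / total


def poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    """Poisson log-likelihood up to the data-only ``-ln y!`` term."""
    return float(xlogy(y, lam).sum() - lam.sum())


def profile_amplitude_offset(
    y: np.ndarray,
    shape: np.ndarray,
    amp0: float | None = None,
    off0: float | None = None,
    max_iter: int = 500,
) -> tuple[float, float, float, int]:
    """Maximize the Poisson likelihood over amplitude and flat offset.

    Model: ``lambda_k = A * shape_k + b`` with ``shape`` summing to 1.  Uses
    multiplicative EM updates (the classic Poisson-mixture fixed point), which
    keep both parameters non-negative and increase the likelihood
    monotonically.  Returns ``(A, b, loglik, n_iter)``.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    total = y.sum()
    if total <= 0:
        raise ValueError("profile_amplitude_offset requires at least one count")
    A = float(amp0) if amp0 is not None and amp0 > 0 else 0.9 * total
    b = float(off0) if off0 is not None and off0 > 0 else max(0.1 * total / n, 1e-12)
    nz = y > 0
    y_nz = y[nz]
    s_nz = shape[nz]
    it = 0
    for it in range(1, max_iter + 1):
        lam_nz = A * s_nz + b
        ratio = y_nz / lam_nz
        A_new = A * float(ratio @ s_nz)
        b_new = b * float(ratio.sum()) / n
        # parameter-based stopping: likelihood-based rules can fire early
        # while EM still crawls along the amplitude/offset ridge
        done = abs(A_new - A) <= 1e-9 * A + 1e-14 and abs(b_new - b) <= 1e-9 * b + 1e-14
        A, b = A_new, b_new
        if done:
            break
    ll = float(xlogy(y_nz, A * s_nz + b).sum()) - (A + n * b)
    return A, b, ll, it
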