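"""Between-chain convergence diagnostics for posterior samples.

Implements the classic potential scale reduction factor (the
Brooks-Gelman-Rubin diagnostic) from between- and within-chain variances,
and an autocorrelation-based effective sample size with initial-positive-
sequence truncation. Parameters whose chains have zero within-chain
variance (e.g., a presence indicator that is always 1 for an individual
with sightings) are reported as undefined (NaN) rather than raising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import PosteriorSamples

__all__ = ["gelman_rubin", "effective_sample_size", "convergence_table"]

RHAT_THRESHOLD = 1.1
ESS_THRESHOLD = 400.0


def _psrf(x: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter, x: (chains, draws)."""
    m, n = x.shape
    if m < 2 or n < 2:
        return float("nan")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def _ess(x: np.ndarray) -> float:
    """Effective sample size for one parameter, x: (chains, draws).

    Autocorrelations are estimated per chain (about the chain mean) and
    averaged; the sum 1 + 2*sum(rho_k) is truncated at the first lag pair
    with a non-positive sum (Geyer's initial positive sequence), and the
    result capped at the total draw count.
    """
    m, n = x.shape
    total = m * n
    if n < 4:
        return float("nan")
    var = x.var(axis=1, ddof=0)
    if np.any(var == 0):
        return float("nan")
    # per-chain autocovariance via FFT
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), nfft, axis=1)[:, :n].real / n
    rho = (acov / acov[:, :1]).mean(axis=0)  # averaged over chains
    tau = 1.0
    for p in range(1, (n - 1) // 2):
        pair = rho[2 * p - 1] + rho[2 * p]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(min(total, total / tau))


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """Per-parameter potential scale reduction factors, indexed by label."""
    views = samples.scalar_views()
    return pd.Series({k: _psrf(v.astype(float)) for k, v in views.items()},
                     name="rhat")


def effective_sample_size(samples: PosteriorSamples) -> pd.Series:
    """Per-parameter effective sample sizes, indexed by label."""
    views = samples.scalar_views()
    return pd.Series({k: _ess(v.astype(float)) for k, v in views.items()},
                     name="ess")


def convergence_table(samples: PosteriorSamples,
                      rhat_threshold: float = RHAT_THRESHOLD,
                      ess_threshold: float = ESS_THRESHOLD) -> pd.DataFrame:
    """Combined diagnostics with pass flags at the configured thresholds.

    ``rhat_ok`` is True when the diagnostic is below ``rhat_threshold`` and
    ``ess_ok`` when the effective sample size exceeds ``ess_threshold``;
    undefined diagnostics (constant chains) yield NA flags.
    """
    rhat = gelman_rubin(samples)
    ess = effective_sample_size(samples)
    out = pd.DataFrame({"rhat": rhat, "ess": ess})
    out["rhat_ok"] = out["rhat"].map(lambda r: bool(r < rhat_threshold) if np.isfinite(r) else pd.NA)
    out["ess_ok"] = out["ess"].map(lambda e: bool(e > ess_threshold) if np.isfinite(e) else pd.NA)
    out.index.name = "parameter"
    return out
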