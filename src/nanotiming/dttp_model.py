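"""Nucleotide pool-competition model and dTTP kinetics.

BrdUTP (concentration B) competes with dTTP (concentration T) for
incorporation opposite adenine, so the mean BrdU content of DNA replicated
when the pool is (B, T) is MBC = B / (B + T). Inverting, T = B * (1/MBC - 1)
estimates the dTTP pool from a measured MBC. Plotting T against normalized
S-phase progression s (0 = start, 1 = end of S) exposes the roughly
exponential dTTP pool expansion, modelled as T(s) = T0 * fold**s. B is taken
equal to the extracellular labelling dose; the intracellular conversion
efficiency is unknown, so this is an explicit, configurable assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "mbc_from_pools",
    "dttp_from_mbc",
    "ExpFit",
    "fit_dttp_kinetics",
    "predict_mbc_curve",
    "dttp_series",
    "s_from_copy_number",
]


def mbc_from_pools(B: float, T: float | np.ndarray) -> float | np.ndarray:
    """Mean BrdU content for pools (B, T): MBC = B / (B + T)."""
    if B <= 0:
        raise ValueError("B must be positive")
    T = np.asarray(T, dtype=float) if np.ndim(T) else float(T)
    if np.any(np.asarray(T) < 0):
        raise ValueError("T must be non-negative")
    return B / (B + T)


def dttp_from_mbc(mbc: float | np.ndarray, B: float) -> float | np.ndarray:
    """Invert the pool model: T = B * (1/MBC - 1). Exact inverse of
    :func:`mbc_from_pools`; mbc must lie in (0, 1]."""
    if B <= 0:
        raise ValueError("B must be positive")
    arr = np.asarray(mbc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("mbc must be positive (zero implies an infinite pool)")
    out = B * (1.0 / arr - 1.0)
    return out if np.ndim(mbc) else float(out)


@dataclass
class ExpFit:
    """Exponential dTTP kinetics T(s) = T0 * fold**s = T0 * exp(rate * s)."""

    T0: float
    fold: float
    rate: float
    residual: float  # sum of squared residuals
    n: int

    def __call__(self, s: np.ndarray | float) -> np.ndarray | float:
        return self.T0 * np.exp(self.rate * np.asarray(s, dtype=float))


def fit_dttp_kinetics(s: np.ndarray, T: np.ndarray, xtol: float = 1e-12) -> ExpFit:
    """Nonlinear least squares of T(s) = T0 * exp(k*s) on (s, T) points.

    Initialization is deterministic: T0 from the point at smallest s, k from a
    log-linear regression, so the fit is reproducible given the data. Raises
    on fewer than 3 points, non-positive T, or non-convergence.
    """
    s = np.asarray(s, dtype=float)
    T = np.asarray(T, dtype=float)
    ok = np.isfinite(s) & np.isfinite(T)
    s, T = s[ok], T[ok]
    if s.size < 3:
        raise ValueError("need at least 3 points to fit dTTP kinetics")
    if np.any(T <= 0):
        raise ValueError("T values must be positive")
    k0, logT0 = np.polyfit(s, np.log(T), 1)
    t0_init = float(T[np.argmin(s)])
    model = lambda x, T0, k: T0 * np.exp(k * x)
    try:
        popt, _ = optimize.curve_fit(
            model, s, T, p0=(t0_init, float(k0)), maxfev=10000, xtol=xtol,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"dTTP kinetics fit did not converge: {exc}") from exc
    T0, k = float(popt[0]), float(popt[1])
    resid = float(np.sum((model(s, T0, k) - T) ** 2))
    return ExpFit(T0=T0, fold=float(np.exp(k)), rate=k, residual=resid, n=int(s.size))


def predict_mbc_curve(fit: ExpFit, B: float, s_grid: np.ndarray) -> np.ndarray:
    """Forward-predict MBC(s) = B / (B + T0*fold**s) on a grid; strictly
    decreasing whenever fold > 1."""
    return mbc_from_pools(B, fit(np.asarray(s_grid, dtype=float)))


def dttp_series(mbc: np.ndarray, s: np.ndarray, B: float) -> pd.DataFrame:
    """Per-bin inverted dTTP series: (s, T) points sorted by s.

    ``mbc`` must be raw (unrescaled) mean BrdU content; bins with undefined or
    non-positive MBC are dropped.
    """
    mbc = np.asarray(mbc, dtype=float)
    s = np.asarray(s, dtype=float)
    ok = np.isfinite(mbc) & np.isfinite(s) & (mbc > 0)
    df = pd.DataFrame({"s": s[ok], "T": dttp_from_mbc(mbc[ok], B)})
    return df.sort_values("s", kind="mergesort").reset_index(drop=True)


def s_from_copy_number(cn: np.ndarray) -> np.ndarray:
    """Normalize a relative-copy-number profile to S-phase progression in
    [0, 1]: the highest copy number (earliest) maps to 0, the lowest to 1."""
    cn = np.asarray(cn, dtype=float)
    lo, hi = np.nanmin(cn), np.nanmax(cn)
    if hi == lo:
        raise ValueError("constant copy-number profile")
    return (hi - cn) / (hi - lo)
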