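"""Logistic exposure-response models for noise annoyance.

Two fitted curves link loudness (sones) to annoyance: a short-term
model for jury ratings on the 0-10 ICBEN scale,

    Annoyance(N) = 1 / (0.1 + 0.463 * 0.936^N),

and a long-term model for the percentage of highly annoyed residents,

    %HA(N) = 1 / (0.01 + 0.043 * 0.97^N).

Both are the generalised logistic L / (1 + e^{-k(x-x0)}) rewritten in
reciprocal form 1/(1/L + a b^x) with maxima 10 and 100: the scale
ceilings appear as the reciprocal of the constant terms, and the
nonzero intercepts reflect residents annoyed even at zero loudness.
This module evaluates the fitted curves, refits the three-parameter
logistic to new data, and provides the %HA bookkeeping (cutoff at a
rating of 8 or more, 5-sone loudness binning, indoor-level
corrections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LogisticParams",
    "AnnoyanceModel",
    "SHORT_TERM",
    "LONG_TERM",
    "logistic",
    "short_term_annoyance",
    "long_term_pct_ha",
    "fit_logistic",
    "pct_highly_annoyed",
    "bin_by_loudness",
    "indoor_level",
    "HA_CUTOFF",
]

#: Ratings of 8, 9, 10 on the 0-10 scale count as "highly annoyed".
HA_CUTOFF = 8

#: Indoor-minus-outdoor level corrections (windows slightly open), dBA.
INDOOR_CORRECTION_DB = {"aircraft": 15.0, "road": 15.8}


@dataclass(frozen=True)
class LogisticParams:
    """Generalised logistic f(x) = L / (1 + e^{-k (x - x0)}).

    Interconverts exactly with the reciprocal parameterization
    f(x) = 1 / (1/L + a b^x), where a = e^{k x0} / L and b = e^{-k}.
    """

    L: float
    k: float
    x0: float

    def __post_init__(self):
        if not self.L > 0:
            raise ValueError("curve maximum L must be positive")

    @property
    def a(self) -> float:
        return float(np.exp(self.k * self.x0) / self.L)

    @property
    def b(self) -> float:
        return float(np.exp(-self.k))

    @classmethod
    def from_reciprocal(cls, L: float, a: float, b: float) -> "LogisticParams":
        """Build from f(x) = 1 / (1/L + a b^x)."""
        if not (0.0 < b < 1.0):
            raise ValueError("base b must lie in (0, 1)")
        if not a > 0:
            raise ValueError("scale a must be positive")
        k = -np.log(b)
        return cls(L=float(L), k=float(k), x0=float(np.log(a * L) / k))


@dataclass(frozen=True)
class AnnoyanceModel:
    """A fitted logistic annoyance curve with its response-scale tag."""

    kind: str                  # 'short_term' | 'long_term'
    params: LogisticParams
    r_squared: float = float("nan")

    def __post_init__(self):
        ceiling = {"short_term": 10.0, "long_term": 100.0}.get(self.kind)
        if ceiling is None:
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if self.params.L > ceiling + 1e-9:
            raise ValueError(f"{self.kind} maximum exceeds its scale ({ceiling})")

    def __call__(self, loudness_sones):
        return logistic(loudness_sones, self.params)

    @property
    def scale_max(self) -> float:
        return {"short_term": 10.0, "long_term": 100.0}[self.kind]


#: The fitted short-term (jury) model: maximum 10, a = 0.463, b = 0.936.
SHORT_TERM = AnnoyanceModel(
    "short_term", LogisticParams.from_reciprocal(10.0, 0.463, 0.936), 0.939
)
#: The fitted long-term (%HA) model: maximum 100, a = 0.043, b = 0.97.
LONG_TERM = AnnoyanceModel(
    "long_term", LogisticParams.from_reciprocal(100.0, 0.043, 0.97), 0.882
)


def logistic(x, params: LogisticParams):
    """Evaluate the generalised logistic; strictly increasing for k > 0."""
    x = np.asarray(x, dtype=float)
    val = params.L / (1.0 + np.exp(-params.k * (x - params.x0)))
    return float(val) if val.ndim == 0 else val


def _require_nonneg(loudness):
    x = np.asarray(loudness, dtype=float)
    if np.any(x < 0):
        raise ValueError("loudness must be non-negative")
    return x


def short_term_annoyance(loudness_sones):
    """Mean annoyance rating (0-10 scale) at a given loudness in sones."""
    x = _require_nonneg(loudness_sones)
    return logistic(x, SHORT_TERM.params)


def long_term_pct_ha(loudness_sones):
    """Long-term percentage of highly annoyed residents at a loudness."""
    x = _require_nonneg(loudness_sones)
    return logistic(x, LONG_TERM.params)


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

def _reciprocal_logistic(x, L, a, b):
    return 1.0 / (1.0 / L + a * np.power(b, x))


def fit_logistic(
    xs,
    ys,
    scale_max: float = 10.0,
    weights=None,
    kind: str | None = None,
) -> AnnoyanceModel:
    """Nonlinear least-squares fit of the three-parameter logistic.

    Fit is performed in the reciprocal parameterization (L, a, b) with
    bounds b in (0, 1), a > 0 and L bounded by the response-scale
    maximum.  Initialisation: L at the scale maximum and (a, b) from a
    log-linear regression of log(1/y - 1/L).  Deterministic given the
    data.  Raises on degenerate (constant) responses and reports
    non-convergence instead of failing silently.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.unique(xs).size < 4:
        raise ValueError("need at least 4 distinct x values")
    if np.ptp(ys) == 0:
        raise ValueError("degenerate response: all y values identical")
    if np.any(ys <= 0) or np.any(ys >= scale_max):
        raise ValueError("responses must lie strictly within (0, scale max)")

    L0 = scale_max
    resid = np.maximum(1.0 / ys - 1.0 / L0, 1e-9)
    slope, intercept = np.polyfit(xs, np.log(resid), 1)
    b0 = float(np.clip(np.exp(slope), 1e-6, 1.0 - 1e-6))
    a0 = float(np.clip(np.exp(intercept), 1e-9, None))
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))
    try:
        popt, _ = curve_fit(
            _reciprocal_logistic,
            xs,
            ys,
            p0=[L0 * (1 - 1e-6), a0, b0],
            bounds=([1e-6, 1e-12, 1e-9], [scale_max, np.inf, 1.0 - 1e-9]),
            sigma=sigma,
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"logistic fit did not converge: {err}") from err
    L, a, b = map(float, popt)
    pred = _reciprocal_logistic(xs, L, a, b)
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if kind is None:
        kind = "short_term" if scale_max <= 10.0 else "long_term"
    return AnnoyanceModel(kind, LogisticParams.from_reciprocal(L, a, b), r2)


# ---------------------------------------------------------------------
# %HA bookkeeping
# ---------------------------------------------------------------------

def pct_highly_annoyed(ratings, cutoff: int = HA_CUTOFF) -> float:
    """Percentage of ratings at or above the highly-annoyed cutoff."""
    r = np.asarray(ratings)
    if r.size == 0:
        raise ValueError("empty rating list")
    if np.any((r < 0) | (r > 10)):
        raise ValueError("ratings must lie in 0..10")
    return float(100.0 * np.mean(r >= cutoff))


def bin_by_loudness(
    records: pd.DataFrame,
    width_sones: float = 5.0,
    loudness_col: str = "loudness_sone",
    ha_col: str = "highly_annoyed",
) -> pd.DataFrame:
    """Group records into contiguous [0,5), [5,10), ... loudness bins.

    Returns one row per non-empty bin with the bin bounds, midpoint,
    record count and the empirical %HA.
    """
    loud = np.asarray(records[loudness_col], dtype=float)
    if np.any(loud < 0):
        raise ValueError("loudness must be non-negative")
    ha = np.asarray(records[ha_col]).astype(bool)
    idx = np.floor(loud / width_sones).astype(int)
    rows = []
    for i in range(int(idx.max()) + 1):
        sel = idx == i
        if not np.any(sel):
            continue
        rows.append(
            {
                "lower_sone": i * width_sones,
                "upper_sone": (i + 1) * width_sones,
                "midpoint_sone": (i + 0.5) * width_sones,
                "n": int(sel.sum()),
                "pct_ha": float(100.0 * ha[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


def indoor_level(outdoor_dba: float, source: str) -> float:
    """Indoor level behind a slightly open window for a given source.

    Corrections: aircraft -15.0 dBA, road -15.8 dBA.  No flooring is
    applied; callers decide audibility.
    """
    try:
        corr = INDOOR_CORRECTION_DB[source]
    except KeyError:
        raise ValueError(f"unknown source: {source!r} (use 'aircraft' or 'road')")
    return float(outdoor_dba) - corr
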