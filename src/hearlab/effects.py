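"""Standardized mean differences and inverse-variance pooling.

Implements the comparison machinery used to contrast web- and lab-based
group results and to pool effect sizes across studies: Hedges' bias-corrected
standardized mean difference

    g = J * (mu_a - mu_b) / s_p,    J = 1 - 3 / (4*df - 1),  df = n_a + n_b - 2,

with either the classical n-weighted pooled SD or, when group sizes are
unknown (common when digitising printed tables), the equal-weight pooled SD
``sqrt((sigma_a^2 + sigma_b^2) / 2)`` with J = 1.  Reported SEMs are
converted to SDs via ``sigma = SEM * sqrt(n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

Z_95 = 1.96  # meta-analytic convention; no small-sample t adjustment


@dataclass(frozen=True)
class GroupStats:
    """Central value, dispersion (SD), and size of one group."""

    mu: float
    sigma: float
    n: int | None = None
    units: str = ""
    central_kind: str = "mean"  # "mean" or "median", provenance only

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n is not None and self.n < 2:
            raise ValueError("n must be >= 2 when provided")


def stats_from_report(
    central: float,
    dispersion_kind: str,
    dispersion: float,
    n: int | None = None,
    units: str = "",
    central_kind: str = "mean",
) -> GroupStats:
    """Build :class:`GroupStats` from reported summary statistics.

    ``dispersion_kind`` is ``"SD"`` (passed through) or ``"SEM"`` (converted
    via ``sigma = SEM * sqrt(n)``; requires ``n``).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    kind = dispersion_kind.upper()
    if kind == "SD":
        sigma = dispersion
    elif kind == "SEM":
        if n is None:
            raise ValueError("SEM reported without n; cannot recover the SD")
        sigma = dispersion * math.sqrt(n)
    else:
        raise ValueError("dispersion_kind must be 'SD' or 'SEM'")
    return GroupStats(mu=central, sigma=sigma, n=n, units=units, central_kind=central_kind)


@dataclass(frozen=True)
class EffectSize:
    """Bias-corrected standardized mean difference with its variance."""

    g: float
    variance: float | None
    j: float
    pooling: str
    ci_95: tuple | None = None

    def __post_init__(self):
        if not (0 < self.j <= 1):
            raise ValueError("J must lie in (0, 1]")
        if not math.isfinite(self.g):
            raise ValueError("g must be finite")

    @property
    def se(self) -> float | None:
        return None if self.variance is None else math.sqrt(self.variance)


def hedges_g(a: GroupStats, b: GroupStats, pooling: str = "equal-weight") -> EffectSize:
    """Hedges' g for ``a - b``.

    ``pooling`` is ``"n-weighted"`` (classical; both n's required, small-sample
    correction J applied) or ``"equal-weight"`` (sqrt of the mean variance;
    J = 1 when either n is unknown).  The sampling variance
    ``(n_a+n_b)/(n_a*n_b) + g^2 / (2*(n_a+n_b-2))`` is reported when both
    n's are known, else left as None.
    """
    if a.sigma == 0 and b.sigma == 0:
        raise ValueError("both SDs are zero; standardization undefined")
    have_n = a.n is not None and b.n is not None
    if pooling == "n-weighted":
        if not have_n:
            raise ValueError("n-weighted pooling requires both group sizes")
        df = a.n + b.n - 2
        s_p = math.sqrt(((a.n - 1) * a.sigma**2 + (b.n - 1) * b.sigma**2) / df)
    elif pooling == "equal-weight":
        s_p = math.sqrt((a.sigma**2 + b.sigma**2) / 2.0)
    else:
        raise ValueError("pooling must be 'n-weighted' or 'equal-weight'")
    if have_n:
        df = a.n + b.n - 2
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
    else:
        j = 1.0
    g = j * (a.mu - b.mu) / s_p
    if have_n:
        var = (a.n + b.n) / (a.n * b.n) + g**2 / (2.0 * (a.n + b.n - 2))
        var *= j**2
        ci = (g - Z_95 * math.sqrt(var), g + Z_95 * math.sqrt(var))
    else:
        var, ci = None, None
    return EffectSize(g=g, variance=var, j=j, pooling=pooling, ci_95=ci)


def pool_effects(effects) -> EffectSize:
    """Inverse-variance (fixed-effect) pooling of effect sizes.

    Weights are ``1/var_i``; the pooled variance is ``1 / sum(w_i)``.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects to pool")
    gs, ws = [], []
    for e in effects:
        if e.variance is None or e.variance <= 0:
            raise ValueError("every effect needs a positive variance for pooling")
        gs.append(e.g)
        ws.append(1.0 / e.variance)
    gs, ws = np.asarray(gs), np.asarray(ws)
    g = float(np.sum(ws * gs) / np.sum(ws))
    var = float(1.0 / np.sum(ws))
    se = math.sqrt(var)
    return EffectSize(
        g=g, variance=var, j=1.0, pooling="inverse-variance",
        ci_95=(g - Z_95 * se, g + Z_95 * se),
    )


def sd_ratio(a: GroupStats, b: GroupStats) -> float:
    """Ratio of group SDs, ``a.sigma / b.sigma``."""
    if b.sigma == 0:
        raise ValueError("denominator SD is zero")
    return a.sigma / b.sigma
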