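"""Bayesian psychometric-function fitting with a beta-binomial observer model.

The model is the standard one for n-alternative forced-choice data: at
stimulus level ``x`` (on a log axis) the probability of a correct response is

    psi(x) = gamma + (1 - gamma - lambda) * S((x - m) / s),

with ``gamma`` the fixed guess rate (1/6, 1/3 or 1/2 by design), ``lambda``
a lapse rate, ``S`` a logistic sigmoid, ``m`` the midpoint and ``w`` the
width of the rise (the interval over which S goes from 5% to 95%;
``s = w / (2 ln 19)``).  Between-block variability is absorbed by a
beta-binomial likelihood with overdispersion ``eta`` (beta variance
``eta^2 p (1-p)``; ``eta = 0`` recovers the pure binomial).

The posterior over (m, w, lambda, eta) is computed by numerical integration
on a dense grid, optionally refined once around the bulk of the posterior
mass.  Priors: uniform in ``m`` over the padded data range, log-uniform in
``w``, a scaled Beta(1, 24) on ``lambda`` in [0, 0.1], and Beta(1, 9) on
``eta``.

Usage follows the Model/Results idiom::

    fit = PsychometricModel(data).fit()
    print(fit.summary())
    est = fit.threshold_at(0.794)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

LOG19 = math.log(19.0)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricData:
    """Per-level binomial counts for one observer and task."""

    levels: tuple
    n_trials: tuple
    n_correct: tuple
    chance: float

    def __post_init__(self):
        lv = np.asarray(self.levels, float)
        n = np.asarray(self.n_trials, int)
        k = np.asarray(self.n_correct, int)
        if not (lv.shape == n.shape == k.shape) or lv.ndim != 1:
            raise ValueError("levels, n_trials, n_correct must be matched 1-d")
        if len(lv) > 1 and np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(lv <= 0):
            raise ValueError("levels must be positive (fits run on a log axis)")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_correct <= n_trials")
        if not 0 < self.chance < 1:
            raise ValueError("chance must lie in (0, 1)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, chance: float) -> "PsychometricData":
        """Build from a frame with columns level, n_trials, n_correct."""
        df = df.sort_values("level")
        return cls(
            levels=tuple(df["level"]),
            n_trials=tuple(df["n_trials"]),
            n_correct=tuple(df["n_correct"]),
            chance=chance,
        )

    @property
    def accuracy(self) -> np.ndarray:
        return np.asarray(self.n_correct, float) / np.asarray(self.n_trials, float)


# ---------------------------------------------------------------------------
# Sigmoid helpers (module-level so tests can check the closed forms)
# ---------------------------------------------------------------------------


def logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def performance(x, m, w, gamma, lapse):
    """psi(x) on the log-stimulus axis."""
    s = w / (2.0 * LOG19)
    return gamma + (1.0 - gamma - lapse) * logistic((x - m) / s)


def invert_performance(target_pc, m, w, gamma, lapse):
    """Log-level at which psi reaches ``target_pc`` (closed-form inversion)."""
    q = (target_pc - gamma) / (1.0 - gamma - lapse)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("target proportion outside the attainable range")
    s = w / (2.0 * LOG19)
    return m + s * np.log(q / (1.0 - q))


# ---------------------------------------------------------------------------
# Grid configuration and likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridConfig:
    """Posterior grid resolution and prior hyperparameters."""

    n_threshold: int = 40
    n_width: int = 40
    n_lapse: int = 20
    n_overdisp: int = 10
    lapse_max: float = 0.1
    lapse_beta_b: float = 24.0
    overdisp_beta_b: float = 9.0
    overdisp_max: float = 0.6
    threshold_pad: float = 0.5     # padding as a fraction of the data span
    width_max_factor: float = 3.0


def _log_beta_binomial(k, n, p, eta):
    """Log pmf of the (possibly overdispersed) binomial; eta = 0 is binomial."""
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    if eta == 0.0:
        return log_choose + k * np.log(p) + (n - k) * np.log1p(-p)
    nu = 1.0 / eta**2 - 1.0
    a = p * nu
    b = (1.0 - p) * nu
    return log_choose + betaln(k + a, n - k + b) - betaln(a, b)


class PsychometricModel:
    """Grid-based Bayesian fit of a psychometric function to count data.

    Parameters
    ----------
    data : PsychometricData
    grid : GridConfig, optional
    refine : bool
        After a first pass over the full prior range, re-grid midpoint and
        width around the posterior bulk (mean +/- 5 marginal SDs) and
        integrate again.  Removes most grid-coarseness bias at the cost of a
        second pass.
    """

    def __init__(self, data: PsychometricData, grid: GridConfig | None = None,
                 refine: bool = True):
        if len(data.levels) < 3:
            raise ValueError("fitting needs responses at >= 3 stimulus levels")
        self.data = data
        self.grid = grid or GridConfig()
        self.refine = refine
        x = np.log(np.asarray(data.levels, float))
        span = x.max() - x.min()
        pad = self.grid.threshold_pad * span
        self._m_range = (x.min() - pad, x.max() + pad)
        w_min = max(np.diff(x).min(), 1e-3)
        self._w_range = (w_min, self.grid.width_max_factor * span)
        self._x = x

    # -- grids ------------------------------------------------------------

    def _axes(self, m_range, w_range):
        g = self.grid
        m = np.linspace(*m_range, g.n_threshold)
        w = np.geomspace(*w_range, g.n_width)
        lam = np.linspace(0.0, g.lapse_max, g.n_lapse)
        eta = np.linspace(0.0, g.overdisp_max, g.n_overdisp)
        return m, w, lam, eta

    def _log_prior(self, m, w, lam, eta):
        # m uniform, w log-uniform (uniform on the log-spaced grid), scaled
        # Beta(1, b) for lapse and overdispersion.  Constants drop out in the
        # normalization.
        g = self.grid
        lp_l = (g.lapse_beta_b - 1.0) * np.log1p(-lam / g.lapse_max * (1 - 1e-12))
        lp_e = (g.overdisp_beta_b - 1.0) * np.log1p(-eta * (1 - 1e-12))
        return lp_l, lp_e

    def _posterior(self, m, w, lam, eta):
        gamma = self.data.chance
        n = np.asarray(self.data.n_trials, float)
        k = np.asarray(self.data.n_correct, float)
        x = self._x
        s = w / (2.0 * LOG19)
        S = logistic((x[None, None, :] - m[:, None, None]) / s[None, :, None])
        # p: (M, W, L) -> (M, W, Lam, L)
        p = gamma + (1.0 - gamma - lam[None, None, :, None]) * S[:, :, None, :]
        loglik = np.empty(p.shape[:3] + (len(eta),))
        for h, e in enumerate(eta):
            loglik[..., h] = _log_beta_binomial(
                k[None, None, None, :], n[None, None, None, :], p, float(e)
            ).sum(axis=-1)
        lp_l, lp_e = self._log_prior(m, w, lam, eta)
        logpost = loglik + lp_l[None, None, :, None] + lp_e[None, None, None, :]
        logpost -= logsumexp(logpost)
        return np.exp(logpost)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "PsychometricFit":
        m, w, lam, eta = self._axes(self._m_range, self._w_range)
        post = self._posterior(m, w, lam, eta)
        if self.refine:
            m_mean, m_sd = _axis_moments(post, m, axis=0)
            lw = np.log(w)
            w_mean, w_sd = _axis_moments(post, lw, axis=1)
            m_lo = max(self._m_range[0], m_mean - 5 * max(m_sd, 1e-6))
            m_hi = min(self._m_range[1], m_mean + 5 * max(m_sd, 1e-6))
            w_lo = max(math.log(self._w_range[0]), w_mean - 5 * max(w_sd, 1e-6))
            w_hi = min(math.log(self._w_range[1]), w_mean + 5 * max(w_sd, 1e-6))
            m = np.linspace(m_lo, m_hi, self.grid.n_threshold)
            w = np.exp(np.linspace(w_lo, w_hi, self.grid.n_width))
            post = self._posterior(m, w, lam, eta)
        return PsychometricFit(
            model=self, posterior=post, m_grid=m, w_grid=w,
            lapse_grid=lam, overdisp_grid=eta,
        )


def _axis_moments(post, values, axis):
    marg = post.sum(axis=tuple(i for i in range(post.ndim) if i != axis))
    mean = float(np.sum(marg * values))
    var = float(np.sum(marg * (values - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0))


def _weighted_quantile(values, weights, qs):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    cw = np.cumsum(np.asarray(weights)[order])
    cw /= cw[-1]
    return np.interp(qs, cw, v)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Stimulus level at a target proportion correct, with 95% credible interval."""

    level: float
    ci_95: tuple
    target_pc: float

    def __post_init__(self):
        lo, hi = self.ci_95
        if not (lo - 1e-12 <= self.level <= hi + 1e-12):
            raise ValueError("credible interval must contain the point estimate")


class PsychometricFit:
    """Posterior summaries of a grid-integrated psychometric fit."""

    def __init__(self, model, posterior, m_grid, w_grid, lapse_grid, overdisp_grid):
        self.model = model
        self.data = model.data
        self.posterior = posterior
        self.m_grid = m_grid
        self.w_grid = w_grid
        self.lapse_grid = lapse_grid
        self.overdisp_grid = overdisp_grid

    # -- marginals --------------------------------------------------------

    def marginal(self, axis: int):
        grids = [self.m_grid, np.log(self.w_grid), self.lapse_grid, self.overdisp_grid]
        w = self.posterior.sum(axis=tuple(i for i in range(4) if i != axis))
        return grids[axis], w

    @property
    def params(self) -> dict:
        """Posterior means: threshold midpoint (linear units), width (log units),
        lapse, and overdispersion."""
        out = {}
        for name, axis, transform in [
            ("threshold", 0, np.exp),
            ("width", 1, np.exp),
            ("lapse", 2, None),
            ("overdispersion", 3, None),
        ]:
            vals, wts = self.marginal(axis)
            mean = float(np.sum(vals * wts))
            out[name] = float(transform(mean)) if transform else mean
        return out

    def ci(self, param: str, level: float = 0.95) -> tuple:
        axis = {"threshold": 0, "width": 1, "lapse": 2, "overdispersion": 3}[param]
        vals, wts = self.marginal(axis)
        qs = [(1 - level) / 2, 1 - (1 - level) / 2]
        lo, hi = _weighted_quantile(vals, wts, qs)
        if axis in (0, 1):
            lo, hi = math.exp(lo), math.exp(hi)
        return (float(lo), float(hi))

    # -- curve and threshold ----------------------------------------------

    def predict(self, levels) -> np.ndarray:
        """Posterior-mean probability correct at the given stimulus levels."""
        x = np.log(np.asarray(levels, float))
        post3 = self.posterior.sum(axis=3)  # marginal over overdispersion
        s = self.w_grid / (2.0 * LOG19)
        S = logistic((x[None, None, :] - self.m_grid[:, None, None]) / s[None, :, None])
        gamma = self.data.chance
        p = gamma + (1 - gamma - self.lapse_grid[None, None, :, None]) * S[:, :, None, :]
        return np.einsum("mwl,mwlx->x", post3, p)

    def threshold_at(self, target_pc: float) -> ThresholdEstimate:
        """Level at ``target_pc`` (e.g. 0.794 for 3AFC, 0.75 for 2AFC).

        The fitted curve is inverted at every grid point and the posterior
        propagated: the point estimate is the posterior geometric mean and
        the interval the central 95% of the posterior over thresholds.
        """
        gamma = self.data.chance
        lam_max = float(self.lapse_grid.max())
        if not gamma < target_pc < 1.0 - lam_max:
            raise ValueError(
                f"target {target_pc} outside attainable range "
                f"({gamma:.3f}, {1 - lam_max:.3f})"
            )
        post3 = self.posterior.sum(axis=3)
        xt = invert_performance(
            target_pc,
            self.m_grid[:, None, None],
            self.w_grid[None, :, None],
            gamma,
            self.lapse_grid[None, None, :],
        )
        w = post3.ravel()
        v = np.broadcast_to(xt, post3.shape).ravel()
        mean = float(np.sum(w * v))
        lo, hi = _weighted_quantile(v, w, [0.025, 0.975])
        return ThresholdEstimate(
            level=math.exp(mean), ci_95=(math.exp(lo), math.exp(hi)),
            target_pc=target_pc,
        )

    # -- diagnostics ------------------------------------------------------

    @property
    def diagnostics(self) -> dict:
        acc = self.data.accuracy
        n = np.asarray(self.data.n_trials, float)
        gamma = self.data.chance
        total_n = n.sum()
        overall = float(np.sum(acc * n) / total_n)
        chance_se = math.sqrt(gamma * (1 - gamma) / total_n)
        mvals, mw = self.marginal(0)
        edge = int(max(2, len(mvals) // 10))
        return {
            "all_correct": bool(np.all(self.data.accuracy == 1.0)),
            "at_chance": bool(abs(overall - gamma) < 3 * chance_se),
            "threshold_at_grid_edge": bool(mw[:edge].sum() + mw[-edge:].sum() > 0.5),
        }

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        lines = [
            "Psychometric fit (beta-binomial, grid integration)",
            f"  levels: {len(self.data.levels)}, trials: {int(np.sum(self.data.n_trials))},"
            f" chance: {self.data.chance:.3f}",
        ]
        for name in ("threshold", "width", "lapse", "overdispersion"):
            lo, hi = self.ci(name)
            lines.append(f"  {name:>15}: {p[name]:.4g}  [{lo:.4g}, {hi:.4g}]")
        flags = [k for k, v in self.diagnostics.items() if v]
        if flags:
            lines.append(f"  diagnostics: {', '.join(flags)}")
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 100):
        """Data proportions and the posterior-mean curve on a log-level axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lv = np.asarray(self.data.levels, float)
        grid = np.geomspace(lv.min(), lv.max(), n_points)
        ax.semilogx(grid, self.predict(grid), "-", label="posterior mean")
        ax.semilogx(lv, self.data.accuracy, "o", label="data")
        ax.axhline(self.data.chance, ls=":", color="gray")
        ax.set_xlabel("stimulus level")
        ax.set_ylabel("proportion correct")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# CMR effect computation
# ---------------------------------------------------------------------------


def cmr_effect(thresholds: dict) -> dict:
    """Masking-release differences between CMR flanker conditions.

    ``thresholds`` maps condition labels (REF, CORR, ACORR) to a threshold in
    dB SNR, or to ``(threshold, (ci_lo, ci_hi))``.  Returns the conventional
    CMR magnitudes, positive when the CORR threshold is lower (a release):
    ``"CORR-REF" = REF - CORR`` and ``"CORR-ACORR" = ACORR - CORR``.  When
    both operands carry intervals, half-widths combine in quadrature.
    """

    def unpack(label):
        if label not in thresholds:
            raise ValueError(f"missing threshold for condition {label}")
        v = thresholds[label]
        if isinstance(v, (tuple, list)):
            thr, (lo, hi) = v
            return float(thr), (hi - lo) / 2.0
        return float(v), None

    ref, ref_hw = unpack("REF")
    corr, corr_hw = unpack("CORR")
    acorr, acorr_hw = unpack("ACORR")

    def diff(a, a_hw, b, b_hw):
        value = a - b
        if a_hw is None or b_hw is None:
            return {"value_db": value, "ci_95": None}
        hw = math.hypot(a_hw, b_hw)
        return {"value_db": value, "ci_95": (value - hw, value + hw)}

    return {
        "CORR-REF": diff(ref, ref_hw, corr, corr_hw),
        "CORR-ACORR": diff(acorr, acorr_hw, corr, corr_hw),
    }
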