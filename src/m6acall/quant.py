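"""Small quantitative models: decay half-life, ddCq, tumor volume, Spearman.

* Exponential-decay half-life for transcription/translation-blockade time
  courses (actinomycin D for mRNA, cycloheximide for protein):
  y(t) = y0 * 2^(-t / t_half), fitted by OLS on ln y vs t (default) or by a
  nonlinear single-exponential fit.
* Livak ddCq relative expression for qPCR normalized against a reference
  gene (GAPDH) and a control condition: expression = 2^(-ddCq).
* Caliper tumor volume v = d^2 * D / 2 (d, D = shortest/longest diameter).
* Spearman rank correlation with mid-ranks for ties; exact permutation p
  for n <= 9, normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InputError, ValidationError

LN2 = math.log(2.0)


@dataclass
class DecaySeries:
    """One decay time course; the value at t = 0 is defined as 1."""

    timepoints: np.ndarray
    values: np.ndarray
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.size != self.values.size:
            raise ValueError("timepoints and values differ in length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.timepoints[0] != 0:
            raise ValueError("first timepoint must be 0")
        if np.any(self.values <= 0):
            raise ValueError("values must be positive")


@dataclass
class DecayFit:
    """Fitted exponential decay: rate k (per hour), half-life, fit quality.

    ``decaying`` is False when the fitted slope is non-negative; then
    ``t_half`` is +inf and no exception is raised.
    """

    k: float
    t_half: float
    r2: float
    se_thalf: float
    decaying: bool
    method: str = "ols"
    n: int = 0

    def summary(self) -> str:
        lines = [
            "Exponential decay fit",
            f"  method        : {self.method} (n = {self.n})",
            f"  k (1/h)       : {self.k:.4g}",
            f"  t_1/2 (h)     : {self.t_half:.4g}",
            f"  s.e.(t_1/2)   : {self.se_thalf:.4g}",
            f"  R^2 (log)     : {self.r2:.4f}",
            f"  decaying      : {self.decaying}",
        ]
        return "\n".join(lines)


class ExponentialDecayModel:
    """Single-exponential decay model for one time course.

    Statsmodels-style usage::

        fit = ExponentialDecayModel(t, y).fit()
        fit.t_half, fit.r2
    """

    def __init__(self, timepoints, values):
        self.series = (
            timepoints if isinstance(timepoints, DecaySeries)
            else DecaySeries(np.asarray(timepoints, float), np.asarray(values, float))
        )
        if self.series.timepoints.size < 3:
            raise InputError("half-life fit requires >= 3 timepoints")

    def fit(self, method: str = "ols") -> DecayFit:
        t = self.series.timepoints
        y = self.series.values
        if method == "ols":
            res = stats.linregress(t, np.log(y))
            k = -res.slope
            r2 = float(res.rvalue ** 2)
            if k <= 0:
                return DecayFit(k, math.inf, r2, math.inf, False, "ols", t.size)
            # delta method: t_half = ln2/k, se = ln2/k^2 * se_k
            se = LN2 / k**2 * res.stderr
            return DecayFit(k, LN2 / k, r2, float(se), True, "ols", t.size)
        if method == "nls":
            def model(tt, y0, k):
                return y0 * np.exp(-k * tt)

            popt, pcov = optimize.curve_fit(
                model, t, y, p0=(1.0, LN2 / max(t[-1], 1.0)), maxfev=10000
            )
            y0, k = popt
            resid = y - model(t, *popt)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            if k <= 0:
                return DecayFit(float(k), math.inf, r2, math.inf, False, "nls", t.size)
            se_k = float(np.sqrt(pcov[1, 1]))
            return DecayFit(float(k), LN2 / k, r2, LN2 / k**2 * se_k, True, "nls", t.size)
        raise ValueError(f"unknown fit method {method!r}")


def fit_half_life(series: DecaySeries, method: str = "ols") -> DecayFit:
    """Fit a half-life to one decay series (see :class:`ExponentialDecayModel`)."""
    return ExponentialDecayModel(series, None).fit(method=method)


def fit_half_lives(df: pd.DataFrame, method: str = "ols") -> pd.DataFrame:
    """Fit per (group, replicate) series from a long table (time, value, ...).

    Columns: time, value, optional replicate and group.  Returns one row per
    fitted series plus per-group summary statistics of t_half.
    """
    df = df.copy()
    if "replicate" not in df:
        df["replicate"] = "rep1"
    if "group" not in df:
        df["group"] = "all"
    rows = []
    for (group, rep), sub in df.groupby(["group", "replicate"]):
        sub = sub.sort_values("time")
        fit = fit_half_life(DecaySeries(sub["time"].to_numpy(),
                                        sub["value"].to_numpy(), str(rep)), method)
        rows.append({
            "group": group, "replicate": rep, "n": fit.n, "k": fit.k,
            "t_half": fit.t_half, "se_thalf": fit.se_thalf, "r2": fit.r2,
            "decaying": fit.decaying,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# qPCR relative expression (Livak ddCq)
# ---------------------------------------------------------------------- #
def relative_expression(cq: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-sample 2^(-ddCq) relative expression.

    ``cq`` columns: sample, condition, cq_target, cq_ref.  dCq = cq_target -
    cq_ref; ddCq subtracts the mean dCq of the control condition, whose mean
    expression therefore maps to exactly 1.
    """
    required = {"sample", "condition", "cq_target", "cq_ref"}
    missing = required - set(cq.columns)
    if missing:
        raise InputError(f"Cq table missing columns: {sorted(missing)}")
    bad = cq[cq["cq_ref"].isna() | cq["cq_target"].isna()]
    if len(bad):
        raise InputError(
            "missing Cq value for sample(s): " + ", ".join(map(str, bad["sample"]))
        )
    out = cq.copy()
    out["dcq"] = out["cq_target"] - out["cq_ref"]
    control = out[out["condition"] == control_condition]
    if control.empty:
        raise InputError(f"no samples in control condition {control_condition!r}")
    ref = control["dcq"].mean()
    out["ddcq"] = out["dcq"] - ref
    out["rel_expression"] = np.power(2.0, -out["ddcq"])
    return out


# ---------------------------------------------------------------------- #
# tumor volume
# ---------------------------------------------------------------------- #
def tumor_volume(d: float, D: float) -> float:
    """Caliper tumor volume in mm^3: v = d^2 * D / 2.

    d and D are the shortest and longest diameters (mm); d > D raises
    :class:`ValidationError` (diameters swapped upstream).
    """
    if d <= 0 or D <= 0:
        raise ValidationError("diameters must be positive")
    if d > D:
        raise ValidationError(f"shortest diameter d={d} exceeds longest D={D}")
    return d * d * D / 2.0


# ---------------------------------------------------------------------- #
# Spearman rank correlation
# ---------------------------------------------------------------------- #
def spearman_rho(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with mid-ranks; exact permutation p for small n.

    For n <= ``exact_max_n`` the p-value enumerates all n! permutations of
    one vector (two-sided, |rho_perm| >= |rho_obs|); otherwise the normal
    approximation z = rho * sqrt(n - 1) is used.  A constant vector yields
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise InputError("spearman_rho requires >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("spearman_rho: constant vector, rho undefined")
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = (rx - rx.mean()) / (rx.std() * n)
        pc = (perms - ry.mean()) / ry.std()
        rhos = pc @ rxc
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        z = rho * math.sqrt(n - 1)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return rho, min(p, 1.0)
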