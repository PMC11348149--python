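"""Benchmark-dose (BMD) gene selection for dose-series studies.

A reduced model family {linear, power, exponential, Hill} is fitted per gene
by least squares under constant variance; the minimum-AIC fit defines the
benchmark response BMR = bmrf * residual SD and the BMD solves
|f(bmd) - f(0)| = BMR.  BMDL/BMDU come from a seeded nonparametric bootstrap
over replicates, and the stated lack-of-fit and ratio filters decide which
genes feed the framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, ParameterError, ValidationError
from .expression_io import DEGSelection


@dataclass
class DoseSeries:
    """Replicate log-expression at each dose level (dose 0 = control)."""

    gene: str
    doses: np.ndarray  # unique, sorted dose levels
    responses: np.ndarray  # (n_replicates, n_doses)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(np.unique(self.doses)) < 3:
            raise ValidationError("need >= 3 distinct dose levels")
        if 0.0 not in self.doses:
            raise ValidationError("dose 0 (control) must be present")
        if self.responses.shape[1] != self.doses.size:
            raise ValidationError("responses must have one column per dose")


@dataclass
class BMDRecord:
    gene: str
    model_name: str
    aic: float
    lof_p: float
    bmd: float
    bmdl: float
    bmdu: float
    passed: bool


# -- model family ----------------------------------------------------------


def _f_linear(d, a, b):
    return a + b * d


def _f_power(d, a, b, c):
    return a + b * np.power(d, c)


def _f_exponential(d, a, b):
    return a * np.exp(b * d)


def _f_hill(d, a, b, k, n):
    return a + b * d**n / (k**n + d**n)


ALL_MODELS = ("linear", "power", "exponential", "hill")


def _fit_models(x: np.ndarray, y: np.ndarray, max_dose: float, models=ALL_MODELS):
    """Least-squares fit of each family member; returns list of
    (name, fitted_fun, n_params, rss)."""
    fits = []
    a0, span = float(y[x == 0].mean()), float(y.max() - y.min() + 1e-9)
    slope0 = float(np.polyfit(x, y, 1)[0])

    if "linear" in models:
        coef = np.polyfit(x, y, 1)
        fits.append(("linear", lambda d, c=coef: c[1] + c[0] * d, 2))

    specs = [
        ("power", _f_power, [a0, slope0 * 1.0 or span, 1.0],
         ([-np.inf, -np.inf, 0.3], [np.inf, np.inf, 8.0])),
        ("exponential", _f_exponential, [max(abs(a0), 1e-6) * np.sign(a0 or 1.0), 0.0],
         (-np.inf, np.inf)),
        ("hill", _f_hill, [a0, span * np.sign(slope0 or 1.0), max_dose / 2.0, 1.0],
         ([-np.inf, -np.inf, 1e-9, 0.5], [np.inf, np.inf, max_dose * 10.0, 8.0])),
    ]
    for name, fun, p0, bounds in specs:
        if name not in models:
            continue
        try:
            popt, _ = optimize.curve_fit(fun, x, y, p0=p0, bounds=bounds, maxfev=5000)
            fits.append((name, lambda d, f=fun, p=popt: f(d, *p), len(p0)))
        except (RuntimeError, ValueError):
            continue

    out = []
    for name, fun, k in fits:
        resid = y - fun(x)
        rss = float(resid @ resid)
        out.append((name, fun, k, rss))
    return out


def _aic(rss: float, n: int, k: int) -> float:
    # +1 counts the variance parameter
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * (k + 1)


def _lack_of_fit_p(series: DoseSeries, fun, n_params: int) -> float:
    """Pure-error F test of the fitted curve against the per-dose means."""
    y = series.responses
    means = y.mean(axis=0)
    n_per = y.shape[0]
    ss_pe = float(((y - means) ** 2).sum())
    df_pe = y.size - series.doses.size
    ss_lof = float((n_per * (means - fun(series.doses)) ** 2).sum())
    df_lof = series.doses.size - n_params
    if df_lof <= 0 or df_pe <= 0 or ss_pe <= 0:
        return 1.0
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(f, df_lof, df_pe))


def _solve_bmd(fun, bmr: float, max_dose: float) -> float:
    """Smallest dose in (0, max_dose] where |f(d) - f(0)| reaches ``bmr``."""
    f0 = fun(0.0)
    grid = np.linspace(0.0, max_dose, 512)
    dev = np.abs(fun(grid) - f0) - bmr
    above = np.nonzero(dev >= 0)[0]
    if above.size == 0 or above[0] == 0:
        return np.nan
    lo, hi = grid[above[0] - 1], grid[above[0]]
    try:
        return float(optimize.brentq(lambda d: abs(fun(d) - f0) - bmr, lo, hi))
    except ValueError:
        return float(hi)


def fit_bmd(
    series: DoseSeries,
    max_dose: float,
    bmrf: float = 1.349,
    n_boot: int = 250,
    seed: int = 0,
    models=ALL_MODELS,
) -> BMDRecord:
    """Fit the model family, pick the minimum-AIC member and invert it at
    BMR = ``bmrf`` * residual SD; the 95% BMDL/BMDU interval is a seeded
    nonparametric bootstrap over replicates."""
    if bmrf <= 0:
        raise ParameterError("bmrf must be positive")
    x_levels = series.doses
    n_rep = series.responses.shape[0]
    x = np.tile(x_levels, n_rep)
    y = series.responses.reshape(-1)
    if np.allclose(x, x[0]):
        raise FitError("singular design: a single dose level")

    fits = _fit_models(x, y, max_dose, models=models)
    scored = [(name, fun, k, rss, _aic(rss, y.size, k)) for name, fun, k, rss in fits]
    name, fun, k, rss, aic = min(scored, key=lambda t: t[4])
    sigma = np.sqrt(rss / max(y.size - k, 1))
    bmr = bmrf * sigma
    lof_p = _lack_of_fit_p(series, fun, k)
    bmd = _solve_bmd(fun, bmr, max_dose)

    bmdl = bmdu = np.nan
    if np.isfinite(bmd):
        rng = np.random.default_rng(seed)
        boots = []
        fitted = fun(x)
        resid = y - fitted
        for _ in range(n_boot):
            # residual bootstrap: constant variance lets residuals be pooled
            xb = x
            yb = fitted + rng.choice(resid, size=resid.size, replace=True)
            bfits = _fit_models(xb, yb, max_dose, models=(name,))
            match = [f for f in bfits if f[0] == name]
            if not match:
                continue
            _, bfun, bk, brss = match[0]
            bsig = np.sqrt(brss / max(yb.size - bk, 1))
            bbmd = _solve_bmd(bfun, bmrf * bsig, max_dose)
            if np.isfinite(bbmd):
                boots.append(bbmd)
        if len(boots) >= max(10, n_boot // 4):
            bmdl = float(np.percentile(boots, 2.5))
            bmdu = float(np.percentile(boots, 97.5))
            bmdl = min(bmdl, bmd)
            bmdu = max(bmdu, bmd)
    passed = bool(np.isfinite(bmd) and np.isfinite(bmdl) and np.isfinite(bmdu))
    return BMDRecord(
        gene=series.gene,
        model_name=name,
        aic=float(aic),
        lof_p=float(lof_p),
        bmd=float(bmd),
        bmdl=float(bmdl),
        bmdu=float(bmdu),
        passed=passed,
    )


def filter_bmd_genes(records: list[BMDRecord], max_dose: float) -> DEGSelection:
    """Apply the lack-of-fit, range and ratio filters to fitted records."""
    kept = []
    for r in sorted(records, key=lambda r: r.gene):
        if not r.passed or not all(np.isfinite(v) for v in (r.bmd, r.bmdl, r.bmdu)):
            continue
        if r.lof_p <= 0.01:
            continue
        if r.bmd > max_dose or r.bmdu > max_dose:
            continue
        if r.bmdl <= 0 or r.bmd / r.bmdl > 20 or r.bmdu / r.bmd > 20 or r.bmdu / r.bmdl > 40:
            continue
        kept.append(r.gene)
    return DEGSelection(
        genes=kept,
        direction="both",
        criterion={"rule": "bmd", "max_dose": max_dose},
    )


def records_to_frame(records: list[BMDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "model": r.model_name,
                "aic": r.aic,
                "lof_p": r.lof_p,
                "bmd": r.bmd,
                "bmdl": r.bmdl,
                "bmdu": r.bmdu,
                "passed": r.passed,
            }
            for r in records
        ]
    )
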