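"""Critical nitrogen dilution curve and the nitrogen nutrition index (NNI).

The critical N concentration Nc is the minimal shoot N concentration
that sustains maximal dry-matter accumulation; it is modeled as a power
function of shoot biomass, ``Nc = a * DM ** b``.  Following the
Justes-type procedure, treatments in which additional fertilizer
significantly increases shoot biomass are labeled N-limiting; the curve
is fitted on their (biomass, N concentration) points by least squares
in log-log space, and evaluated at a reference biomass from the
non-N-limiting treatments.  The NNI of a sample is Nt / Nc, where Nt is
its measured shoot N concentration: NNI < 1 indicates deficiency,
NNI = 1 optimal nutrition, NNI > 1 surplus.

Note the exponent ``b`` may be positive: under frequent small
fertilizer applications shoot N concentration can rise, rather than
dilute, as biomass accumulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "DilutionCurve",
    "classify_limiting",
    "fit_dilution_curve",
    "critical_n",
    "compute_nni",
    "round_half_up",
    "classify_status",
    "nni_table",
    "CriticalNitrogenCurve",
]


@dataclass
class DilutionCurve:
    """Fitted critical-N curve Nc = a * DM**b (a in g/kg at unit biomass)."""

    a: float
    b: float
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("curve coefficient a must be positive")

    def __call__(self, dm) -> np.ndarray | float:
        return critical_n(self, dm)


def classify_limiting(
    records: pd.DataFrame,
    alpha: float = 0.05,
    dose_order: list[str] | None = None,
    days: list | None = None,
) -> dict:
    """Label treatments N-limiting or non-N-limiting from replicate biomass.

    ``records`` needs columns ``treatment``, ``day``, ``biomass_dm`` and,
    unless ``dose_order`` is given, ``dose``.  At each date a one-way
    ANOVA across treatments is followed by one-sided Welch comparisons
    of each treatment against every higher dose: a treatment is
    N-limiting on that date if the omnibus test is significant and some
    higher dose has significantly greater biomass at ``alpha`` (extra
    fertilizer demonstrably increased biomass).  The top dose is
    non-N-limiting by construction.  Per-date labels are aggregated by
    majority over the dates considered (``days``; default all).

    Returns a dict with ``per_date`` (DataFrame) and ``overall``
    (treatment -> "N-limiting" / "non-N-limiting").
    """
    if dose_order is None:
        doses = records.groupby("treatment")["dose"].first().sort_values()
        dose_order = list(doses.index)
    if len(dose_order) < 2:
        raise ValueError("need at least two treatments")
    use_days = sorted(records["day"].unique()) if days is None else list(days)

    rows = []
    for day in use_days:
        sub = records[records["day"] == day]
        groups = [sub.loc[sub["treatment"] == t, "biomass_dm"].to_numpy()
                  for t in dose_order]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"day {day}: every treatment needs >= 2 replicates")
        if np.ptp(np.concatenate(groups)) == 0:
            omnibus_p = 1.0
        else:
            omnibus_p = float(stats.f_oneway(*groups).pvalue)
            if math.isnan(omnibus_p):
                omnibus_p = 1.0
        for i, trt in enumerate(dose_order):
            if i == len(dose_order) - 1:
                limiting = False
                pair_p = float("nan")
            else:
                pvals = []
                for j in range(i + 1, len(dose_order)):
                    res = stats.ttest_ind(
                        groups[j], groups[i], equal_var=False,
                        alternative="greater",
                    )
                    p = float(res.pvalue)
                    pvals.append(1.0 if math.isnan(p) else p)
                pair_p = min(pvals)
                limiting = omnibus_p < alpha and pair_p < alpha
            rows.append({
                "day": day, "treatment": trt, "omnibus_p": omnibus_p,
                "pairwise_p": pair_p, "limiting": limiting,
            })
    per_date = pd.DataFrame(rows)
    overall = {}
    for trt in dose_order:
        flags = per_date.loc[per_date["treatment"] == trt, "limiting"]
        overall[trt] = (
            "N-limiting" if flags.sum() > len(flags) / 2 else "non-N-limiting"
        )
    return {"per_date": per_date, "overall": overall}


def fit_dilution_curve(biomass, n_conc) -> DilutionCurve:
    """Least-squares fit of ln(N) = ln(a) + b ln(DM)."""
    dm = np.asarray(biomass, dtype=float)
    n = np.asarray(n_conc, dtype=float)
    if dm.size < 3:
        raise ValueError("need at least 3 points to fit the dilution curve")
    if np.any(dm <= 0) or np.any(n <= 0):
        raise ValueError("biomass and N concentration must be positive")
    if np.ptp(dm) == 0:
        raise ValueError("degenerate design: biomass values are all identical")
    res = stats.linregress(np.log(dm), np.log(n))
    return DilutionCurve(a=float(np.exp(res.intercept)), b=float(res.slope),
                         fit_r2=float(res.rvalue**2))


def critical_n(curve: DilutionCurve, dm_ref):
    """Evaluate the curve: Nc = a * dm_ref**b (dm_ref in g/plant, Nc in g/kg)."""
    dm = np.asarray(dm_ref, dtype=float)
    if np.any(dm <= 0):
        raise ValueError("reference biomass must be positive")
    out = curve.a * dm**curve.b
    return float(out) if out.ndim == 0 else out


def compute_nni(nt, nc):
    """Nitrogen nutrition index Nt / Nc."""
    nc_arr = np.asarray(nc, dtype=float)
    if np.any(nc_arr <= 0):
        raise ValueError("critical N concentration must be positive")
    out = np.asarray(nt, dtype=float) / nc_arr
    return float(out) if out.ndim == 0 else out


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (reporting convention for NNI tables).

    Operates on the shortest decimal representation of ``x`` so that
    e.g. 1.005 rounds to 1.01 despite binary floating point.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def classify_status(nni: float, tol: float = 0.005) -> str:
    """Deficient / optimal / excessive; optimal when |NNI - 1| <= tol."""
    if nni < 0:
        raise ValueError("NNI must be non-negative")
    if abs(nni - 1.0) <= tol:
        return "optimal"
    return "excessive" if nni > 1.0 else "deficient"


def nni_table(
    records: pd.DataFrame,
    nc_by_day: dict | None = None,
    curve: DilutionCurve | None = None,
    dm_ref_by_day: dict | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-record NNI table from either explicit per-date Nc values or a curve.

    ``records`` needs columns ``treatment``, ``day``, ``n_conc``.  Either
    pass ``nc_by_day`` (day -> Nc, e.g. a published list) or a fitted
    ``curve`` plus ``dm_ref_by_day`` (day -> reference biomass of the
    non-N-limiting treatments).  NNI is reported rounded half-up to
    ``decimals`` places alongside the exact ratio.
    """
    if nc_by_day is None:
        if curve is None or dm_ref_by_day is None:
            raise ValueError("pass nc_by_day, or curve with dm_ref_by_day")
        nc_by_day = {d: critical_n(curve, dm) for d, dm in dm_ref_by_day.items()}
    rows = []
    for _, rec in records.iterrows():
        nc = nc_by_day[rec["day"]]
        nni_exact = compute_nni(rec["n_conc"], nc)
        nni = round_half_up(nni_exact, decimals)
        rows.append({
            "day": rec["day"], "treatment": rec["treatment"],
            "nt": rec["n_conc"], "nc": nc, "nni": nni,
            "nni_exact": nni_exact, "status": classify_status(nni),
        })
    return pd.DataFrame(rows)


class CriticalNitrogenCurve(BaseEstimator, RegressorMixin):
    """Estimator form of the dilution-curve fit.

    ``fit(X, y)`` takes shoot biomass (g/plant, shape (n,) or (n, 1))
    and shoot N concentration (g/kg DW); ``predict`` evaluates the
    fitted critical concentration.  Fitted attributes: ``a_``, ``b_``,
    ``fit_r2_``, ``curve_``.
    """

    def fit(self, X, y):
        dm = np.asarray(X, dtype=float).reshape(-1)
        curve = fit_dilution_curve(dm, y)
        self.a_, self.b_, self.fit_r2_ = curve.a, curve.b, curve.fit_r2
        self.curve_ = curve
        return self

    def predict(self, X):
        dm = np.asarray(X, dtype=float).reshape(-1)
        return critical_n(self.curve_, dm)
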