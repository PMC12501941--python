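"""Background-corrected viability and four-parameter-logistic GI50.

Plate readings (fluorescence a.u.) are background-corrected using the
cell-free wells, expressed per replicate as a percentage of that
replicate's untreated control, then fitted with

    f(c) = bottom + (top - bottom) / (1 + (c / c0)**h)

by multi-start least squares.  GI50 is the concentration at which the
fitted curve equals 50 percent-of-control, solved in closed form; it is
NA when the curve never crosses 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

PLATE_COLUMNS = ["condition", "replicate", "concentration_uM", "intensity", "is_background"]


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV lacks columns: {missing}")
    df["is_background"] = df["is_background"].astype(bool)
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities")
    return df


def percent_of_control(readings: pd.DataFrame) -> pd.DataFrame:
    """Per-dose mean and sd of percent-of-control for one condition.

    The background (mean of cell-free wells) is subtracted from every
    well; each replicate's doses are divided by that replicate's
    corrected control mean; mean/sd are taken across replicates.
    """
    bg_wells = readings.loc[readings["is_background"], "intensity"]
    if len(bg_wells):
        background = float(bg_wells.mean())
    else:
        warnings.warn("no background wells; assuming background = 0")
        background = 0.0

    wells = readings[~readings["is_background"]].copy()
    if not (wells["concentration_uM"] == 0).any():
        raise ValueError("no control (zero-concentration) wells")
    wells["corrected"] = wells["intensity"] - background

    pct_rows = []
    for rep, sub in wells.groupby("replicate"):
        ctrl = sub.loc[sub["concentration_uM"] == 0, "corrected"].mean()
        if not ctrl > 0:
            raise ValueError(f"replicate {rep}: corrected control signal is not positive")
        for conc, dsub in sub.groupby("concentration_uM"):
            pct_rows.append(
                {"replicate": rep, "concentration_uM": conc, "pct": 100.0 * dsub["corrected"].mean() / ctrl}
            )
    pct = pd.DataFrame(pct_rows)
    out = (
        pct.groupby("concentration_uM")["pct"]
        .agg(mean_pct="mean", sd_pct="std")
        .reset_index()
        .sort_values("concentration_uM")
        .reset_index(drop=True)
    )
    return out


@dataclass
class DoseResponseFit:
    """4PL parameters (percent-of-control units), GI50 and diagnostics."""

    bottom: float
    top: float
    hill: float
    c0: float
    rss: float
    converged: bool

    @property
    def gi50(self) -> float:
        if not self.converged:
            return float("nan")
        return gi50(self)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return _four_pl(np.asarray(conc, dtype=float), self.bottom, self.top, self.hill, self.c0)


def _four_pl(c, bottom, top, hill, c0):
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (c / c0) ** hill)


def fit_4pl(doses: np.ndarray, responses: np.ndarray, seed: int = 0) -> DoseResponseFit:
    """Multi-start least-squares 4PL fit on nonzero doses.

    Deterministic for fixed data and seed: starts combine a fixed grid of
    midpoints/slopes with a few seeded jittered restarts.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    keep = np.isfinite(doses) & np.isfinite(responses) & (doses > 0)
    c, y = doses[keep], responses[keep]
    if len(np.unique(c)) < 4:
        raise ValueError("need >=4 informative (nonzero-dose) points")

    # parametrize c0 = exp(q) to keep the midpoint positive
    def resid(theta):
        bottom, top, hill, q = theta
        return _four_pl(c, bottom, top, hill, np.exp(np.clip(q, -200.0, 200.0))) - y

    rng = np.random.default_rng(seed)
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    q_grid = np.log(np.geomspace(c.min(), c.max(), 4))
    starts = [
        np.array([y_lo, y_hi, h, q])
        for h in (0.5, 1.0, 2.0)
        for q in q_grid
    ]
    starts += [s + rng.normal(0, 0.2, size=4) for s in starts[:4]]

    best, best_cost = None, np.inf
    for s0 in starts:
        try:
            sol = least_squares(resid, s0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            best, best_cost = sol, sol.cost

    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    bottom, top, hill, q = best.x
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        hill=float(hill),
        c0=float(np.exp(q)),
        rss=float(2 * best.cost),
        converged=bool(best.success),
    )


def gi50(fit: DoseResponseFit) -> float:
    """Concentration where the fitted curve equals 50 percent-of-control.

    Closed form ``c0 * ((top - 50)/(50 - bottom))**(1/h)``; NA when 50
    does not lie strictly between bottom and top.
    """
    if fit.hill == 0:
        raise ValueError("hill slope is zero; the curve is flat")
    lo, hi = min(fit.bottom, fit.top), max(fit.bottom, fit.top)
    if not lo < 50.0 < hi:
        return float("nan")
    return float(fit.c0 * ((fit.top - 50.0) / (50.0 - fit.bottom)) ** (1.0 / fit.hill))


def fit_plate(readings: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Percent-of-control + 4PL fit per condition; one row per condition."""
    rows = []
    for cond, sub in readings.groupby("condition"):
        pct = percent_of_control(sub)
        nonzero = pct[pct["concentration_uM"] > 0]
        fit = fit_4pl(nonzero["concentration_uM"].to_numpy(), nonzero["mean_pct"].to_numpy(), seed=seed)
        rows.append(
            {
                "condition": cond,
                "bottom": fit.bottom,
                "top": fit.top,
                "hill": fit.hill,
                "c0": fit.c0,
                "gi50_uM": fit.gi50,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
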