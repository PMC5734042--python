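"""Michaelis-Menten characterization of aryl-aldehyde reductase activity.

Assay arithmetic and model fitting for NAD(P)H-linked spectrophotometric
initial-rate data: conversion of absorbance slopes to specific activities,
nonlinear least-squares fitting of v = Vmax*S/(Km+S), normalization of
activity profiles to a reference enzyme, and kcat bookkeeping from Vmax.

Units follow the assay conventions: substrate concentrations in uM, rates
(specific activities) in umol*min^-1*mg^-1, extinction coefficients in
mM^-1*cm^-1, kcat in min^-1.  The default extinction coefficients are those
of NAD(P)H at 340 nm (6.2) and 355 nm (5.12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

EPSILON_340 = 6.2   # mM^-1 cm^-1, NAD(P)H at 340 nm
EPSILON_355 = 5.12  # mM^-1 cm^-1, NAD(P)H at 355 nm


@dataclass
class RateDataset:
    """Initial-rate data for one substrate: (S, v) pairs with replicates."""

    substrate: str
    concentrations_uM: np.ndarray
    rates: np.ndarray
    replicate: Optional[np.ndarray] = None
    cofactor: str = "NADPH"

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.concentrations_uM.shape != self.rates.shape:
            raise ValueError("concentrations and rates must have equal length")
        if (self.concentrations_uM <= 0).any():
            raise ValueError("substrate concentrations must be > 0")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.rates.shape:
                raise ValueError("replicate labels must match data length")

    @property
    def n_distinct_concentrations(self) -> int:
        return len(np.unique(self.concentrations_uM))

    @staticmethod
    def from_csv(path, substrate: Optional[str] = None) -> "list[RateDataset]":
        """Read the kinetics CSV contract:
        substrate, concentration_uM, rate_umol_min_mg[, replicate].
        """
        df = pd.read_csv(path)
        required = {"substrate", "concentration_uM", "rate_umol_min_mg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"kinetics CSV missing columns: {sorted(missing)}")
        out = []
        for name, grp in df.groupby("substrate", sort=False):
            if substrate is not None and name != substrate:
                continue
            out.append(
                RateDataset(
                    substrate=str(name),
                    concentrations_uM=grp["concentration_uM"].to_numpy(),
                    rates=grp["rate_umol_min_mg"].to_numpy(),
                    replicate=grp["replicate"].to_numpy()
                    if "replicate" in grp.columns
                    else None,
                )
            )
        return out


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten estimates with asymptotic standard errors."""

    vmax: float
    vmax_se: float
    km: float
    km_se: float
    rss: float
    converged: bool
    iterations: int
    n_points: int
    substrate: str = ""

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class ActivityProfile:
    """Activities normalized to a reference activity (set to 100%)."""

    rows: tuple[tuple[str, float, float, float], ...]  # substrate, mean, sd, percent

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["substrate", "mean_activity", "sd", "percent_of_reference"]
        )


def specific_activity(
    slope_abs_per_min: float,
    epsilon_mM_cm: float = EPSILON_340,
    path_cm: float = 1.0,
    enzyme_mg_per_ml: float = 1.0,
) -> float:
    """Specific activity (umol*min^-1*mg^-1) from an absorbance slope.

    activity = slope / (epsilon * path * [enzyme]); cofactor consumption is
    reported with a positive sign.
    """
    if epsilon_mM_cm <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be > 0")
    if enzyme_mg_per_ml <= 0:
        raise ValueError("enzyme concentration must be > 0")
    return slope_abs_per_min / (epsilon_mM_cm * path_cm * enzyme_mg_per_ml)


def mm_rate(s, vmax: float, km: float):
    """The Michaelis-Menten model v = Vmax*S/(Km+S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_mm(data: RateDataset, max_iterations: int = 2000) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Initialization: Vmax0 = max(v); Km0 = S at the rate closest to Vmax0/2.
    Standard errors are asymptotic, from the curvature of the least-squares
    surface at the optimum.  Non-convergence is flagged, with the best
    parameters found still reported.
    """
    if data.n_distinct_concentrations < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    s, v = data.concentrations_uM, data.rates
    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise ValueError("all rates are non-positive; nothing to fit")
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    converged = True
    try:
        popt, pcov, infodict, _, ier = optimize.curve_fit(
            mm_rate,
            s,
            v,
            p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=max_iterations,
            full_output=True,
        )
        nfev = int(infodict.get("nfev", 0))
    except RuntimeError:
        # keep the starting point as the honest "best found" report
        popt = np.array([vmax0, km0])
        pcov = np.full((2, 2), np.nan)
        nfev = max_iterations
        converged = False
    resid = v - mm_rate(s, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else np.array([np.nan, np.nan])
    return MMFit(
        vmax=float(popt[0]),
        vmax_se=float(se[0]),
        km=float(popt[1]),
        km_se=float(se[1]),
        rss=rss,
        converged=converged,
        iterations=nfev,
        n_points=len(v),
        substrate=data.substrate,
    )


def profile_vs_reference(
    activities: Sequence[tuple[str, float] | tuple[str, float, float]],
    reference_activity: float,
) -> ActivityProfile:
    """Normalize (substrate, mean[, sd]) activities to a reference = 100%."""
    if reference_activity <= 0:
        raise ValueError("reference activity must be > 0")
    rows = []
    for entry in activities:
        if len(entry) == 2:
            name, mean = entry
            sd = 0.0
        else:
            name, mean, sd = entry
        if mean < 0:
            raise ValueError(f"negative activity for {name!r}")
        rows.append((name, float(mean), float(sd), 100.0 * mean / reference_activity))
    return ActivityProfile(tuple(rows))


def kcat_from_vmax(vmax: float, molar_mass_g_per_mol: float) -> float:
    """kcat (min^-1) from Vmax (umol*min^-1*mg^-1) and molar mass (g/mol).

    umol product per min per mg enzyme x (g/mol / 1000 mg/g x umol/mol
    bookkeeping) = turnovers per enzyme per minute.
    """
    if vmax <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("vmax and molar mass must be > 0")
    return vmax * molar_mass_g_per_mol / 1000.0


def vmax_from_kcat(kcat: float, molar_mass_g_per_mol: float) -> float:
    if kcat <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("kcat and molar mass must be > 0")
    return kcat * 1000.0 / molar_mass_g_per_mol


def compare_to_blank(
    sample_rates: Sequence[float],
    blank_rates: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, bool]:
    """Two-sample two-tailed t test of enzyme rates against a blank.

    Returns (t, two-sided p, degenerate_flag); equal variances are assumed
    by default, Welch's correction is optional.  Identical groups yield
    t = 0, p = 1.  With fewer than 3 points per group and zero pooled
    variance the test is degenerate and flagged.
    """
    a = np.asarray(sample_rates, dtype=float)
    b = np.asarray(blank_rates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    degenerate = False
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, min(len(a), len(b)) < 3
        degenerate = True
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if not np.isfinite(t):
        degenerate = True
    if min(len(a), len(b)) < 3 and (np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0):
        degenerate = True
    return float(t), float(p), degenerate


def fits_to_frame(fits: Sequence[MMFit]) -> pd.DataFrame:
    """One row per substrate: Vmax, SE, Km, SE, n, converged."""
    return pd.DataFrame(
        {
            "substrate": [f.substrate for f in fits],
            "vmax": [f.vmax for f in fits],
            "vmax_se": [f.vmax_se for f in fits],
            "km": [f.km for f in fits],
            "km_se": [f.km_se for f in fits],
            "rss": [f.rss for f in fits],
            "n": [f.n_points for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
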