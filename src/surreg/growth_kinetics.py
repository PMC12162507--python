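"""Exponential growth-rate estimation and sulfur x pressure rate grids.

The specific growth rate mu (h^-1) is the slope of ln(cell density) against
time during exponential phase. With batch cultures counted at <= 10 time
points, the robust standard estimator is a sliding-window log-linear fit:
among all contiguous windows of at least ``min_window`` points whose linear
fit on ln(counts) reaches an R^2 floor, the best-fitting (highest R^2, then
longest) window's slope is taken as mu. Lag-phase and plateau points are
excluded implicitly because windows that include them fit worse than the
purely exponential stretch.

Qualitative growth classes (-, +, ++, +++) compare a mutant's rate and final
density to the parental strain grown under the same condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Condition",
    "GrowthCurve",
    "GrowthRateEstimate",
    "fit_growth_rate",
    "read_counts_tsv",
    "curves_from_frame",
    "rate_grid",
    "classify_growth",
    "class_matrix",
]


@dataclass(frozen=True)
class Condition:
    """A culture condition: hydrostatic pressure and sulfur supplementation.

    The study's pressure levels are 0.1, 40 and 70 MPa but any value is
    accepted. Sulfidogenic cultures default to 0.25 g/L colloidal sulfur;
    induction experiments use 0.5 or 2 g/L.
    """

    pressure_mpa: float
    sulfur: bool
    sulfur_conc_g_per_l: float = 0.25

    def __post_init__(self) -> None:
        if self.sulfur and self.sulfur_conc_g_per_l <= 0:
            raise ValueError("sulfur present requires a positive concentration")
        if not self.sulfur and self.sulfur_conc_g_per_l not in (0, 0.25):
            raise ValueError("sulfur absent is incompatible with a set concentration")

    def normalized(self) -> "Condition":
        if not self.sulfur:
            return Condition(self.pressure_mpa, False, 0)
        return self


@dataclass(frozen=True)
class GrowthCurve:
    """Timestamped cell densities for one replicate culture."""

    strain: str
    condition: Condition
    replicate_id: str
    times: tuple[float, ...]  # hours
    counts: tuple[float, ...]  # cells/mL

    def __post_init__(self) -> None:
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if any(c <= 0 for c in self.counts):
            raise ValueError("cell counts must be positive (log is taken)")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class GrowthRateEstimate:
    """A fitted specific growth rate with its window and fit quality."""

    mu: float  # h^-1
    window: tuple[int, int]  # inclusive index span used
    r_squared: float
    low_quality: bool = False

    @property
    def doubling_time(self) -> float:
        """Doubling time in hours (inf for mu <= 0)."""
        return math.log(2) / self.mu if self.mu > 0 else math.inf


def fit_growth_rate(
    curve: GrowthCurve,
    *,
    min_window: int = 4,
    min_r2: float = 0.95,
) -> GrowthRateEstimate:
    """Fit mu by sliding-window log-linear regression.

    Among contiguous windows of >= ``min_window`` points with R^2 >= ``min_r2``
    on ln(counts) vs time, the best-fitting window wins (highest R^2, longest
    on ties, steepest among those). Lag and plateau points depress a window's
    R^2 below the purely exponential stretch, so they are excluded
    automatically; ranking by fit quality rather than raw slope keeps the
    estimator unbiased under counting noise, where the steepest short window
    is systematically a noise artifact. If no window reaches the floor, the
    best-R^2 window's slope is returned flagged ``low_quality``. A perfectly
    flat curve returns mu = 0 with R^2 = nan, flagged.
    """
    n = len(curve.times)
    if n < min_window:
        raise ValueError(
            f"need >= {min_window} points to fit, curve has {n}"
        )
    t = np.asarray(curve.times, dtype=float)
    y = np.log(np.asarray(curve.counts, dtype=float))

    qualifying: list[tuple[float, tuple[int, int], float]] = []
    rejected: list[tuple[float, float, tuple[int, int]]] = []  # (r2, slope, win)
    saw_flat = False
    for i in range(n - min_window + 1):
        for j in range(i + min_window - 1, n):
            ti, yi = t[i : j + 1], y[i : j + 1]
            if np.allclose(yi, yi[0]):
                saw_flat = True  # slope 0, R^2 undefined on a flat segment
                continue
            res = stats.linregress(ti, yi)
            r2 = float(res.rvalue**2)
            if r2 >= min_r2:
                qualifying.append((float(res.slope), (i, j), r2))
            else:
                rejected.append((r2, float(res.slope), (i, j)))
    if qualifying:
        slope, window, r2 = max(
            qualifying, key=lambda q: (q[2], q[1][1] - q[1][0], q[0])
        )
        return GrowthRateEstimate(mu=slope, window=window, r_squared=r2)
    if rejected:
        r2, slope, window = max(rejected, key=lambda q: q[0])
        return GrowthRateEstimate(
            mu=slope, window=window, r_squared=r2, low_quality=True
        )
    assert saw_flat  # every window was flat
    return GrowthRateEstimate(
        mu=0.0, window=(0, n - 1), r_squared=float("nan"), low_quality=True
    )


_COUNT_COLUMNS = [
    "strain",
    "pressure_MPa",
    "sulfur",
    "sulfur_conc_g_per_L",
    "replicate",
    "time_h",
    "cells_per_mL",
]


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a cell-count TSV with the canonical column set."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _parse_sulfur(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("present", "true", "yes", "1")
    return bool(value)


def curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    """Group a tidy counts table into per-replicate :class:`GrowthCurve` objects."""
    curves = []
    keys = ["strain", "pressure_MPa", "sulfur", "sulfur_conc_g_per_L", "replicate"]
    for (strain, pressure, sulfur, conc, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        sulfur_b = _parse_sulfur(sulfur)
        curves.append(
            GrowthCurve(
                strain=str(strain),
                condition=Condition(
                    float(pressure), sulfur_b, float(conc) if sulfur_b else 0
                ),
                replicate_id=str(rep),
                times=tuple(grp["time_h"].astype(float)),
                counts=tuple(grp["cells_per_mL"].astype(float)),
            )
        )
    return curves


def rate_grid(
    curves: Sequence[GrowthCurve],
    *,
    min_window: int = 4,
    min_r2: float = 0.95,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean +/- SD growth rate by strain x condition.

    One row per (strain, pressure, sulfur) cell with the per-replicate mean
    and sample SD of mu (SD is NaN for a single replicate). With ``pooled``
    an extra ``mu_pooled`` column reports the fit on all replicate points
    merged — the two conventions bracket what a published per-cell rate could
    have been.
    """
    if not curves:
        raise ValueError("no growth curves supplied")
    rows = []
    by_cell: dict[tuple, list[GrowthCurve]] = {}
    for c in curves:
        cond = c.condition.normalized()
        by_cell.setdefault((c.strain, cond.pressure_mpa, cond.sulfur), []).append(c)
    for (strain, pressure, sulfur), cell in sorted(by_cell.items()):
        mus = [
            fit_growth_rate(c, min_window=min_window, min_r2=min_r2).mu
            for c in cell
        ]
        row = {
            "strain": strain,
            "pressure_MPa": pressure,
            "sulfur": "present" if sulfur else "absent",
            "n_replicates": len(mus),
            "mu_mean": float(np.mean(mus)),
            "mu_sd": float(np.std(mus, ddof=1)) if len(mus) > 1 else np.nan,
        }
        if pooled:
            merged = sorted(
                (t, n)
                for c in cell
                for t, n in zip(c.times, c.counts)
            )
            pooled_curve = GrowthCurve(
                strain=strain,
                condition=cell[0].condition,
                replicate_id="pooled",
                times=tuple(t + 1e-9 * i for i, (t, _) in enumerate(merged)),
                counts=tuple(n for _, n in merged),
            )
            row["mu_pooled"] = fit_growth_rate(
                pooled_curve, min_window=min_window, min_r2=min_r2
            ).mu
        rows.append(row)
    return pd.DataFrame(rows)


def classify_growth(
    mu: float | GrowthRateEstimate,
    parental_mu: float | GrowthRateEstimate,
    final_density_ratio: float = 1.0,
    *,
    dead_mu: float = 0.05,
    dead_density: float = 0.1,
    full_fraction: float = 0.8,
    partial_fraction: float = 0.4,
) -> str:
    """Assign a qualitative growth class relative to the parental strain.

    Defaults: "-" for mu below 0.05 h^-1 (rates an order of magnitude below
    parental indicate essentially no growth) or final density under 10% of
    parental; "+++" for >= 80% of parental rate and density; "++" for >= 40%
    of parental rate; "+" otherwise.
    """
    mu = mu.mu if isinstance(mu, GrowthRateEstimate) else mu
    parental_mu = (
        parental_mu.mu
        if isinstance(parental_mu, GrowthRateEstimate)
        else parental_mu
    )
    if parental_mu <= 0:
        raise ValueError("parental growth rate must be positive")
    if mu < dead_mu or final_density_ratio < dead_density:
        return "-"
    if mu >= full_fraction * parental_mu and final_density_ratio >= full_fraction:
        return "+++"
    if mu >= partial_fraction * parental_mu:
        return "++"
    return "+"


def class_matrix(
    grid: pd.DataFrame,
    parental_strain: str,
    density_ratios: pd.DataFrame | None = None,
    **thresholds,
) -> pd.DataFrame:
    """Classify every strain x condition cell of a rate grid.

    ``grid`` is the output of :func:`rate_grid` (or a pre-fitted table with
    the same columns). Final-density ratios default to 1 when not supplied.
    Returns a tidy frame with strain, pressure, sulfur and class columns; the
    parental strain classifies as itself (always "+++" under the defaults).
    """
    parental = grid[grid["strain"] == parental_strain].set_index(
        ["pressure_MPa", "sulfur"]
    )["mu_mean"]
    if parental.empty:
        raise ValueError(f"parental strain {parental_strain!r} absent from grid")
    rows = []
    for _, row in grid.iterrows():
        key = (row["pressure_MPa"], row["sulfur"])
        if key not in parental.index:
            continue
        ratio = 1.0
        if density_ratios is not None:
            sel = density_ratios[
                (density_ratios["strain"] == row["strain"])
                & (density_ratios["pressure_MPa"] == row["pressure_MPa"])
                & (density_ratios["sulfur"] == row["sulfur"])
            ]
            if not sel.empty:
                ratio = float(sel["density_ratio"].iloc[0])
        rows.append(
            {
                "strain": row["strain"],
                "pressure_MPa": row["pressure_MPa"],
                "sulfur": row["sulfur"],
                "mu_mean": row["mu_mean"],
                "growth_class": classify_growth(
                    row["mu_mean"], float(parental.loc[key]), ratio, **thresholds
                ),
            }
        )
    return pd.DataFrame(rows)
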