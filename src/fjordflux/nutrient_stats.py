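"""Nutrient / chlorophyll statistics on water-mass-labelled bottle samples.

The analysis unit is the station-level median: bottle samples are grouped by
(region, year, water mass, station) and reduced to per-analyte medians, which
are then treated as independent observations.  On those medians the module
provides descriptive summaries (median, quartiles, mean, percentile-bootstrap
confidence interval), two-sample Mann–Whitney U tests between regions,
Benjamini–Hochberg multiplicity correction, and stoichiometric ratios.

All inferential procedures are implemented from first principles (rank-sum
U with exact enumeration for small tie-free samples, step-up adjusted
p-values, percentile bootstrap); scipy is used only for the normal CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "ANALYTES",
    "DEFAULT_DETECTION_LIMITS",
    "SummaryStats",
    "MannWhitneyResult",
    "TestResult",
    "flag_below_detection",
    "aggregate_station_medians",
    "mann_whitney_u",
    "benjamini_hochberg",
    "bootstrap_ci",
    "summarize_water_mass",
    "summary_table",
    "stoichiometric_ratios",
    "compare_regions",
]

ANALYTES = ("ammonium", "nitrate_nitrite", "nitrite", "phosphate",
            "silicic_acid", "chl_a")

# mmol m^-3 (chl_a has no limit configured); ammonium limit 0.09 uM.
DEFAULT_DETECTION_LIMITS = {
    "ammonium": 0.09,
    "nitrate_nitrite": 0.5,
    "nitrite": 0.06,
    "phosphate": 0.06,
    "silicic_acid": 0.7,
}

DEFAULT_BOOTSTRAP_B = 9999
DEFAULT_BOOTSTRAP_SEED = 20160725


def flag_below_detection(samples: pd.DataFrame,
                         limits: dict[str, float] | None = None) -> pd.DataFrame:
    """Add per-analyte ``<analyte>_bd`` boolean columns.

    A value is flagged when it is strictly below the detection limit; the
    measured value itself is never altered or substituted.  Missing values
    get a missing flag.
    """
    limits = DEFAULT_DETECTION_LIMITS if limits is None else limits
    if any(v <= 0 for v in limits.values()):
        raise ValueError("detection limits must be positive")
    out = samples.copy()
    for analyte, limit in limits.items():
        if analyte not in out.columns:
            continue
        vals = out[analyte]
        flags = pd.array(vals < limit, dtype="boolean")
        flags[vals.isna()] = pd.NA
        out[f"{analyte}_bd"] = flags
    return out


def aggregate_station_medians(samples: pd.DataFrame,
                              analytes: tuple[str, ...] = ANALYTES
                              ) -> pd.DataFrame:
    """Station-level medians per (region, year, water_mass, station).

    ``samples`` must carry a ``water_mass`` column; rows labelled
    ``Unclassified`` are excluded.  Missing analyte values are ignored
    per analyte.  Returns one row per cell with per-analyte medians and
    an ``n_samples`` count.
    """
    if samples.empty:
        cols = ["region", "year", "water_mass", "station_id",
                *[a for a in analytes], "n_samples"]
        return pd.DataFrame(columns=cols)
    df = samples[samples["water_mass"] != "Unclassified"]
    present = [a for a in analytes if a in df.columns]
    grouped = df.groupby(["region", "year", "water_mass", "station_id"],
                         sort=True, observed=True)
    cells = grouped[present].median()
    cells["n_samples"] = grouped.size()
    return cells.reset_index()


# --------------------------------------------------------------------------
# Mann–Whitney U
# --------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int
    n2: int
    method: str          # "exact" or "normal"
    degenerate: bool = False


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    U is the statistic of the first sample, computed from midrank sums.
    The p-value comes from exhaustive enumeration of rank assignments when
    n1 + n2 <= 12 and the pooled data are tie-free; otherwise from the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(counts > 1)
    n = n1 + n2

    if not has_ties and n <= 12:
        # exact: U under the null over all C(n, n1) rank subsets
        all_ranks = np.arange(1, n + 1)
        offset = n1 * (n1 + 1) / 2.0
        us = np.fromiter(
            (sum(c) - offset for c in combinations(all_ranks, n1)),
            dtype=float, count=comb(n, n1),
        )
        p_le = np.mean(us <= u1)
        p_ge = np.mean(us >= u1)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u1, p, n1, n2, "exact")

    mu = n1 * n2 / 2.0
    tie_term = ((counts ** 3 - counts).sum() / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        warnings.warn("all pooled values identical; degenerate test (p = 1)")
        return MannWhitneyResult(u1, 1.0, n1, n2, "normal", degenerate=True)
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (1.0 - float(ndtr(z))))
    return MannWhitneyResult(u1, p, n1, n2, "normal")


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bootstrap_ci(values, b: int = DEFAULT_BOOTSTRAP_B, level: float = 0.95,
                 seed: int = DEFAULT_BOOTSTRAP_SEED) -> tuple[float, float]:
    """Percentile bootstrap CI for the arithmetic mean."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    n = len(vals)
    if n == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    if n == 1:
        warnings.warn("single observation: degenerate bootstrap interval")
        return float(vals[0]), float(vals[0])
    if b < 200:
        raise ValueError("b must be >= 200")
    rng = np.random.default_rng(seed)
    vals = np.sort(vals)  # input-order invariance
    idx = rng.integers(0, n, size=(b, n))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class SummaryStats:
    median: float
    q25: float
    q75: float
    mean: float
    ci_low: float
    ci_high: float
    n: int


def summarize_water_mass(values, b: int = DEFAULT_BOOTSTRAP_B,
                         seed: int = DEFAULT_BOOTSTRAP_SEED) -> SummaryStats:
    """Descriptive summary over station-level medians (one water mass).

    Quantiles use linear interpolation between order statistics (the
    type-7 convention).
    """
    vals = np.asarray(values, dtype=float)
    vals = np.sort(vals[~np.isnan(vals)])  # input-order invariance
    if len(vals) < 1:
        raise ValueError("no values to summarize")
    q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
    lo, hi = bootstrap_ci(vals, b=b, seed=seed) if len(vals) > 1 \
        else (float(vals[0]), float(vals[0]))
    return SummaryStats(float(med), float(q25), float(q75),
                        float(vals.mean()), lo, hi, len(vals))


def summary_table(cells: pd.DataFrame,
                  analytes: tuple[str, ...] = ANALYTES,
                  b: int = DEFAULT_BOOTSTRAP_B,
                  seed: int = DEFAULT_BOOTSTRAP_SEED) -> pd.DataFrame:
    """Tidy per (region, year pooled, water mass, analyte) summary rows."""
    rows = []
    present = [a for a in analytes if a in cells.columns]
    for (region, wm), grp in cells.groupby(["region", "water_mass"],
                                           observed=True):
        for analyte in present:
            vals = grp[analyte].dropna()
            if vals.empty:
                continue
            s = summarize_water_mass(vals, b=b, seed=seed)
            rows.append({"region": region, "water_mass": wm,
                         "analyte": analyte, "n": s.n, "median": s.median,
                         "q25": s.q25, "q75": s.q75, "mean": s.mean,
                         "ci_low": s.ci_low, "ci_high": s.ci_high})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    analyte: str
    water_mass: str
    u_statistic: float
    p: float
    p_corr: float
    n1: int
    n2: int
    direction: str


def compare_regions(cells: pd.DataFrame, region_a: str, region_b: str,
                    analytes: tuple[str, ...] = ANALYTES) -> list[TestResult]:
    """Mann–Whitney tests per analyte × water mass between two regions.

    Only "comparable" water masses are tested: those with at least one
    station-level median for the analyte in each region.  BH correction is
    applied across all tests performed.
    """
    present = [a for a in analytes if a in cells.columns]
    tests: list[tuple[str, str, MannWhitneyResult, str]] = []
    for analyte in present:
        for wm, grp in cells.groupby("water_mass", observed=True):
            xa = grp.loc[grp["region"] == region_a, analyte].dropna().to_numpy()
            xb = grp.loc[grp["region"] == region_b, analyte].dropna().to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                continue
            res = mann_whitney_u(xa, xb)
            direction = region_a if np.median(xa) > np.median(xb) else region_b
            tests.append((analyte, wm, res, direction))
    if not tests:
        return []
    p_corr = benjamini_hochberg([t[2].p for t in tests])
    return [
        TestResult(analyte, wm, res.u, res.p, float(pc),
                   res.n1, res.n2, direction)
        for (analyte, wm, res, direction), pc in zip(tests, p_corr)
    ]


def stoichiometric_ratios(sample) -> dict:
    """DIN:P and DIN:Si ratios for one sample (mapping or Series).

    DIN = nitrate + nitrite + ammonium; the ``nitrate_nitrite`` column
    already carries nitrate + nitrite, so DIN = nitrate_nitrite + ammonium.
    Zero or missing denominators yield a missing ratio with a flag.
    """
    def get(key):
        v = sample.get(key, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        return float(v)

    nn, amm = get("nitrate_nitrite"), get("ammonium")
    phos, sil = get("phosphate"), get("silicic_acid")
    din = nn + amm
    out = {"din": din, "din_p": np.nan, "din_si": np.nan,
           "din_p_undefined": False, "din_si_undefined": False,
           "redfield_excess": False}
    if np.isnan(din):
        out["din_p_undefined"] = out["din_si_undefined"] = True
        return out
    if np.isnan(phos) or phos == 0:
        out["din_p_undefined"] = True
    else:
        out["din_p"] = din / phos
        out["redfield_excess"] = bool(out["din_p"] > 16.0)
    if np.isnan(sil) or sil == 0:
        out["din_si_undefined"] = True
    else:
        out["din_si"] = din / sil
    return out
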