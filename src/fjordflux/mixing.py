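"""Model II regression and endmember-mixing source/sink estimation.

Mixing diagrams plot nutrient concentration against salinity within one
(region, year, analyte, water mass) stratum; the association is summarized
with standardized major axis (SMA) regression and with Deming regression at
error-variance ratio lambda = 1, which coincides with major-axis regression
and supplies the uncertainty/significance machinery for the slope.

The endmember estimator compares fjord water against shelf water of a
chosen source water mass: with a freshwater endmember (S0, C0) the
conservative expectation is

    C_cons = C0 + (S_fjord - S0) * (C_shelf - C0) / (S_shelf - S0)

and the estimate is Sources - Sinks = C_fjord - C_cons (negative values are
biogeochemical sinks).  Salinity/concentration on each side are arithmetic
means over qualifying bottle samples restricted to the top 100 m by default.
Concentrations are accepted in mmol m^-3 and reported as umol kg^-1 without
density conversion (a < 3 % approximation for seawater).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .nutrient_stats import ANALYTES, benjamini_hochberg

__all__ = [
    "RegressionFit",
    "EndmemberSpec",
    "SourceSinkInput",
    "SourceSinkResult",
    "sma_fit",
    "deming_fit",
    "compute_pair_means",
    "source_sink",
    "attach_hydrography",
    "mixing_diagrams",
    "StationRoles",
    "sourcesink_table",
]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    method: str                  # "SMA" or "MA/Deming"
    se_slope: float = float("nan")


def _moments(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 observations")
    return x, y


def _r_pvalue(r: float, n: int) -> float:
    # two-sided test of Pearson r = 0, t with n-2 df
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sstats.t.sf(abs(t), n - 2))


def sma_fit(x, y) -> RegressionFit:
    """Standardized major axis fit: slope = sign(r) * sd_y / sd_x."""
    x, y = _moments(x, y)
    sd_x = x.std(ddof=1)
    sd_y = y.std(ddof=1)
    if sd_x == 0:
        raise ValueError("zero variance in x")
    if sd_y == 0:
        raise ValueError("zero variance in y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sd_y / sd_x
    intercept = y.mean() - slope * x.mean()
    return RegressionFit(float(slope), float(intercept), r,
                         _r_pvalue(r, len(x)), len(x), "SMA")


def _deming_slope(x, y, lam):
    s_xx = x.var(ddof=1)
    s_yy = y.var(ddof=1)
    s_xy = np.cov(x, y, ddof=1)[0, 1]
    if s_xy == 0 and s_yy == lam * s_xx:
        raise ValueError("orientation undefined: s_xy = 0 and s_yy = lambda*s_xx")
    if s_xy == 0:
        # axis-aligned: principal axis is vertical or horizontal
        return np.inf if s_yy > lam * s_xx else 0.0
    d = s_yy - lam * s_xx
    return (d + np.sqrt(d * d + 4.0 * lam * s_xy * s_xy)) / (2.0 * s_xy)


def deming_fit(x, y, lam: float = 1.0) -> RegressionFit:
    """Deming (errors-in-both-variables) fit; lam = 1 is major-axis.

    The slope significance is the two-sided test of Pearson r = 0 and the
    slope standard error is a leave-one-out jackknife.
    """
    x, y = _moments(x, y)
    slope = _deming_slope(x, y, lam)
    intercept = y.mean() - slope * x.mean() if np.isfinite(slope) else np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    # jackknife SE of the slope
    se = np.nan
    if np.isfinite(slope) and n > 3:
        loo = []
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            try:
                loo.append(_deming_slope(x[mask], y[mask], lam))
            except ValueError:
                loo.append(np.nan)
            mask[i] = True
        loo = np.asarray(loo, dtype=float)
        if np.all(np.isfinite(loo)):
            se = float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    return RegressionFit(float(slope), float(intercept), r,
                         _r_pvalue(r, n), n, "MA/Deming", se)


# --------------------------------------------------------------------------
# Endmember mixing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EndmemberSpec:
    """Freshwater endmember; zero salinity and concentration by default."""
    s0: float = 0.0
    c0: float = 0.0

    def __post_init__(self):
        if self.s0 < 0 or self.c0 < 0:
            raise ValueError("endmember salinity/concentration must be >= 0")


@dataclass(frozen=True)
class SourceSinkInput:
    c_fjord: float
    c_shelf: float
    s_fjord: float
    s_shelf: float
    shelf_water_mass: str
    fjord_water_mass: str
    analyte: str
    depth_cutoff: float = 100.0
    n_fjord: int = 0
    n_shelf: int = 0


@dataclass(frozen=True)
class SourceSinkResult:
    value: float                 # umol kg^-1; negative = sink
    pair: tuple[str, str]        # (shelf water mass, fjord water mass)
    analyte: str


def attach_hydrography(nutrients: pd.DataFrame,
                       ctd: pd.DataFrame) -> pd.DataFrame:
    """Join salinity and water-mass labels from a classified CTD table.

    Exact match on (station_id, year, depth_m).  Columns already present in
    the nutrient table (e.g. ``sal`` emitted by the simulator) are kept.
    """
    cols = ["station_id", "year", "depth_m"]
    take = [c for c in ("sal", "water_mass") if c not in nutrients.columns]
    if not take:
        return nutrients
    return nutrients.merge(ctd[cols + take], on=cols, how="left",
                           validate="many_to_one")


def compute_pair_means(samples: pd.DataFrame,
                       shelf_stations: set[str], fjord_stations: set[str],
                       shelf_wm: str, fjord_wm: str, analyte: str,
                       depth_cutoff: float = 100.0) -> SourceSinkInput:
    """Mean salinity/concentration per side within one water-mass pair.

    ``samples`` needs station_id, depth_m, sal, water_mass and the analyte
    column.  Only samples at depth <= cutoff with non-missing salinity and
    concentration qualify.
    """
    if depth_cutoff <= 0:
        raise ValueError("depth_cutoff must be > 0")
    df = samples[(samples["depth_m"] <= depth_cutoff)
                 & samples[analyte].notna() & samples["sal"].notna()]

    def side(stations, wm, name):
        sub = df[df["station_id"].isin(stations) & (df["water_mass"] == wm)]
        if sub.empty:
            raise ValueError(
                f"no qualifying samples on the {name} side "
                f"(water mass {wm}, analyte {analyte})"
            )
        return float(sub["sal"].mean()), float(sub[analyte].mean()), len(sub)

    s_shelf, c_shelf, n_s = side(shelf_stations, shelf_wm, "shelf")
    s_fjord, c_fjord, n_f = side(fjord_stations, fjord_wm, "fjord")
    return SourceSinkInput(c_fjord, c_shelf, s_fjord, s_shelf,
                           shelf_wm, fjord_wm, analyte, depth_cutoff,
                           n_fjord=n_f, n_shelf=n_s)


def source_sink(inp: SourceSinkInput,
                em: EndmemberSpec = EndmemberSpec()) -> SourceSinkResult:
    """Two-endmember Sources - Sinks estimate (negative = sink)."""
    if inp.s_shelf == em.s0:
        raise ValueError("s_shelf equals the freshwater endmember salinity; "
                         "dilution line undefined")
    c_cons = em.c0 + (inp.s_fjord - em.s0) * \
        (inp.c_shelf - em.c0) / (inp.s_shelf - em.s0)
    value = inp.c_fjord - c_cons
    if not np.isfinite(value):
        raise ValueError("non-finite source/sink estimate")
    return SourceSinkResult(float(value),
                            (inp.shelf_water_mass, inp.fjord_water_mass),
                            inp.analyte)


# --------------------------------------------------------------------------
# Study-level drivers
# --------------------------------------------------------------------------

def mixing_diagrams(samples: pd.DataFrame,
                    analytes: tuple[str, ...] = ANALYTES,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-stratum Model II regressions of concentration on salinity.

    Strata are the full cross of (region, year, analyte, water mass)
    present in the data with at least 3 samples and non-degenerate spread.
    Returns one row per stratum with SMA and Deming(1) fits and BH-corrected
    p-values (correction across all fitted strata).
    """
    present = [a for a in analytes if a in samples.columns]
    rows = []
    for (region, year, wm), grp in samples.groupby(
            ["region", "year", "water_mass"], observed=True):
        if wm == "Unclassified":
            continue
        for analyte in present:
            sub = grp[["sal", analyte]].dropna()
            stratum = {"region": region, "year": year, "water_mass": wm,
                       "analyte": analyte, "n": len(sub)}
            if len(sub) < 3 or sub["sal"].nunique() < 2 \
                    or sub[analyte].nunique() < 2:
                stratum.update({"fitted": False})
                rows.append(stratum)
                continue
            x, y = sub["sal"].to_numpy(), sub[analyte].to_numpy()
            sma = sma_fit(x, y)
            dem = deming_fit(x, y)
            stratum.update({
                "fitted": True, "sma_slope": sma.slope,
                "sma_intercept": sma.intercept, "r": sma.r, "p": sma.p,
                "ma_slope": dem.slope, "ma_se_slope": dem.se_slope,
            })
            rows.append(stratum)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    fitted = out["fitted"].fillna(False).astype(bool) if "fitted" in out \
        else pd.Series(False, index=out.index)
    if fitted.any():
        out.loc[fitted, "p_corr"] = benjamini_hochberg(
            out.loc[fitted, "p"].to_numpy())
        out["significant"] = (out.get("p_corr") < alpha).fillna(False)
    return out


@dataclass
class StationRoles:
    """Shelf/fjord station rosters and water-mass pairs per region/year."""

    shelf: dict[str, list[str]]                 # region -> stations
    fjord: dict[str, list[str]]
    # region -> year -> list of (shelf_wm, fjord_wm) pairs
    pairs: dict[str, dict[int, list[tuple[str, str]]]] = field(
        default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "StationRoles":
        shelf, fjord, pairs = {}, {}, {}
        for region, spec in cfg["regions"].items():
            shelf[region] = list(spec["shelf"])
            fjord[region] = list(spec["fjord"])
            pairs[region] = {
                int(yr): [tuple(p) for p in plist]
                for yr, plist in spec.get("pairs", {}).items()
            }
        return cls(shelf, fjord, pairs)


def sourcesink_table(samples: pd.DataFrame, roles: StationRoles,
                     analyte: str, depth_cutoff: float = 100.0,
                     em: EndmemberSpec = EndmemberSpec()) -> pd.DataFrame:
    """Sources-Sinks per (region, year, water-mass pair) for one analyte."""
    rows = []
    for region, by_year in roles.pairs.items():
        shelf = set(roles.shelf[region])
        fjord = set(roles.fjord[region])
        for year, pairs in by_year.items():
            sub = samples[(samples["region"] == region)
                          & (samples["year"] == year)]
            for shelf_wm, fjord_wm in pairs:
                try:
                    inp = compute_pair_means(sub, shelf, fjord, shelf_wm,
                                             fjord_wm, analyte, depth_cutoff)
                except ValueError:
                    continue
                res = source_sink(inp, em)
                rows.append({"region": region, "year": year,
                             "shelf_water_mass": shelf_wm,
                             "fjord_water_mass": fjord_wm,
                             "analyte": analyte,
                             "sources_minus_sinks": res.value,
                             "n_shelf": inp.n_shelf, "n_fjord": inp.n_fjord})
    return pd.DataFrame(rows)
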