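"""Water-mass classification from temperature–salinity(–density) envelopes.

Each hydrographic record (one depth on one CTD cast) is assigned to one of
seven named water masses — Surface Water (SW), Intermediate Water (IW),
Atlantic Water (AW), Transformed Atlantic Water (TAW), Arctic Water (ArW),
Local Water (LW), Winter-cooled Water (WCW) — or ``Unclassified``.  The
envelopes are rectangles in T–S space, optionally constrained by a potential
density anomaly (sigma-theta) ceiling for the Atlantic-derived classes.

Classification follows a fixed decision ladder:

1. collect every envelope whose full constraints (T, S, and sigma where
   defined) contain the record;
2. exactly one match -> that label;
3. several matches -> the first match in the table's ``precedence`` order;
4. no match, but T and S fall inside the AW or TAW T–S limits while
   sigma-theta >= the density threshold -> AW (checked first) or TAW;
5. no match, but salinity below the ArW lower limit and temperature below
   the LW lower limit -> ArW;
6. otherwise ``Unclassified``.

Envelope bounds are configuration data (YAML), not code constants; a default
table is shipped as package data.  Bound convention: lower bounds closed,
upper bounds open, unless the config overrides per edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WATER_MASS_LABELS",
    "UNCLASSIFIED",
    "DEFAULT_PRECEDENCE",
    "TSRecord",
    "WaterMassEnvelope",
    "EnvelopeTable",
    "compute_sigma_theta",
    "classify_record",
    "classify_profile",
    "classify_table",
    "default_envelope_table",
]

WATER_MASS_LABELS = ("SW", "IW", "AW", "TAW", "ArW", "LW", "WCW")
UNCLASSIFIED = "Unclassified"

# Coldest / most specific classes first; used to break multi-envelope ties.
DEFAULT_PRECEDENCE = ("WCW", "ArW", "LW", "SW", "IW", "TAW", "AW")


class ConfigError(ValueError):
    """Invalid envelope table or configuration."""


class DataError(ValueError):
    """Invalid or out-of-range hydrographic data."""


# --------------------------------------------------------------------------
# Equation of state
# --------------------------------------------------------------------------

# UNESCO (1983) EOS-80 one-atmosphere international equation of state.
# rho(S, T, 0) in kg m^-3; published check value rho(35, 5, 0) = 1027.67547.
_RHO_W = (999.842594, 6.793952e-2, -9.095290e-3, 1.001685e-4,
          -1.120083e-6, 6.536332e-9)
_A = (8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9)
_B = (-5.72466e-3, 1.0227e-4, -1.6546e-6)
_C = 4.8314e-4


def compute_sigma_theta(salinity, temperature):
    """Potential density anomaly at surface pressure, kg m^-3.

    Evaluates the EOS-80 one-atmosphere polynomial and subtracts 1000.
    Inputs are treated as practical salinity and temperature at p = 0; for
    the salinity/temperature ranges of fjord water the difference from a
    TEOS-10 evaluation is far below the envelope resolution.

    Parameters
    ----------
    salinity : float or array-like
        Salinity, must lie in [0, 45].
    temperature : float or array-like
        Temperature in degrees Celsius, must lie in [-3, 40].

    Returns
    -------
    float or ndarray
        sigma-theta = rho(S, T, 0) - 1000.
    """
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    if np.any(~np.isfinite(s)) or np.any((s < 0) | (s > 45)):
        raise DataError("salinity out of valid range [0, 45]")
    if np.any(~np.isfinite(t)) or np.any((t < -3) | (t > 40)):
        raise DataError("temperature out of valid range [-3, 40]")
    rho_w = np.polynomial.polynomial.polyval(t, _RHO_W)
    a = np.polynomial.polynomial.polyval(t, _A)
    b = np.polynomial.polynomial.polyval(t, _B)
    rho = rho_w + a * s + b * s ** 1.5 + _C * s ** 2
    out = rho - 1000.0
    if out.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TSRecord:
    """One depth-resolved hydrographic observation."""

    station_id: str
    region: str
    year: int
    depth: float
    temperature: float
    salinity: float
    sigma_theta: float | None = None

    def __post_init__(self):
        if self.depth < 0:
            raise DataError(f"depth must be >= 0, got {self.depth}")
        if self.salinity < 0:
            raise DataError(f"salinity must be >= 0, got {self.salinity}")
        if self.sigma_theta is not None:
            st = self.sigma_theta
            if not np.isfinite(st) or not (-5.0 < st < 50.0):
                raise DataError(f"sigma_theta out of plausible range: {st}")

    def resolved_sigma(self) -> float:
        if self.sigma_theta is not None:
            return self.sigma_theta
        if not (np.isfinite(self.temperature) and np.isfinite(self.salinity)):
            raise DataError(
                f"record {self.station_id}@{self.depth}m: sigma_theta missing "
                "and T/S not usable to compute it"
            )
        return compute_sigma_theta(self.salinity, self.temperature)


# closedness flags: True = closed (inclusive) edge
_DEFAULT_CLOSED = {"t_min": True, "t_max": False, "s_min": True, "s_max": False}


@dataclass(frozen=True)
class WaterMassEnvelope:
    """A named T–S(–sigma) rectangle.  Unbounded edges are ``None``."""

    label: str
    t_min: float | None = None
    t_max: float | None = None
    s_min: float | None = None
    s_max: float | None = None
    sigma_max: float | None = None
    closed: dict = field(default_factory=lambda: dict(_DEFAULT_CLOSED))

    def __post_init__(self):
        if self.t_min is not None and self.t_max is not None and self.t_min > self.t_max:
            raise ConfigError(f"{self.label}: t_min > t_max")
        if self.s_min is not None and self.s_max is not None and self.s_min > self.s_max:
            raise ConfigError(f"{self.label}: s_min > s_max")

    def _edge(self, value: float, bound: float | None, name: str, lower: bool) -> bool:
        if bound is None:
            return True
        closed = self.closed.get(name, _DEFAULT_CLOSED[name])
        if lower:
            return value >= bound if closed else value > bound
        return value <= bound if closed else value < bound

    def contains_ts(self, t: float, s: float) -> bool:
        """Containment in the T–S box only, ignoring any sigma constraint."""
        return (self._edge(t, self.t_min, "t_min", True)
                and self._edge(t, self.t_max, "t_max", False)
                and self._edge(s, self.s_min, "s_min", True)
                and self._edge(s, self.s_max, "s_max", False))

    def contains(self, t: float, s: float, sigma: float) -> bool:
        if not self.contains_ts(t, s):
            return False
        if self.sigma_max is not None and not sigma < self.sigma_max:
            return False
        return True


@dataclass
class EnvelopeTable:
    """Ordered envelope set plus tie-break policy and density threshold."""

    envelopes: list[WaterMassEnvelope]
    precedence: tuple[str, ...] | None = None
    sigma_threshold: float = 27.92

    def __post_init__(self):
        labels = [e.label for e in self.envelopes]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate envelope labels: {labels}")
        if self.sigma_threshold <= 0:
            raise ConfigError("sigma_threshold must be > 0")
        if self.precedence is None:
            self.precedence = tuple(l for l in DEFAULT_PRECEDENCE if l in labels)
        else:
            self.precedence = tuple(self.precedence)
            if sorted(self.precedence) != sorted(labels):
                raise ConfigError(
                    "precedence must be a permutation of the envelope labels; "
                    f"got {self.precedence} for labels {labels}"
                )

    def __getitem__(self, label: str) -> WaterMassEnvelope:
        for e in self.envelopes:
            if e.label == label:
                return e
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(e.label == label for e in self.envelopes)

    @classmethod
    def from_dict(cls, cfg: dict) -> "EnvelopeTable":
        try:
            raw = cfg["envelopes"]
        except KeyError:
            raise ConfigError("envelope config lacks an 'envelopes' section")
        envs = []
        for label, bounds in raw.items():
            bounds = dict(bounds or {})
            closed = dict(_DEFAULT_CLOSED)
            closed.update(bounds.pop("closed", {}))
            envs.append(WaterMassEnvelope(label=label, closed=closed, **bounds))
        return cls(
            envelopes=envs,
            precedence=tuple(cfg["precedence"]) if "precedence" in cfg else None,
            sigma_threshold=float(cfg.get("sigma_threshold", 27.92)),
        )

    @classmethod
    def from_yaml(cls, path) -> "EnvelopeTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_envelope_table() -> EnvelopeTable:
    """Envelope table shipped as package data (Svalbard-fjord convention)."""
    ref = resources.files("fjordflux").joinpath("data/envelopes.yaml")
    return EnvelopeTable.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_record(rec: TSRecord, env: EnvelopeTable) -> str:
    """Assign a single record to a water-mass label via the decision ladder."""
    t, s = rec.temperature, rec.salinity
    if not (np.isfinite(t) and np.isfinite(s)):
        raise DataError(
            f"record {rec.station_id}@{rec.depth}m has non-finite T or S"
        )
    sigma = rec.resolved_sigma()

    matches = [e.label for e in env.envelopes if e.contains(t, s, sigma)]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        for label in env.precedence:
            if label in matches:
                return label

    # density exception: inside the AW/TAW T–S box but too dense
    if sigma >= env.sigma_threshold:
        for label in ("AW", "TAW"):
            if label in env and env[label].contains_ts(t, s):
                return label

    # fresher than ArW's lower salinity limit and colder than LW's lower
    # temperature limit -> ArW
    if "ArW" in env and "LW" in env:
        arw_smin = env["ArW"].s_min
        lw_tmin = env["LW"].t_min
        if (arw_smin is not None and lw_tmin is not None
                and s < arw_smin and t < lw_tmin):
            return "ArW"

    return UNCLASSIFIED


def classify_profile(
    records: Iterable[TSRecord], env: EnvelopeTable
) -> list[tuple[TSRecord, str]]:
    """Element-wise classification; order preserved, records independent."""
    return [(rec, classify_record(rec, env)) for rec in records]


def classify_table(df: pd.DataFrame, env: EnvelopeTable) -> pd.DataFrame:
    """Classify a CTD table, returning a copy with a ``water_mass`` column.

    Requires columns station_id, region, year, depth_m, temp_c, sal;
    an existing ``sigma_theta`` column is honoured, otherwise sigma is
    computed from T and S.
    """
    out = df.copy()
    if "sigma_theta" not in out.columns:
        out["sigma_theta"] = compute_sigma_theta(
            out["sal"].to_numpy(float), out["temp_c"].to_numpy(float)
        )
    labels = []
    for row in out.itertuples(index=False):
        sigma = getattr(row, "sigma_theta", None)
        rec = TSRecord(
            station_id=str(row.station_id),
            region=str(row.region),
            year=int(row.year),
            depth=float(row.depth_m),
            temperature=float(row.temp_c),
            salinity=float(row.sal),
            sigma_theta=None if sigma is None or pd.isna(sigma) else float(sigma),
        )
        labels.append(classify_record(rec, env))
    out["water_mass"] = labels
    return out
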