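"""Domain data types and CSV readers/writers for population reconstruction.

Age-at-harvest data are annual harvest counts cross-classified by year and age
class (young-of-the-year "juvenile" vs. the pooled adult class "A+"), together
with an annual hunter-effort series.  Auxiliary radiotelemetry records and, for
the two-season turkey model, known-removal series are carried as separate
tables.  All readers validate their input and raise :class:`ValidationError`
naming the offending row and field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "AgeAtHarvestData",
    "TelemetryData",
    "RemovalData",
    "ModelSpec",
    "read_age_at_harvest",
    "write_age_at_harvest",
    "read_telemetry",
    "write_telemetry",
    "read_removals",
    "write_removals",
    "write_fit",
    "read_config",
]

JUVENILE = "juvenile"
ADULT = "adult"
POOLED = "pooled"
_AGE_CLASSES = (JUVENILE, ADULT, POOLED)


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


def _as_int_counts(values, name: str, years=None) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.all(np.isfinite(arr.astype(float))):
        raise ValidationError(f"{name}: missing or non-finite value")
    if arr.size and np.any(arr.astype(float) != np.round(arr.astype(float))):
        raise ValidationError(f"{name}: counts must be integers")
    out = np.asarray(np.round(arr.astype(float)), dtype=np.int64)
    if np.any(out < 0):
        i = int(np.argmax(out < 0))
        row = years[i] if years is not None else i
        raise ValidationError(f"{name}: negative count in row {row!r}")
    return out


@dataclass(frozen=True)
class AgeAtHarvestData:
    """A Y x 2 age-at-harvest matrix plus the annual effort series.

    Attributes
    ----------
    years : contiguous, strictly increasing calendar years (length Y >= 3).
    juvenile_harvest, adult_harvest : harvest counts x_{i,J}, x_{i,A+} per year.
    effort : positive hunter-effort measure f_i per year (arbitrary units; the
        harvest probability is ``1 - exp(-c f_i e^nu)``, so only ``c f`` is
        identified).
    """

    years: np.ndarray
    juvenile_harvest: np.ndarray
    adult_harvest: np.ndarray
    effort: np.ndarray
    effort_se: np.ndarray | None = None  # metadata only; never enters a likelihood

    def __post_init__(self):
        years = np.asarray(self.years, dtype=np.int64)
        juv = _as_int_counts(self.juvenile_harvest, "juvenile_harvest", years)
        adu = _as_int_counts(self.adult_harvest, "adult_harvest", years)
        eff = np.asarray(self.effort, dtype=float)
        if not (len(years) == len(juv) == len(adu) == len(eff)):
            raise ValidationError("age-at-harvest columns have unequal lengths")
        if len(years) < 3:
            raise ValidationError("need at least 3 years of age-at-harvest data")
        if np.any(np.diff(years) != 1):
            raise ValidationError("years must be contiguous and strictly increasing")
        if np.any(~np.isfinite(eff)) or np.any(eff <= 0):
            i = int(np.argmax(~(eff > 0)))
            raise ValidationError(f"effort: non-positive value in row {years[i]!r}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "juvenile_harvest", juv)
        object.__setattr__(self, "adult_harvest", adu)
        object.__setattr__(self, "effort", eff)
        if self.effort_se is not None:
            object.__setattr__(self, "effort_se", np.asarray(self.effort_se, dtype=float))

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def total_harvest(self) -> np.ndarray:
        return self.juvenile_harvest + self.adult_harvest

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.n_years:
            raise KeyError(f"year {year} outside study period")
        return idx


@dataclass(frozen=True)
class TelemetryData:
    """Radiotelemetry tagging records: animals at risk and harvested per year.

    ``age_class`` is 'juvenile', 'adult' or 'pooled' (single shared harvest
    probability).  An empty table is valid and contributes nothing.
    """

    year: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    age_class: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    n_at_risk: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_harvested: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        year = np.asarray(self.year, dtype=np.int64)
        cls = np.asarray(self.age_class, dtype=object)
        risk = _as_int_counts(self.n_at_risk, "n_at_risk", year)
        harv = _as_int_counts(self.n_harvested, "n_harvested", year)
        if not (len(year) == len(cls) == len(risk) == len(harv)):
            raise ValidationError("telemetry columns have unequal lengths")
        for i, c in enumerate(cls):
            if c not in _AGE_CLASSES:
                raise ValidationError(f"age_class: unknown class {c!r} in row {year[i]!r}")
        bad = harv > risk
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"n_harvested: {harv[i]} exceeds n_at_risk {risk[i]} in row {year[i]!r}"
            )
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "age_class", cls)
        object.__setattr__(self, "n_at_risk", risk)
        object.__setattr__(self, "n_harvested", harv)

    def __len__(self) -> int:
        return len(self.year)

    def subset(self, age_class: str) -> "TelemetryData":
        m = self.age_class == age_class
        return TelemetryData(self.year[m], self.age_class[m], self.n_at_risk[m], self.n_harvested[m])


@dataclass(frozen=True)
class RemovalData:
    """Known removals for the two-season turkey model (one row per year).

    Spring non-permittee removals (NPR: landowner and youth harvest) occur
    before the permitted spring season; fall harvests are treated as known
    removals.  ``poult_hen_ratio`` may include one pre-study year (used for the
    one-year-advanced productivity comparison); optional columns may be NaN.
    """

    years: np.ndarray
    spring_npr_juvenile: np.ndarray
    spring_npr_adult: np.ndarray
    fall_harvest_juvenile: np.ndarray
    fall_harvest_adult: np.ndarray
    poult_hen_ratio: np.ndarray | None = None
    archer_index: np.ndarray | None = None

    def __post_init__(self):
        years = np.asarray(self.years, dtype=np.int64)
        cols = {}
        for name in ("spring_npr_juvenile", "spring_npr_adult",
                     "fall_harvest_juvenile", "fall_harvest_adult"):
            cols[name] = _as_int_counts(getattr(self, name), name, years)
            if len(cols[name]) != len(years):
                raise ValidationError(f"{name}: length mismatch")
        object.__setattr__(self, "years", years)
        for name, v in cols.items():
            object.__setattr__(self, name, v)
        for name in ("poult_hen_ratio", "archer_index"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of a reconstruction model.

    abundance_mode : 'HT' (second-stage Horvitz-Thompson) or 'AA' (initial
        cohort abundances estimated in the likelihood).
    effects_mode : 'RE' (temporal random effects, Laplace-marginalized) or 'FE'.
    include_catch_effort : add the auxiliary catch-effort binomial likelihood.
    re_structure : which processes carry random effects.
    """

    abundance_mode: str = "HT"
    effects_mode: str = "RE"
    include_catch_effort: bool = False
    re_structure: tuple[str, ...] = ("survival", "vulnerability")

    def __post_init__(self):
        if self.abundance_mode not in ("HT", "AA"):
            raise ValidationError(f"abundance_mode must be HT or AA, got {self.abundance_mode!r}")
        if self.effects_mode not in ("RE", "FE"):
            raise ValidationError(f"effects_mode must be RE or FE, got {self.effects_mode!r}")
        for r in self.re_structure:
            if r not in ("survival", "vulnerability"):
                raise ValidationError(f"unknown random-effect structure {r!r}")
        if self.abundance_mode == "AA" and self.effects_mode == "FE" and not self.include_catch_effort:
            raise ValidationError(
                "AA_FE requires the catch-effort auxiliary likelihood (numerically "
                "unstable without it)"
            )

    @property
    def code(self) -> str:
        return f"{self.abundance_mode}_{self.effects_mode}"

    @classmethod
    def from_code(cls, code: str, include_catch_effort: bool = False,
                  re_structure: tuple[str, ...] = ("survival", "vulnerability")) -> "ModelSpec":
        a, e = code.upper().split("_")
        return cls(a, e, include_catch_effort, re_structure if e == "RE" else ())


# ---------------------------------------------------------------------------
# CSV IO


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_age_at_harvest(path) -> AgeAtHarvestData:
    """Read a year,juvenile_harvest,adult_harvest,effort CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["year", "juvenile_harvest", "adult_harvest", "effort"], path)
    se = df["effort_se"].to_numpy() if "effort_se" in df.columns else None
    return AgeAtHarvestData(
        df["year"].to_numpy(), df["juvenile_harvest"].to_numpy(),
        df["adult_harvest"].to_numpy(), df["effort"].to_numpy(), se,
    )


def write_age_at_harvest(path, data: AgeAtHarvestData) -> None:
    df = pd.DataFrame({
        "year": data.years,
        "juvenile_harvest": data.juvenile_harvest,
        "adult_harvest": data.adult_harvest,
        "effort": data.effort,
    })
    if data.effort_se is not None:
        df["effort_se"] = data.effort_se
    df.to_csv(path, index=False)


def read_telemetry(path) -> TelemetryData:
    """Read year,age_class,n_at_risk,n_harvested records (empty file allowed)."""
    df = pd.read_csv(path)
    if df.empty:
        return TelemetryData()
    _require_columns(df, ["year", "age_class", "n_at_risk", "n_harvested"], path)
    return TelemetryData(
        df["year"].to_numpy(), df["age_class"].to_numpy(),
        df["n_at_risk"].to_numpy(), df["n_harvested"].to_numpy(),
    )


def write_telemetry(path, tel: TelemetryData) -> None:
    pd.DataFrame({
        "year": tel.year, "age_class": tel.age_class,
        "n_at_risk": tel.n_at_risk, "n_harvested": tel.n_harvested,
    }).to_csv(path, index=False)


def read_removals(path) -> RemovalData:
    df = pd.read_csv(path)
    _require_columns(df, ["year", "spring_npr_juvenile", "spring_npr_adult",
                          "fall_harvest_juvenile", "fall_harvest_adult"], path)
    opt = {c: df[c].to_numpy() for c in ("poult_hen_ratio", "archer_index") if c in df.columns}
    return RemovalData(
        df["year"].to_numpy(), df["spring_npr_juvenile"].to_numpy(),
        df["spring_npr_adult"].to_numpy(), df["fall_harvest_juvenile"].to_numpy(),
        df["fall_harvest_adult"].to_numpy(), **opt,
    )


def write_removals(path, rem: RemovalData) -> None:
    df = pd.DataFrame({
        "year": rem.years,
        "spring_npr_juvenile": rem.spring_npr_juvenile,
        "spring_npr_adult": rem.spring_npr_adult,
        "fall_harvest_juvenile": rem.fall_harvest_juvenile,
        "fall_harvest_adult": rem.fall_harvest_adult,
    })
    if rem.poult_hen_ratio is not None:
        df["poult_hen_ratio"] = rem.poult_hen_ratio
    if rem.archer_index is not None:
        df["archer_index"] = rem.archer_index
    df.to_csv(path, index=False)


def write_fit(path_prefix, fit) -> None:
    """Write a FitResult to ``<prefix>_params.csv`` and ``<prefix>_abundance.csv``."""
    prefix = str(path_prefix)
    rows = []
    for name, value in fit.params.items():
        rows.append({"parameter": name, "estimate": value,
                     "se": fit.se.get(name, np.nan)})
    rows.append({"parameter": "loglik", "estimate": fit.loglik, "se": np.nan})
    rows.append({"parameter": "aic", "estimate": fit.aic, "se": np.nan})
    pd.DataFrame(rows).to_csv(prefix + "_params.csv", index=False)
    fit.abundance.to_csv(prefix + "_abundance.csv", index=False)


def read_config(path) -> dict:
    """Read a key: value (YAML subset) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping of key: value pairs")
    return cfg
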