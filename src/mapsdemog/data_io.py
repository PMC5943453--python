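"""Dataset tables, covariate assembly and filtering rules for constant-effort
banding (MAPS-style) data.

The analysis consumes four tables: station metadata (region, human-footprint
index, activity, effort), station-year adult counts, station-year
juvenile/total captures, and individual capture histories.  This module owns
the record types, CSV round-trip, the region classification and
footprint-year assignment rules, the station filters applied before each
sub-analysis, and the covariate standardization that produces model-ready
arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REGIONS = ("west", "central", "east")
REGION_INDEX = {name: k for k, name in enumerate(REGIONS)}

FEMALE, MALE = 0, 1

#: Years at which the global human-footprint rasters were sampled.
FOOTPRINT_YEARS = (1993, 2009)


class CoordinateError(ValueError):
    """Coordinates fall outside the configured plausibility bounding box."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable boundaries, thresholds and scaling conventions.

    ``west_boundary``
        Meridian separating west from central/east; stations strictly west of
        it are "west" (a station exactly on the boundary is not west).
    ``east_max_latitude`` / ``east_meridian``
        A non-west station is "east" when its latitude is below
        ``east_max_latitude`` and its longitude is east of ``east_meridian``.
    ``scale_ddof``
        Delta degrees of freedom for covariate standardization (0 =
        population SD).
    """

    west_boundary: float = -102.0
    east_max_latitude: float = 47.0
    east_meridian: float = -90.0
    bbox_lon: tuple[float, float] = (-170.0, -50.0)
    bbox_lat: tuple[float, float] = (24.0, 72.0)
    survival_min_individuals: int = 5
    hf_scale: str = "1km"
    scale_ddof: int = 0


DEFAULT_CONFIG = AnalysisConfig()


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("bbox_lon", "bbox_lat"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationRecord:
    """One banding station with covariates and activity.

    ``hf_1km``/``hf_10km`` are the per-station human-footprint values (0-50
    scale) assigned from the 1993/2009 raw values by
    :func:`assign_footprint_value`; ``effort_by_year`` maps calendar year to
    net-hours.
    """

    station_id: str
    region: str
    longitude: float
    latitude: float
    hf_1993_1km: float
    hf_2009_1km: float
    hf_1993_10km: float
    hf_2009_10km: float
    active_years: frozenset[int]
    effort_by_year: dict[int, float] = field(default_factory=dict)
    hf_1km: float = float("nan")
    hf_10km: float = float("nan")

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        for name in ("hf_1993_1km", "hf_2009_1km", "hf_1993_10km", "hf_2009_10km"):
            v = getattr(self, name)
            if not (0.0 <= v <= 50.0):
                raise ValueError(
                    f"station {self.station_id}: {name}={v} outside [0, 50]"
                )

    def hf(self, scale: str) -> float:
        if scale == "1km":
            return self.hf_1km
        if scale == "10km":
            return self.hf_10km
        raise ValueError(f"unknown footprint scale {scale!r}")


@dataclass(frozen=True)
class CountObservation:
    """Adult count for one operated station-year (year is a 0-based index)."""

    station_id: str
    year: int
    adult_count: int
    effort: float

    def __post_init__(self) -> None:
        if self.adult_count < 0:
            raise ValueError("adult_count must be >= 0")
        if self.effort <= 0:
            raise ValueError(
                f"station {self.station_id} year {self.year}: effort must be "
                "positive; unoperated station-years must be absent, not zero"
            )


@dataclass(frozen=True)
class ProductivityObservation:
    """Juvenile vs total captures for one station-year."""

    station_id: str
    year: int
    juveniles: int
    total: int

    def __post_init__(self) -> None:
        if self.juveniles < 0 or self.total < 0:
            raise ValueError("counts must be >= 0")
        if self.juveniles > self.total:
            raise ValueError(
                f"station {self.station_id} year {self.year}: "
                f"juveniles ({self.juveniles}) exceed total ({self.total})"
            )


@dataclass(frozen=True)
class CaptureHistory:
    """One marked individual's annual detection record.

    ``detections`` is a full-length 0/1 tuple over study years 0..T-1 with a 1
    at ``first_year`` (conditioning occasion) and no detections before it.
    ``predetermined`` flags within-season repeat capture, which identifies the
    bird as a resident.
    """

    individual_id: str
    station_id: str
    sex: int
    first_year: int
    detections: tuple[int, ...]
    predetermined: int

    def __post_init__(self) -> None:
        y = self.detections
        f = self.first_year
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"individual {self.individual_id}: sex must be 0/1")
        if self.predetermined not in (0, 1):
            raise ValueError("predetermined flag must be 0/1")
        if not 0 <= f < len(y):
            raise ValueError("first_year outside the study span")
        if y[f] != 1:
            raise ValueError(
                f"individual {self.individual_id}: no detection at first_year"
            )
        if any(v not in (0, 1) for v in y):
            raise ValueError("detections must be 0/1")
        if any(y[: f]):
            raise ValueError(
                f"individual {self.individual_id}: detection before first_year"
            )

    @property
    def last_detection(self) -> int:
        return max(t for t, v in enumerate(self.detections) if v)


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

def classify_region(
    longitude: float, latitude: float, config: AnalysisConfig = DEFAULT_CONFIG
) -> str:
    """Assign a station to west/central/east from its coordinates.

    West is strictly west of ``config.west_boundary`` (102°W by default, the
    approximate midpoint between the Alberta and Ontario/Minnesota station
    clusters); among the remainder, stations south of ``east_max_latitude``
    and east of ``east_meridian`` are east, everything else central.
    """
    if not (config.bbox_lon[0] <= longitude <= config.bbox_lon[1]) or not (
        config.bbox_lat[0] <= latitude <= config.bbox_lat[1]
    ):
        raise CoordinateError(
            f"({longitude}, {latitude}) outside plausible bounds "
            f"lon {config.bbox_lon}, lat {config.bbox_lat}"
        )
    if longitude < config.west_boundary:
        return "west"
    if latitude < config.east_max_latitude and longitude > config.east_meridian:
        return "east"
    return "central"


def assign_footprint_value(
    active_years: Iterable[int], hf_1993: float, hf_2009: float
) -> float:
    """Pick the footprint value representing a station's operating period.

    Stations active in both raster years get the average of the two values;
    otherwise the value whose raster year is nearest the station's median
    active year is used, ties going to 2009.
    """
    years = sorted(set(active_years))
    if not years:
        raise ValueError("active_years must be non-empty")
    for name, v in (("hf_1993", hf_1993), ("hf_2009", hf_2009)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing raw footprint value {name}")
    if FOOTPRINT_YEARS[0] in years and FOOTPRINT_YEARS[1] in years:
        return 0.5 * (hf_1993 + hf_2009)
    median_year = float(np.median(years))
    d93 = abs(median_year - FOOTPRINT_YEARS[0])
    d09 = abs(median_year - FOOTPRINT_YEARS[1])
    return hf_1993 if d93 < d09 else hf_2009


def assign_station_footprints(
    stations: Sequence[StationRecord],
) -> list[StationRecord]:
    """Fill ``hf_1km``/``hf_10km`` for every station via the assignment rule."""
    out = []
    for s in stations:
        try:
            hf1 = assign_footprint_value(s.active_years, s.hf_1993_1km, s.hf_2009_1km)
            hf10 = assign_footprint_value(
                s.active_years, s.hf_1993_10km, s.hf_2009_10km
            )
        except ValueError as err:
            raise ValueError(f"station {s.station_id}: {err}") from err
        out.append(replace(s, hf_1km=hf1, hf_10km=hf10))
    return out


# ---------------------------------------------------------------------------
# Station filters
# ---------------------------------------------------------------------------

def filter_abundance_stations(
    counts: Sequence[CountObservation],
    histories: Sequence[CaptureHistory] = (),
) -> set[str]:
    """Stations with at least one capture (adult or juvenile) over all years."""
    kept: set[str] = set()
    totals: dict[str, int] = {}
    for c in counts:
        totals[c.station_id] = totals.get(c.station_id, 0) + c.adult_count
    for sid, n in totals.items():
        if n >= 1:
            kept.add(sid)
    for h in histories:
        kept.add(h.station_id)
    if not kept:
        logger.warning("abundance filter retained no stations")
    return kept


def filter_productivity_stations(
    productivity: Sequence[ProductivityObservation],
) -> set[str]:
    """Drop stations whose captures were all juveniles (no adults ever)."""
    juv: dict[str, int] = {}
    tot: dict[str, int] = {}
    for p in productivity:
        juv[p.station_id] = juv.get(p.station_id, 0) + p.juveniles
        tot[p.station_id] = tot.get(p.station_id, 0) + p.total
    kept = set()
    for sid in tot:
        if tot[sid] > 0 and juv[sid] == tot[sid]:
            logger.info("productivity filter: dropped juvenile-only station %s", sid)
            continue
        kept.add(sid)
    return kept


def filter_survival_stations(
    histories: Sequence[CaptureHistory], min_individuals: int = 5
) -> set[str]:
    """Stations with at least ``min_individuals`` marked individuals."""
    n: dict[str, set[str]] = {}
    for h in histories:
        n.setdefault(h.station_id, set()).add(h.individual_id)
    kept = {sid for sid, inds in n.items() if len(inds) >= min_individuals}
    dropped = set(n) - kept
    if dropped:
        logger.info(
            "survival filter: dropped %d station(s) with < %d individuals",
            len(dropped), min_individuals,
        )
    return kept


# ---------------------------------------------------------------------------
# Model-ready arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateScaling:
    """Standardization constants, kept so coefficients back-transform."""

    hf_mean: float
    hf_sd: float
    effort_mean: float
    effort_sd: float
    year_mid: float


@dataclass
class AbundanceData:
    """Arrays for the Poisson count model (one row per station-year)."""

    station_ids: list[str]
    region_idx: np.ndarray          # (S,)
    hf_std: np.ndarray              # (S,)
    obs_station: np.ndarray         # (n,) int index into station_ids
    obs_t: np.ndarray               # (n,) midpoint-centered year, unit = 1 yr
    obs_effort_std: np.ndarray      # (n,)
    counts: np.ndarray              # (n,) int
    scaling: CovariateScaling

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)

    @property
    def obs_region(self) -> np.ndarray:
        return self.region_idx[self.obs_station]


@dataclass
class ProductivityData:
    """Arrays for the binomial juvenile-proportion model."""

    station_ids: list[str]
    region_idx: np.ndarray
    hf_std: np.ndarray
    obs_station: np.ndarray
    obs_t: np.ndarray
    juveniles: np.ndarray
    totals: np.ndarray
    scaling: CovariateScaling

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)

    @property
    def obs_region(self) -> np.ndarray:
        return self.region_idx[self.obs_station]


@dataclass
class SurvivalData:
    """Arrays for the transient Cormack-Jolly-Seber likelihood.

    ``t_std`` holds the midpoint-centered year value for each occasion;
    survival over the interval t -> t+1 is evaluated at ``t_std[t]``.
    ``int_mask[i, t]`` is True for survival intervals between an individual's
    first and last detections.
    """

    station_ids: list[str]
    region_idx: np.ndarray          # (S,)
    hf_std: np.ndarray              # (S,)
    n_occasions: int
    t_std: np.ndarray               # (T,)
    ind_ids: list[str]
    ind_station: np.ndarray         # (n,) int
    ind_sex: np.ndarray             # (n,)
    first: np.ndarray               # (n,)
    last: np.ndarray                # (n,)
    predetermined: np.ndarray       # (n,)
    n_redetect: np.ndarray          # (n,) detections in (first, last]
    n_miss: np.ndarray              # (n,) misses in (first, last]
    int_mask: np.ndarray            # (n, T-1) bool
    scaling: CovariateScaling

    @property
    def n_individuals(self) -> int:
        return len(self.ind_ids)

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)

    @property
    def ind_region(self) -> np.ndarray:
        return self.region_idx[self.ind_station]

    @property
    def ind_hf(self) -> np.ndarray:
        return self.hf_std[self.ind_station]


@dataclass
class ModelData:
    """Bundle of model-ready arrays produced by :func:`standardize_covariates`."""

    abundance: AbundanceData | None
    productivity: ProductivityData | None
    survival: SurvivalData | None
    scaling: CovariateScaling


def _standardize(values: np.ndarray, ddof: int, what: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=ddof))
    if sd == 0.0:
        raise ValueError(f"zero-variance covariate: {what}")
    return (values - mean) / sd, mean, sd


def standardize_covariates(
    stations: Sequence[StationRecord],
    counts: Sequence[CountObservation] | None = None,
    productivity: Sequence[ProductivityObservation] | None = None,
    histories: Sequence[CaptureHistory] | None = None,
    *,
    config: AnalysisConfig = DEFAULT_CONFIG,
    hf_scale: str | None = None,
    first_year: int = 0,
    n_years: int | None = None,
) -> ModelData:
    """Assemble standardized model-ready arrays from the filtered tables.

    Footprint is z-scored across stations and effort across station-years
    (SD convention set by ``config.scale_ddof``); the year covariate is
    centered at the study midpoint with unit = 1 year, so trend coefficients
    are per-year on the link scale.  The constants are recorded in
    :class:`CovariateScaling`.
    """
    hf_scale = hf_scale or config.hf_scale
    ddof = config.scale_ddof
    station_ids = [s.station_id for s in stations]
    sidx = {sid: i for i, sid in enumerate(station_ids)}
    region_idx = np.array([REGION_INDEX[s.region] for s in stations], dtype=np.int64)
    hf_raw = np.array([s.hf(hf_scale) for s in stations], dtype=float)
    if np.any(~np.isfinite(hf_raw)):
        raise ValueError("footprint values not assigned; run assign_station_footprints")
    hf_std, hf_mean, hf_sd = _standardize(hf_raw, ddof, f"footprint ({hf_scale})")

    # Study span: union of count years and history length.
    t_hi = 0
    if counts:
        t_hi = max(t_hi, max(c.year for c in counts) + 1)
    if productivity:
        t_hi = max(t_hi, max(p.year for p in productivity) + 1)
    if histories:
        t_hi = max(t_hi, len(histories[0].detections))
    if n_years is not None:
        t_hi = max(t_hi, n_years)
    if t_hi < 2:
        raise ValueError("study span must cover at least 2 years")
    year_mid = first_year + (t_hi - 1) / 2.0

    effort_mean = effort_sd = float("nan")
    abundance = None
    if counts:
        effort = np.array([c.effort for c in counts], dtype=float)
        eff_std, effort_mean, effort_sd = _standardize(effort, ddof, "effort")
        abundance = AbundanceData(
            station_ids=station_ids,
            region_idx=region_idx,
            hf_std=hf_std,
            obs_station=np.array([sidx[c.station_id] for c in counts]),
            obs_t=np.array([first_year + c.year for c in counts], dtype=float)
            - year_mid,
            obs_effort_std=eff_std,
            counts=np.array([c.adult_count for c in counts], dtype=np.int64),
            scaling=None,  # filled below
        )

    scaling = CovariateScaling(hf_mean, hf_sd, effort_mean, effort_sd, year_mid)
    if abundance is not None:
        abundance.scaling = scaling

    productivity_data = None
    if productivity:
        productivity_data = ProductivityData(
            station_ids=station_ids,
            region_idx=region_idx,
            hf_std=hf_std,
            obs_station=np.array([sidx[p.station_id] for p in productivity]),
            obs_t=np.array([first_year + p.year for p in productivity], dtype=float)
            - year_mid,
            juveniles=np.array([p.juveniles for p in productivity], dtype=np.int64),
            totals=np.array([p.total for p in productivity], dtype=np.int64),
            scaling=scaling,
        )

    survival_data = None
    if histories:
        survival_data = build_survival_data(
            histories, station_ids, region_idx, hf_std, t_hi, first_year, scaling
        )

    return ModelData(abundance, productivity_data, survival_data, scaling)


def build_survival_data(
    histories: Sequence[CaptureHistory],
    station_ids: list[str],
    region_idx: np.ndarray,
    hf_std: np.ndarray,
    n_occasions: int,
    first_year: int,
    scaling: CovariateScaling,
) -> SurvivalData:
    sidx = {sid: i for i, sid in enumerate(station_ids)}
    n = len(histories)
    first = np.empty(n, dtype=np.int64)
    last = np.empty(n, dtype=np.int64)
    det_total = np.empty(n, dtype=np.int64)
    for i, h in enumerate(histories):
        if len(h.detections) != n_occasions:
            raise ValueError(
                f"individual {h.individual_id}: history length "
                f"{len(h.detections)} != {n_occasions} occasions"
            )
        if h.station_id not in sidx:
            raise ValueError(f"individual {h.individual_id}: unknown station")
        first[i] = h.first_year
        last[i] = h.last_detection
        det_total[i] = sum(h.detections)
    n_redetect = det_total - 1
    n_miss = (last - first) - n_redetect
    tt = np.arange(n_occasions - 1)
    int_mask = (tt[None, :] >= first[:, None]) & (tt[None, :] < last[:, None])
    t_std = first_year + np.arange(n_occasions, dtype=float) - scaling.year_mid
    return SurvivalData(
        station_ids=station_ids,
        region_idx=region_idx,
        hf_std=hf_std,
        n_occasions=n_occasions,
        t_std=t_std,
        ind_ids=[h.individual_id for h in histories],
        ind_station=np.array([sidx[h.station_id] for h in histories]),
        ind_sex=np.array([h.sex for h in histories], dtype=np.int64),
        first=first,
        last=last,
        predetermined=np.array([h.predetermined for h in histories], dtype=np.int64),
        n_redetect=n_redetect,
        n_miss=n_miss,
        int_mask=int_mask,
        scaling=scaling,
    )


def destandardize_linear(
    intercept_std: float, coefs_std: dict[str, float], scaling: CovariateScaling
) -> tuple[float, dict[str, float]]:
    """Back-transform coefficients fitted on standardized covariates.

    For eta = a + sum_j b_j (x_j - m_j)/s_j the raw-scale coefficients are
    b_j/s_j with intercept a - sum_j b_j m_j/s_j; predictions are identical.
    Recognized keys: ``hf``, ``effort``, ``year``.
    """
    ms = {
        "hf": (scaling.hf_mean, scaling.hf_sd),
        "effort": (scaling.effort_mean, scaling.effort_sd),
        "year": (scaling.year_mid, 1.0),
    }
    intercept = intercept_std
    raw = {}
    for key, b in coefs_std.items():
        m, s = ms[key]
        raw[key] = b / s
        intercept -= b * m / s
    return intercept, raw


def prepare_joint_data(
    stations: Sequence[StationRecord],
    counts: Sequence[CountObservation],
    histories: Sequence[CaptureHistory],
    *,
    config: AnalysisConfig = DEFAULT_CONFIG,
    hf_scale: str | None = None,
    first_year: int = 1993,
    n_years: int | None = None,
) -> ModelData:
    """Apply the abundance and survival filters and build model-ready arrays.

    The station list (hence random-effect indexing) is the union of stations
    passing either filter; capture histories keep only stations with enough
    marked individuals.
    """
    keep_counts = filter_abundance_stations(counts, histories)
    keep_surv = filter_survival_stations(
        histories, config.survival_min_individuals
    )
    keep = keep_counts | keep_surv
    stations = [s for s in stations if s.station_id in keep]
    counts = [c for c in counts if c.station_id in keep]
    histories = [h for h in histories if h.station_id in keep_surv]
    return standardize_covariates(
        stations, counts, histories=histories, config=config,
        hf_scale=hf_scale, first_year=first_year, n_years=n_years,
    )


def prepare_productivity_data(
    stations: Sequence[StationRecord],
    productivity: Sequence[ProductivityObservation],
    *,
    config: AnalysisConfig = DEFAULT_CONFIG,
    hf_scale: str | None = None,
    first_year: int = 1993,
    n_years: int | None = None,
) -> ModelData:
    """Drop juvenile-only stations and build model-ready arrays."""
    keep = filter_productivity_stations(productivity)
    stations = [s for s in stations if s.station_id in keep]
    productivity = [p for p in productivity if p.station_id in keep]
    return standardize_covariates(
        stations, productivity=productivity, config=config,
        hf_scale=hf_scale, first_year=first_year, n_years=n_years,
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _pack_effort(effort_by_year: dict[int, float]) -> str:
    return ";".join(f"{y}:{v!r}" for y, v in sorted(effort_by_year.items()))


def _unpack_effort(packed: str) -> dict[int, float]:
    if not packed or (isinstance(packed, float) and np.isnan(packed)):
        return {}
    out = {}
    for item in str(packed).split(";"):
        y, v = item.split(":")
        out[int(y)] = float(v)
    return out


def write_stations(stations: Sequence[StationRecord], path: str | Path) -> None:
    rows = []
    for s in stations:
        rows.append(
            {
                "station_id": s.station_id,
                "region": s.region,
                "longitude": repr(s.longitude),
                "latitude": repr(s.latitude),
                "hf_1993_1km": repr(s.hf_1993_1km),
                "hf_2009_1km": repr(s.hf_2009_1km),
                "hf_1993_10km": repr(s.hf_1993_10km),
                "hf_2009_10km": repr(s.hf_2009_10km),
                "hf_1km": repr(s.hf_1km),
                "hf_10km": repr(s.hf_10km),
                "active_years": ";".join(str(y) for y in sorted(s.active_years)),
                "effort_by_year": _pack_effort(s.effort_by_year),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stations(path: str | Path) -> list[StationRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StationRecord(
                station_id=row.station_id,
                region=row.region,
                longitude=float(row.longitude),
                latitude=float(row.latitude),
                hf_1993_1km=float(row.hf_1993_1km),
                hf_2009_1km=float(row.hf_2009_1km),
                hf_1993_10km=float(row.hf_1993_10km),
                hf_2009_10km=float(row.hf_2009_10km),
                active_years=frozenset(
                    int(y) for y in row.active_years.split(";") if y
                ),
                effort_by_year=_unpack_effort(row.effort_by_year),
                hf_1km=float(row.hf_1km),
                hf_10km=float(row.hf_10km),
            )
        )
    return out


def write_counts(counts: Sequence[CountObservation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "station_id": [c.station_id for c in counts],
            "year": [c.year for c in counts],
            "adult_count": [c.adult_count for c in counts],
            "effort": [repr(c.effort) for c in counts],
        }
    ).to_csv(path, index=False)


def read_counts(path: str | Path) -> list[CountObservation]:
    df = pd.read_csv(path, dtype={"station_id": str})
    return [
        CountObservation(r.station_id, int(r.year), int(r.adult_count), float(r.effort))
        for r in df.itertuples(index=False)
    ]


def write_productivity(
    productivity: Sequence[ProductivityObservation], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "station_id": [p.station_id for p in productivity],
            "year": [p.year for p in productivity],
            "juveniles": [p.juveniles for p in productivity],
            "total": [p.total for p in productivity],
        }
    ).to_csv(path, index=False)


def read_productivity(path: str | Path) -> list[ProductivityObservation]:
    df = pd.read_csv(path, dtype={"station_id": str})
    return [
        ProductivityObservation(r.station_id, int(r.year), int(r.juveniles), int(r.total))
        for r in df.itertuples(index=False)
    ]


def write_captures(histories: Sequence[CaptureHistory], path: str | Path) -> None:
    """Wide form: one row per individual, detection vector as a 0/1 string."""
    pd.DataFrame(
        {
            "individual_id": [h.individual_id for h in histories],
            "station_id": [h.station_id for h in histories],
            "sex": [h.sex for h in histories],
            "first_year": [h.first_year for h in histories],
            "detections": ["".join(map(str, h.detections)) for h in histories],
            "predetermined": [h.predetermined for h in histories],
        }
    ).to_csv(path, index=False)


def read_captures(path: str | Path) -> list[CaptureHistory]:
    df = pd.read_csv(path, dtype={"station_id": str, "individual_id": str,
                                  "detections": str})
    if "detections" in df.columns:
        return [
            CaptureHistory(
                r.individual_id, r.station_id, int(r.sex), int(r.first_year),
                tuple(int(c) for c in r.detections), int(r.predetermined),
            )
            for r in df.itertuples(index=False)
        ]
    # Long form: individual_id, station_id, sex, predetermined, year, detected.
    out = []
    n_years = int(df["year"].max()) + 1
    for (iid,), grp in df.groupby(["individual_id"], sort=True):
        y = [0] * n_years
        for r in grp.itertuples(index=False):
            if int(r.detected):
                y[int(r.year)] = 1
        first = y.index(1)
        r0 = grp.iloc[0]
        out.append(
            CaptureHistory(iid, r0["station_id"], int(r0["sex"]), first,
                           tuple(y), int(r0["predetermined"]))
        )
    return out
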