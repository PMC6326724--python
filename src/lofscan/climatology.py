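"""Seasonal drought climatology from weekly Vegetative Health Index rasters.

The Vegetative Health Index (VHI) is a satellite-derived drought indicator on
a 0-100 scale; weeks with VHI below 40 are classified as drought conditions.
This module turns a multi-year weekly VHI raster into per-pixel seasonal
drought frequencies, a drought-timing index (the natural log of the ratio of
spring to summer drought frequency), per-ecotype climate values extracted at
locations of origin, and a multiple regression of flowering time on the
seasonal drought frequencies.

Seasons are photoperiodic quarters: 13 ISO weeks centred on the week of the
spring equinox, summer solstice, fall equinox and winter solstice.  The
calendar is a plain config object so alternative (e.g. southern-hemisphere)
windows can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "fall", "winter")

DEFAULT_ANCHOR_WEEKS = {"spring": 12, "summer": 25, "fall": 38, "winter": 51}


class ClimatologyError(ValueError):
    """Raised for invalid climatology parameters or degenerate designs."""


@dataclass(frozen=True)
class SeasonCalendar:
    """Assignment of ISO weeks to photoperiodic seasons.

    Each season covers ``2 * half_width + 1`` weeks centred on its anchor
    week, wrapping around the year end.  Anchors default to the
    northern-hemisphere equinox/solstice weeks.
    """

    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHOR_WEEKS))
    half_width: int = 6
    n_weeks: int = 52

    def __post_init__(self):
        mapping = {}
        for season, anchor in self.anchors.items():
            for off in range(-self.half_width, self.half_width + 1):
                week = (anchor - 1 + off) % self.n_weeks + 1
                if week in mapping:
                    raise ClimatologyError(
                        f"week {week} assigned to both {mapping[week]!r} and {season!r}"
                    )
                mapping[week] = season
        object.__setattr__(self, "_week_to_season", mapping)

    def season_of(self, week: int) -> str | None:
        """Season containing ISO ``week`` (1-based), or None if unassigned."""
        return self._week_to_season.get(week)

    def weeks_of(self, season: str) -> np.ndarray:
        """Sorted 1-based ISO weeks belonging to ``season``."""
        return np.array(sorted(w for w, s in self._week_to_season.items() if s == season))


@dataclass
class VhiGrid:
    """Weekly VHI values on a regular lat/lon grid.

    values
        Array of shape (rows, cols, n_years, n_weeks); NaN marks missing
        observations.  Values are on the 0-100 VHI scale.
    water_mask
        Boolean (rows, cols); True marks water pixels, which carry no VHI
        obligations.
    lat0, lon0
        Latitude/longitude of the centre of pixel (0, 0).  Rows run
        north-to-south, columns west-to-east.
    cell
        Pixel size in degrees.
    """

    values: np.ndarray
    water_mask: np.ndarray
    lat0: float
    lon0: float
    cell: float
    years: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ClimatologyError("values must be (rows, cols, years, weeks)")
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        if self.water_mask.shape != self.values.shape[:2]:
            raise ClimatologyError("water_mask shape must match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ClimatologyError("VHI values must lie in [0, 100]")
        if self.years is None:
            self.years = np.arange(self.values.shape[2])

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def pixel_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest pixel (row, col) for a lat/lon point; may be out of bounds."""
        row = int(round((self.lat0 - lat) / self.cell))
        col = int(round((lon - self.lon0) / self.cell))
        return row, col

    def latlon_of(self, row: int, col: int) -> tuple[float, float]:
        return self.lat0 - row * self.cell, self.lon0 + col * self.cell

    def in_bounds(self, row: int, col: int) -> bool:
        rows, cols = self.values.shape[:2]
        return 0 <= row < rows and 0 <= col < cols

    def to_csv(self, path) -> None:
        """Write the grid in long format (row, col, year, week, vhi).

        Water pixels and missing weeks are omitted; water membership is
        recoverable because water pixels contribute no rows.
        """
        rows, cols, n_years, n_weeks = self.values.shape
        r, c, y, w = np.nonzero(np.isfinite(self.values))
        df = pd.DataFrame(
            {
                "row": r,
                "col": c,
                "year": np.asarray(self.years)[y],
                "week": w + 1,
                "vhi": self.values[r, c, y, w],
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# lat0={self.lat0} lon0={self.lon0} cell={self.cell} "
                f"rows={rows} cols={cols} weeks={n_weeks}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "VhiGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ClimatologyError("raster CSV missing georeference header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            df = pd.read_csv(fh)
        rows, cols = int(meta["rows"]), int(meta["cols"])
        n_weeks = int(meta["weeks"])
        years = np.sort(df["year"].unique())
        year_idx = {y: i for i, y in enumerate(years)}
        values = np.full((rows, cols, len(years), n_weeks), np.nan)
        values[
            df["row"].to_numpy(),
            df["col"].to_numpy(),
            df["year"].map(year_idx).to_numpy(),
            df["week"].to_numpy() - 1,
        ] = df["vhi"].to_numpy()
        water = ~np.isfinite(values).any(axis=(2, 3))
        return cls(
            values=values,
            water_mask=water,
            lat0=float(meta["lat0"]),
            lon0=float(meta["lon0"]),
            cell=float(meta["cell"]),
            years=years,
        )


@dataclass
class SeasonalDroughtProfile:
    """Per-pixel drought frequency by photoperiodic season.

    ``frequency[season]`` is drought weeks divided by observed (non-missing)
    weeks, in [0, 1]; NaN where a pixel has no observed weeks in the season.
    """

    frequency: dict
    n_observed: dict
    water_mask: np.ndarray
    lat0: float = 0.0
    lon0: float = 0.0
    cell: float = 1.0


def drought_flags(grid: VhiGrid, threshold: float = 40.0) -> np.ndarray:
    """Flag drought weeks: 1.0 where VHI < threshold, 0.0 where not, NaN missing.

    The inequality is strict: VHI exactly at the threshold is not drought.
    """
    if not 0 <= threshold <= 100:
        raise ClimatologyError(f"threshold must be in [0, 100], got {threshold}")
    flags = np.where(grid.values < threshold, 1.0, 0.0)
    flags[~np.isfinite(grid.values)] = np.nan
    return flags


def seasonal_frequency(
    grid: VhiGrid,
    threshold: float = 40.0,
    calendar: SeasonCalendar | None = None,
) -> SeasonalDroughtProfile:
    """Per-pixel drought frequency for each season across all years.

    Frequency = drought weeks / non-missing weeks within the season's ISO
    weeks, pooled over years.  Pixels with zero observed weeks in a season
    get NaN there.
    """
    calendar = calendar or SeasonCalendar()
    flags = drought_flags(grid, threshold)
    frequency, n_observed = {}, {}
    for season in SEASONS:
        weeks = calendar.weeks_of(season)
        sel = flags[..., weeks - 1]  # (rows, cols, years, season weeks)
        observed = np.isfinite(sel).sum(axis=(2, 3))
        with np.errstate(invalid="ignore"):
            freq = np.nansum(sel, axis=(2, 3)) / np.where(observed > 0, observed, np.nan)
        freq[grid.water_mask] = np.nan
        frequency[season] = freq
        n_observed[season] = observed
    return SeasonalDroughtProfile(
        frequency=frequency,
        n_observed=n_observed,
        water_mask=grid.water_mask,
        lat0=grid.lat0,
        lon0=grid.lon0,
        cell=grid.cell,
    )


def drought_timing_index(
    profile: SeasonalDroughtProfile, epsilon: float | str = "auto"
) -> np.ndarray:
    """Drought-timing index: ln((spring + eps) / (summer + eps)) per pixel.

    Positive values mark spring-drought environments (drought frequency
    decreasing over the reproductive season), negative values summer-drought
    environments.  ``epsilon='auto'`` uses 1 / (2 * observed spring+summer
    weeks) per pixel to keep zero frequencies finite; ``epsilon=0`` is
    allowed, with the resulting +/-inf suppressed to NaN.
    """
    sp = profile.frequency["spring"]
    su = profile.frequency["summer"]
    if epsilon == "auto":
        total = profile.n_observed["spring"] + profile.n_observed["summer"]
        with np.errstate(divide="ignore"):
            eps = np.where(total > 0, 1.0 / (2.0 * np.maximum(total, 1)), np.nan)
    else:
        eps = float(epsilon)
        if eps < 0:
            raise ClimatologyError("epsilon must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.log((sp + eps) / (su + eps))
    index = np.where(np.isfinite(index), index, np.nan)
    return index


def extract_at_locations(
    layer: np.ndarray,
    ecotypes: pd.DataFrame,
    profile_or_grid,
) -> tuple[pd.Series, pd.DataFrame]:
    """Nearest-pixel values of a per-pixel layer at ecotype locations.

    ``ecotypes`` must have columns ``id``, ``lat``, ``lon``.  Ecotypes with
    missing coordinates, coordinates outside the grid, locations on water
    pixels, or no data at their pixel are excluded; the second return value
    lists each exclusion with its reason (``missing_coords``,
    ``out_of_bounds``, ``water``, ``no_data``).
    """
    geo = profile_or_grid
    values, excluded = {}, []
    for rec in ecotypes.itertuples(index=False):
        if pd.isna(rec.lat) or pd.isna(rec.lon):
            excluded.append((rec.id, "missing_coords"))
            continue
        row = int(round((geo.lat0 - rec.lat) / geo.cell))
        col = int(round((rec.lon - geo.lon0) / geo.cell))
        nrow, ncol = layer.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            excluded.append((rec.id, "out_of_bounds"))
            continue
        if geo.water_mask[row, col]:
            excluded.append((rec.id, "water"))
            continue
        val = layer[row, col]
        if not np.isfinite(val):
            excluded.append((rec.id, "no_data"))
            continue
        values[rec.id] = float(val)
    series = pd.Series(values, name="value", dtype=float)
    exclusions = pd.DataFrame(excluded, columns=["id", "reason"])
    return series, exclusions


def fit_seasonal_flowering_model(
    season_values: pd.DataFrame,
    flowering: pd.Series,
    seasons: tuple = SEASONS,
) -> pd.DataFrame:
    """Multiple linear regression of flowering time on seasonal drought frequencies.

    ``season_values`` holds one column per season of per-ecotype drought
    frequency; ``flowering`` is days to flower, aligned on the index.  Returns
    a coefficient table (coef, se, t, p) including the intercept.  Raises
    ``ClimatologyError`` naming collinear/constant seasons when the design is
    rank deficient.
    """
    import statsmodels.api as sm

    cols = [s for s in seasons if s in season_values.columns]
    data = season_values[cols].join(flowering.rename("flowering"), how="inner").dropna()
    if len(data) < 10:
        raise ClimatologyError(f"need >= 10 complete ecotypes, got {len(data)}")
    X = sm.add_constant(data[cols], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        degenerate = [c for c in cols if data[c].nunique() <= 1]
        if not degenerate:
            corr = data[cols].corr().abs()
            np.fill_diagonal(corr.values, 0)
            degenerate = sorted(set(corr.stack().idxmax()))
        raise ClimatologyError(
            f"rank-deficient design: collinear or constant season columns {degenerate}"
        )
    fit = sm.OLS(data["flowering"], X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
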