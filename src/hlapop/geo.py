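"""Diversity-vs-geography analysis: waypoint distances out of Africa,
logit-transformed PIC, outlier exclusion and two-predictor linear models.

Distances are summed great-circle (haversine, mean Earth radius 6371 km) legs
from an origin through land-migration waypoints to each population.  The five
default waypoints route journeys out of Addis Ababa through an African exit,
a Eurasian hub, Beringia and two American relays; the table is configurable
and explicitly replaceable.  The response is logit(PIC); a population is an
outlier if its logit(PIC) at ANY analysis locus is beyond mean ± 2 SD for
that locus (single pass).  Models are ordinary least squares with t-based 95%
confidence intervals; Bonferroni adjustment uses the number of models fitted
in the run as the family size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit as inverse_logit
from scipy.special import logit as _logit

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    name: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (abs(self.latitude) <= 90 and abs(self.longitude) <= 180):
            raise ValueError(
                f"invalid coordinates for {self.name}: ({self.latitude}, {self.longitude})"
            )


#: Suggested point of departure for out-of-Africa distances.
ORIGIN = GeoPoint("Addis Ababa", 9.03, 38.74)

#: Replaceable waypoint table: an Africa exit, a Eurasian hub, Beringia and
#: two American relays approximating coastal/land migration routes.
DEFAULT_WAYPOINTS = {
    "cairo": GeoPoint("Cairo", 30.05, 31.25),
    "istanbul": GeoPoint("Istanbul", 41.01, 28.98),
    "beringia": GeoPoint("Anadyr", 64.73, 177.51),
    "alaska": GeoPoint("Anchorage", 61.22, -149.90),
    "panama": GeoPoint("Panama City", 8.98, -79.52),
}

#: Which waypoints apply en route to a destination region.
DEFAULT_ROUTES: dict[str, tuple[str, ...]] = {
    "Africa": (),
    "Europe": ("cairo",),
    "Asia": ("cairo", "istanbul"),
    "Oceania": ("cairo", "istanbul"),
    "NorthAmerica": ("cairo", "istanbul", "beringia", "alaska"),
    "SouthAmerica": ("cairo", "istanbul", "beringia", "alaska", "panama"),
}


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance on a sphere of mean Earth radius."""
    lat1, lon1, lat2, lon2 = map(
        math.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def waypoint_distance(origin: GeoPoint, waypoints, dest: GeoPoint) -> float:
    """Sum of great-circle legs origin -> waypoints (in order) -> destination."""
    total = 0.0
    prev = origin
    for w in waypoints:
        total += haversine_km(prev, w)
        prev = w
    return total + haversine_km(prev, dest)


def distance_from_origin(
    dest: GeoPoint,
    region: str,
    origin: GeoPoint = ORIGIN,
    waypoints: dict[str, GeoPoint] | None = None,
    routes: dict[str, tuple[str, ...]] | None = None,
) -> float:
    """Routed out-of-Africa distance for a destination in a named region."""
    waypoints = waypoints if waypoints is not None else DEFAULT_WAYPOINTS
    routes = routes if routes is not None else DEFAULT_ROUTES
    if region not in routes:
        raise ValueError(f"no route configured for region {region!r}")
    return waypoint_distance(origin, [waypoints[w] for w in routes[region]], dest)


def logit(p: float) -> float:
    """log(p / (1 − p)); defined on the open interval (0, 1)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit requires 0 < p < 1, got {p}")
    return float(_logit(p))


def exclude_outliers(
    table: pd.DataFrame, columns, n_sd: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass ±n SD outlier partition on logit-transformed columns.

    A row is excluded if its logit value in ANY of the listed columns lies
    beyond mean ± n_sd standard deviations for that column.  Returns
    (kept, excluded).
    """
    columns = list(columns)
    if len(table) < 3:
        raise ValueError("need at least three rows to define outliers")
    logits = table[columns].apply(lambda col: col.map(logit))
    mask = pd.Series(False, index=table.index)
    for c in columns:
        mu = logits[c].mean()
        sd = logits[c].std(ddof=1)
        if sd > 0:
            mask |= (logits[c] - mu).abs() > n_sd * sd
    return table[~mask], table[mask]


@dataclass
class GLMFit:
    """An ordinary-least-squares fit with t-based intervals."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    r_squared: float
    n_used: int
    excluded: tuple[str, ...] = ()
    bonferroni_family: int | None = None

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        """Raw significance, Bonferroni-adjusted when a family size is set."""
        m = self.bonferroni_family or 1
        return self.p_values[name] <= alpha / m


class CollinearityError(ValueError):
    pass


def fit_glm(table: pd.DataFrame, response: str, predictors) -> GLMFit:
    """OLS of ``response`` on an intercept plus ``predictors``."""
    predictors = list(predictors)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError(f"n={n} too small for {len(predictors)} predictors")
    x = table[predictors].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the offending columns: those whose removal restores full rank
        offenders = [
            p
            for i, p in enumerate(predictors)
            if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
            == np.linalg.matrix_rank(design)
        ]
        raise CollinearityError(f"collinear design; offending columns: {offenders}")
    y = table[response].to_numpy(dtype=float)
    res = sm.OLS(y, design).fit()
    names = ["intercept"] + predictors
    ci = res.conf_int(alpha=0.05)
    return GLMFit(
        response=response,
        predictors=tuple(predictors),
        coefficients={nm: float(b) for nm, b in zip(names, res.params)},
        conf_int={nm: (float(lo), float(hi)) for nm, (lo, hi) in zip(names, ci)},
        p_values={nm: float(p) for nm, p in zip(names, res.pvalues)},
        r_squared=float(res.rsquared),
        n_used=n,
    )


def diversity_regressions(
    table: pd.DataFrame,
    loci=("A", "B", "DRB1"),
    richness_columns=("pathogen_richness", "viral_richness"),
    distance_column: str = "distance_km",
    exclude: bool = True,
) -> list[GLMFit]:
    """The full family of models: logit(PIC_locus) ~ distance + richness.

    One model per (locus x richness column); the Bonferroni family size is
    the number of models fitted, recorded on every fit.
    """
    pic_cols = [f"PIC_{l}" for l in loci]
    excluded_ids: tuple[str, ...] = ()
    if exclude:
        kept, dropped = exclude_outliers(table, pic_cols)
        if "population" in dropped:
            excluded_ids = tuple(dropped["population"].astype(str))
        table = kept
    work = table.copy()
    for c in pic_cols:
        work[f"logit_{c}"] = work[c].map(logit)
    fits: list[GLMFit] = []
    for locus in loci:
        for rc in richness_columns:
            fit = fit_glm(work, f"logit_PIC_{locus}", [distance_column, rc])
            fit.excluded = excluded_ids
            fits.append(fit)
    for f in fits:
        f.bonferroni_family = len(fits)
    return fits
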