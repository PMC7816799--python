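"""Processing of multi-day tag records into an activity model.

Input is one row per tag-hour: deployment id, hour start (UTC), longitude,
latitude, lunge count and mean lunge depth (empty when no lunges).  From
these the module derives:

* hourly behavioral states — not feeding (NF) when no lunge was detected,
  otherwise shallow (SF) or deep feeding (DF) by the posterior component of
  the hour's mean lunge depth under a two-component Gaussian mixture;
* gaps between foraging bouts — maximal runs of NF hours strictly between
  feeding hours (leading/trailing non-foraging time excluded);
* a first-order Markov chain over the three states, whose stationary
  distribution is the daily activity budget;
* daily ranging areas — the Minimum Convex Polygon (convex hull) of each
  complete feeding day's hourly fixes, in km^2.

The resulting :class:`ActivityModel` is what the disturbance simulation
samples days, rates and gaps from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.mixture import GaussianMixture

STATES = ("NF", "SF", "DF")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

#: fallback state-typical lunge rates (lunges/h), used for days that lack a
#: state and for depth-missing classification priors
DEFAULT_MEDIAN_RATES = {"SF": 15.0, "DF": 19.0}

EARTH_RADIUS_KM = 6371.0

logger = logging.getLogger(__name__)

__all__ = [
    "DepthMixture",
    "DeploymentDay",
    "ActivityModel",
    "read_hourly_csv",
    "fit_depth_mixture",
    "assign_states",
    "extract_bout_gaps",
    "fit_markov_chain",
    "stationary_distribution",
    "mcp_area",
    "build_days",
    "MCPError",
    "MarkovFitError",
]


class MCPError(ValueError):
    """Raised when a day's fixes do not span a polygon (too few or collinear)."""


class MarkovFitError(ValueError):
    """Raised when a state was never visited so its transition row is undefined."""


# ---------------------------------------------------------------------------
# depth mixture


@dataclass(frozen=True)
class DepthMixture:
    """Two-component Gaussian mixture of hourly mean lunge depths (m).

    Components are ordered by increasing mean: the shallow component first,
    the deep component second.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.means[0] < self.means[1]:
            raise ValueError("components must be ordered by ascending mean")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component SDs must be positive")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if any(not 0 < w < 1 for w in self.weights):
            raise ValueError("weights must lie in (0, 1)")

    def posterior_deep(self, depth_m) -> np.ndarray:
        """Posterior probability that the depth belongs to the deep component."""
        depth = np.asarray(depth_m, dtype=float)
        log_d = np.empty(depth.shape + (2,))
        for i in range(2):
            log_d[..., i] = (
                np.log(self.weights[i])
                - np.log(self.sds[i])
                - 0.5 * ((depth - self.means[i]) / self.sds[i]) ** 2
            )
        m = log_d.max(axis=-1)
        p = np.exp(log_d - m[..., None])
        return p[..., 1] / p.sum(axis=-1)

    def classify(self, depth_m) -> np.ndarray:
        """Hard assignment: 'DF' where the deep posterior wins, else 'SF'."""
        deep = self.posterior_deep(depth_m) >= 0.5
        return np.where(deep, "DF", "SF")


def fit_depth_mixture(depths, seed: int = 0, tol: float = 1e-6,
                      max_iter: int = 500) -> DepthMixture:
    """EM fit of a two-component univariate Gaussian mixture to lunge depths."""
    d = np.asarray(depths, dtype=float).reshape(-1, 1)
    if d.shape[0] < 10:
        raise ValueError(f"need at least 10 feeding-hour depths, got {d.shape[0]}")
    if np.std(d) == 0:
        raise ValueError("all depths identical: degenerate mixture fit")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", tol=tol, max_iter=max_iter,
        n_init=3, random_state=seed,
    ).fit(d)
    if not gm.converged_:
        raise RuntimeError(
            f"mixture EM did not converge within {max_iter} iterations (tol={tol})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(2))
    weights = gm.weights_
    order = np.argsort(means)
    return DepthMixture(
        means=tuple(float(means[i]) for i in order),
        sds=tuple(float(sds[i]) for i in order),
        weights=tuple(float(weights[i]) for i in order),
    )


# ---------------------------------------------------------------------------
# hourly records and state assignment

REQUIRED_COLUMNS = ["deployment_id", "hour_start", "lon", "lat", "n_lunges"]


def read_hourly_csv(path) -> pd.DataFrame:
    """Read the hourly tag CSV, validating columns and within-tag ordering."""
    df = pd.read_csv(path, parse_dates=["hour_start"])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hourly CSV missing columns: {missing}")
    if "mean_lunge_depth" not in df.columns:
        df["mean_lunge_depth"] = np.nan
    if (df["n_lunges"] < 0).any():
        raise ValueError("negative lunge counts in input")
    for dep, g in df.groupby("deployment_id"):
        if not g["hour_start"].is_monotonic_increasing:
            raise ValueError(f"hours not increasing within deployment {dep!r}")
        if g["hour_start"].duplicated().any():
            raise ValueError(f"duplicate hours within deployment {dep!r}")
    return df


def assign_states(
    df: pd.DataFrame,
    mixture: DepthMixture,
    missing_depth_policy: str = "prior",
    median_rates: dict | None = None,
) -> pd.DataFrame:
    """Assign an hourly behavioral state to each record.

    NF whenever no lunge was detected; otherwise SF or DF by the maximum
    posterior component of the hour's mean lunge depth under the mixture.
    Feeding hours with a missing depth follow ``missing_depth_policy``:
    ``"prior"`` (default) classifies by a lunge-rate-weighted prior over the
    two feeding states given the hour's lunge count, ``"error"`` raises.
    """
    rates = dict(DEFAULT_MEDIAN_RATES, **(median_rates or {}))
    out = df.copy()
    out["state"] = "NF"
    feeding = out["n_lunges"] > 0
    depth = out["mean_lunge_depth"]
    ok = feeding & depth.notna()
    if ok.any():
        out.loc[ok, "state"] = mixture.classify(depth[ok].to_numpy())
    bad = feeding & depth.isna()
    if bad.any():
        if missing_depth_policy == "error":
            raise ValueError(f"{int(bad.sum())} feeding hours lack a mean depth")
        if missing_depth_policy != "prior":
            raise ValueError(f"unknown missing-depth policy {missing_depth_policy!r}")
        # Poisson likelihood of the hour's lunge count under each state's
        # typical rate, weighted by the mixture weights
        n = out.loc[bad, "n_lunges"].to_numpy(dtype=float)
        score_sf = np.log(mixture.weights[0]) + n * np.log(rates["SF"]) - rates["SF"]
        score_df = np.log(mixture.weights[1]) + n * np.log(rates["DF"]) - rates["DF"]
        out.loc[bad, "state"] = np.where(score_df > score_sf, "DF", "SF")
        logger.warning(
            "%d feeding hours lacked a mean lunge depth; classified by "
            "lunge-rate-weighted prior", int(bad.sum()),
        )
    return out


# ---------------------------------------------------------------------------
# bout gaps


def _contiguous_segments(hours: pd.Series) -> list[np.ndarray]:
    """Split positional indices into runs of strictly consecutive hours."""
    idx = np.arange(len(hours))
    if len(hours) == 0:
        return []
    dt = hours.diff().dt.total_seconds().to_numpy()
    breaks = np.flatnonzero(dt[1:] != 3600.0) + 1
    return np.split(idx, breaks)


def extract_bout_gaps(df: pd.DataFrame) -> np.ndarray:
    """Durations (h) of breaks >= 1 h between foraging bouts, per deployment.

    A gap is a maximal run of NF hours strictly between feeding hours within
    a contiguous stretch of records; non-foraging time at the start or end of
    a deployment (or around a recording gap) is excluded.
    """
    gaps: list[int] = []
    for _, g in df.groupby("deployment_id"):
        g = g.sort_values("hour_start")
        states = g["state"].to_numpy()
        for seg in _contiguous_segments(g["hour_start"]):
            s = states[seg]
            feeding = np.flatnonzero(s != "NF")
            if feeding.size < 2:
                continue
            inner = s[feeding[0]: feeding[-1] + 1]
            run = 0
            for st in inner:
                if st == "NF":
                    run += 1
                elif run:
                    gaps.append(run)
                    run = 0
    return np.asarray(gaps, dtype=int)


# ---------------------------------------------------------------------------
# Markov chain


def fit_markov_chain(sequences, states=None) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood transition matrix and stationary distribution.

    ``sequences`` is an iterable of state sequences over contiguous hours
    (no transition is counted across a recording gap).  ``states`` fixes the
    state space (default: the states observed, in canonical NF/SF/DF order).
    Returns the row-normalized transition-count matrix P and the stationary
    distribution pi solving pi P = pi, sum(pi) = 1.
    """
    seqs = [list(s) for s in sequences]
    if states is None:
        seen = {x for s in seqs for x in s}
        states = [s for s in STATES if s in seen] or sorted(seen)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    counts = np.zeros((n, n))
    for seq in seqs:
        s = [index[x] for x in seq]
        for a, b in zip(s, s[1:]):
            counts[a, b] += 1
    row_sums = counts.sum(axis=1)
    unvisited = [states[i] for i in range(n) if row_sums[i] == 0]
    if unvisited:
        raise MarkovFitError(
            f"states never left in the data, transition rows undefined: {unvisited}"
        )
    P = counts / row_sums[:, None]
    return P, stationary_distribution(P)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix via a linear solve."""
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    # solve pi (P - I) = 0 with the normalization sum(pi) = 1
    A = np.vstack([(P.T - np.eye(n)), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# daily ranging area


def mcp_area(lon, lat) -> float:
    """Minimum Convex Polygon area (km^2) of one day's fixes.

    Fixes are projected to a local planar system by an equirectangular
    projection about the day's mean latitude (adequate at daily ranging
    scales of tens of km), then the convex-hull area is returned.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    pts = np.unique(np.column_stack([lon, lat]), axis=0)
    if pts.shape[0] < 3:
        raise MCPError(f"need >= 3 distinct fixes, got {pts.shape[0]}")
    # midpoint of the latitude span: invariant to ordering and to duplicated
    # or interior fixes, unlike the mean
    lat0 = math.radians(0.5 * (lat.min() + lat.max()))
    x = EARTH_RADIUS_KM * math.cos(lat0) * np.radians(pts[:, 0])
    y = EARTH_RADIUS_KM * np.radians(pts[:, 1])
    try:
        hull = ConvexHull(np.column_stack([x, y]))
    except QhullError as e:
        raise MCPError(f"fixes are collinear or degenerate: {e}") from None
    return float(hull.volume)  # 2-D "volume" is the area


# ---------------------------------------------------------------------------
# deployment days and the activity model


@dataclass
class DeploymentDay:
    """One complete tag day (24 hourly records) with some feeding."""

    deployment_id: str
    date: object
    hourly_states: list
    hourly_lunges: np.ndarray
    area_km2: float
    rate_DF: float
    rate_SF: float
    month: int = 0
    mean_lat: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.hourly_states) != 24:
            raise ValueError("a deployment day needs exactly 24 hourly states")
        if not (np.asarray(self.hourly_lunges) > 0).any():
            raise ValueError("a qualifying day must contain some feeding")
        if not self.area_km2 > 0:
            raise ValueError("daily area must be positive")

    @property
    def state_fractions(self) -> np.ndarray:
        """Empirical state distribution over the day's 24 hours (NF, SF, DF)."""
        s = np.asarray(self.hourly_states)
        return np.array([(s == st).mean() for st in STATES])

    def rate(self, state: str) -> float:
        return {"DF": self.rate_DF, "SF": self.rate_SF}[state]


def build_days(
    df: pd.DataFrame,
    median_rates: dict | None = None,
    tz_offset_hours: int = 0,
) -> list[DeploymentDay]:
    """Assemble qualifying deployment days from state-assigned records.

    A day qualifies when it has 24 consecutive hourly records in the chosen
    local calendar day, at least one hour with lunges, and a well-defined
    MCP area.  Day-specific lunge rates are the day's mean lunges/h within
    each feeding state, falling back to dataset-typical medians when the day
    lacks that state.
    """
    rates_fb = dict(DEFAULT_MEDIAN_RATES, **(median_rates or {}))
    days: list[DeploymentDay] = []
    local = df["hour_start"] + pd.Timedelta(hours=tz_offset_hours)
    for (dep, date), g in df.assign(_date=local.dt.date).groupby(
        ["deployment_id", "_date"]
    ):
        if len(g) != 24:
            continue
        g = g.sort_values("hour_start")
        if not (g["n_lunges"] > 0).any():
            continue
        try:
            area = mcp_area(g["lon"].to_numpy(), g["lat"].to_numpy())
        except MCPError as e:
            logger.info("excluding %s %s: %s", dep, date, e)
            continue
        states = g["state"].to_numpy()
        lunges = g["n_lunges"].to_numpy(dtype=float)
        rates = {}
        for st in ("DF", "SF"):
            mask = states == st
            rates[st] = float(lunges[mask].mean()) if mask.any() else rates_fb[st]
        days.append(
            DeploymentDay(
                deployment_id=str(dep),
                date=date,
                hourly_states=list(states),
                hourly_lunges=lunges,
                area_km2=area,
                rate_DF=rates["DF"],
                rate_SF=rates["SF"],
                month=pd.Timestamp(date).month,
                mean_lat=float(g["lat"].mean()),
            )
        )
    return days


@dataclass
class ActivityModel:
    """Fitted movement/behavior summaries the disturbance simulation draws on."""

    P: np.ndarray
    pi: np.ndarray
    days: list
    gaps_h: np.ndarray
    median_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_MEDIAN_RATES)
    )
    mixture: DepthMixture | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(np.abs(self.P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition-matrix rows must sum to 1")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("stationary distribution must be a probability vector")
        if np.max(np.abs(self.pi @ self.P - self.pi)) > 1e-10:
            raise ValueError("pi is not stationary for P")
        if len(self.days) == 0:
            raise ValueError("activity model has no qualifying days")
        if len(self.gaps_h) == 0:
            raise ValueError("activity model has no foraging-bout gaps")

    @property
    def areas_km2(self) -> np.ndarray:
        return np.array([d.area_km2 for d in self.days])

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        mixture: DepthMixture | None = None,
        seed: int = 0,
        tz_offset_hours: int = 0,
        states: str = "infer",
    ) -> "ActivityModel":
        """Full tag-processing pipeline: mixture, states, chain, days, gaps.

        If no fitted depth mixture is supplied, one is fitted to the feeding
        hours' mean lunge depths.  ``states="given"`` trusts an existing
        ``state`` column instead of classifying depths (useful for data whose
        true states are known, e.g. synthetic benchmarks).
        """
        if states not in ("infer", "given"):
            raise ValueError("states must be 'infer' or 'given'")
        if mixture is None and states == "infer":
            depths = df.loc[
                (df["n_lunges"] > 0) & df["mean_lunge_depth"].notna(),
                "mean_lunge_depth",
            ]
            mixture = fit_depth_mixture(depths.to_numpy(), seed=seed)
        if states == "given":
            if "state" not in df.columns:
                raise ValueError("states='given' requires a state column")
            sdf = df
        else:
            sdf = assign_states(df, mixture)
        # dataset-wide typical (median) hourly lunge rates per feeding state
        med = {}
        for st in ("SF", "DF"):
            vals = sdf.loc[sdf["state"] == st, "n_lunges"]
            med[st] = float(vals.median()) if len(vals) else DEFAULT_MEDIAN_RATES[st]
        seqs = [
            sdf.loc[seg_idx, "state"].tolist()
            for _, g in sdf.groupby("deployment_id")
            for seg_idx in (
                g.sort_values("hour_start").index[seg]
                for seg in _contiguous_segments(
                    g.sort_values("hour_start")["hour_start"]
                )
            )
        ]
        P, pi = fit_markov_chain(seqs, states=list(STATES))
        days = build_days(sdf, median_rates=med, tz_offset_hours=tz_offset_hours)
        gaps = extract_bout_gaps(sdf)
        return cls(
            P=P, pi=pi, days=days, gaps_h=gaps, median_rates=med, mixture=mixture
        )

    def subset(
        self,
        lat_range: tuple[float, float] | None = None,
        months=None,
        df: pd.DataFrame | None = None,
    ) -> "ActivityModel":
        """Re-fit on a spatial or temporal subset of the underlying records.

        Requires the original state-assigned records ``df`` (or raw records;
        states are re-derived with the shared mixture).  The depth mixture
        and the state-typical lunge rates are shared with the pooled fit.
        """
        if df is None:
            raise ValueError("subsetting requires the hourly records dataframe")
        sub = df
        if lat_range is not None:
            lo, hi = lat_range
            sub = sub[(sub["lat"] >= lo) & (sub["lat"] <= hi)]
        if months is not None:
            months = {months} if np.isscalar(months) else set(months)
            sub = sub[sub["hour_start"].dt.month.isin(months)]
        if len(sub) == 0:
            raise ValueError("subset selects no records")
        model = ActivityModel.fit(
            sub,
            mixture=self.mixture,
            states="given" if self.mixture is None else "infer",
        )
        model.median_rates = dict(self.median_rates)
        for d in model.days:  # lunge rates are shared across subsets
            for st in ("DF", "SF"):
                mask = np.asarray(d.hourly_states) == st
                if not mask.any():
                    setattr(d, f"rate_{st}", self.median_rates[st])
        return model

    def summary(self) -> dict:
        """JSON-serializable summary of the fitted model."""
        out = {
            "transition_matrix": self.P.tolist(),
            "stationary": self.pi.tolist(),
            "states": list(STATES),
            "n_days": len(self.days),
            "n_gaps": int(len(self.gaps_h)),
            "gap_mean_h": float(np.mean(self.gaps_h)),
            "gap_sd_h": float(np.std(self.gaps_h, ddof=1)) if len(self.gaps_h) > 1 else 0.0,
            "area_mean_km2": float(self.areas_km2.mean()),
            "area_range_km2": [float(self.areas_km2.min()), float(self.areas_km2.max())],
            "median_rates": self.median_rates,
        }
        if self.mixture is not None:
            out["depth_mixture"] = {
                "means_m": list(self.mixture.means),
                "sds_m": list(self.mixture.sds),
                "weights": list(self.mixture.weights),
            }
        return out
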