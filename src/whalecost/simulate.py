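"""Daily Monte-Carlo simulation of disturbance from a localized noise source.

Each replicate samples one observed-style deployment day, places a circle of
that day's ranging area uniformly in a 100 km x 100 km region containing the
source, and partitions the day into short intervals (6 min for the discrete
exposure-response functions, 30 min for the continuous ones).  Intervals are
assigned a distance band around the source in proportion to the geometric
overlap of the daily circle with each band, and a behavioral state from the
day's own activity budget.  While the source is active, each exposed interval
responds with the probability given by the exposure-response function for its
received-level (or distance) bin and behavioral context; a response costs the
response interval plus a randomly sampled gap between foraging bouts (the
time to find a new krill patch), during which the animal cannot respond
again.  Lost feeding hours convert to lost lunges via the day's state-
specific lunge rates and then to lost energy via per-lunge krill draws;
undisturbed intake, expenditure and net intake are computed from the same
interval grid and the same density draws, so a replicate with no response
reproduces the undisturbed budget exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bioenergetics import KrillDistribution, WhaleParams
from .dose_response import (
    CONTEXTS,
    ContinuousER,
    DiscreteER,
    exposure_context,
    load_continuous_er_config,
    load_discrete_er_config,
)
from .geometry import bin_occupancy, place_daily_area, range_for_level, received_level
from .tags import STATES, ActivityModel

__all__ = [
    "SourceScenario",
    "DayResult",
    "simulate_day",
    "run_scenarios",
    "summarize",
    "load_er_functions",
]

POSITIONS = ("center", "corner", "midside")


@dataclass(frozen=True)
class SourceScenario:
    """A fixed disturbance source within the square study region."""

    sl_db: float
    duration_min: float
    position: object = "center"  # named position or explicit (x, y) in km
    square_km: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.duration_min <= 1440:
            raise ValueError("duration must lie in [0, 1440] minutes")
        if isinstance(self.position, str) and self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS} or (x, y)")
        if not isinstance(self.position, str):
            x, y = self.position
            if not (0 <= x <= self.square_km and 0 <= y <= self.square_km):
                raise ValueError("explicit source position must lie in the square")

    @property
    def source_xy(self) -> tuple[float, float]:
        s = self.square_km
        if isinstance(self.position, str):
            return {
                "center": (s / 2, s / 2),
                "corner": (0.0, 0.0),
                "midside": (s / 2, 0.0),
            }[self.position]
        return tuple(float(v) for v in self.position)


@dataclass
class _BinTable:
    """Distance bands around the source with their response-probability hooks."""

    edges_km: np.ndarray          # outer edges, strictly increasing
    near: np.ndarray              # bool per bin: entirely within 1 km
    rl_upper: np.ndarray          # conservative (upper-extreme) RL per bin, dB
    dose_upper: np.ndarray        # dose key per bin (RL dB or outer km)


def _build_bins(scenario: SourceScenario, er) -> _BinTable:
    """Distance bands induced by the ER function's doses of interest."""
    sl = scenario.sl_db
    if er.kind == "discrete":
        rls = [rl for rl in er.anchor_rls if rl <= sl]
        edges = sorted({range_for_level(sl, rl) / 1000.0 for rl in rls} | {1.0})
    elif er.dose_kind == "SPL":
        floor = er.floor_db if er.floor_db is not None else min(er.bin_upper)
        thresholds = np.arange(floor, sl, 10.0)
        edges = sorted({range_for_level(sl, rl) / 1000.0 for rl in thresholds})
        if not edges:  # SL at or below the floor: no exposed area at all
            edges = [range_for_level(sl, sl) / 1000.0]
    else:  # distance dose: fixed 1-km bins out to 5 km, then open-ended
        edges = [1.0, 2.0, 3.0, 4.0, 5.0, math.inf]
    edges = np.asarray(edges, dtype=float)
    inner = np.concatenate(([0.0], edges[:-1]))
    rl_upper = np.array([received_level(sl, r * 1000.0) for r in inner])
    near = edges <= 1.0 + 1e-12
    dose = edges if (er.kind == "continuous" and er.dose_kind == "range") else rl_upper
    return _BinTable(edges_km=edges, near=near, rl_upper=rl_upper, dose_upper=dose)


@dataclass
class DayResult:
    """Losses and energy budget of one replicate day."""

    sl_db: float
    duration_min: float
    position: object
    length_m: float
    krill: str
    er: str
    day_id: str
    area_km2: float
    lost_DF_h: float
    lost_SF_h: float
    lost_NF_h: float
    lost_lunges: float
    gross_MJ: float
    lost_MJ: float
    expended_MJ: float
    expended_disturbed_MJ: float
    net_undisturbed_MJ: float
    net_disturbed_MJ: float
    proportional_loss: float


def _weighted_head_sum(values: np.ndarray, count: float) -> float:
    """Sum of the first ``count`` entries, fractional tail weighted."""
    whole = int(count)
    s = float(values[:whole].sum())
    frac = count - whole
    if frac > 0 and whole < len(values):
        s += frac * float(values[whole])
    return s


def simulate_day(
    activity: ActivityModel,
    scenario: SourceScenario,
    er,
    whale: WhaleParams,
    krill: KrillDistribution,
    rng: np.random.Generator,
    reproductive_stage: str = "none",
    redraw_continuous: bool = False,
) -> DayResult:
    """Simulate one day of exposure and return its losses and energy budget.

    ``redraw_continuous`` switches the continuous-ER probability from one
    truncated-normal draw per bin per day (default) to an independent draw
    per interval.
    """
    if er.kind not in ("discrete", "continuous"):
        raise ValueError(f"unknown ER kind {er.kind!r}")
    days = activity.days
    day = days[int(rng.integers(len(days)))]

    # --- geometry: place the daily circle, split it into distance bands
    placed = place_daily_area(day.area_km2, scenario.square_km, rng)
    table = _build_bins(scenario, er)
    occ = bin_occupancy(placed, scenario.source_xy, table.edges_km)
    n_bins = len(occ.proportions)

    # --- interval grid
    delta = er.interval_min
    n_int = int(1440 // delta)
    p_assign = np.concatenate([occ.proportions, [occ.remainder]])
    p_assign = np.clip(p_assign, 0, None)
    p_assign /= p_assign.sum()
    bin_idx = rng.choice(n_bins + 1, size=n_int, p=p_assign)  # n_bins = unexposed
    state_idx = rng.choice(3, size=n_int, p=day.state_fractions)

    # --- source activity window
    start = rng.uniform(0.0, 1440.0 - scenario.duration_min)
    mid = (np.arange(n_int) + 0.5) * delta
    active = (
        (mid >= start) & (mid < start + scenario.duration_min)
        if scenario.duration_min > 0
        else np.zeros(n_int, dtype=bool)
    )

    # --- response probabilities per bin (and context, for the discrete case)
    if er.kind == "discrete":
        prob = np.zeros((n_bins, len(CONTEXTS)))
        ctx_index = {c: j for j, c in enumerate(CONTEXTS)}
        outer_rl = [
            received_level(scenario.sl_db, e * 1000.0) if math.isfinite(e)
            else -math.inf
            for e in table.edges_km
        ]
        for i in range(n_bins):
            rl_hi = table.rl_upper[i]  # RL at the bin's inner edge
            rl_lo = min(outer_rl[i], rl_hi)
            for c in CONTEXTS:
                prob[i, ctx_index[c]] = er.probability(c, rl_lo, rl_hi)
    else:
        if redraw_continuous:
            prob = None
        else:
            prob = np.array(
                [er.probability(table.dose_upper[i], rng) for i in range(n_bins)]
            )

    # --- sequential response / lost-time bookkeeping
    lost = np.zeros(n_int, dtype=bool)
    gaps = activity.gaps_h
    k = 0
    while k < n_int:
        if active[k] and not lost[k] and bin_idx[k] < n_bins:
            st = STATES[state_idx[k]]
            if er.kind == "discrete":
                ctx = exposure_context(st, bool(table.near[bin_idx[k]]))
                p = prob[bin_idx[k], ctx_index[ctx]]
            elif redraw_continuous:
                p = er.probability(table.dose_upper[bin_idx[k]], rng)
            else:
                p = prob[bin_idx[k]]
            if p > 0 and rng.random() < p:
                gap_h = float(gaps[int(rng.integers(len(gaps)))])
                n_lost = int(math.ceil(gap_h * 60.0 / delta))
                lost[k: k + 1 + n_lost] = True
                k += 1 + n_lost
                continue
        k += 1

    # --- tallies
    dt_h = delta / 60.0
    hours = {s: float((state_idx == i).sum()) * dt_h for i, s in enumerate(STATES)}
    lost_h = {
        s: float(((state_idx == i) & lost).sum()) * dt_h
        for i, s in enumerate(STATES)
    }

    # --- energy: shared per-lunge density draws so lost <= gross exactly
    per = (
        whale.engulfment_volume
        * whale.krill_energy_density
        * whale.assimilation_efficiency
    )
    gross = 0.0
    lost_mj = 0.0
    lost_lunges = 0.0
    for st in ("DF", "SF"):
        n_gross = hours[st] * day.rate(st)
        n_lost = lost_h[st] * day.rate(st)
        lost_lunges += n_lost
        if n_gross <= 0:
            continue
        dens = krill.draw(int(math.ceil(n_gross)) + 1, rng)
        gross += per * _weighted_head_sum(dens, n_gross)
        lost_mj += per * _weighted_head_sum(dens, n_lost)

    c = {s: whale.cost_rate(s) for s in STATES}
    expended = sum(hours[s] * c[s] for s in STATES)
    # lost feeding time is re-costed at the not-feeding rate
    saved = sum(lost_h[s] * (c[s] - c["NF"]) for s in ("SF", "DF"))
    expended_dist = expended - saved

    maintenance = 24.0 * c["NF"]
    if reproductive_stage != "none":
        from .bioenergetics import reproduction_cost

        maintenance += reproduction_cost(reproductive_stage, whale)
    foraging_cost = sum(hours[s] * (c[s] - c["NF"]) for s in ("SF", "DF"))
    foraging_cost_dist = foraging_cost - saved
    net_und = max(gross - foraging_cost, 0.0) - maintenance
    net_dist = max((gross - lost_mj) - foraging_cost_dist, 0.0) - maintenance

    return DayResult(
        sl_db=scenario.sl_db,
        duration_min=scenario.duration_min,
        position=scenario.position if isinstance(scenario.position, str) else tuple(scenario.position),
        length_m=whale.length_m,
        krill=krill.label,
        er=getattr(er, "variant", er.kind),
        day_id=f"{day.deployment_id}/{day.date}",
        area_km2=day.area_km2,
        lost_DF_h=lost_h["DF"],
        lost_SF_h=lost_h["SF"],
        lost_NF_h=lost_h["NF"],
        lost_lunges=lost_lunges,
        gross_MJ=gross,
        lost_MJ=lost_mj,
        expended_MJ=expended,
        expended_disturbed_MJ=expended_dist,
        net_undisturbed_MJ=net_und,
        net_disturbed_MJ=net_dist,
        proportional_loss=0.0 if gross <= 0 else min(max(lost_mj / gross, 0.0), 1.0),
    )


def load_er_functions(discrete_path=None, continuous_path=None) -> dict:
    """All six ER functions keyed by id (discrete:<variant>, continuous:<dose>)."""
    out = {}
    for variant, er in load_discrete_er_config(discrete_path).items():
        out[f"discrete:{variant}"] = er
    for kind, er in load_continuous_er_config(continuous_path).items():
        out[f"continuous:{kind}"] = er
    return out


#: factor levels of the full published scenario grid
FULL_FACTORIAL = {
    "sl_db": [235.0, 210.0, 200.0, 180.0, 160.0],
    "duration_min": [6.0, 30.0, 60.0, 120.0, 360.0, 720.0, 1440.0],
    "position": ["center", "corner", "midside"],
    "length_m": [22.0, 25.0, 27.0],
    "krill": ["lower", "upper"],
    "er": [
        "discrete:moderate-median",
        "discrete:moderate-upperCI",
        "discrete:high-median",
        "discrete:high-upperCI",
        "continuous:SPL",
        "continuous:range",
    ],
}


def run_scenarios(
    activity: ActivityModel,
    factors: dict,
    reps: int,
    seed: int,
    er_functions: dict | None = None,
    bio_config: dict | None = None,
    square_km: float = 100.0,
) -> pd.DataFrame:
    """Run the factorial scenario grid; one row per replicate per scenario.

    ``factors`` maps factor names (sl_db, duration_min, position, length_m,
    krill, er) to lists of levels; missing factors default to the full
    published grid.  Reproducible given the master seed: every scenario gets
    an independent child random stream.
    """
    from .bioenergetics import krill_from_config, load_bioenergetics_config

    er_functions = er_functions or load_er_functions()
    bio = bio_config or load_bioenergetics_config()

    levels = {k: list(factors.get(k, FULL_FACTORIAL[k])) for k in FULL_FACTORIAL}
    for er_id in levels["er"]:
        if er_id not in er_functions:
            raise ValueError(f"unknown ER function id {er_id!r}")
    for pos in levels["position"]:
        if isinstance(pos, str) and pos not in POSITIONS:
            raise ValueError(f"unknown source position {pos!r}")

    combos = list(itertools.product(*(levels[k] for k in FULL_FACTORIAL)))
    children = np.random.SeedSequence(seed).spawn(len(combos))
    rows = []
    for combo, child in zip(combos, children):
        sl, dur, pos, length, krill_label, er_id = combo
        scenario = SourceScenario(
            sl_db=sl, duration_min=dur, position=pos, square_km=square_km
        )
        whale = WhaleParams.from_config(bio, length_m=length)
        krill = krill_from_config(bio, krill_label)
        er = er_functions[er_id]
        rng = np.random.default_rng(child)
        for _ in range(int(reps)):
            rows.append(
                asdict(
                    simulate_day(activity, scenario, er, whale, krill, rng)
                )
            )
    return pd.DataFrame(rows)


SCENARIO_KEYS = ["sl_db", "duration_min", "position", "length_m", "krill", "er"]
LOSS_METRICS = ["lost_lunges", "lost_MJ", "proportional_loss"]
QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario summary: moments, quantiles and outcome-class fractions."""
    if len(results) == 0:
        raise ValueError("no results to summarize")
    df = results.copy()
    df["lost_feeding_h"] = df["lost_DF_h"] + df["lost_SF_h"]
    metrics = LOSS_METRICS + ["lost_feeding_h", "net_disturbed_MJ"]
    recs = []
    for key, g in df.groupby(SCENARIO_KEYS, sort=False):
        rec = dict(zip(SCENARIO_KEYS, key))
        rec["n"] = len(g)
        for m in metrics:
            v = g[m].to_numpy()
            rec[f"{m}_mean"] = float(v.mean())
            for q in QUANTILES:
                rec[f"{m}_q{q}"] = float(np.quantile(v, q))
        unchanged = g["net_disturbed_MJ"] == g["net_undisturbed_MJ"]
        rec["frac_no_change"] = float(unchanged.mean())
        rec["frac_net_decreased"] = float(
            (g["net_disturbed_MJ"] < g["net_undisturbed_MJ"]).mean()
        )
        rec["frac_sign_flip"] = float(
            ((g["net_undisturbed_MJ"] > 0) & (g["net_disturbed_MJ"] < 0)).mean()
        )
        recs.append(rec)
    return pd.DataFrame(recs)
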