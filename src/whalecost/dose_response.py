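"""Exposure-response (ER) functions: probability of a behavioral response.

Two families are supported:

* **Discrete step functions** anchored at response probabilities
  (1, 10, 50, 90, 99)%.  Three exposure contexts of decreasing sensitivity
  are distinguished: deep-feeding near the source (<= 1 km), deep-feeding far
  or any other state near, and other states far.  The 1% anchor sits at the
  ambient-noise level in the mid-frequency sonar band, the 99% anchor at the
  temporary-threshold-shift (TTS) onset level, and the 90% anchor 10 dB below
  TTS onset; the 10% and 50% anchors are context- and variant-specific.
  Four variants are shipped (median / upper CI of the underlying survival
  analysis, for moderate / high response severity).

* **Continuous curves** summarised per dose bin (10-dB received-level bins,
  or distance bins 0-1, ..., 4-5, >5 km) by a posterior mean and standard
  deviation; evaluating a bin draws one response probability from a normal
  truncated to [0, 1].

Anchor and bin values are configuration data, not estimated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import special

__all__ = [
    "STATES",
    "CONTEXTS",
    "exposure_context",
    "DiscreteER",
    "ContinuousER",
    "build_discrete_er",
    "load_discrete_er_config",
    "load_continuous_er_config",
    "truncated_normal_probability",
]

STATES = ("NF", "SF", "DF")

#: ER contexts ordered by decreasing sensitivity.
CONTEXTS = ("DF_near", "DF_far_other_near", "other_far")

ANCHOR_PROBS = (0.01, 0.10, 0.50, 0.90, 0.99)


def exposure_context(state: str, near: bool) -> str:
    """Map a behavioral state and proximity class to an ER context.

    Deep feeding near the source is the most sensitive context; deep feeding
    far from it is treated as comparable to any other state near it; other
    states far from the source are the least sensitive.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if state == "DF":
        return "DF_near" if near else "DF_far_other_near"
    return "DF_far_other_near" if near else "other_far"


@dataclass(frozen=True)
class DiscreteER:
    """One variant of the discrete step ER function (all three contexts).

    ``anchors[context]`` is an ordered tuple of (RL dB, probability) pairs,
    strictly increasing in both coordinates, running from the ambient floor
    (p = 0.01) to TTS onset (p = 0.99).
    """

    variant: str
    anchors: dict[str, tuple[tuple[float, float], ...]]
    ambient_floor_db: float
    tts_onset_db: float

    kind: str = field(default="discrete", init=False)
    #: response opportunity spacing the functions were derived for
    interval_min: int = field(default=6, init=False)

    def __post_init__(self) -> None:
        for ctx in CONTEXTS:
            if ctx not in self.anchors:
                raise ValueError(f"variant {self.variant!r}: missing context {ctx!r}")
            pts = self.anchors[ctx]
            rls = [p[0] for p in pts]
            probs = [p[1] for p in pts]
            if tuple(probs) != ANCHOR_PROBS:
                raise ValueError(
                    f"variant {self.variant!r}, context {ctx!r}: anchor "
                    f"probabilities must be {ANCHOR_PROBS}, got {tuple(probs)}"
                )
            if any(b <= a for a, b in zip(rls, rls[1:])):
                raise ValueError(
                    f"variant {self.variant!r}, context {ctx!r}: anchor RLs "
                    f"must be strictly increasing, got {rls}"
                )

    @property
    def anchor_rls(self) -> np.ndarray:
        """Sorted union of anchor RLs over all contexts (the RLs of interest)."""
        vals = sorted({rl for pts in self.anchors.values() for rl, _ in pts})
        return np.asarray(vals)

    def step(self, context: str, rl_db: float) -> float:
        """Step-function value: probability of the highest anchor at or below rl_db.

        Below the ambient floor no response is simulated (returns 0).
        """
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        p = 0.0
        for rl, prob in self.anchors[context]:
            if rl_db >= rl - 1e-9:
                p = prob
            else:
                break
        return p

    def probability(self, context: str, rl_lo: float, rl_hi: float) -> float:
        """Response probability for an RL bin [rl_lo, rl_hi).

        The conservative convention applies: the whole bin responds with the
        probability at its upper extreme.
        """
        if rl_hi < rl_lo:
            raise ValueError("rl_hi must be >= rl_lo")
        return self.step(context, rl_hi)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "ambient_floor_db": self.ambient_floor_db,
            "tts_onset_db": self.tts_onset_db,
            "anchors": {
                ctx: [[float(rl), float(p)] for rl, p in pts]
                for ctx, pts in self.anchors.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteER":
        return cls(
            variant=d["variant"],
            ambient_floor_db=float(d["ambient_floor_db"]),
            tts_onset_db=float(d["tts_onset_db"]),
            anchors={
                ctx: tuple((float(rl), float(p)) for rl, p in pts)
                for ctx, pts in d["anchors"].items()
            },
        )


def truncated_normal_probability(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    """One probability draw from Normal(mean, sd) truncated to [0, 1].

    A zero standard deviation returns the mean exactly (clipped to [0, 1]).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return float(min(max(mean, 0.0), 1.0))
    # inverse-CDF sampling on the truncated standard normal
    lo = special.ndtr((0.0 - mean) / sd)
    hi = special.ndtr((1.0 - mean) / sd)
    u = lo + rng.uniform() * (hi - lo)
    z = special.ndtri(min(max(u, 1e-15), 1 - 1e-15))
    return float(min(max(mean + sd * z, 0.0), 1.0))


@dataclass(frozen=True)
class ContinuousER:
    """Continuous ER curve summarised per dose bin by posterior mean and sd.

    ``dose_kind`` is ``"SPL"`` (received level, 10-dB bins keyed by their
    upper edge in dB) or ``"range"`` (distance from the source, bins keyed by
    their outer edge in km, the last of which may be infinite).
    """

    dose_kind: str
    bin_upper: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    #: ambient floor for SPL curves: RLs below it are not evaluated at all
    floor_db: float | None = None

    kind: str = field(default="continuous", init=False)
    interval_min: int = field(default=30, init=False)

    def __post_init__(self) -> None:
        if self.dose_kind not in ("SPL", "range"):
            raise ValueError(f"dose_kind must be 'SPL' or 'range', got {self.dose_kind!r}")
        if not (len(self.bin_upper) == len(self.means) == len(self.sds)):
            raise ValueError("bin_upper, means and sds must have equal length")
        if any(b <= a for a, b in zip(self.bin_upper, self.bin_upper[1:])):
            raise ValueError("bin upper edges must be strictly increasing")
        if any(not (0.0 <= m <= 1.0) for m in self.means):
            raise ValueError("bin means must lie in [0, 1]")
        if any(s < 0 for s in self.sds):
            raise ValueError("bin sds must be non-negative")

    def bin_index(self, dose_upper: float) -> int:
        """Index of the bin whose upper edge matches/covers ``dose_upper``.

        Doses above the last finite edge clamp to the last bin.
        """
        for i, hi in enumerate(self.bin_upper):
            if dose_upper <= hi + 1e-9:
                return i
        return len(self.bin_upper) - 1

    def probability(self, dose_upper: float, rng: np.random.Generator) -> float:
        """Draw a response probability for the bin with this upper-extreme dose."""
        i = self.bin_index(dose_upper)
        return truncated_normal_probability(self.means[i], self.sds[i], rng)

    @property
    def variant(self) -> str:
        return f"continuous-{self.dose_kind}"


def build_discrete_er(config: dict) -> dict[str, DiscreteER]:
    """Build the four discrete ER variants from a configuration mapping.

    The configuration supplies the ambient floor, the TTS-onset level, and
    per variant/context the RLs of the 10% and 50% anchors; the 1, 90 and
    99% anchors are derived (floor, TTS-10 dB, TTS).
    """
    floor = float(config["ambient_floor_db"])
    tts = float(config["tts_onset_db"])
    if tts <= floor:
        raise ValueError("TTS onset must exceed the ambient floor")
    p90 = tts - 10.0
    out: dict[str, DiscreteER] = {}
    for variant, contexts in config["variants"].items():
        anchors: dict[str, tuple[tuple[float, float], ...]] = {}
        for ctx in CONTEXTS:
            if ctx not in contexts:
                raise ValueError(f"variant {variant!r}: missing context {ctx!r}")
            spec = contexts[ctx]
            rl10, rl50 = float(spec["p10"]), float(spec["p50"])
            anchors[ctx] = (
                (floor, 0.01),
                (rl10, 0.10),
                (rl50, 0.50),
                (p90, 0.90),
                (tts, 0.99),
            )
        out[variant] = DiscreteER(
            variant=variant, anchors=anchors, ambient_floor_db=floor, tts_onset_db=tts
        )
    return out


def _read_yaml(path_or_none) -> dict:
    if path_or_none is None:
        ref = resources.files("whalecost").joinpath("config")
        raise ValueError(f"no config path given (package fixtures live in {ref})")
    return yaml.safe_load(Path(path_or_none).read_text())


def _packaged(name: str) -> dict:
    text = resources.files("whalecost").joinpath("config", name).read_text()
    return yaml.safe_load(text)


def load_discrete_er_config(path=None) -> dict[str, DiscreteER]:
    """Load discrete ER variants from YAML (packaged fixture if no path)."""
    cfg = _packaged("er_discrete.yaml") if path is None else _read_yaml(path)
    return build_discrete_er(cfg)


def load_continuous_er_config(path=None) -> dict[str, ContinuousER]:
    """Load the two continuous ER curves from YAML (packaged fixture if no path)."""
    cfg = _packaged("er_continuous.yaml") if path is None else _read_yaml(path)
    out: dict[str, ContinuousER] = {}
    for kind in ("SPL", "range"):
        block = cfg[kind.lower()] if kind == "SPL" else cfg["range"]
        uppers, means, sds = [], [], []
        for b in block["bins"]:
            hi = b["upper"]
            uppers.append(math.inf if hi in ("inf", ".inf", None) else float(hi))
            means.append(float(b["mean"]))
            sds.append(float(b["sd"]))
        out[kind] = ContinuousER(
            dose_kind=kind,
            bin_upper=tuple(uppers),
            means=tuple(means),
            sds=tuple(sds),
            floor_db=float(block["floor_db"]) if "floor_db" in block else None,
        )
    return out
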