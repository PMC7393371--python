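"""Synthetic data with the statistical structure the analyses assume.

Three generators emulate the three experimental datasets:

* :func:`gen_pair_logs` — frame-scored event logs for isolated mating pairs.
  Copulation latency, duration and interval are log-normal per species
  (*M. janickei* copulations about five times longer and less frequent than
  *M. lignano*); sucks follow copulations with a pairing-type-dependent
  probability and log-normal delay/duration; heterospecific pairs mix the
  two species' location parameters and inflate the spread, and only rarely
  produce (hybrid) offspring — never from both partners of one pair.

* :func:`gen_drops` — copulation sequences in 2+2 mate-choice drops.  Free
  pairs carry competing exponential clocks; the hazard of pair (i, j) is
  proportional to ``propensity_i * propensity_j``, times the conspecific
  preference multiplier for same-species pairs, times a homotypic factor 2
  that makes the no-preference copulation-type rates exactly the
  Hardy-Weinberg-style participation null (p^2, 2pq, q^2) with
  p = propensity_L / (propensity_L + propensity_J) — the random-mating
  expectation the analysis tests against (0.25 : 0.50 : 0.25 for equal
  propensities).  Copulating individuals are unavailable until their
  copulation ends.

* :func:`gen_stylets` — 60-landmark stylet configurations: a packaged
  hand-drawn mean polyline per species (straight-tipped vs hook-tipped;
  these are synthetic fixtures, not tracings), a hybrid mean interpolated
  between the aligned species means, and isotropic Gaussian landmark noise.

One global seed fans out to independent substreams per generator, so any
dataset can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .events import CopulationEvent, DropRecord, PairRecord, SuckEvent
from .morpho import (
    LandmarkConfiguration,
    N_LANDMARKS,
    centroid_size,
    gpa_align,
)

WINDOW_S = 7200  # 2 h at 1 frame/s
MIN_COPULATION_S = 5

_SUBSTREAM = {"pairs": 0, "drops": 1, "stylets": 2}


@dataclass
class LogNormalSpec:
    """A log-normal duration in seconds: exp(mu) is the median."""

    median_s: float
    sd_log: float

    def draw(self, rng: np.random.Generator, size=None):
        return np.exp(rng.normal(math.log(self.median_s), self.sd_log, size))


@dataclass
class SpeciesBehaviour:
    """Per-species behavioural distributions (all times in seconds).

    ``sd_log`` values correspond, through CV = 100*sqrt(exp(sd^2)-1), to the
    stereotypy each behaviour shows in conspecific pairings.
    """

    latency: LogNormalSpec
    duration: LogNormalSpec
    interval: LogNormalSpec
    suck_delay: LogNormalSpec
    suck_duration: LogNormalSpec
    suck_prob: float


def _default_lignano() -> SpeciesBehaviour:
    return SpeciesBehaviour(
        latency=LogNormalSpec(600.0, 0.745),
        duration=LogNormalSpec(100.0, 0.265),
        interval=LogNormalSpec(300.0, 0.833),
        suck_delay=LogNormalSpec(2.0, 1.0),
        suck_duration=LogNormalSpec(10.0, 0.208),
        suck_prob=0.9,
    )


def _default_janickei() -> SpeciesBehaviour:
    return SpeciesBehaviour(
        latency=LogNormalSpec(900.0, 0.980),
        duration=LogNormalSpec(480.0, 0.376),
        interval=LogNormalSpec(600.0, 0.624),
        suck_delay=LogNormalSpec(60.0, 0.668),
        suck_duration=LogNormalSpec(15.0, 0.159),
        suck_prob=0.7,
    )


@dataclass
class FecunditySpec:
    """Offspring (14-day counts) per pairing type.

    Conspecific pairs have one maternal individual isolated; heterospecific
    pairs both, with success rare and never in both partners at once.
    """

    conspecific_mean: float = 15.0
    hetero_success_prob: float = 0.2
    hetero_mean_given_success: float = 3.0


@dataclass
class ShapeSpec:
    """Synthetic stylet morphology."""

    hybrid_weight: float = 0.5  # 0 = janickei, 1 = lignano
    noise_sd: float = 0.8  # image units; stylet length is ~60 units
    hybrid_size_multiplier: float = 1.15
    n_lignano: int = 25
    n_hybrid: int = 29
    n_janickei: int = 18

    def __post_init__(self) -> None:
        if not 0.0 <= self.hybrid_weight <= 1.0:
            raise ValueError("hybrid_weight must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulationParams:
    """Full parameterisation of the synthetic generators."""

    seed: int = 0
    n_pairs: int = 57  # per pairing type
    lignano: SpeciesBehaviour = field(default_factory=_default_lignano)
    janickei: SpeciesBehaviour = field(default_factory=_default_janickei)
    hetero_sd_inflation: float = 1.4
    hetero_suck_prob: float = 0.3
    propensity_L: float = 3.0  # sqrt(copulations per hour) scale
    propensity_J: float = 1.5
    preference: float = 1.0  # conspecific multiplier; 1 = no preference
    #: block copulating individuals until their copulation ends (physical
    #: default).  Blocking induces positive homotypic correlation in the
    #: copulation sequence even without preference (while an LL pair mates
    #: only the JJ pair is free, and vice versa), so the statistical null of
    #: independent participations is exactly true only with blocking off.
    busy_blocking: bool = True
    n_drops: int = 68
    n_drops_injured: int = 5
    n_drops_dim: int = 4
    window_s: int = WINDOW_S
    fecundity: FecunditySpec = field(default_factory=FecunditySpec)
    shape: ShapeSpec = field(default_factory=ShapeSpec)

    def __post_init__(self) -> None:
        if self.preference <= 0:
            raise ValueError("preference must be > 0")
        if min(self.propensity_L, self.propensity_J) < 0:
            raise ValueError("propensities must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAM))
        return np.random.default_rng(children[_SUBSTREAM[stream]])

    def hetero_behaviour(self) -> SpeciesBehaviour:
        """Mixture behaviour for heterospecific pairs.

        Location parameters are the log-scale average of the two species;
        spreads are inflated, emulating the high heterospecific CVs (the two
        partners disagree about timing, so realised behaviour is noisier).
        """

        def mix(a: LogNormalSpec, b: LogNormalSpec) -> LogNormalSpec:
            return LogNormalSpec(
                median_s=math.exp(
                    (math.log(a.median_s) + math.log(b.median_s)) / 2
                ),
                sd_log=self.hetero_sd_inflation
                * math.sqrt((a.sd_log**2 + b.sd_log**2) / 2),
            )

        l, j = self.lignano, self.janickei
        return SpeciesBehaviour(
            latency=mix(l.latency, j.latency),
            duration=mix(l.duration, j.duration),
            interval=mix(l.interval, j.interval),
            suck_delay=mix(l.suck_delay, j.suck_delay),
            suck_duration=mix(l.suck_duration, j.suck_duration),
            suck_prob=self.hetero_suck_prob,
        )

    def to_yaml(self, path) -> None:
        with open(str(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationParams":
        def ln(d):
            return LogNormalSpec(**d)

        def beh(d):
            d = dict(d)
            for key in ("latency", "duration", "interval", "suck_delay",
                        "suck_duration"):
                d[key] = ln(d[key])
            return SpeciesBehaviour(**d)

        kwargs = dict(raw)
        if "lignano" in kwargs:
            kwargs["lignano"] = beh(kwargs["lignano"])
        if "janickei" in kwargs:
            kwargs["janickei"] = beh(kwargs["janickei"])
        if "fecundity" in kwargs:
            kwargs["fecundity"] = FecunditySpec(**kwargs["fecundity"])
        if "shape" in kwargs:
            kwargs["shape"] = ShapeSpec(**kwargs["shape"])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# pair logs


def _behaviour_for(params: SimulationParams, pairing_type: str
                   ) -> SpeciesBehaviour:
    return {
        "lignano": params.lignano,
        "janickei": params.janickei,
        "hetero": params.hetero_behaviour(),
    }[pairing_type]


def _draw_offspring(
    params: SimulationParams, pairing_type: str, rng: np.random.Generator
) -> tuple[int, ...]:
    fec = params.fecundity
    if pairing_type == "hetero":
        # both partners isolated; at most one of them productive
        if rng.random() < fec.hetero_success_prob:
            n = 1 + rng.poisson(fec.hetero_mean_given_success)
            which = rng.integers(2)
            return (int(n), 0) if which == 0 else (0, int(n))
        return (0, 0)
    return (int(rng.poisson(fec.conspecific_mean)),)


def gen_pair_logs(
    params: SimulationParams,
    pairing_type: str,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PairRecord]:
    """Generate scored event logs for ``n`` pairs of one pairing type."""
    if n is None:
        n = params.n_pairs
    if rng is None:
        rng = params.rng("pairs")
    beh = _behaviour_for(params, pairing_type)
    window = params.window_s
    records = []
    for idx in range(n):
        pid = f"{pairing_type}_{idx:03d}"
        cops: list[CopulationEvent] = []
        sucks: list[SuckEvent] = []
        t = float(beh.latency.draw(rng))
        while True:
            start = int(t)
            if start + MIN_COPULATION_S > window:
                break
            dur = max(MIN_COPULATION_S, int(round(beh.duration.draw(rng))))
            end = min(start + dur, window)
            if end - start < MIN_COPULATION_S:
                break
            cops.append(
                CopulationEvent(
                    pair_or_drop_id=pid, actor_a="a", actor_b="b",
                    start_s=start, end_s=end, copulation_type="NA",
                )
            )
            gap = float(beh.interval.draw(rng))
            next_start = end + gap
            # maybe a suck in the gap after this copulation
            if rng.random() < beh.suck_prob:
                s_start = end + int(round(beh.suck_delay.draw(rng)))
                s_dur = max(1, int(round(beh.suck_duration.draw(rng))))
                s_end = min(s_start + s_dur, int(next_start), window)
                if s_start < s_end:
                    sucks.append(
                        SuckEvent(
                            pair_or_drop_id=pid,
                            start_s=s_start, end_s=s_end,
                            preceding_copulation_index=len(cops) - 1,
                        )
                    )
            t = next_start
        records.append(
            PairRecord(
                pair_id=pid,
                pairing_type=pairing_type,
                copulations=cops,
                sucks=sucks,
                offspring_counts=_draw_offspring(params, pairing_type, rng),
                window_s=window,
            )
        )
    return records


# --------------------------------------------------------------------------
# mate-choice drops


def _drop_pairs(params: SimulationParams):
    """The six candidate pairs of a 2+2 drop with their hazards (per s).

    Hazard of pair (i, j) = prop_i * prop_j * preference^[conspecific]
    * 2^[conspecific] / 3600.  The homotypic factor 2 makes the
    no-preference copulation-type rates equal the Hardy-Weinberg
    participation null (p^2, 2pq, q^2).
    """
    pl, pj, pref = params.propensity_L, params.propensity_J, params.preference
    pairs = [
        ((0, 1), "LL", 2.0 * pl * pl * pref),
        ((2, 3), "JJ", 2.0 * pj * pj * pref),
        ((0, 2), "LJ", pl * pj),
        ((0, 3), "LJ", pl * pj),
        ((1, 2), "LJ", pl * pj),
        ((1, 3), "LJ", pl * pj),
    ]
    return [(members, ctype, h / 3600.0) for members, ctype, h in pairs]


_DURATION_BY_TYPE = {"LL": "lignano", "JJ": "janickei", "LJ": "hetero"}


def gen_one_drop(
    params: SimulationParams,
    drop_id: str,
    rng: np.random.Generator,
    max_copulations: Optional[int] = None,
) -> DropRecord:
    """Simulate one drop's copulation sequence over the window.

    Competing exponential clocks over the currently free pairs; copulating
    individuals are blocked until their copulation ends.  ``max_copulations``
    stops early (used when only the first copulation is of interest).
    """
    pairs = _drop_pairs(params)
    busy_until = [0.0, 0.0, 0.0, 0.0]
    durations = {
        ctype: _behaviour_for(params, sp).duration
        for ctype, sp in _DURATION_BY_TYPE.items()
    }
    events: list[CopulationEvent] = []
    t = 0.0
    window = float(params.window_s)
    while t < window:
        avail = [
            (members, ctype, h)
            for members, ctype, h in pairs
            if h > 0 and busy_until[members[0]] <= t and busy_until[members[1]] <= t
        ]
        if not avail:
            pending = [b for b in busy_until if b > t]
            if not pending:
                break
            t = min(pending)
            continue
        total = sum(h for _, _, h in avail)
        wait = rng.exponential(1.0 / total)
        release = min((b for b in busy_until if b > t), default=math.inf)
        if t + wait >= release:
            t = release  # availability changes; exponential clocks are memoryless
            continue
        t = t + wait
        if t >= window:
            break
        u = rng.random() * total
        acc = 0.0
        for members, ctype, h in avail:
            acc += h
            if u <= acc:
                break
        dur = max(
            float(MIN_COPULATION_S), float(durations[ctype].draw(rng))
        )
        start = int(t)
        end = min(int(t + dur), params.window_s)
        if end - start >= MIN_COPULATION_S:
            a, b = members
            names = ["L1", "L2", "J1", "J2"]
            events.append(
                CopulationEvent(
                    pair_or_drop_id=drop_id,
                    actor_a=names[a], actor_b=names[b],
                    start_s=start, end_s=end, copulation_type=ctype,
                )
            )
        if params.busy_blocking:
            busy_until[members[0]] = busy_until[members[1]] = t + dur
        if max_copulations is not None and len(events) >= max_copulations:
            break
        t = t  # clocks restart; memoryless
    return DropRecord(drop_id=drop_id, copulations=events,
                      window_s=params.window_s)


def gen_drops(
    params: SimulationParams,
    n_drops: Optional[int] = None,
    max_copulations: Optional[int] = None,
) -> list[DropRecord]:
    """Simulate the mate-choice drops, flagging the excluded replicates.

    The first ``n_drops_injured`` drops are flagged injured and the next
    ``n_drops_dim`` dim_lighting (emulating one badly lit chamber), leaving
    ``n_drops - n_drops_injured - n_drops_dim`` analysable replicates.
    """
    from dataclasses import replace

    if n_drops is None:
        n_drops = params.n_drops
    rng = params.rng("drops")
    drops = []
    for i in range(n_drops):
        d = gen_one_drop(params, f"drop_{i:04d}", rng, max_copulations)
        if i < params.n_drops_injured:
            d = replace(d, excluded=True, exclusion_reason="injured")
        elif i < params.n_drops_injured + params.n_drops_dim:
            d = replace(d, excluded=True, exclusion_reason="dim_lighting")
        drops.append(d)
    return drops


# --------------------------------------------------------------------------
# stylet shapes


def _polyline_stylet(total_curvature: float, hook_power: float,
                     length: float, base_width: float) -> np.ndarray:
    """Hand-drawn 60-point stylet outline (two 30-point curves).

    A tapering tube around a centerline whose heading turns by
    ``total_curvature`` radians, concentrated toward the tip for large
    ``hook_power`` (hooked tip) and spread out for small (gentle arc).
    Landmarks 1-30 run tip-to-base along the far side, 31-60 tip-to-base
    along the near side; ordinals 1, 30, 31, 60 are the fixed tip/base
    points.  Synthetic fixture geometry, not a tracing of any specimen.
    """
    k = 30
    s = np.linspace(0.0, 1.0, 200)
    heading = total_curvature * s**hook_power
    step = length / (len(s) - 1)
    xs = np.concatenate([[0.0], np.cumsum(np.cos(heading[:-1]) * step)])
    ys = np.concatenate([[0.0], np.cumsum(np.sin(heading[:-1]) * step)])
    center = np.column_stack([xs, ys])
    # resample at 30 equally spaced arc-length stations, base (s=0) to tip
    stations = np.linspace(0.0, 1.0, k)
    si = np.linspace(0.0, 1.0, len(s))
    cx = np.interp(stations, si, center[:, 0])
    cy = np.interp(stations, si, center[:, 1])
    hx = np.interp(stations, si, np.cos(heading))
    hy = np.interp(stations, si, np.sin(heading))
    normal = np.column_stack([-hy, hx])
    width = base_width * (1.0 - stations) ** 0.8 + 0.6
    c = np.column_stack([cx, cy])
    far = c + normal * (width / 2)[:, None]
    near = c - normal * (width / 2)[:, None]
    # ordinals 1..30: far side, tip->base; 31..60: near side, tip->base
    return np.vstack([far[::-1], near[::-1]])


def species_mean_shapes() -> dict[str, np.ndarray]:
    """Packaged mean stylet polylines (synthetic, qualitatively species-like).

    *M. lignano*: gently curved, nearly straight tip.  *M. janickei*:
    drastically hooked tip.  Units are arbitrary image units with stylet
    length around 60.
    """
    return {
        "lignano": _polyline_stylet(
            total_curvature=0.7, hook_power=1.2, length=60.0, base_width=10.0
        ),
        "janickei": _polyline_stylet(
            total_curvature=3.2, hook_power=3.0, length=65.0, base_width=12.0
        ),
    }


def hybrid_mean_shape(
    lignano: np.ndarray,
    janickei: np.ndarray,
    weight: float = 0.5,
    size_multiplier: float = 1.15,
) -> np.ndarray:
    """Hybrid mean: interpolation of the GPA-aligned species means.

    ``weight`` is the lignano share; the result is scaled to
    ``size_multiplier`` times the species' mean centroid size (the observed
    hybrids were larger than either parent, a pattern without a mechanistic
    model — this is purely a knob).
    """
    aligned = gpa_align([lignano, janickei]).aligned
    mean_unit = weight * aligned[0] + (1.0 - weight) * aligned[1]
    mean_unit -= mean_unit.mean(axis=0)
    target_cs = size_multiplier * (
        centroid_size(lignano) + centroid_size(janickei)
    ) / 2.0
    return mean_unit / centroid_size(mean_unit) * target_cs


def gen_stylets(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> list[LandmarkConfiguration]:
    """Generate landmark configurations for the three specimen groups."""
    if rng is None:
        rng = params.rng("stylets")
    spec = params.shape
    means = species_mean_shapes()
    means["hybrid"] = hybrid_mean_shape(
        means["lignano"], means["janickei"],
        weight=spec.hybrid_weight,
        size_multiplier=spec.hybrid_size_multiplier,
    )
    sizes = {
        "lignano": spec.n_lignano,
        "hybrid": spec.n_hybrid,
        "janickei": spec.n_janickei,
    }
    configs = []
    for group in ("lignano", "hybrid", "janickei"):
        for i in range(sizes[group]):
            pts = means[group] + rng.normal(
                0.0, spec.noise_sd, size=(N_LANDMARKS, 2)
            )
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{group}_{i:03d}", group=group, points=pts
                )
            )
    return configs


def drop_counts_table(drops: Sequence[DropRecord]):
    """Convenience: DropCounts for every included drop."""
    from .events import filter_drops
    from .matechoice import count_copulation_types

    return [count_copulation_types(d) for d in filter_drops(list(drops))]
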