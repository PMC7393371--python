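"""Behavioural trait extraction and group comparisons.

Six traits are derived per mating pair from the scored event log, using only
the first five copulations and the sucks that follow them:

* **copulation latency** — time (s) from the start of observation to the
  start of the first copulation;
* **mean copulation duration** — mean of ``end - start`` over the scored
  copulations;
* **mean copulation interval** — mean gap between the end of one copulation
  and the start of the next (undefined with fewer than two copulations);
* **mean time until suck** — mean delay from the end of a copulation to the
  start of the suck attributed to it;
* **mean suck duration**;
* **number of sucks** — defined only for pairs with at least five
  copulations, so pairs are compared over the same observation effort.

A suck is attributed to a copulation if it is the first suck starting after
that copulation's end and before the next copulation's start; sucks after the
fifth copulation are ignored.  Pairs with zero copulations yield an
all-undefined row flagged for exclusion.  Fecundity (14-day offspring count)
is averaged over the maternal individuals that were isolated.

Stereotypy of each behaviour is summarised by a coefficient of variation:
``CV = 100 * sqrt(exp(sd^2) - 1)`` on natural-log-transformed data for the
timed traits, and the plain ``100 * sd/mean`` on raw data for suck counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .events import PairRecord

MAX_SCORED_COPULATIONS = 5

TRAIT_COLUMNS = [
    "copulation_latency_s",
    "mean_copulation_duration_s",
    "mean_copulation_interval_s",
    "mean_time_until_suck_s",
    "mean_suck_duration_s",
    "n_sucks",
    "offspring_number",
]

#: Traits compared parametrically (ANOVA + Tukey on log data); the rest use
#: Kruskal-Wallis + Mann-Whitney with Bonferroni correction.
PARAMETRIC_TRAITS = frozenset(
    [
        "copulation_latency_s",
        "mean_copulation_duration_s",
        "mean_copulation_interval_s",
        "mean_time_until_suck_s",
        "mean_suck_duration_s",
    ]
)

#: time-until-suck can be exactly 0 (suck starting the frame the copulation
#: ends), so 1 is added before the log transform.
LOG_OFFSET_TRAITS = frozenset(["mean_time_until_suck_s"])


def attribute_sucks(pair: PairRecord) -> list[Optional[int]]:
    """For each scored copulation, index of its attributed suck (or None).

    Only the first ``MAX_SCORED_COPULATIONS`` copulations are considered.
    """
    cops = pair.copulations[:MAX_SCORED_COPULATIONS]
    out: list[Optional[int]] = []
    for i, cop in enumerate(cops):
        nxt = (
            pair.copulations[i + 1].start_s
            if i + 1 < len(pair.copulations)
            else math.inf
        )
        chosen = None
        for j, suck in enumerate(pair.sucks):
            if cop.end_s <= suck.start_s < nxt:
                chosen = j
                break
        out.append(chosen)
    return out


def extract_traits(pair: PairRecord) -> dict:
    """Derive the per-pair trait row (undefined traits become NaN)."""
    cops = pair.copulations[:MAX_SCORED_COPULATIONS]
    row: dict = {
        "pair_id": pair.pair_id,
        "pairing_type": pair.pairing_type,
        "n_copulations": len(cops),
        "excluded_no_copulations": len(cops) == 0,
    }
    for col in TRAIT_COLUMNS:
        row[col] = np.nan

    if pair.offspring_counts is not None:
        row["offspring_number"] = float(np.mean(pair.offspring_counts))

    if not cops:
        return row

    row["copulation_latency_s"] = float(cops[0].start_s)
    row["mean_copulation_duration_s"] = float(
        np.mean([c.duration_s for c in cops])
    )
    if len(cops) >= 2:
        gaps = [b.start_s - a.end_s for a, b in zip(cops, cops[1:])]
        row["mean_copulation_interval_s"] = float(np.mean(gaps))

    links = attribute_sucks(pair)
    delays, durations = [], []
    for i, j in enumerate(links):
        if j is None:
            continue
        suck = pair.sucks[j]
        delays.append(suck.start_s - cops[i].end_s)
        durations.append(suck.duration_s)
    if delays:
        row["mean_time_until_suck_s"] = float(np.mean(delays))
        row["mean_suck_duration_s"] = float(np.mean(durations))
    if len(cops) >= MAX_SCORED_COPULATIONS:
        row["n_sucks"] = float(sum(1 for j in links if j is not None))
    return row


def traits_table(pairs: Sequence[PairRecord]) -> pd.DataFrame:
    """Trait rows for a set of pairs, one row per pair."""
    return pd.DataFrame([extract_traits(p) for p in pairs])


def cv_lognormal(sd_log: float) -> float:
    """CV (%) of a log-normal variable from the sd of its natural log.

    ``CV = 100 * sqrt(exp(sd^2) - 1)``; exact for log-normal data, which is
    why timed behavioural traits are summarised this way after log transform.
    """
    if sd_log < 0:
        raise ValueError(f"sd of log data must be >= 0, got {sd_log}")
    return 100.0 * math.sqrt(math.expm1(sd_log**2))


def cv_raw(values: Sequence[float]) -> float:
    """Plain CV (%) = 100 * sample sd / mean, for count-like traits."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"cv_raw requires a positive mean, got {mean}")
    if len(arr) < 2:
        raise ValueError("cv_raw requires at least two values")
    return 100.0 * arr.std(ddof=1) / mean


def summarize_cv(table: pd.DataFrame) -> pd.DataFrame:
    """Per pairing-type CV summary of every trait (Table-1 style).

    Timed traits use the log-normal CV on natural-log data (with the +1
    offset for time-until-suck); suck counts use the raw CV.
    """
    rows = []
    for ptype, sub in table.groupby("pairing_type", sort=False):
        for trait in TRAIT_COLUMNS:
            if trait == "offspring_number":
                continue
            vals = sub[trait].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            if trait in PARAMETRIC_TRAITS:
                offset = 1.0 if trait in LOG_OFFSET_TRAITS else 0.0
                logged = np.log(vals + offset)
                cv = cv_lognormal(float(np.std(logged, ddof=1)))
                mean_log = float(np.mean(logged))
                sd_log = float(np.std(logged, ddof=1))
            else:
                if vals.mean() <= 0:
                    continue  # CV undefined (e.g. no sucks observed at all)
                cv = cv_raw(vals)
                mean_log, sd_log = float(np.mean(vals)), float(
                    np.std(vals, ddof=1)
                )
            rows.append(
                {
                    "pairing_type": ptype,
                    "trait": trait,
                    "n": len(vals),
                    "mean_log": mean_log,
                    "sd_log": sd_log,
                    "cv_percent": cv,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Group comparisons


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    p_value: float
    p_corrected: float
    significant: bool


@dataclass
class GroupComparison:
    """Omnibus test plus all pairwise post-hoc results for one trait."""

    trait: str
    family: str
    statistic: float  # F for ANOVA, chi-square approximation for KW
    df: tuple
    p_value: float
    group_means: dict
    pairwise: list[PairwiseResult]
    letters: dict

    def summary(self) -> str:
        stat_name = "F" if self.family == "parametric" else "KW chi2"
        lines = [
            f"{self.trait} ({self.family}): {stat_name}={self.statistic:.3f}, "
            f"df={self.df}, p={self.p_value:.4g}"
        ]
        for pw in self.pairwise:
            lines.append(
                f"  {pw.group_a} vs {pw.group_b}: p={pw.p_value:.4g} "
                f"(corrected {pw.p_corrected:.4g})"
                f"{' *' if pw.significant else ''}"
            )
        lines.append(
            "  letters: "
            + ", ".join(f"{g}={l}" for g, l in self.letters.items())
        )
        return "\n".join(lines)


def letter_groupings(
    groups: Sequence[str],
    means: dict,
    significant: dict,
) -> dict:
    """Compact letter display: groups sharing a letter do not differ.

    ``significant[(a, b)]`` is True when a and b differ at the chosen alpha.
    Letters are assigned to maximal cliques of the "not significantly
    different" graph, ordered by group mean.
    """
    order = sorted(groups, key=lambda g: means[g])

    def nonsig(a: str, b: str) -> bool:
        return not significant.get((a, b), significant.get((b, a), False))

    cliques = []
    for r in range(len(order), 0, -1):
        for combo in itertools.combinations(order, r):
            if all(nonsig(a, b) for a, b in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in order}
    for letter, clique in zip("abcdefghij", cliques):
        for g in clique:
            letters[g] += letter
    return letters


def compare_groups(
    trait: str,
    table: pd.DataFrame,
    family: Literal["parametric", "nonparametric"] | None = None,
    alpha: float = 0.05,
    group_col: str = "pairing_type",
    log_transform: Optional[bool] = None,
) -> GroupComparison:
    """Omnibus + post-hoc comparison of one trait across pairing types.

    Parametric behavioural traits are natural-log transformed first
    (time-until-suck gets +1 before the log); ``log_transform=False`` keeps
    the raw scale, as used for shape variables.  The omnibus test is a
    one-way ANOVA followed by Tukey HSD.  Nonparametric traits use
    Kruskal-Wallis followed by pairwise Mann-Whitney tests with Bonferroni
    correction (factor = number of pairs).
    """
    if family is None:
        family = "parametric" if trait in PARAMETRIC_TRAITS else "nonparametric"
    if log_transform is None:
        log_transform = trait in PARAMETRIC_TRAITS
    sub = table[[group_col, trait]].dropna()
    groups = list(dict.fromkeys(sub[group_col]))
    samples = {g: sub.loc[sub[group_col] == g, trait].to_numpy(float)
               for g in groups}
    for g, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(
                f"group {g!r} has n={len(vals)} < 2 for trait {trait!r}; "
                "cannot test"
            )
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups for trait {trait!r}")

    if family == "parametric" and log_transform:
        offset = 1.0 if trait in LOG_OFFSET_TRAITS else 0.0
        samples = {g: np.log(v + offset) for g, v in samples.items()}

    means = {g: float(np.mean(v)) for g, v in samples.items()}
    k = len(groups)
    n_total = sum(len(v) for v in samples.values())
    pairs = list(itertools.combinations(groups, 2))

    pairwise: list[PairwiseResult] = []
    if family == "parametric":
        f_stat, p = stats.f_oneway(*samples.values())
        df = (k - 1, n_total - k)
        flat = np.concatenate([samples[g] for g in groups])
        labels = np.concatenate([[g] * len(samples[g]) for g in groups])
        tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        for (a, b), padj, rej in zip(
            itertools.combinations(sorted(groups), 2),
            tukey.pvalues,
            tukey.reject,
        ):
            pairwise.append(
                PairwiseResult(a, b, float(padj), float(padj), bool(rej))
            )
        statistic, p_value = float(f_stat), float(p)
    else:
        h_stat, p = stats.kruskal(*samples.values())
        df = (k - 1,)
        n_tests = len(pairs)
        for a, b in pairs:
            _, p_mw = stats.mannwhitneyu(
                samples[a], samples[b], alternative="two-sided"
            )
            p_corr = min(1.0, float(p_mw) * n_tests)
            pairwise.append(
                PairwiseResult(a, b, float(p_mw), p_corr, p_corr < alpha)
            )
        statistic, p_value = float(h_stat), float(p)

    sig = {(pw.group_a, pw.group_b): pw.significant for pw in pairwise}
    letters = letter_groupings(groups, means, sig)
    return GroupComparison(
        trait=trait,
        family=family,
        statistic=statistic,
        df=df,
        p_value=p_value,
        group_means=means,
        pairwise=pairwise,
        letters=letters,
    )
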