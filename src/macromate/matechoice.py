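"""Mate-choice statistics for the 2+2 drop experiment.

Each drop holds two *M. lignano* and two *M. janickei* worms, so of the six
possible pairs one is an LL pair, four are LJ pairs and one is a JJ pair.
Under random mating the first copulation of a drop is therefore expected at
LL : LJ : JJ = 0.25 : 0.50 : 0.25, and the same proportions serve as the
initial null for copulation-type frequencies within drops.

The module implements:

* the first-copulation Pearson chi-square test against 0.25:0.50:0.25;
* repeated G-tests of goodness-of-fit across drops, with the heterogeneity
  G computed as the independence-table G (drops x 3 categories) and the
  additivity identity total G = pooled G + heterogeneity G available as a
  cross-check;
* per-drop mating rates p = (2 m_LL + m_LJ) / (2 m_T) and
  q = (2 m_JJ + m_LJ) / (2 m_T), the fraction of copulation participations
  attributable to each species;
* the mating-rate-adjusted null e_LL = p^2 m_T, e_LJ = 2pq m_T,
  e_JJ = q^2 m_T (a Hardy-Weinberg-style expectation given the observed
  rates) and its per-drop chi-square test.

A drop that fits the rate-adjusted null but not the 1:2:1 null shows
assortative mating explained by a mating-rate difference between the
species, not by an explicit partner preference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .events import DropRecord

logger = logging.getLogger(__name__)

#: Random-mating null for 2+2 drops: 1 LL pair, 4 LJ pairs, 1 JJ pair.
RANDOM_MATING_PROPS = (0.25, 0.50, 0.25)

COPULATION_CATEGORIES = ("LL", "LJ", "JJ")


@dataclass(frozen=True)
class DropCounts:
    """Observed copulation-type counts for one drop."""

    drop_id: str
    m_LL: int
    m_LJ: int
    m_JJ: int

    def __post_init__(self) -> None:
        if min(self.m_LL, self.m_LJ, self.m_JJ) < 0:
            raise ValueError(f"{self.drop_id}: negative count")

    @property
    def m_T(self) -> int:
        return self.m_LL + self.m_LJ + self.m_JJ

    def as_array(self) -> np.ndarray:
        return np.array([self.m_LL, self.m_LJ, self.m_JJ], dtype=float)


@dataclass(frozen=True)
class MatingRates:
    """Per-drop mating rates; p + q = 1 by construction."""

    p: float
    q: float


@dataclass(frozen=True)
class ExpectedCounts:
    e_LL: float
    e_LJ: float
    e_JJ: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e_LL, self.e_LJ, self.e_JJ])


@dataclass
class GofReport:
    """One goodness-of-fit test result."""

    test: str  # "chi2" or "G"
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    bonferroni_corrected_p: Optional[float] = None
    infinite_statistic: bool = False
    note: str = ""

    def significant(self, alpha: float = 0.05, corrected: bool = True) -> bool:
        p = self.bonferroni_corrected_p if corrected else self.p_value
        if p is None:
            p = self.p_value
        return p < alpha


def count_copulation_types(drop: DropRecord) -> DropCounts:
    """Tally LL / LJ / JJ copulations over the whole observation window."""
    tally = {c: 0 for c in COPULATION_CATEGORIES}
    for e in drop.copulations:
        if e.copulation_type not in tally:
            raise ValueError(
                f"{drop.drop_id}: copulation with type "
                f"{e.copulation_type!r}; drop logs must be fully typed"
            )
        tally[e.copulation_type] += 1
    return DropCounts(drop.drop_id, tally["LL"], tally["LJ"], tally["JJ"])


def first_copulation_test(
    first_types: Sequence[str],
    expected_props: Sequence[float] = RANDOM_MATING_PROPS,
) -> GofReport:
    """Pearson chi-square of first-copulation types against the 1:2:1 null.

    ``first_types`` holds one copulation type per drop (its earliest
    copulation; ties broken upstream by event-row order).
    """
    if len(first_types) == 0:
        raise ValueError("no drops with a first copulation")
    observed = np.array(
        [sum(1 for t in first_types if t == c) for c in COPULATION_CATEGORIES],
        dtype=float,
    )
    if observed.sum() != len(first_types):
        bad = set(first_types) - set(COPULATION_CATEGORIES)
        raise ValueError(f"unknown first-copulation types: {sorted(bad)}")
    expected = np.asarray(expected_props, dtype=float) * observed.sum()
    chi2, p = stats.chisquare(observed, expected)
    return GofReport(
        test="chi2",
        statistic=float(chi2),
        df=len(observed) - 1,
        p_value=float(p),
        observed=observed,
        expected=expected,
    )


def g_goodness_of_fit(
    observed: Sequence[float],
    expected_props: Sequence[float],
    n_tests: int = 1,
) -> GofReport:
    """Log-likelihood-ratio (G) goodness-of-fit test for one replicate.

    G = 2 * sum o_i * ln(o_i / e_i) with the 0 * ln 0 = 0 convention.  A
    category with expected proportion 0 but observed counts makes G infinite;
    this is reported via ``infinite_statistic`` rather than raised.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"expected proportions must sum to 1, got {props.sum()}")
    if obs.sum() <= 0:
        raise ValueError("observed total must be positive")
    exp = props * obs.sum()
    df = len(obs) - 1
    if np.any((exp == 0) & (obs > 0)):
        return GofReport(
            test="G", statistic=math.inf, df=df, p_value=0.0,
            observed=obs, expected=exp,
            bonferroni_corrected_p=0.0, infinite_statistic=True,
            note="observed counts in a zero-expectation category",
        )
    # drop structural zeros (expected 0 and observed 0) from the sum
    mask = exp > 0
    g, p = stats.power_divergence(
        obs[mask], exp[mask], ddof=len(obs[mask]) - 1 - df,
        lambda_="log-likelihood",
    )
    return GofReport(
        test="G", statistic=float(g), df=df, p_value=float(p),
        observed=obs, expected=exp,
        bonferroni_corrected_p=min(1.0, float(p) * n_tests),
    )


@dataclass
class RepeatedGReport:
    """Repeated G-tests of goodness-of-fit across replicate drops.

    Follows the sequential logic: per-drop G tests (Bonferroni corrected),
    then a heterogeneity G (independence G on the drops x categories table).
    If the drops are heterogeneous, the pooled test is still reported but
    flagged not interpretable, and conclusions rest on the per-drop tests.
    Total G = sum of per-drop G = pooled G + heterogeneity G.
    """

    per_drop: list[GofReport]
    drop_ids: list[str]
    heterogeneity: GofReport
    pooled: GofReport
    total_g: float
    total_df: int
    total_p: float
    heterogeneous: bool
    pooled_interpretable: bool
    excluded_empty: list[str] = field(default_factory=list)

    def summary(self) -> str:
        n_sig_raw = sum(
            1 for r in self.per_drop
            if not r.infinite_statistic and r.p_value < 0.05
        )
        n_sig = sum(1 for r in self.per_drop if r.significant(0.05))
        lines = [
            f"repeated G-tests over {len(self.per_drop)} drops",
            f"  per-drop: {n_sig_raw} significant at raw p<0.05, "
            f"{n_sig} after Bonferroni",
            f"  heterogeneity G = {self.heterogeneity.statistic:.2f}, "
            f"df = {self.heterogeneity.df}, p = {self.heterogeneity.p_value:.3g}",
            f"  pooled G = {self.pooled.statistic:.2f}, df = {self.pooled.df}"
            + ("  [not interpretable — data heterogeneous]"
               if not self.pooled_interpretable else ""),
            f"  total G = {self.total_g:.2f}, df = {self.total_df}",
        ]
        return "\n".join(lines)


def repeated_g_procedure(
    drops: Sequence[DropCounts],
    expected_props: Sequence[float] = RANDOM_MATING_PROPS,
    alpha: float = 0.05,
) -> RepeatedGReport:
    """Run the repeated G-test hierarchy over replicate drops."""
    included = [d for d in drops if d.m_T > 0]
    excluded = [d.drop_id for d in drops if d.m_T == 0]
    if excluded:
        logger.info("excluding %d empty drops from G tests: %s",
                    len(excluded), excluded)
    if len(included) < 2:
        raise ValueError("repeated G procedure needs >= 2 non-empty drops")

    n = len(included)
    per_drop = [
        g_goodness_of_fit(d.as_array(), expected_props, n_tests=n)
        for d in included
    ]

    table = np.stack([d.as_array() for d in included])
    # drop all-zero category columns so the independence test is well posed;
    # df uses the retained table dimensions
    col_mask = table.sum(axis=0) > 0
    het_table = table[:, col_mask]
    het_g, het_p, het_df, _ = stats.chi2_contingency(
        het_table, correction=False, lambda_="log-likelihood"
    )
    heterogeneity = GofReport(
        test="G", statistic=float(het_g), df=int(het_df), p_value=float(het_p),
        observed=table, expected=np.array([]),
    )

    pooled_counts = table.sum(axis=0)
    pooled = g_goodness_of_fit(pooled_counts, expected_props)
    heterogeneous = heterogeneity.p_value < alpha

    finite = [r.statistic for r in per_drop if not r.infinite_statistic]
    total_g = float(sum(finite)) if len(finite) == len(per_drop) else math.inf
    total_df = n * (len(expected_props) - 1)
    total_p = float(stats.chi2.sf(total_g, total_df)) if math.isfinite(
        total_g
    ) else 0.0

    return RepeatedGReport(
        per_drop=per_drop,
        drop_ids=[d.drop_id for d in included],
        heterogeneity=heterogeneity,
        pooled=pooled,
        total_g=total_g,
        total_df=total_df,
        total_p=total_p,
        heterogeneous=heterogeneous,
        pooled_interpretable=not heterogeneous,
        excluded_empty=excluded,
    )


def mating_rates(counts: DropCounts) -> Optional[MatingRates]:
    """Mating rates p (lignano) and q (janickei) for one drop.

    p = (2 m_LL + m_LJ) / (2 m_T); q = (2 m_JJ + m_LJ) / (2 m_T).  Each
    copulation involves two participations, conspecific ones contribute two
    of the same species, heterospecific one each.  Returns None for an
    empty drop (rates undefined).
    """
    if counts.m_T == 0:
        return None
    p = (2 * counts.m_LL + counts.m_LJ) / (2 * counts.m_T)
    q = (2 * counts.m_JJ + counts.m_LJ) / (2 * counts.m_T)
    return MatingRates(p=p, q=q)


def rate_adjusted_expected(rates: MatingRates, m_T: int) -> ExpectedCounts:
    """Expected counts e = (p^2, 2pq, q^2) * m_T under random pairing."""
    if m_T < 0:
        raise ValueError("m_T must be >= 0")
    return ExpectedCounts(
        e_LL=rates.p**2 * m_T,
        e_LJ=2 * rates.p * rates.q * m_T,
        e_JJ=rates.q**2 * m_T,
    )


def rate_adjusted_test(
    counts: DropCounts,
    n_tests: int = 1,
    df: int = 1,
) -> GofReport:
    """Per-drop Pearson chi-square against the rate-adjusted expectations.

    The default df = 1 accounts for the one mating-rate parameter estimated
    from the same counts (3 categories - 1 - 1, the Hardy-Weinberg analogy);
    df = 2 is accepted for the uncorrected convention.  Categories with
    expected 0 necessarily have observed 0 under these formulas (q = 0
    forces m_LJ = m_JJ = 0) and contribute nothing.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    if counts.m_T == 0:
        raise ValueError(f"{counts.drop_id}: empty drop, rates undefined")
    rates = mating_rates(counts)
    assert rates is not None
    expected = rate_adjusted_expected(rates, counts.m_T).as_array()
    observed = counts.as_array()
    zero_exp = expected == 0
    assert not np.any(zero_exp & (observed > 0)), (
        "observed counts in a zero-expectation category are impossible "
        "under the rate-adjusted null"
    )
    mask = ~zero_exp
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    p = float(stats.chi2.sf(chi2, df))
    return GofReport(
        test="chi2", statistic=chi2, df=df, p_value=p,
        observed=observed, expected=expected,
        bonferroni_corrected_p=min(1.0, p * n_tests),
        note=f"rate-adjusted null, p={rates.p:.4f}, q={rates.q:.4f}",
    )


def rate_adjusted_report(
    drops: Sequence[DropCounts], df: int = 1
) -> list[GofReport]:
    """Rate-adjusted test for every non-empty drop, Bonferroni over all."""
    included = [d for d in drops if d.m_T > 0]
    return [rate_adjusted_test(d, n_tests=len(included), df=df)
            for d in included]
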