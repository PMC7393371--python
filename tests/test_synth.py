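import collections
import logging

import numpy as np
import pytest

from macromate.events import filter_drops, read_event_log, write_event_log
from macromate.matechoice import (
    count_copulation_types,
    mating_rates,
    rate_adjusted_test,
)
from macromate.morpho import gpa_align, relative_warps
from macromate.synth import (
    SimulationParams,
    gen_drops,
    gen_pair_logs,
    gen_stylets,
    species_mean_shapes,
)
from macromate.traits import traits_table


def _null_params(seed, **kw):
    defaults = dict(
        propensity_L=3.0, propensity_J=3.0, preference=1.0,
        n_drops_injured=0, n_drops_dim=0,
    )
    defaults.update(kw)
    return SimulationParams(seed=seed, **defaults)


class TestPairLogs:
    def test_fixed_seed_reproducible(self):
        a = gen_pair_logs(SimulationParams(seed=7), "lignano", n=5)
        b = gen_pair_logs(SimulationParams(seed=7), "lignano", n=5)
        for x, y in zip(a, b):
            assert x.copulations == y.copulations
            assert x.sucks == y.sucks
            assert x.offspring_counts == y.offspring_counts

    def test_zero_suck_probability_means_no_sucks(self):
        params = SimulationParams(seed=3)
        params.lignano.suck_prob = 0.0
        recs = gen_pair_logs(params, "lignano", n=30)
        assert all(not r.sucks for r in recs)

    def test_duration_ratio_recovers_five_fold(self):
        """Mean copulation duration janickei:lignano ~ 5 over 200 pairs."""
        params = SimulationParams(seed=3)
        lig = traits_table(gen_pair_logs(params, "lignano", n=200))
        jan = traits_table(gen_pair_logs(params, "janickei", n=200))
        dl = lig.mean_copulation_duration_s.dropna()
        dj = jan.mean_copulation_duration_s.dropna()
        ratio = dj.mean() / dl.mean()
        se = ratio * np.sqrt(
            dl.sem() ** 2 / dl.mean() ** 2 + dj.sem() ** 2 / dj.mean() ** 2
        )
        target = (
            params.janickei.duration.median_s
            * np.exp(params.janickei.duration.sd_log ** 2 / 2)
        ) / (
            params.lignano.duration.median_s
            * np.exp(params.lignano.duration.sd_log ** 2 / 2)
        )
        assert abs(ratio - target) < 2 * se
        assert 4.0 < ratio < 6.0

    def test_heterospecific_offspring_from_at_most_one_parent(self):
        params = SimulationParams(seed=9)
        recs = gen_pair_logs(params, "hetero", n=200)
        productive = 0
        for r in recs:
            assert len(r.offspring_counts) == 2
            assert min(r.offspring_counts) == 0  # never both partners
            productive += max(r.offspring_counts) > 0
        # rare hybrid success, roughly the configured 20%
        assert 0.10 < productive / 200 < 0.32

    def test_events_fit_window_and_validate(self):
        recs = gen_pair_logs(SimulationParams(seed=5), "janickei", n=50)
        for r in recs:
            for e in r.copulations + r.sucks:
                assert 0 <= e.start_s < e.end_s <= 7200


class TestDrops:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            write_event_log(
                gen_drops(SimulationParams(seed=4), n_drops=10),
                tmp_path / name,
            )
        assert (tmp_path / "a.csv").read_bytes() == (
            tmp_path / "b.csv"
        ).read_bytes()

    def test_exclusion_flags(self):
        drops = gen_drops(SimulationParams(seed=4))
        assert len(drops) == 68
        reasons = collections.Counter(
            d.exclusion_reason for d in drops if d.excluded
        )
        assert reasons == {"injured": 5, "dim_lighting": 4}
        assert len(filter_drops(drops)) == 59

    def test_first_copulation_null_proportions(self):
        """Equal propensities, no preference: first copulations at 1:2:1."""
        drops = gen_drops(_null_params(5), n_drops=4000, max_copulations=1)
        firsts = [d.first_copulation_type() for d in drops if d.copulations]
        n = len(firsts)
        counts = collections.Counter(firsts)
        for ctype, p0 in (("LL", 0.25), ("LJ", 0.5), ("JJ", 0.25)):
            se = np.sqrt(p0 * (1 - p0) / n)
            assert abs(counts[ctype] / n - p0) < 3 * se

    def test_zero_janickei_propensity_gives_only_ll(self):
        params = _null_params(6, propensity_J=0.0)
        drops = gen_drops(params, n_drops=20)
        types = {e.copulation_type for d in drops for e in d.copulations}
        assert types == {"LL"}

    def test_strong_preference_suppresses_heterospecifics(self):
        params = _null_params(6, preference=1000.0)
        drops = gen_drops(params, n_drops=50)
        tally = collections.Counter(
            e.copulation_type for d in drops for e in d.copulations
        )
        total = sum(tally.values())
        assert total > 0
        assert tally["LJ"] / total < 0.01

    def test_mating_rate_recovers_propensity_share(self):
        """Mean per-drop p estimates prop_L / (prop_L + prop_J)."""
        params = SimulationParams(
            seed=8, propensity_L=3.0, propensity_J=1.5, preference=1.0,
            n_drops_injured=0, n_drops_dim=0, busy_blocking=False,
        )
        drops = gen_drops(params, n_drops=1000)
        ps = [
            mating_rates(count_copulation_types(d)).p
            for d in drops
            if d.copulations
        ]
        target = 3.0 / 4.5
        se = np.std(ps, ddof=1) / np.sqrt(len(ps))
        assert abs(np.mean(ps) - target) < 2 * se + 1e-3

    def test_rate_adjusted_type_i_calibrated_without_blocking(self):
        """When participations really are independent, the per-drop
        rate-adjusted test rejects at <= nominal alpha (and never after
        Bonferroni)."""
        params = _null_params(11, busy_blocking=False)
        drops = gen_drops(params, n_drops=300)
        counts = [count_copulation_types(d) for d in drops]
        inc = [c for c in counts if c.m_T > 0]
        reports = [rate_adjusted_test(c, n_tests=len(inc)) for c in inc]
        raw = np.mean([r.p_value < 0.05 for r in reports])
        bonf = np.mean([r.bonferroni_corrected_p < 0.05 for r in reports])
        se = np.sqrt(0.05 * 0.95 / len(inc))
        assert raw <= 0.05 + 3 * se
        assert bonf <= 0.01

    def test_busy_blocking_induces_apparent_assortativity(self):
        """The physical arena (blocking) correlates copulations homotypically
        even without preference, inflating rejections of the independence
        null — the statistical null is about participations, not arenas."""
        blocked = _null_params(12, busy_blocking=True)
        free = _null_params(12, busy_blocking=False)

        def rejection_rate(params):
            counts = [
                count_copulation_types(d)
                for d in gen_drops(params, n_drops=150)
            ]
            inc = [c for c in counts if c.m_T > 0]
            return np.mean(
                [rate_adjusted_test(c).p_value < 0.05 for c in inc]
            )

        assert rejection_rate(blocked) > rejection_rate(free) + 0.05

    def test_rate_adjusted_power_under_strong_preference(self):
        """Strong conspecific preference is detected in >80% of drops with
        at least 50 copulations."""
        params = _null_params(13, preference=10.0, busy_blocking=False)
        drops = gen_drops(params, n_drops=100)
        counts = [count_copulation_types(d) for d in drops]
        big = [c for c in counts if c.m_T >= 50]
        assert len(big) >= 50
        power = np.mean([rate_adjusted_test(c).p_value < 0.05 for c in big])
        assert power > 0.8


class TestStylets:
    def test_group_sizes_and_reproducibility(self):
        a = gen_stylets(SimulationParams(seed=2))
        b = gen_stylets(SimulationParams(seed=2))
        assert len(a) == 72
        sizes = collections.Counter(c.group for c in a)
        assert sizes == {"lignano": 25, "hybrid": 29, "janickei": 18}
        assert all(
            np.array_equal(x.points, y.points) for x, y in zip(a, b)
        )

    def test_noiseless_midpoint_hybrid_scores_midway(self):
        params = SimulationParams(seed=2)
        params.shape.noise_sd = 0.0
        params.shape.hybrid_weight = 0.5
        params.shape.hybrid_size_multiplier = 1.0
        params.shape.n_lignano = params.shape.n_hybrid = 2
        params.shape.n_janickei = 2
        configs = gen_stylets(params)
        rw = relative_warps(gpa_align(configs), variance_tol=1e-6)
        scores = {}
        for g in ("lignano", "hybrid", "janickei"):
            idx = [i for i, x in enumerate(rw.groups) if x == g]
            scores[g] = rw.rws(1)[idx].mean()
        mid = (scores["lignano"] + scores["janickei"]) / 2
        span = abs(scores["lignano"] - scores["janickei"])
        assert abs(scores["hybrid"] - mid) < 0.02 * span

    def test_species_means_are_valid_configurations(self):
        for name, pts in species_mean_shapes().items():
            assert pts.shape == (60, 2)
            assert not np.any(np.all(np.diff(pts[:30], axis=0) == 0, axis=1))


class TestPipelineClosure:
    def test_generated_pair_logs_read_back_without_warnings(
        self, tmp_path, caplog
    ):
        params = SimulationParams(seed=14)
        recs = gen_pair_logs(params, "hetero", n=10)
        path = tmp_path / "pairs.csv"
        write_event_log(recs, path)
        with caplog.at_level(logging.WARNING, logger="macromate.events"):
            back = read_event_log(path, schema="pair")
        assert not caplog.records
        # an event table can only carry records that have events; pairs that
        # never copulated re-enter the analysis via the trait-table roster
        with_events = [r for r in recs if r.copulations or r.sucks]
        assert len(back) == len(with_events)
        for orig, rt in zip(with_events, back):
            assert rt.copulations == orig.copulations
            assert rt.sucks == orig.sucks
        traits_table(back)  # analysable without error

    def test_generated_drops_read_back_and_counted(self, tmp_path, caplog):
        drops = gen_drops(SimulationParams(seed=14), n_drops=8)
        path = tmp_path / "drops.csv"
        write_event_log(drops, path)
        with caplog.at_level(logging.WARNING, logger="macromate.events"):
            back = read_event_log(path, schema="drop")
        assert not caplog.records
        for d in back:
            count_copulation_types(d)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SimulationParams(preference=0.0)
    with pytest.raises(ValueError):
        SimulationParams(propensity_L=-1.0)


def test_yaml_round_trip(tmp_path):
    params = SimulationParams(seed=42, preference=2.5)
    params.to_yaml(tmp_path / "p.yaml")
    back = SimulationParams.from_yaml(tmp_path / "p.yaml")
    assert back == params
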