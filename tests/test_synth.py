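"""Cohort, pool, search-result and dedup behavior of the generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from vapexposure import synth
from vapexposure.metrics import cohen_kappa


class TestCohort:
    def test_default_design_is_16_profiles(self):
        cohort = synth.generate_profile_cohort(synth.GeneratorConfig())
        assert len(cohort) == 16
        assert sum(p.race == "white" for p in cohort) == 8
        assert sum(p.race == "african_american" for p in cohort) == 4
        assert sum(p.race == "hispanic" for p in cohort) == 4

    def test_every_age_sex_cell_occupied(self):
        cohort = synth.generate_profile_cohort(synth.GeneratorConfig())
        cells = {(p.age, p.sex) for p in cohort}
        assert cells == {(a, s) for a in (16, 24) for s in ("female", "male")}
        assert len({p.profile_id for p in cohort}) == 16

    def test_single_race_block_is_2x2(self):
        cfg = synth.GeneratorConfig(races=(("hispanic", 1),))
        cohort = synth.generate_profile_cohort(cfg)
        assert len(cohort) == 4
        assert {(p.age, p.sex) for p in cohort} == \
            {(a, s) for a in (16, 24) for s in ("female", "male")}


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,field", [
        ({"pages": 0}, "pages"),
        ({"page_size": 0}, "page_size"),
        ({"overlap_kappa": 1.5}, "overlap_kappa"),
        ({"theme_noise_max": -0.1}, "theme_noise_max"),
        ({"n_terms": 2, "terms": ("a", "b", "c")}, "terms"),
        ({"subpool_frac": 0.0}, "subpool_frac"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            synth.GeneratorConfig(**kwargs)

    def test_mixture_must_sum_to_one(self):
        bad = {(a, s): {"product_review": 0.5, "health_information": 0.2,
                        "instructional": 0.2, "other": 0.2}
               for a in (16, 24) for s in ("female", "male")}
        with pytest.raises(ValueError, match="theme_mixture"):
            synth.GeneratorConfig(theme_mixture=bad)

    def test_default_term_list_has_18_entries(self):
        cfg = synth.GeneratorConfig()
        assert cfg.n_terms == len(cfg.terms) == 18
        assert cfg.per_term_budget == 7 * 20 == 140


class TestVideoPool:
    def test_forced_themes(self, small_config):
        pool = synth.generate_video_pool(small_config, 4,
                                         force_themes=synth.THEMES)
        assert [v.true_theme for v in pool] == list(synth.THEMES)
        assert all(v.title and v.description for v in pool)

    def test_same_seed_same_pool(self):
        cfg = synth.GeneratorConfig(seed=11)
        assert synth.generate_video_pool(cfg, 50) == \
            synth.generate_video_pool(cfg, 50)

    def test_too_few_videos_rejected(self, small_config):
        with pytest.raises(ValueError):
            synth.generate_video_pool(small_config, 3)

    def test_theme_counts_follow_pool_mixture(self):
        cfg = synth.GeneratorConfig(seed=5)
        n = 4201
        pool = synth.generate_video_pool(cfg, n)
        p = cfg.pool_mixture_vector()
        counts = np.array([sum(v.true_theme == t for v in pool)
                           for t in cfg.themes])
        sd = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) <= 3 * sd).all()


class TestSearchResults:
    def test_result_lists_fill_budget(self, results, small_config):
        assert all(len(rs.results) == small_config.per_term_budget
                   for rs in results)
        assert len(results) == 16 * small_config.n_terms

    def test_empty_inputs_rejected(self, small_config, cohort, pool):
        with pytest.raises(ValueError):
            synth.simulate_search_results([], cohort, small_config)
        with pytest.raises(ValueError):
            synth.simulate_search_results(pool, [], small_config)

    @staticmethod
    def _common_same_attribute(kappa, seed):
        cfg = synth.GeneratorConfig(
            seed=seed, n_terms=2, pages=2, overlap_kappa=kappa,
            races=(("white", 2),), ages=(24,), sexes=("male",),
            theme_mixture={(24, "male"): synth.DEFAULT_THEME_MIXTURE[
                (24, "male")]})
        cohort = synth.generate_profile_cohort(cfg)
        pool = synth.generate_video_pool(cfg, 400)
        res = synth.simulate_search_results(pool, cohort, cfg)
        seen = {}
        for rs in res:
            seen.setdefault(rs.profile.profile_id, set()).update(rs.results)
        a, b = seen.values()
        return len(a & b)

    def test_overlap_kappa_increases_common_videos(self):
        low = [self._common_same_attribute(0.0, s) for s in range(20)]
        high = [self._common_same_attribute(1.0, s) for s in range(20)]
        assert np.mean(high) > np.mean(low)

    def test_overlap_kappa_trend_is_monotone(self):
        kappas = [0.0, 0.3, 0.6, 1.0]
        means = [np.mean([self._common_same_attribute(k, s)
                          for s in range(10)]) for k in kappas]
        rho, _ = spearmanr(kappas, means)
        assert rho > 0


def test_group_theme_frequencies_follow_mixture():
    """Occurrence-level theme rates per group converge to the configured
    mixture within a multinomial standard-error bound."""
    cfg = synth.GeneratorConfig(seed=31, n_terms=6, pages=3)
    cohort = synth.generate_profile_cohort(cfg)
    pool = synth.generate_video_pool(cfg, 1200)
    theme_of = {v.video_id: v.true_theme for v in pool}
    results = synth.simulate_search_results(pool, cohort, cfg)
    by_group = {}
    for rs in results:
        g = (rs.profile.age, rs.profile.sex)
        by_group.setdefault(g, []).extend(theme_of[v] for v in rs.results)
    for g, drawn in by_group.items():
        n = len(drawn)
        p = cfg.mixture_vector(*g)
        counts = np.array([drawn.count(t) for t in cfg.themes])
        sd = np.sqrt(n * p * (1 - p))
        assert (np.abs(counts - n * p) <= 4 * sd + 1).all()


class TestDeduplicate:
    def test_hand_counted_example(self, cohort):
        rs = synth.SearchResultSet(cohort[0], "vape",
                                   ("a", "a", "b", "c", "c", "c"))
        unique, n_collected, n_dup = synth.deduplicate([rs])
        assert unique == {"a", "b", "c"}
        assert (n_collected, n_dup) == (6, 3)

    def test_all_distinct(self, cohort):
        rs = synth.SearchResultSet(cohort[0], "vape", tuple("abcdef"))
        unique, n_collected, n_dup = synth.deduplicate([rs])
        assert n_dup == 0 and len(unique) == 6 == n_collected

    @given(st.lists(st.integers(min_value=0, max_value=30), max_size=200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_dedup_identity(self, ids):
        profile = synth.ProfileSpec("p", 24, "male", "white")
        rs = synth.SearchResultSet(profile, "t",
                                   tuple(f"v{i}" for i in ids))
        unique, n_collected, n_dup = synth.deduplicate([rs])
        assert len(unique) + n_dup == n_collected == len(ids)


def test_simulated_raters_agree_almost_perfectly():
    cfg = synth.GeneratorConfig(seed=3)
    rng = np.random.default_rng(3)
    truth = list(rng.choice(synth.THEMES, size=1000,
                            p=cfg.pool_mixture_vector()))
    rater_a, rater_b = synth.simulate_raters(truth, cfg)
    kappa = cohen_kappa(rater_a, rater_b)
    assert 0.85 < kappa <= 1.0


def test_pool_roundtrip_jsonl(tmp_path, pool):
    path = tmp_path / "pool.jsonl"
    synth.write_pool_jsonl(pool, path)
    assert synth.read_pool_jsonl(path) == list(pool)


def test_results_roundtrip_csv(tmp_path, results, cohort):
    path = tmp_path / "results.csv"
    synth.write_results_csv(results, path)
    back = synth.read_results_csv(path, cohort)
    assert back == list(results)
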