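"""Synthetic cohorts, video pools and per-profile search-result lists.

Emulates the audit design this pipeline analyzes: 16 fictitious user
profiles (age 16 or 24, female or male, a race/ethnicity tag carried but
not analyzed) each searching 18 e-cigarette-related terms and retaining 7
pages x 20 = 140 results per term.  Videos carry a latent content theme
(product review, health information, instructional, other); titles and
descriptions are bags of words drawn from Zipf-weighted theme
vocabularies plus a shared vocabulary, so the four themes are
statistically separable but overlapping.  Which themes a profile sees is
governed by a demographically conditioned theme mixture, and profiles
that share age and sex draw from a common sub-pool whose strength is the
``overlap_kappa`` parameter — this is what produces the common-video
structure the network stage measures.

All stochastic operations draw from ``numpy`` generators derived
deterministically from ``GeneratorConfig.seed``, so every artifact is
bit-reproducible.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._stopwords import STOPWORDS
from ._porter import porter_stem

THEMES = ("product_review", "health_information", "instructional", "other")

#: The 18 e-cigarette search terms used by the audit design.
DEFAULT_SEARCH_TERMS = (
    "box mods", "cigalikes", "disposable e-cigs", "disposables",
    "disposable vape", "e-cig", "e-cigarette", "e-juice",
    "electronic cigarette", "e-liquid", "ENDS", "pod mods", "vape",
    "vaping", "vape juice", "vape mods", "vape pens", "vape pods",
)

# Per-(age, sex) theme mixtures.  The modal entries (16F instructional
# 42.5%, 16M instructional 30.9%, 24M review 39.4%, 24F review 38%) anchor
# the demographic gradient the audit reports; the remaining mass is spread
# to keep each vector a probability distribution.
DEFAULT_THEME_MIXTURE: dict[tuple[int, str], dict[str, float]] = {
    (16, "female"): {"product_review": 0.200, "health_information": 0.120,
                     "instructional": 0.425, "other": 0.255},
    (16, "male"):   {"product_review": 0.280, "health_information": 0.150,
                     "instructional": 0.309, "other": 0.261},
    (24, "female"): {"product_review": 0.380, "health_information": 0.150,
                     "instructional": 0.270, "other": 0.200},
    (24, "male"):   {"product_review": 0.394, "health_information": 0.150,
                     "instructional": 0.250, "other": 0.206},
}

_RNG_VOCAB, _RNG_POOL, _RNG_SEARCH, _RNG_RATERS = 101, 202, 303, 404


@dataclass(frozen=True)
class ProfileSpec:
    """One fictitious user profile."""

    profile_id: str
    age: int
    sex: str
    race: str

    def __post_init__(self):
        if self.age not in (16, 24):
            raise ValueError(f"age must be 16 or 24, got {self.age}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex}")


@dataclass(frozen=True)
class VideoRecord:
    """One video's metadata plus its synthetic ground-truth theme."""

    video_id: str
    title: str
    description: str
    channel: str
    view_count: int
    true_theme: str


@dataclass(frozen=True)
class SearchResultSet:
    """The ordered result list for one profile x search term."""

    profile: ProfileSpec
    term: str
    results: tuple[str, ...]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study design (defaults = audit design)."""

    seed: int = 0
    n_terms: int = 18
    terms: tuple[str, ...] | None = None
    pages: int = 7
    page_size: int = 20
    themes: tuple[str, ...] = THEMES
    theme_mixture: Mapping[tuple[int, str], Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_THEME_MIXTURE)
    pool_mixture: Mapping[str, float] | None = None
    overlap_kappa: float = 0.7
    vocab_size_per_theme: int = 150
    shared_vocab_size: int = 100
    shared_word_prob: float = 0.3
    zipf_exponent: float = 1.05
    theme_noise_max: float = 0.8
    title_len_mean: float = 12.0
    desc_len_mean: float = 40.0
    subpool_frac: float = 0.35
    subpool_frac_by_age: tuple[tuple[int, float], ...] | None = (
        (16, 0.25), (24, 0.45))
    races: tuple[tuple[str, int], ...] = (
        ("african_american", 1), ("hispanic", 1), ("white", 2))
    ages: tuple[int, ...] = (16, 24)
    sexes: tuple[str, ...] = ("female", "male")

    def __post_init__(self):
        if self.pages < 1:
            raise ValueError(f"pages must be >= 1, got {self.pages}")
        if self.page_size < 1:
            raise ValueError(f"page_size must be >= 1, got {self.page_size}")
        if self.n_terms < 1:
            raise ValueError(f"n_terms must be >= 1, got {self.n_terms}")
        if not 0.0 <= self.overlap_kappa <= 1.0:
            raise ValueError(
                f"overlap_kappa must lie in [0, 1], got {self.overlap_kappa}")
        if self.vocab_size_per_theme < 1:
            raise ValueError("vocab_size_per_theme must be >= 1")
        if self.shared_vocab_size < 0:
            raise ValueError("shared_vocab_size must be >= 0")
        if not 0.0 <= self.theme_noise_max <= 1.0:
            raise ValueError(
                f"theme_noise_max must lie in [0, 1], got {self.theme_noise_max}")
        if not 0.0 < self.subpool_frac <= 1.0:
            raise ValueError(
                f"subpool_frac must lie in (0, 1], got {self.subpool_frac}")
        if self.subpool_frac_by_age is not None:
            for age, frac in self.subpool_frac_by_age:
                if not 0.0 < frac <= 1.0:
                    raise ValueError(
                        f"subpool_frac_by_age[{age}] must lie in (0, 1], "
                        f"got {frac}")
        if self.terms is None:
            if self.n_terms <= len(DEFAULT_SEARCH_TERMS):
                self.terms = DEFAULT_SEARCH_TERMS[: self.n_terms]
            else:
                extra = tuple(f"search term {i}" for i in range(
                    len(DEFAULT_SEARCH_TERMS), self.n_terms))
                self.terms = DEFAULT_SEARCH_TERMS + extra
        elif len(self.terms) != self.n_terms:
            raise ValueError(
                f"terms has {len(self.terms)} entries but n_terms={self.n_terms}")
        for key, mix in self.theme_mixture.items():
            total = sum(mix.get(t, 0.0) for t in self.themes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"theme_mixture[{key}] sums to {total}, expected 1")
        if self.pool_mixture is not None:
            total = sum(self.pool_mixture.get(t, 0.0) for t in self.themes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"pool_mixture sums to {total}, expected 1")

    @property
    def per_term_budget(self) -> int:
        return self.pages * self.page_size

    def subpool_frac_for(self, age: int) -> float:
        if self.subpool_frac_by_age is not None:
            for a, frac in self.subpool_frac_by_age:
                if a == age:
                    return frac
        return self.subpool_frac

    def mixture_vector(self, age: int, sex: str) -> np.ndarray:
        try:
            mix = self.theme_mixture[(age, sex)]
        except KeyError:
            raise ValueError(
                f"theme_mixture has no entry for (age={age}, sex={sex!r})")
        return np.array([mix.get(t, 0.0) for t in self.themes])

    def pool_mixture_vector(self) -> np.ndarray:
        if self.pool_mixture is not None:
            return np.array([self.pool_mixture.get(t, 0.0)
                             for t in self.themes])
        vecs = [self.mixture_vector(a, s) for a, s in self.theme_mixture
                if a in self.ages and s in self.sexes]
        v = np.mean(vecs, axis=0)
        return v / v.sum()


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def generate_profile_cohort(config: GeneratorConfig) -> list[ProfileSpec]:
    """Build the profile cohort: one age x sex cell per race block.

    Defaults give 16 profiles — 4 African American, 4 Hispanic and 8 White
    (two White blocks), balanced over the 2 x 2 age x sex design.
    Deterministic: profile ids encode race, age, sex and block index.
    """
    cohort = []
    for race, n_blocks in config.races:
        for b in range(1, n_blocks + 1):
            for age in config.ages:
                for sex in config.sexes:
                    pid = f"{race}_{age}{sex[0].upper()}_{b}"
                    cohort.append(ProfileSpec(pid, age, sex, race))
    ids = [p.profile_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("profile_id collision in cohort")
    return cohort


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.power(np.arange(1, n + 1, dtype=float), exponent)
    return w / w.sum()


def generate_vocabularies(config: GeneratorConfig
                          ) -> tuple[dict[str, list[str]], list[str]]:
    """Draw disjoint per-theme vocabularies plus a shared vocabulary.

    Words are random letter strings filtered to be Porter-stem fixed
    points outside the stop list, so preprocessing passes them through
    unchanged and theme separability is controlled here, not downstream.
    """
    rng = _rng(config, _RNG_VOCAB)
    needed = len(config.themes) * config.vocab_size_per_theme \
        + config.shared_vocab_size
    words: list[str] = []
    seen: set[str] = set()
    letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
    while len(words) < needed:
        length = int(rng.integers(4, 9))
        w = "".join(rng.choice(letters, size=length))
        if w in seen or w in STOPWORDS or porter_stem(w) != w:
            continue
        seen.add(w)
        words.append(w)
    theme_vocab = {}
    for i, theme in enumerate(config.themes):
        lo = i * config.vocab_size_per_theme
        theme_vocab[theme] = words[lo: lo + config.vocab_size_per_theme]
    shared = words[len(config.themes) * config.vocab_size_per_theme:]
    return theme_vocab, shared


def generate_video_pool(config: GeneratorConfig, n_videos: int,
                        force_themes: Sequence[str] | None = None
                        ) -> list[VideoRecord]:
    """Generate *n_videos* records with theme-conditioned bag-of-words text.

    Title and description lengths are Poisson (means 12 and 40 words).
    Each video gets a document-level off-theme rate drawn uniformly from
    [0, ``theme_noise_max``]; every word is, with that probability, drawn
    from a uniformly chosen *other* theme's vocabulary — emulating real
    videos whose text mixes content themes, so that some documents are
    genuinely ambiguous.  On top of this, each word is replaced by a
    shared-vocabulary word with probability ``shared_word_prob``.  All
    vocabulary draws are Zipf-weighted.  ``force_themes`` overrides the
    multinomial theme assignment (used for controlled fixtures).
    """
    if n_videos < len(config.themes):
        raise ValueError(
            f"n_videos={n_videos} is below the number of themes "
            f"({len(config.themes)})")
    rng = _rng(config, _RNG_POOL)
    theme_vocab, shared = generate_vocabularies(config)
    if force_themes is not None:
        if len(force_themes) != n_videos:
            raise ValueError("force_themes length must equal n_videos")
        themes = list(force_themes)
    else:
        themes = list(rng.choice(config.themes, size=n_videos,
                                 p=config.pool_mixture_vector()))
    zipf_theme = {t: _zipf_weights(len(v), config.zipf_exponent)
                  for t, v in theme_vocab.items()}
    zipf_shared = (_zipf_weights(len(shared), config.zipf_exponent)
                   if shared else None)
    shared_arr = np.array(shared) if shared else None
    vocab_arr = {t: np.array(v) for t, v in theme_vocab.items()}
    pool = []
    n_channels = max(10, n_videos // 20)
    for i, theme in enumerate(themes):
        others = [t for t in config.themes if t != theme]
        noise = rng.uniform(0.0, config.theme_noise_max) if others else 0.0

        def draw(n: int) -> list[str]:
            out = rng.choice(vocab_arr[theme], size=n, p=zipf_theme[theme])
            if others and noise > 0:
                off = rng.random(n) < noise
                for j in np.where(off)[0]:
                    t2 = others[int(rng.integers(len(others)))]
                    out[j] = rng.choice(vocab_arr[t2], p=zipf_theme[t2])
            if shared_arr is not None and config.shared_word_prob > 0:
                mask = rng.random(n) < config.shared_word_prob
                k = int(mask.sum())
                if k:
                    out[mask] = rng.choice(shared_arr, size=k, p=zipf_shared)
            return list(out)

        title = " ".join(draw(max(3, int(rng.poisson(config.title_len_mean)))))
        desc = " ".join(draw(max(5, int(rng.poisson(config.desc_len_mean)))))
        pool.append(VideoRecord(
            video_id=f"v{i:06d}",
            title=title,
            description=desc,
            channel=f"channel_{int(rng.integers(n_channels))}",
            view_count=int(np.exp(rng.normal(8.0, 2.0))),
            true_theme=theme,
        ))
    return pool


def simulate_search_results(pool: Sequence[VideoRecord],
                            cohort: Sequence[ProfileSpec],
                            config: GeneratorConfig
                            ) -> list[SearchResultSet]:
    """Simulate per-profile, per-term ranked result lists.

    For each (age, sex) group a per-theme group sub-pool is sampled whose
    size is an age-dependent fraction of the theme pool (smaller for
    16-year-old groups by default, emulating age-restriction of this
    content, which is what makes the 24M-24F common-video edge the
    strongest and 16M-16F the weakest); each profile's accessible
    sub-pool copies each group slot with probability ``overlap_kappa`` and
    otherwise substitutes a random video of that theme, so ``kappa=1``
    gives identical supports within a group and ``kappa=0`` independent
    ones.  Result slots draw a theme from the group's mixture, then a
    video uniformly (with replacement) from the profile's sub-pool —
    duplicates within and across terms are expected, as in real search
    exposure.
    """
    if not pool:
        raise ValueError("pool is empty")
    if not cohort:
        raise ValueError("cohort is empty")
    rng = _rng(config, _RNG_SEARCH)
    by_theme: dict[str, np.ndarray] = {}
    for t in config.themes:
        ids = np.array([v.video_id for v in pool if v.true_theme == t])
        by_theme[t] = ids
    groups = sorted({(p.age, p.sex) for p in cohort})
    for age, sex in groups:
        mix = config.mixture_vector(age, sex)
        for t, w in zip(config.themes, mix):
            if w > 0 and len(by_theme[t]) == 0:
                raise ValueError(
                    f"pool has no videos of theme {t!r} required by the "
                    f"(age={age}, sex={sex!r}) mixture")
    group_subpool: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    for g in groups:
        group_subpool[g] = {}
        # total accessible slice scales with age (emulating age
        # restriction); its per-theme composition follows the group's
        # mixture, so unique-video prevalence reflects the mixture at any
        # budget, not only before coverage saturates
        m_total = config.subpool_frac_for(g[0]) * len(pool)
        mix = config.mixture_vector(*g)
        for t, w in zip(config.themes, mix):
            ids = by_theme[t]
            if len(ids) == 0 or w <= 0:
                group_subpool[g][t] = ids[:0]
                continue
            m = min(len(ids), max(1, round(m_total * w)))
            group_subpool[g][t] = rng.choice(ids, size=m, replace=False)

    results = []
    for profile in cohort:
        g = (profile.age, profile.sex)
        mix = config.mixture_vector(*g)
        subpool = {}
        for t in config.themes:
            base = group_subpool[g][t]
            ids = by_theme[t]
            if len(base) == 0:
                subpool[t] = base
                continue
            keep = rng.random(len(base)) < config.overlap_kappa
            own = base.copy()
            n_swap = int((~keep).sum())
            if n_swap:
                own[~keep] = rng.choice(ids, size=n_swap)
            subpool[t] = own
        budget = config.per_term_budget
        for term in config.terms:
            slot_themes = rng.choice(len(config.themes), size=budget, p=mix)
            picks = np.empty(budget, dtype=object)
            for ti, t in enumerate(config.themes):
                mask = slot_themes == ti
                k = int(mask.sum())
                if k:
                    picks[mask] = rng.choice(subpool[t], size=k)
            results.append(SearchResultSet(profile, term, tuple(picks)))
    return results


def deduplicate(results: Iterable[SearchResultSet]
                ) -> tuple[set[str], int, int]:
    """Collapse result lists to unique video ids.

    Returns ``(unique_ids, n_collected, n_duplicates)`` where every
    occurrence of a video id beyond its first — anywhere across profiles
    and terms — counts as a duplicate, so
    ``len(unique_ids) + n_duplicates == n_collected`` always holds.
    """
    counts: Counter[str] = Counter()
    for rs in results:
        counts.update(rs.results)
    n_collected = sum(counts.values())
    unique_ids = set(counts)
    return unique_ids, n_collected, n_collected - len(unique_ids)


def simulate_raters(true_labels: Sequence[str], config: GeneratorConfig,
                    n_raters: int = 2, error_rate: float = 0.025,
                    themes: Sequence[str] = THEMES) -> list[list[str]]:
    """Simulate independent human coders standing in for the label step.

    Each rater reports the true theme with probability ``1 - error_rate``
    and otherwise a uniform draw from the remaining themes.  The default
    error rate of 2.5% per rater puts two-rater chance-corrected agreement
    (Cohen's kappa) near the "almost perfect" level reported for human
    coding of this content (~0.93).
    """
    rng = _rng(config, _RNG_RATERS)
    themes = list(themes)
    out = []
    for _ in range(n_raters):
        labels = []
        for y in true_labels:
            if rng.random() < error_rate:
                alternatives = [t for t in themes if t != y]
                labels.append(alternatives[int(rng.integers(len(alternatives)))])
            else:
                labels.append(y)
        out.append(labels)
    return out


# ---------------------------------------------------------------------------
# plain-text I/O

def write_pool_jsonl(pool: Sequence[VideoRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in pool:
            fh.write(json.dumps(v.__dict__) + "\n")


def read_pool_jsonl(path) -> list[VideoRecord]:
    pool = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                pool.append(VideoRecord(**json.loads(line)))
    return pool


def write_results_csv(results: Sequence[SearchResultSet], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["profile_id", "term", "rank", "video_id"])
        for rs in results:
            for rank, vid in enumerate(rs.results, start=1):
                writer.writerow([rs.profile.profile_id, rs.term, rank, vid])


def write_cohort_csv(cohort: Sequence[ProfileSpec], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["profile_id", "age", "sex", "race"])
        for p in cohort:
            writer.writerow([p.profile_id, p.age, p.sex, p.race])


def read_cohort_csv(path) -> list[ProfileSpec]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [ProfileSpec(r["profile_id"], int(r["age"]), r["sex"], r["race"])
                for r in csv.DictReader(fh)]


def read_results_csv(path, cohort: Sequence[ProfileSpec]
                     ) -> list[SearchResultSet]:
    by_id = {p.profile_id: p for p in cohort}
    acc: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for r in csv.DictReader(fh):
            key = (r["profile_id"], r["term"])
            if key not in acc:
                acc[key] = []
                order.append(key)
            acc[key].append(r["video_id"])
    out = []
    for pid, term in order:
        if pid not in by_id:
            raise ValueError(f"profile {pid!r} not present in cohort")
        out.append(SearchResultSet(by_id[pid], term, tuple(acc[(pid, term)])))
    return out
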