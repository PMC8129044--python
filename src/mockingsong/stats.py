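"""Adjacent-vs-distant phrase comparison and per-feature tests.

Each phrase that has a successor is compared to that successor (the
*adjacent* score) and to ``k`` phrases sampled uniformly without replacement
from outside a symmetric ``exclusion``-phrase window around it (the
*distant* scores, the chance baseline). Per feature, adjacent scores are
tested against the pooled distant scores with a two-sided Welch t-test, and
significance is assessed at a Bonferroni-corrected alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .distance import PairDistance, phrase_distance
from .errors import InputError, InsufficientDistantPhrases
from .phrasing import Phrase

__all__ = [
    "FEATURES",
    "TransitionComparison",
    "FeatureTestResult",
    "sample_distant_phrases",
    "compare_song",
    "test_features",
    "results_to_frame",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)

FEATURES = ("amplitude", "frequency", "entropy", "duration_ratio")

_FIELD = {
    "amplitude": "amp_dist",
    "frequency": "freq_dist",
    "entropy": "ent_dist",
    "duration_ratio": "dur_ratio",
}


@dataclass(frozen=True)
class TransitionComparison:
    """One focal phrase vs its successor and k sampled distant phrases."""

    focal_index: int
    adjacent: PairDistance
    distant: list[PairDistance]
    distant_indices: list[int]
    seed: int | None = None


@dataclass(frozen=True)
class FeatureTestResult:
    """Welch test of adjacent vs pooled distant scores for one feature."""

    feature: str
    mean_adjacent: float
    sem_adjacent: float
    mean_distant: float
    sem_distant: float
    t_statistic: float
    p_value: float
    corrected_alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


def sample_distant_phrases(
    focal: int,
    n_phrases: int,
    k: int = 10,
    exclusion: int = 10,
    rng: np.random.Generator | None = None,
) -> list[int]:
    """Draw k distinct phrase indices outside the exclusion window.

    Eligible indices d satisfy |d - focal| > exclusion (which also rules out
    the focal phrase and, for exclusion >= 1, its successor). Raises
    :class:`InsufficientDistantPhrases` when fewer than k indices qualify, a
    signal to drop the focal phrase from the analysis.
    """
    rng = rng or np.random.default_rng()
    candidates = np.arange(n_phrases)
    eligible = candidates[
        (np.abs(candidates - focal) > exclusion) & (candidates != focal + 1)
    ]
    if len(eligible) < k:
        raise InsufficientDistantPhrases(
            f"focal phrase {focal}: only {len(eligible)} eligible distant phrases, need {k}"
        )
    return sorted(int(i) for i in rng.choice(eligible, size=k, replace=False))


def compare_song(
    phrases: list[Phrase],
    k: int = 10,
    exclusion: int = 10,
    seed: int | None = None,
) -> list[TransitionComparison]:
    """Adjacent and distant phrase-distance scores for every eligible phrase.

    Phrases without enough eligible distant partners are skipped with a
    logged message; the sampling RNG is seeded once for the whole song so a
    fixed seed reproduces the result exactly.
    """
    if len(phrases) < 2:
        raise InputError(f"need at least 2 phrases, got {len(phrases)}")
    rng = np.random.default_rng(seed)
    out: list[TransitionComparison] = []
    for focal in range(len(phrases) - 1):
        try:
            distant_idx = sample_distant_phrases(
                focal, len(phrases), k=k, exclusion=exclusion, rng=rng
            )
        except InsufficientDistantPhrases as exc:
            logger.info("skipping focal phrase: %s", exc)
            continue
        out.append(
            TransitionComparison(
                focal_index=focal,
                adjacent=phrase_distance(phrases[focal], phrases[focal + 1]),
                distant=[phrase_distance(phrases[focal], phrases[d]) for d in distant_idx],
                distant_indices=distant_idx,
                seed=seed,
            )
        )
    return out


def _pooled(comparisons: list[TransitionComparison], feature: str):
    attr = _FIELD[feature]
    adjacent = np.array([getattr(c.adjacent, attr) for c in comparisons])
    distant = np.array([getattr(d, attr) for c in comparisons for d in c.distant])
    return adjacent, distant


def test_features(
    comparisons: list[TransitionComparison],
    n_tests_for_correction: int = 4,
    alpha: float = 0.05,
) -> list[FeatureTestResult]:
    """Two-sided Welch t-test per feature, Bonferroni-corrected.

    Adjacent scores (one per focal phrase) are compared against the pooled
    distant scores. Exactly identical zero-variance samples get the t = 0,
    p = 1 convention.
    """
    if not comparisons:
        raise InputError("no transition comparisons to test")
    corrected = alpha / n_tests_for_correction
    results = []
    for feature in FEATURES:
        adj, dist = _pooled(comparisons, feature)
        if len(adj) < 2 or len(dist) < 2:
            raise InputError(f"{feature}: need >= 2 scores per condition")
        if np.ptp(adj) == 0 and np.ptp(dist) == 0 and adj[0] == dist[0]:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(adj, dist, equal_var=False)
        results.append(
            FeatureTestResult(
                feature=feature,
                mean_adjacent=float(adj.mean()),
                sem_adjacent=float(sps.sem(adj)),
                mean_distant=float(dist.mean()),
                sem_distant=float(sps.sem(dist)),
                t_statistic=float(t),
                p_value=float(p),
                corrected_alpha=corrected,
            )
        )
    return results


def results_to_frame(results: list[FeatureTestResult], bird: str = "") -> pd.DataFrame:
    """Statistics table: one row per feature, means +/- SEM, t, p, significance."""
    return pd.DataFrame(
        {
            "bird": [bird] * len(results),
            "feature": [r.feature for r in results],
            "mean_adj": [r.mean_adjacent for r in results],
            "sem_adj": [r.sem_adjacent for r in results],
            "mean_dist": [r.mean_distant for r in results],
            "sem_dist": [r.sem_distant for r in results],
            "t": [r.t_statistic for r in results],
            "p": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


def comparisons_to_frame(comparisons: list[TransitionComparison]) -> pd.DataFrame:
    """Long-format table of every phrase comparison (adjacent and distant)."""
    rows = []
    for c in comparisons:
        for kind, other, d in (
            [("adjacent", c.focal_index + 1, c.adjacent)]
            + [("distant", i, pd_) for i, pd_ in zip(c.distant_indices, c.distant)]
        ):
            rows.append(
                {
                    "focal": c.focal_index,
                    "other": other,
                    "kind": kind,
                    "n_comparisons": d.n_comparisons,
                    "amp_dist": d.amp_dist,
                    "freq_dist": d.freq_dist,
                    "ent_dist": d.ent_dist,
                    "dur_ratio": d.dur_ratio,
                    "seed": c.seed,
                }
            )
    return pd.DataFrame(rows)
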