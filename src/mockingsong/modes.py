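"""Rule-based labelling of phrase transitions by morphing mode.

Morphing modes describe which acoustic quality changes most clearly across a
phrase transition while the others are conserved: *pitch* (frequency moves,
everything else stays), *timbre* (entropy moves), *stretch* / *squeeze*
(duration grows / shrinks), or *contrast* (nothing is conserved). "Low" and
"high" are made operational as quantiles of the song's own distant-pair
distance distributions, because absolute feature scales differ between
recordings.

The rule assigns a single label per transition; real transitions often mix
modes, so :func:`transition_conditions` exposes the raw fired conditions for
callers that want to detect mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .distance import PairDistance
from .errors import InputError

__all__ = [
    "MorphMode",
    "ModeThresholds",
    "calibrate_thresholds",
    "classify_transition",
    "transition_conditions",
    "mode_frequency_table",
]


class MorphMode(str, Enum):
    TIMBRE = "timbre"
    PITCH = "pitch"
    STRETCH = "stretch"
    SQUEEZE = "squeeze"
    CONTRAST = "contrast"


@dataclass(frozen=True)
class ModeThresholds:
    """Per-feature low/high cutoffs on the distant-pair distance scale.

    A distance below the low cutoff counts as "low" (conserved feature), one
    above the high cutoff as "high" (changed feature). ``dur_ratio_low`` is a
    cutoff on the duration ratio itself: below it, durations count as
    different.
    """

    amp_low: float
    amp_high: float
    freq_low: float
    freq_high: float
    ent_low: float
    ent_high: float
    dur_ratio_low: float

    def __post_init__(self) -> None:
        for name in ("amp", "freq", "ent"):
            lo, hi = getattr(self, f"{name}_low"), getattr(self, f"{name}_high")
            if not lo < hi:
                raise InputError(
                    f"{name}: degenerate thresholds (low {lo} >= high {hi}); "
                    "distant-pair distances show no spread"
                )


def calibrate_thresholds(
    distant: list[PairDistance],
    low_q: float = 0.10,
    high_q: float | tuple[float, float, float] = (0.30, 0.20, 0.40),
    dur_ratio_cutoff: float = 0.75,
) -> ModeThresholds:
    """Quantile cutoffs from a sample of distant-pair distances.

    ``high_q`` may be a scalar or per-feature (amplitude, frequency,
    entropy) quantiles. The defaults are deliberately asymmetric: a
    morph-scale pitch shift (tens of percent) is small next to the f0 spread
    of random phrase pairs, so the frequency "high" cutoff sits at a lower
    quantile than the entropy one, where even tonal-tonal pairs carry
    frame-level jitter. Duration gets a fixed ratio cutoff rather than a
    quantile: random phrase pairs routinely differ in duration by more than
    the factor ~2 of a stretch/squeeze morph, so "different duration" is an
    absolute notion (shorter:longer below ``dur_ratio_cutoff``).

    Requires at least 20 distant scores so the quantiles are meaningful.
    """
    if len(distant) < 20:
        raise InputError(f"need >= 20 distant-pair scores to calibrate, got {len(distant)}")
    qa_hi, qf_hi, qe_hi = (high_q,) * 3 if np.isscalar(high_q) else high_q
    for hi in (qa_hi, qf_hi, qe_hi):
        if not 0 <= low_q < hi <= 1:
            raise InputError(f"need 0 <= low_q < high_q <= 1, got ({low_q}, {hi})")
    if not 0 < dur_ratio_cutoff <= 1:
        raise InputError(f"dur_ratio_cutoff must lie in (0, 1], got {dur_ratio_cutoff}")

    def q(attr: str, quant: float) -> float:
        return float(np.quantile([getattr(d, attr) for d in distant], quant))

    return ModeThresholds(
        amp_low=q("amp_dist", low_q),
        amp_high=q("amp_dist", qa_hi),
        freq_low=q("freq_dist", low_q),
        freq_high=q("freq_dist", qf_hi),
        ent_low=q("ent_dist", low_q),
        ent_high=q("ent_dist", qe_hi),
        dur_ratio_low=dur_ratio_cutoff,
    )


def transition_conditions(pd_: PairDistance, th: ModeThresholds) -> dict[str, bool]:
    """The raw low/high conditions a transition fires against the thresholds."""
    return {
        "amp_low": pd_.amp_dist <= th.amp_low,
        "amp_high": pd_.amp_dist >= th.amp_high,
        "freq_low": pd_.freq_dist <= th.freq_low,
        "freq_high": pd_.freq_dist >= th.freq_high,
        "ent_low": pd_.ent_dist <= th.ent_low,
        "ent_high": pd_.ent_dist >= th.ent_high,
        "dur_low": pd_.dur_ratio <= th.dur_ratio_low,
    }


def classify_transition(
    pd_: PairDistance,
    durations: tuple[float, float],
    th: ModeThresholds,
) -> MorphMode:
    """Label one transition by its most salient morphing mode.

    ``durations`` are the mean syllable durations (ms) of the pre- and
    post-transition phrase, used only to orient stretch vs squeeze. The rule
    is evaluated in a fixed order; when no signature matches exactly, the
    mode with the fewest violated conditions wins, ties broken by observed
    prevalence (timbre, pitch, squeeze, stretch, contrast).
    """
    pre_ms, post_ms = durations
    c = transition_conditions(pd_, th)
    stretched = post_ms > pre_ms

    if c["dur_low"] and c["amp_low"] and c["freq_low"] and c["ent_low"]:
        return MorphMode.STRETCH if stretched else MorphMode.SQUEEZE
    if c["ent_high"] and c["amp_low"] and c["freq_low"] and not c["dur_low"]:
        return MorphMode.TIMBRE
    if c["freq_high"] and c["amp_low"] and c["ent_low"] and not c["dur_low"]:
        return MorphMode.PITCH
    if c["amp_high"] and c["freq_high"] and c["ent_high"]:
        return MorphMode.CONTRAST

    signatures: list[tuple[MorphMode, list[bool]]] = [
        (MorphMode.TIMBRE, [c["ent_high"], c["amp_low"], c["freq_low"], not c["dur_low"]]),
        (MorphMode.PITCH, [c["freq_high"], c["amp_low"], c["ent_low"], not c["dur_low"]]),
        (MorphMode.SQUEEZE,
         [c["dur_low"], c["amp_low"], c["freq_low"], c["ent_low"], not stretched]),
        (MorphMode.STRETCH,
         [c["dur_low"], c["amp_low"], c["freq_low"], c["ent_low"], stretched]),
        (MorphMode.CONTRAST, [c["amp_high"], c["freq_high"], c["ent_high"]]),
    ]
    # fewest violations wins; list order is the tie-break
    return min(signatures, key=lambda sig: sum(not ok for ok in sig[1]))[0]


def mode_frequency_table(modes: list[MorphMode]) -> pd.DataFrame:
    """Counts and proportions per mode over a list of labelled transitions."""
    if not modes:
        raise InputError("mode_frequency_table requires at least one transition")
    counts = {m: 0 for m in MorphMode}
    for m in modes:
        counts[MorphMode(m)] += 1
    total = len(modes)
    return pd.DataFrame(
        {
            "mode": [m.value for m in MorphMode],
            "count": [counts[m] for m in MorphMode],
            "proportion": [counts[m] / total for m in MorphMode],
        }
    )
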