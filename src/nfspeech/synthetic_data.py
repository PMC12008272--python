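"""Synthetic cohorts of paired ON/OFF transcripts with state scores.

The original clinical recordings are not distributable, so this module
generates cohorts carrying the statistical structure the analysis
assumes: each patient contributes one ON and one OFF recording; latent
neuropsychiatric state scores are drawn from clipped normals (defaults
ON 48.2 ± 8.7, OFF 17.2 ± 12.0, the cohort-level statistics of the
fluctuating-PD population being emulated, clipped to the scale range
[0, 60]); transcript text is template-based, with each content slot
filled from an ON-pole vocabulary with probability ``w * separation``
and from the OFF-pole vocabulary with probability ``(1 - w) *
separation`` where ``w = score / 60``, so lexical content correlates
linearly with the score and ``lexicon_separation`` dials the task
difficulty down to pure noise at 0.

A small fraction of patients ("nonfluctuators", default 3/33) have
|ON - OFF| < 10, i.e. no clinically meaningful fluctuation; their score
pairs are rejection-sampled from the same marginals conditioned on that
event, and all other patients are conditioned on its complement so the
realised nonfluctuator count is exactly binomial in the configured rate.
Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Dataset, MedState, SCORE_MAX, SCORE_MIN, Transcript
from .vocab import NEUTRAL_TERMS, OFF_TERMS, ON_TERMS

NONFLUCTUATOR_GAP = 10.0  # |ON - OFF| below this means no meaningful fluctuation

DEFAULT_TEMPLATES: tuple[str, ...] = (
    "right now i feel {} and {}, mostly {}.",
    "today i have been {} and rather {}, even {}.",
    "this morning i felt {}, then {} and {}.",
    "i would say i am {}, somewhat {} and {}.",
    "at the moment i feel {}, quite {} and a bit {}.",
    "honestly i feel {} and {}, perhaps {}.",
)


@dataclass(frozen=True)
class Lexicons:
    """Pole-specific and neutral vocabularies plus sentence frames."""

    on_terms: tuple[str, ...] = ON_TERMS
    off_terms: tuple[str, ...] = OFF_TERMS
    neutral_terms: tuple[str, ...] = NEUTRAL_TERMS
    templates: tuple[str, ...] = DEFAULT_TEMPLATES

    def __post_init__(self) -> None:
        if set(self.on_terms) & set(self.off_terms):
            raise ValueError("on_terms and off_terms must be disjoint")
        if not self.templates:
            raise ValueError("at least one sentence template required")


DEFAULT_LEXICONS = Lexicons()


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_patients: int = 33
    on_score_mean: float = 48.2
    on_score_sd: float = 8.7
    off_score_mean: float = 17.2
    off_score_sd: float = 12.0
    lexicon_separation: float = 1.0
    nonfluctuator_rate: float = 3 / 33
    sentence_count_range: tuple[int, int] = (6, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.on_score_sd < 0 or self.off_score_sd < 0:
            raise ValueError("score standard deviations must be nonnegative")
        if not 0 <= self.lexicon_separation <= 1:
            raise ValueError("lexicon_separation must be in [0, 1]")
        if not 0 <= self.nonfluctuator_rate <= 1:
            raise ValueError("nonfluctuator_rate must be in [0, 1]")
        lo, hi = self.sentence_count_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentence_count_range")


def generate_transcript(
    mixture_weight: float,
    lexicons: Lexicons,
    sentence_count: int,
    rng: np.random.Generator,
    separation: float = 1.0,
) -> str:
    """Build one transcript; each content slot is ON-pole with probability
    ``mixture_weight * separation``, OFF-pole with ``(1 - mixture_weight)
    * separation`` and neutral otherwise."""
    if sentence_count < 1:
        raise ValueError("sentence_count must be >= 1")
    if not 0 <= mixture_weight <= 1:
        raise ValueError("mixture_weight must be in [0, 1]")
    sentences = []
    for _ in range(sentence_count):
        template = lexicons.templates[int(rng.integers(len(lexicons.templates)))]
        n_slots = template.count("{}")
        terms = []
        for _ in range(n_slots):
            if rng.random() < separation:
                pool = lexicons.on_terms if rng.random() < mixture_weight else lexicons.off_terms
            else:
                pool = lexicons.neutral_terms
            terms.append(pool[int(rng.integers(len(pool)))])
        sentences.append(template.format(*terms))
    return " ".join(sentences)


def _draw_score_pair(
    config: CohortConfig, rng: np.random.Generator, nonfluctuator: bool
) -> tuple[float, float]:
    """Clipped-normal (ON, OFF) pair conditioned on (non)fluctuation."""
    for _ in range(10_000):
        on = float(np.clip(rng.normal(config.on_score_mean, config.on_score_sd), SCORE_MIN, SCORE_MAX))
        off = float(np.clip(rng.normal(config.off_score_mean, config.off_score_sd), SCORE_MIN, SCORE_MAX))
        gap_small = abs(on - off) < NONFLUCTUATOR_GAP
        if gap_small == nonfluctuator:
            return on, off
    raise RuntimeError("rejection sampling failed; check score means/sds")


def generate_cohort(config: CohortConfig, lexicons: Lexicons = DEFAULT_LEXICONS) -> Dataset:
    """Generate a paired ON/OFF cohort (deterministic under config.seed)."""
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_patients)))
    transcripts: list[Transcript] = []
    lo, hi = config.sentence_count_range
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        nonfluct = bool(rng.random() < config.nonfluctuator_rate)
        on_score, off_score = _draw_score_pair(config, rng, nonfluct)
        # OFF recorded first, matching the overnight-withdrawal protocol
        for state, score in ((MedState.OFF, off_score), (MedState.ON, on_score)):
            n_sent = int(rng.integers(lo, hi + 1))
            text = generate_transcript(
                mixture_weight=score / SCORE_MAX,
                lexicons=lexicons,
                sentence_count=n_sent,
                rng=rng,
                separation=config.lexicon_separation,
            )
            transcripts.append(
                Transcript(
                    patient_id=pid,
                    recording_id=f"{pid}-{state.value}",
                    med_state=state,
                    text=text,
                    score=round(score, 1),
                )
            )
    return Dataset(
        transcripts=transcripts,
        provenance=f"synthetic:seed={config.seed},n={config.n_patients},"
        f"sep={config.lexicon_separation:g}",
    )


def generate_repeat_trial(
    dataset: Dataset,
    subset_rate: float,
    rng: np.random.Generator,
    lexicons: Lexicons = DEFAULT_LEXICONS,
    sentence_count_range: tuple[int, int] = (6, 10),
    separation: float = 1.0,
    score_noise_sd: float = 3.0,
) -> Dataset:
    """Add a second OFF recording for a random ceil(rate*n) patient subset.

    The repeat recording's score is the patient's OFF score plus fresh
    noise (shared latent state, new measurement), emulating a
    repeat-trial design used to rule out task-learning effects.
    """
    if not 0 <= subset_rate <= 1:
        raise ValueError("subset_rate must be in [0, 1]")
    patients = sorted(dataset.patient_ids)
    n_repeat = math.ceil(subset_rate * len(patients))
    if n_repeat == 0:
        return dataset
    chosen = sorted(rng.choice(patients, size=n_repeat, replace=False).tolist())
    off_scores = {
        t.patient_id: t.score
        for t in dataset
        if t.med_state is MedState.OFF and t.score is not None
    }
    lo, hi = sentence_count_range
    extra: list[Transcript] = []
    for pid in chosen:
        if pid not in off_scores:
            continue
        score = float(np.clip(off_scores[pid] + rng.normal(0.0, score_noise_sd), SCORE_MIN, SCORE_MAX))
        text = generate_transcript(
            mixture_weight=score / SCORE_MAX,
            lexicons=lexicons,
            sentence_count=int(rng.integers(lo, hi + 1)),
            rng=rng,
            separation=separation,
        )
        extra.append(
            Transcript(
                patient_id=pid,
                recording_id=f"{pid}-OFF2",
                med_state=MedState.OFF,
                text=text,
                score=round(score, 1),
            )
        )
    return Dataset(
        transcripts=list(dataset.transcripts) + extra,
        provenance=dataset.provenance + f";repeat_trial(rate={subset_rate:g})",
        repeat_trial=True,
    )


def nonfluctuators(dataset: Dataset) -> list[str]:
    """Patients whose |ON - OFF| score difference is below the gap threshold."""
    by_patient: dict[str, dict[MedState, float]] = {}
    for t in dataset:
        if t.score is not None and t.med_state in (MedState.ON, MedState.OFF):
            by_patient.setdefault(t.patient_id, {})[t.med_state] = t.score
    return sorted(
        pid
        for pid, scores in by_patient.items()
        if MedState.ON in scores
        and MedState.OFF in scores
        and abs(scores[MedState.ON] - scores[MedState.OFF]) < NONFLUCTUATOR_GAP
    )
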