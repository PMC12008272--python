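"""Pole-specific vocabularies for the ON and OFF medication states.

These word lists encode the neuropsychiatric symptom themes of the two
dopaminergic medication states: the ON pole (well-being, energy, self
confidence, talkativeness) and the OFF pole (fatigue, low mood, anxiety,
lethargy, tremor).  They are used in two places: the synthetic cohort
generator fills transcript content slots from them, and the deterministic
stub language-model backend scores prompts by counting them.  The two
lists are disjoint by construction.
"""

from __future__ import annotations

ON_TERMS: tuple[str, ...] = (
    "well-being",
    "talkative",
    "energetic",
    "confident",
    "sure",
    "cheerful",
    "lively",
    "euphoric",
    "creative",
    "motivated",
    "active",
    "relaxed",
    "optimistic",
    "strong",
    "capable",
)

OFF_TERMS: tuple[str, ...] = (
    "tired",
    "exhausted",
    "drained",
    "low",
    "lethargic",
    "trembling",
    "anxious",
    "worried",
    "tense",
    "sad",
    "heavy",
    "discouraged",
    "slow",
    "weary",
    "listless",
)

NEUTRAL_TERMS: tuple[str, ...] = (
    "awake",
    "seated",
    "indoors",
    "upstairs",
    "downstairs",
    "outside",
    "home",
    "dressed",
    "quiet",
    "ordinary",
    "usual",
    "routine",
    "busy",
    "occupied",
)

# Tokens that negate the clause they appear in; never removed by
# normalization when negation preservation is on.
NEGATION_TOKENS: frozenset[str] = frozenset(
    {"no", "not", "never", "none", "nothing", "nobody", "nowhere", "neither", "nor", "cannot"}
)

assert not set(ON_TERMS) & set(OFF_TERMS)
assert not (set(ON_TERMS) | set(OFF_TERMS)) & set(NEUTRAL_TERMS)
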