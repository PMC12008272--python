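"""Text normalization applied to transcripts and NFS items before embedding.

The normalization mirrors what is standard for short clinical free-speech
documents: lowercase, strip punctuation, remove four closed stop-word
classes (pronouns, conjunctions, articles, prepositions) while always
keeping negation tokens, since "I do not feel well" and "I feel well"
must stay distinguishable.  Contracted negations ("don't") are expanded
before filtering so the negation survives.

A separate pre-pass, :func:`strip_nonsemantic`, removes paralinguistic
fillers ("ehm"), explicit references to medication intake or condition,
and examiner utterances marked in the transcript — content that would
leak the classification label or carries no semantic value.  In the
default pipeline it runs on the raw text, before :func:`normalize`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .vocab import NEGATION_TOKENS

PRONOUNS: frozenset[str] = frozenset(
    """i me my mine myself you your yours yourself yourselves he him his himself
    she her hers herself it its itself we us our ours ourselves they them their
    theirs themselves this that these those who whom whose which what""".split()
)

CONJUNCTIONS: frozenset[str] = frozenset(
    """and but or nor so yet because although though while whereas if unless
    since when whenever where wherever as than whether once until""".split()
)

ARTICLES: frozenset[str] = frozenset({"a", "an", "the"})

PREPOSITIONS: frozenset[str] = frozenset(
    """of in on at by with from to into onto over under about against between
    among through during before after above below up down off out around near
    without within toward towards upon across behind beyond along despite
    except inside outside via per""".split()
)

STOPWORD_CLASSES: dict[str, frozenset[str]] = {
    "pronouns": PRONOUNS,
    "conjunctions": CONJUNCTIONS,
    "articles": ARTICLES,
    "prepositions": PREPOSITIONS,
}

DEFAULT_FILLERS: frozenset[str] = frozenset(
    {"ehm", "uh", "um", "uhm", "er", "erm", "hmm", "mhm", "eh", "hm"}
)

# Default spans referring to medication intake/condition; matched
# case-insensitively as whole-word phrases and removed.
DEFAULT_MEDICATION_PATTERNS: tuple[str, ...] = (
    "levodopa",
    "medication",
    "pill",
    "dose",
    "on state",
    "off state",
)

# Irregular n't contractions; the regular ones are handled by one rule.
_IRREGULAR_CONTRACTIONS = {
    "won't": "will not",
    "can't": "cannot",
    "shan't": "shall not",
    "ain't": "am not",
}
_NT_RE = re.compile(r"\b([a-z]+)n[’']t\b")
_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizationPolicy:
    """Configuration of the normalization pipeline.

    With ``preserve_negations`` on, negation tokens are never removable
    regardless of stop-word class membership ("nor" is both a
    conjunction and a negation).
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    stopword_classes: frozenset[str] = frozenset(STOPWORD_CLASSES)
    preserve_negations: bool = True
    filler_tokens: frozenset[str] = DEFAULT_FILLERS
    medication_patterns: tuple[str, ...] = DEFAULT_MEDICATION_PATTERNS
    examiner_markers: tuple[str, str] = ("[examiner]", "[/examiner]")

    def __post_init__(self) -> None:
        unknown = set(self.stopword_classes) - set(STOPWORD_CLASSES)
        if unknown:
            raise ValueError(f"unknown stop-word class(es): {sorted(unknown)}")

    @property
    def removable_tokens(self) -> frozenset[str]:
        toks: set[str] = set()
        for cls in self.stopword_classes:
            toks |= STOPWORD_CLASSES[cls]
        if self.preserve_negations:
            toks -= NEGATION_TOKENS
        return frozenset(toks)


DEFAULT_POLICY = NormalizationPolicy()


def expand_contractions(text: str) -> str:
    """Expand n't contractions so negations survive punctuation stripping."""
    for contracted, expanded in _IRREGULAR_CONTRACTIONS.items():
        text = re.sub(re.escape(contracted).replace("'", "[’']"), expanded, text)
    return _NT_RE.sub(r"\1 not", text)


def normalize(text: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Normalize one document.

    Returns the cleaned text, or the empty string when every token was
    removable (the flagged-empty result; callers decide exclusion).
    """
    out = text
    if policy.lowercase:
        out = out.lower()
    out = expand_contractions(out)
    if policy.strip_punctuation:
        out = _PUNCT_RE.sub(" ", out)
    tokens = out.split()
    removable = policy.removable_tokens
    kept = [t for t in tokens if t not in removable]
    return " ".join(kept)


def strip_nonsemantic(text: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Remove fillers, medication references and examiner utterances.

    Operates on raw (cased, punctuated) text; removals are whole-word
    and case-insensitive.  Absent patterns are a no-op.
    """
    out = text
    open_m, close_m = policy.examiner_markers
    if open_m and close_m:
        span_re = re.compile(
            re.escape(open_m) + r".*?" + re.escape(close_m), re.DOTALL | re.IGNORECASE
        )
        out = span_re.sub(" ", out)
    for pattern in policy.medication_patterns:
        out = re.sub(r"\b" + re.escape(pattern) + r"\b", " ", out, flags=re.IGNORECASE)
    if policy.filler_tokens:
        filler_re = re.compile(
            r"\b(?:" + "|".join(map(re.escape, sorted(policy.filler_tokens))) + r")\b",
            re.IGNORECASE,
        )
        out = filler_re.sub(" ", out)
    return _WS_RE.sub(" ", out).strip()


def prepare(text: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Default document pipeline: strip_nonsemantic then normalize."""
    return normalize(strip_nonsemantic(text, policy), policy)
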