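"""Approach 3 — few-shot prompting of a generative language model.

The harness owns everything around the model call: similarity-based
selection of in-context examples from other patients, construction of
nine instruction paraphrases (all sharing the identical example set and
query), parsing of free-text outputs into a label or score, ensembling
(modal class / mean score over paraphrases), and first-token confidence
(mean probability mass on the "ON"/"OFF" answer tokens across prompts).

Backends implement a minimal contract and are looked up by name.  The
always-available ``stub`` backend is a deterministic keyword-scoring
simulator: it counts ON-pole and OFF-pole symptom vocabulary in the
query transcript and answers accordingly, with a logistic first-token
probability.  It makes the full pipeline runnable and bit-reproducible
offline; adapters for locally hosted instruction models can be
registered at runtime.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .corpus_io import MedState, SCORE_MAX, SCORE_MIN
from .embed import EmbeddingMatrix, cosine_similarity
from .errors import AbstainError, CapabilityError, PoolError, RegistryError
from .vocab import OFF_TERMS, ON_TERMS

# The base classification instruction (paraphrase 0); the ON and OFF
# conditions are explained to the model through the NFS symptom themes.
CLASSIFY_INSTRUCTIONS: tuple[str, ...] = (
    "You will be provided with transcription of speech from people with "
    "Parkinson's Disease. Please assign the class ON or OFF to each text. "
    "Patients in the OFF condition may experience tiredness, lack of energy, "
    "inability to relax, trembling legs, and feel lethargic and low. In the "
    "ON condition, they usually feel full of energy, sure of themselves, "
    "talkative, and a sense of well-being. Please provide only the class "
    "estimate without any additional text.",
    "Below are speech transcriptions from people with Parkinson's Disease. "
    "Label each text with the class ON or OFF. In the OFF condition patients "
    "often report tiredness, lack of energy, inability to relax, trembling "
    "legs, lethargy and low mood. In the ON condition they typically feel "
    "energetic, self-assured, talkative, and experience a sense of "
    "well-being. Reply with the class only, nothing else.",
    "You are given transcriptions of spontaneous speech from Parkinson's "
    "Disease patients. Decide for each text whether the speaker is in the ON "
    "or OFF medication condition. OFF is characterised by tiredness, lack of "
    "energy, inability to relax, trembling legs, lethargy and feeling low; "
    "ON by energy, self-confidence, talkativeness and well-being. Output "
    "only the class.",
    "The following texts are transcribed speech of people with Parkinson's "
    "Disease. Classify each one as ON or OFF. Typical OFF symptoms: "
    "tiredness, lack of energy, inability to relax, trembling legs, "
    "lethargy, low mood. Typical ON symptoms: feeling full of energy, sure "
    "of oneself, talkative, a sense of well-being. Answer with the class "
    "estimate alone.",
    "Read each speech transcription from a person with Parkinson's Disease "
    "and assign the class ON or OFF. Speakers in the OFF state may be tired, "
    "lacking energy, unable to relax, have trembling legs and feel lethargic "
    "and low; speakers in the ON state usually feel energetic, confident, "
    "talkative and well. Provide nothing but the class.",
    "Here are transcriptions of free speech from Parkinson's Disease "
    "patients. For each text, give the class ON or OFF. The OFF condition "
    "involves tiredness, lack of energy, inability to relax, trembling legs, "
    "lethargy and low mood, while the ON condition involves energy, "
    "self-assurance, talkativeness and a feeling of well-being. Return only "
    "the class label.",
    "You will see speech transcriptions of people with Parkinson's Disease. "
    "Determine whether each speaker is ON or OFF medication. OFF speakers "
    "tend to feel tired, without energy, unable to relax, with trembling "
    "legs, lethargic and low; ON speakers tend to feel full of energy, sure "
    "of themselves, talkative, with a sense of well-being. Respond with the "
    "class and no additional text.",
    "Each text below is a transcription of speech from a person with "
    "Parkinson's Disease. Please classify the text as ON or OFF. In OFF "
    "periods patients experience tiredness, lack of energy, inability to "
    "relax, trembling legs, lethargy and low mood; in ON periods they feel "
    "energetic, self-confident, talkative and a sense of well-being. Give "
    "only the class estimate.",
    "Consider the following transcriptions of speech from people with "
    "Parkinson's Disease and assign each the class ON or OFF. Signs of the "
    "OFF condition include tiredness, lack of energy, inability to relax, "
    "trembling legs, lethargy and feeling low; signs of the ON condition "
    "include energy, confidence, talkativeness and well-being. State the "
    "class only.",
)

REGRESS_INSTRUCTIONS: tuple[str, ...] = (
    "You will be provided with transcription of speech from people with "
    "Parkinson's Disease. Please assign a neuropsychiatric state score "
    "between 0 and 60 to each text, where 0 corresponds to a very low mood "
    "and 60 to a very high mood. Please provide only the numeric score "
    "without any additional text.",
    "Below are speech transcriptions from people with Parkinson's Disease. "
    "Rate each text with a neuropsychiatric state score from 0 (very low "
    "mood) to 60 (very high mood). Reply with the number only.",
    "You are given transcriptions of spontaneous speech from Parkinson's "
    "Disease patients. Estimate for each text a neuropsychiatric state "
    "score on a 0-60 scale, 0 meaning a very low mood and 60 a very high "
    "mood. Output only the score.",
    "The following texts are transcribed speech of people with Parkinson's "
    "Disease. Assign each a neuropsychiatric state score between 0 and 60 "
    "(0 = very low mood, 60 = very high mood). Answer with the numeric "
    "estimate alone.",
    "Read each speech transcription from a person with Parkinson's Disease "
    "and give a neuropsychiatric state score from 0 to 60, where higher "
    "values indicate a higher mood. Provide nothing but the number.",
    "Here are transcriptions of free speech from Parkinson's Disease "
    "patients. For each text, predict the neuropsychiatric state score on "
    "a scale of 0 (very low mood) to 60 (very high mood). Return only the "
    "score.",
    "You will see speech transcriptions of people with Parkinson's "
    "Disease. Judge the speaker's neuropsychiatric state on a 0-60 scale "
    "with 0 a very low mood and 60 a very high mood. Respond with the "
    "number and no additional text.",
    "Each text below is a transcription of speech from a person with "
    "Parkinson's Disease. Please score the neuropsychiatric state between "
    "0 and 60, where 0 is a very low mood and 60 a very high mood. Give "
    "only the numeric score.",
    "Consider the following transcriptions of speech from people with "
    "Parkinson's Disease and assign each a neuropsychiatric state score in "
    "the range 0-60 (low mood to high mood). State the score only.",
)

# Self-explanation variant: the terse output request of the base prompt
# is replaced by a request for the decisive keywords.
EXPLAIN_SUFFIX = (
    "In addition to the class prediction, please identify and provide a "
    "list of the keywords or phrases that contributed most to the "
    "classification decision."
)

N_PARAPHRASES = 9

_LABEL_RE = re.compile(r"\b(on|off)\b", re.IGNORECASE)
_NUMBER_RE = re.compile(r"-?\d+(?:\.\d+)?")


@dataclass(frozen=True)
class LLMResponse:
    """One generation: raw text plus optional first-token probabilities."""

    text: str
    first_token_probs: dict[str, float] | None = None


class LLMBackend(Protocol):
    name: str
    deterministic: bool
    supports_token_probs: bool

    def generate(
        self, prompt: str, candidate_tokens: Sequence[str] | None = None
    ) -> LLMResponse: ...


@dataclass(frozen=True)
class PromptBundle:
    """The paraphrase ensemble for one query.

    Every paraphrase embeds the identical in-context example set and the
    identical query; only the instruction wording differs.
    """

    task: str  # "classify" | "regress" | "explain"
    paraphrases: tuple[str, ...]
    n_shots: int
    example_ids: tuple[str, ...]
    query_id: str = "query"

    def __post_init__(self) -> None:
        if not self.paraphrases:
            raise ValueError("empty paraphrase bundle")
        if self.n_shots != len(self.example_ids):
            raise ValueError("n_shots must equal the number of example ids")


@dataclass
class LLMPrediction:
    """Aggregated ensemble output for one query."""

    query_id: str
    task: str
    raw_outputs: tuple[str, ...]
    parsed: tuple[object, ...]  # MedState | float | None per paraphrase
    parse_failures: int
    final_label: MedState | None = None
    final_score: float | None = None
    confidence_on: float | None = None


def select_fewshot(
    query_vec: np.ndarray,
    pool: EmbeddingMatrix,
    pool_patient_ids: Sequence[str],
    k: int,
    exclude_patient: str | None = None,
) -> list[int]:
    """Indices of the k most cosine-similar pool rows, descending.

    Ties break by ascending doc id; k=0 is valid (zero-shot).  The pool
    must already exclude the query patient.
    """
    if len(pool_patient_ids) != pool.n_docs:
        raise ValueError("pool_patient_ids do not align with matrix rows")
    if exclude_patient is not None and exclude_patient in set(pool_patient_ids):
        raise PoolError(f"pool contains recordings of excluded patient {exclude_patient!r}")
    if not 0 <= k <= pool.n_docs:
        raise ValueError(f"k={k} outside 0..{pool.n_docs}")
    if k == 0:
        return []
    sims = [cosine_similarity(query_vec, pool.row(i)) for i in range(pool.n_docs)]
    return sorted(range(pool.n_docs), key=lambda i: (-sims[i], pool.doc_ids[i]))[:k]


def build_prompt(
    task: str,
    examples: Sequence[tuple[str, object]],
    query_text: str,
    paraphrase_index: int = 0,
) -> str:
    """Assemble one prompt: instruction, labelled examples, open query.

    ``examples`` are (text, label-or-score) pairs in presentation order
    (most similar first by convention).  Byte-deterministic.
    """
    if task in ("classify", "explain"):
        instructions = CLASSIFY_INSTRUCTIONS
        slot = "Class"
    elif task == "regress":
        instructions = REGRESS_INSTRUCTIONS
        slot = "Score"
    else:
        raise ValueError(f"unknown task {task!r}")
    if not 0 <= paraphrase_index < len(instructions):
        raise ValueError(
            f"paraphrase_index {paraphrase_index} outside 0..{len(instructions) - 1}"
        )
    instruction = instructions[paraphrase_index]
    if task == "explain":
        # swap the terse-output request for the self-explanation request
        head, _, _ = instruction.rpartition(". ")
        instruction = f"{head}. {EXPLAIN_SUFFIX}"
    parts = [instruction, ""]
    for text, target in examples:
        if target is None:
            raise ValueError("in-context example lacks its label/score")
        value = target.value if isinstance(target, MedState) else f"{float(target):g}"
        parts.append(f"Transcript: {text}")
        parts.append(f"{slot}: {value}")
        parts.append("")
    parts.append(f"Transcript: {query_text}")
    parts.append(f"{slot}:")
    return "\n".join(parts)


def make_bundle(
    task: str,
    examples: Sequence[tuple[str, object]],
    query_text: str,
    example_ids: Sequence[str],
    query_id: str = "query",
    n_paraphrases: int = N_PARAPHRASES,
) -> PromptBundle:
    """Build the paraphrase ensemble (same examples in every paraphrase)."""
    prompts = tuple(
        build_prompt(task, examples, query_text, paraphrase_index=i)
        for i in range(n_paraphrases)
    )
    return PromptBundle(
        task=task,
        paraphrases=prompts,
        n_shots=len(examples),
        example_ids=tuple(example_ids),
        query_id=query_id,
    )


def parse_output(task: str, raw: str) -> MedState | float | None:
    """Parse a generation into a label or score; None on failure.

    Classification: a single standalone ON/OFF token (case-insensitive);
    conflicting tokens or none fail.  Regression: the first numeric
    literal inside [0, 60]; none fails.
    """
    if task in ("classify", "explain"):
        found = {m.group(1).upper() for m in _LABEL_RE.finditer(raw)}
        if len(found) != 1:
            return None
        return MedState(found.pop())
    if task == "regress":
        for m in _NUMBER_RE.finditer(raw):
            value = float(m.group(0))
            if SCORE_MIN <= value <= SCORE_MAX:
                return value
        return None
    raise ValueError(f"unknown task {task!r}")


def first_token_confidence(
    backend: LLMBackend,
    prompts: Sequence[str],
    candidate_tokens: Sequence[str] = (MedState.ON.value, MedState.OFF.value),
) -> dict[str, float]:
    """Mean first-token probability of each candidate across prompts."""
    if not getattr(backend, "supports_token_probs", False):
        raise CapabilityError(f"backend {backend.name!r} provides no token probabilities")
    sums = {tok: 0.0 for tok in candidate_tokens}
    for prompt in prompts:
        resp = backend.generate(prompt, candidate_tokens=candidate_tokens)
        if resp.first_token_probs is None:
            raise CapabilityError(f"backend {backend.name!r} returned no probabilities")
        for tok in candidate_tokens:
            sums[tok] += resp.first_token_probs.get(tok, 0.0)
    n = len(prompts)
    return {tok: s / n for tok, s in sums.items()}


def ensemble_predict(backend: LLMBackend, bundle: PromptBundle) -> LLMPrediction:
    """Run every paraphrase and aggregate.

    Classification: modal label over successful parses; a tie goes to
    the label with the higher mean first-token confidence, or OFF when
    confidences are unavailable.  Regression: mean of parsed scores,
    clipped to [0, 60].  If every paraphrase fails to parse, abstain.
    """
    want_probs = bundle.task in ("classify", "explain") and getattr(
        backend, "supports_token_probs", False
    )
    candidates = (MedState.ON.value, MedState.OFF.value)
    raw: list[str] = []
    parsed: list[object] = []
    prob_on: list[float] = []
    for prompt in bundle.paraphrases:
        resp = backend.generate(prompt, candidate_tokens=candidates if want_probs else None)
        raw.append(resp.text)
        parsed.append(parse_output(bundle.task, resp.text))
        if want_probs and resp.first_token_probs is not None:
            prob_on.append(resp.first_token_probs.get(MedState.ON.value, 0.0))
    successes = [p for p in parsed if p is not None]
    failures = len(parsed) - len(successes)
    if not successes:
        raise AbstainError(
            f"query {bundle.query_id!r}: all {len(parsed)} paraphrases failed to parse"
        )
    pred = LLMPrediction(
        query_id=bundle.query_id,
        task=bundle.task,
        raw_outputs=tuple(raw),
        parsed=tuple(parsed),
        parse_failures=failures,
        confidence_on=float(np.mean(prob_on)) if prob_on else None,
    )
    if bundle.task in ("classify", "explain"):
        n_on = sum(1 for p in successes if p is MedState.ON)
        n_off = len(successes) - n_on
        if n_on > n_off:
            pred.final_label = MedState.ON
        elif n_off > n_on:
            pred.final_label = MedState.OFF
        elif pred.confidence_on is not None:
            pred.final_label = MedState.ON if pred.confidence_on > 0.5 else MedState.OFF
        else:
            pred.final_label = MedState.OFF
    else:
        pred.final_score = float(
            np.clip(np.mean([float(p) for p in successes]), SCORE_MIN, SCORE_MAX)
        )
    return pred


_EXAMPLE_RE = re.compile(
    r"Transcript:\s*(.*?)\n(Class|Score):[ \t]*(\S*)", re.DOTALL
)


class StubLLMBackend:
    """Deterministic keyword-scoring simulator of an instruction model.

    The stub reads the prompt the way the harness writes it: labelled
    ``Transcript:`` examples followed by the open query slot.  For each
    text it computes the fraction of ON-pole terms among the pole-
    vocabulary hits (the symptom themes the instruction itself spells
    out).  The classification answer blends two signals, mimicking
    in-context learning: a logistic in the query's own ON fraction, and
    a proximity-weighted vote of the example labels (examples whose
    fraction is close to the query's count most).  The regression answer
    is the query fraction mapped onto the 0-60 scale, with a tiny
    seed-keyed per-prompt jitter so the nine paraphrases do not agree
    bit-for-bit and the ensembling logic is exercised.  Everything is a
    pure function of (prompt, seed).
    """

    deterministic = True
    supports_token_probs = True

    def __init__(
        self,
        seed: int = 0,
        on_markers: Sequence[str] = ON_TERMS,
        off_markers: Sequence[str] = OFF_TERMS,
        gain: float = 8.0,
        example_bandwidth: float = 0.25,
    ) -> None:
        self.name = "stub"
        self.seed = int(seed)
        self.on_markers = tuple(on_markers)
        self.off_markers = tuple(off_markers)
        self.gain = float(gain)
        self.example_bandwidth = float(example_bandwidth)
        self._on_res = [re.compile(r"\b" + re.escape(m) + r"\b") for m in self.on_markers]
        self._off_res = [re.compile(r"\b" + re.escape(m) + r"\b") for m in self.off_markers]

    def _fraction(self, text: str) -> tuple[float | None, int, int]:
        """ON fraction among pole-term hits; None when no hits."""
        low = text.lower()
        n_on = sum(len(r.findall(low)) for r in self._on_res)
        n_off = sum(len(r.findall(low)) for r in self._off_res)
        total = n_on + n_off
        return (n_on / total if total else None), n_on, n_off

    def _parse_prompt(self, prompt: str):
        stripped = prompt.rstrip()
        if stripped.endswith("Class:"):
            task = "classify"
        elif stripped.endswith("Score:"):
            task = "regress"
        else:
            raise ValueError("stub backend expects a prompt ending in an answer slot")
        segments = _EXAMPLE_RE.findall(prompt)
        if not segments:
            raise ValueError("stub backend found no Transcript: marker")
        *examples, (query, _, _) = segments
        return task, query.strip(), [(text.strip(), value) for text, _, value in examples]

    def _p_on(self, query: str, examples) -> tuple[float, float | None]:
        w_q, _, _ = self._fraction(query)
        if w_q is None:
            return 0.5, None
        p_kw = 1.0 / (1.0 + math.exp(-self.gain * (w_q - 0.5)))
        num = den = 0.0
        for text, value in examples:
            if value not in ("ON", "OFF"):
                continue
            w_e, _, _ = self._fraction(text)
            if w_e is None:
                continue
            weight = 1.0 / (abs(w_e - w_q) + self.example_bandwidth)
            den += weight
            if value == "ON":
                num += weight
        if den == 0.0:
            return p_kw, w_q
        return 0.5 * p_kw + 0.5 * (num / den), w_q

    def generate(
        self, prompt: str, candidate_tokens: Sequence[str] | None = None
    ) -> LLMResponse:
        task, query, examples = self._parse_prompt(prompt)
        if task == "classify":
            p_on, _ = self._p_on(query, examples)
            probs = None
            if candidate_tokens is not None:
                probs = {
                    tok: (
                        p_on
                        if tok.upper() == "ON"
                        else (1.0 - p_on) if tok.upper() == "OFF" else 0.0
                    )
                    for tok in candidate_tokens
                }
            label = "ON" if p_on > 0.5 else "OFF"
            if "keywords" in prompt.lower():
                markers = self.on_markers if label == "ON" else self.off_markers
                hits = [m for m in markers if re.search(r"\b" + re.escape(m) + r"\b", query.lower())]
                text = f"{label}. Keywords: {', '.join(hits[:5])}" if hits else label
            else:
                text = label
            return LLMResponse(text=text, first_token_probs=probs)
        w_q, _, _ = self._fraction(query)
        w = 0.5 if w_q is None else w_q
        digest = hashlib.blake2b(
            prompt.encode("utf-8"), digest_size=4, key=str(self.seed).encode()
        ).digest()
        jitter = (int.from_bytes(digest, "big") / 0xFFFFFFFF - 0.5) * 4.0  # +/- 2 points
        score = float(np.clip(SCORE_MAX * w + jitter, SCORE_MIN, SCORE_MAX))
        return LLMResponse(text=f"{score:.1f}", first_token_probs=None)


_LLM_REGISTRY: dict[str, Callable[..., LLMBackend]] = {"stub": StubLLMBackend}


def register_llm_backend(name: str, factory: Callable[..., LLMBackend]) -> None:
    """Register an adapter for a locally hosted generative model."""
    _LLM_REGISTRY[name] = factory


def llm_backend(name: str, **kwargs) -> LLMBackend:
    """Instantiate a registered LLM backend ("stub" always exists)."""
    try:
        factory = _LLM_REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown LLM backend {name!r}; available: {sorted(_LLM_REGISTRY)}"
        ) from None
    return factory(**kwargs)
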