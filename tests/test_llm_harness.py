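import numpy as np
import pytest

from nfspeech.corpus_io import MedState
from nfspeech.embed import EmbeddingMatrix
from nfspeech.errors import AbstainError, CapabilityError, PoolError, RegistryError
from nfspeech.llm_harness import (
    CLASSIFY_INSTRUCTIONS,
    LLMResponse,
    N_PARAPHRASES,
    PromptBundle,
    StubLLMBackend,
    build_prompt,
    ensemble_predict,
    first_token_confidence,
    llm_backend,
    make_bundle,
    parse_output,
    select_fewshot,
)


class ScriptedBackend:
    """Test double emitting a fixed sequence of responses."""

    name = "scripted"
    deterministic = True

    def __init__(self, responses, probs=None):
        self._responses = list(responses)
        self._probs = probs
        self._i = 0
        self.supports_token_probs = probs is not None

    def generate(self, prompt, candidate_tokens=None):
        text = self._responses[self._i % len(self._responses)]
        p = None
        if self._probs is not None and candidate_tokens is not None:
            p_on = self._probs[self._i % len(self._probs)]
            p = {"ON": p_on, "OFF": 1.0 - p_on}
        self._i += 1
        return LLMResponse(text=text, first_token_probs=p)


def _pool(vectors, ids=None):
    return EmbeddingMatrix(
        vectors=np.asarray(vectors, dtype=float),
        doc_ids=ids or [f"r{i}" for i in range(len(vectors))],
        backend_name="test",
    )


class TestSelectFewshot:
    def test_zero_shot_returns_empty(self):
        pool = _pool([[1.0, 0.0]])
        assert select_fewshot([0.0, 1.0], pool, ["p0"], k=0) == []

    def test_identical_vector_selected_first(self):
        pool = _pool([[0.0, 1.0], [1.0, 0.1], [0.5, 0.5]])
        idx = select_fewshot([1.0, 0.1], pool, ["a", "b", "c"], k=2)
        assert idx[0] == 1

    def test_matches_brute_force_top_k(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n, k = 15, 6
            vectors = rng.normal(size=(n, 5))
            query = rng.normal(size=5)
            pool = _pool(vectors)
            got = select_fewshot(query, pool, [f"p{i}" for i in range(n)], k=k)
            sims = [
                float(np.dot(query, v) / (np.linalg.norm(query) * np.linalg.norm(v)))
                for v in vectors
            ]
            expected = sorted(range(n), key=lambda i: (-sims[i], f"r{i}"))[:k]
            assert got == expected

    def test_k_beyond_pool_rejected(self):
        with pytest.raises(ValueError):
            select_fewshot([1.0, 0.0], _pool([[1.0, 0.0]]), ["p0"], k=2)

    def test_excluded_patient_present_rejected(self):
        with pytest.raises(PoolError):
            select_fewshot([1.0, 0.0], _pool([[1.0, 0.0]]), ["p9"], k=1, exclude_patient="p9")


class TestBuildPrompt:
    def test_zero_shot_base_prompt_layout(self):
        prompt = build_prompt("classify", [], "i feel tired", paraphrase_index=0)
        assert prompt == CLASSIFY_INSTRUCTIONS[0] + "\n\nTranscript: i feel tired\nClass:"

    def test_byte_deterministic(self):
        args = ("classify", [("ex one", MedState.ON)], "query text", 3)
        assert build_prompt(*args) == build_prompt(*args)

    def test_example_slot_count(self):
        examples = [(f"example {i}", MedState.OFF) for i in range(4)]
        prompt = build_prompt("classify", examples, "the query")
        assert prompt.count("Class:") == 5  # 4 labelled + 1 open slot
        assert prompt.rstrip().endswith("Class:")

    def test_regression_uses_score_slots(self):
        prompt = build_prompt("regress", [("ex", 42.0)], "q")
        assert "Score: 42" in prompt
        assert prompt.rstrip().endswith("Score:")

    def test_explain_variant_requests_keywords(self):
        prompt = build_prompt("explain", [], "q")
        assert "keywords or phrases" in prompt
        assert "without any additional text" not in prompt

    def test_unlabelled_example_rejected(self):
        with pytest.raises(ValueError):
            build_prompt("classify", [("ex", None)], "q")

    def test_paraphrases_are_distinct(self):
        prompts = {build_prompt("classify", [], "q", i) for i in range(N_PARAPHRASES)}
        assert len(prompts) == N_PARAPHRASES


class TestParseOutput:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("ON", MedState.ON),
            ("The class is off.", MedState.OFF),
            ("  ON\n", MedState.ON),
            ("ON OFF", None),  # conflicting labels
            ("I cannot classify this", None),
            ("ONWARD", None),  # no standalone token
        ],
    )
    def test_classification_parsing(self, raw, expected):
        assert parse_output("classify", raw) == expected

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("42.5", 42.5),
            ("The score is 12.", 12.0),
            ("100", None),  # out of scale
            ("no idea", None),
            ("65 or maybe 40", 40.0),  # first literal inside the scale
        ],
    )
    def test_regression_parsing(self, raw, expected):
        assert parse_output("regress", raw) == expected


class TestEnsemble:
    def _bundle(self, task="classify", n=3):
        examples = [("ex", MedState.ON if task != "regress" else 30.0)]
        return make_bundle(task, examples, "the query", ["e0"], n_paraphrases=n)

    def test_modal_label(self):
        backend = ScriptedBackend(["ON", "ON", "OFF"])
        pred = ensemble_predict(backend, self._bundle(n=3))
        assert pred.final_label is MedState.ON
        assert pred.parse_failures == 0

    def test_mean_score_of_symmetric_outputs(self):
        scores = [str(s) for s in (10, 15, 20, 25, 30, 35, 40, 45, 50)]
        backend = ScriptedBackend(scores)
        pred = ensemble_predict(backend, self._bundle(task="regress", n=9))
        assert pred.final_score == pytest.approx(30.0)

    def test_parse_failures_counted_but_not_fatal(self):
        backend = ScriptedBackend(["ON", "gibberish", "ON"])
        pred = ensemble_predict(backend, self._bundle(n=3))
        assert pred.parse_failures == 1
        assert pred.final_label is MedState.ON

    def test_all_failures_abstain(self):
        backend = ScriptedBackend(["???", "ON OFF", "unclear"])
        with pytest.raises(AbstainError):
            ensemble_predict(backend, self._bundle(n=3))

    def test_tie_broken_by_first_token_confidence(self):
        backend = ScriptedBackend(["ON", "OFF", "???", "ON OFF"], probs=[0.9, 0.8, 0.7, 0.6])
        pred = ensemble_predict(backend, self._bundle(n=4))
        assert pred.final_label is MedState.ON  # mean confidence 0.75 > 0.5

    def test_tie_without_confidence_goes_off(self):
        backend = ScriptedBackend(["ON", "OFF"])
        pred = ensemble_predict(backend, self._bundle(n=2))
        assert pred.final_label is MedState.OFF

    def test_bundle_shares_examples_across_paraphrases(self):
        bundle = self._bundle(n=9)
        for prompt in bundle.paraphrases:
            assert prompt.count("Transcript: ex") == 1
            assert "Transcript: the query" in prompt

    def test_mismatched_shots_rejected(self):
        with pytest.raises(ValueError):
            PromptBundle(task="classify", paraphrases=("p",), n_shots=2, example_ids=("a",))


class TestFirstTokenConfidence:
    def test_constant_probability(self):
        backend = ScriptedBackend(["ON"], probs=[0.8])
        conf = first_token_confidence(backend, ["p1", "p2"])
        assert conf["ON"] == pytest.approx(0.8)

    def test_mean_over_prompts(self):
        backend = ScriptedBackend(["ON"], probs=[0.6, 1.0])
        conf = first_token_confidence(backend, ["p1", "p2"])
        assert conf["ON"] == pytest.approx(0.8)
        assert conf["ON"] + conf["OFF"] <= 1.0 + 1e-9

    def test_backend_without_probabilities_rejected(self):
        backend = ScriptedBackend(["ON"])
        with pytest.raises(CapabilityError):
            first_token_confidence(backend, ["p"])


class TestStubBackend:
    def _prompt(self, text, task="classify"):
        return build_prompt(task, [], text)

    def test_keyword_polarity_drives_label(self):
        stub = StubLLMBackend()
        on = stub.generate(self._prompt("i feel cheerful lively and strong"))
        off = stub.generate(self._prompt("i feel tired weary and low"))
        assert on.text == "ON"
        assert off.text == "OFF"

    def test_no_keywords_defaults_off_with_half_confidence(self):
        stub = StubLLMBackend()
        resp = stub.generate(self._prompt("the weather is ordinary"), candidate_tokens=("ON", "OFF"))
        assert resp.text == "OFF"
        assert resp.first_token_probs["ON"] == pytest.approx(0.5)

    def test_bit_reproducible(self):
        prompt = self._prompt("i feel tired but cheerful", task="regress")
        a = StubLLMBackend(seed=4).generate(prompt)
        b = StubLLMBackend(seed=4).generate(prompt)
        assert a.text == b.text

    def test_regression_output_tracks_on_fraction(self):
        stub = StubLLMBackend()
        high = float(stub.generate(self._prompt("cheerful lively strong capable", "regress")).text)
        low = float(stub.generate(self._prompt("tired weary low sad", "regress")).text)
        assert high > 45
        assert low < 15

    def test_examples_inform_classification(self):
        # an ambiguous query flanked by OFF-labelled examples with the
        # same mixed vocabulary leans OFF
        examples = [("i feel tired but cheerful today", MedState.OFF)] * 4
        prompt = build_prompt("classify", examples, "i feel cheerful but tired")
        resp = StubLLMBackend().generate(prompt, candidate_tokens=("ON", "OFF"))
        assert resp.first_token_probs["ON"] < 0.5

    def test_explain_prompt_yields_parseable_label_and_keywords(self):
        prompt = build_prompt("explain", [], "i feel tired weary and low")
        resp = StubLLMBackend().generate(prompt)
        assert parse_output("explain", resp.text) is MedState.OFF
        assert "tired" in resp.text

    def test_registry_lookup(self):
        assert llm_backend("stub").name == "stub"
        with pytest.raises(RegistryError, match="no-such-llm"):
            llm_backend("no-such-llm")
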