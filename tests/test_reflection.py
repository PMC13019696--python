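"""The self-reflective generate--verify loop and its termination guarantees."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treerag.backends import (
    ClarifyingReformulator,
    ConjunctionDecomposer,
    LexicalJudge,
    ScriptedJudge,
    StaticGenerator,
    parse_judge_reply,
)
from treerag.index import build_indexes
from treerag.recall import RecallResult, multi_way_recall
from treerag.reflection import (
    BackendSuite,
    ReflectionCaps,
    answer_plain_rag,
    assess_relevance,
    check_helpfulness,
    check_support,
    max_generator_calls,
    run_reflection_loop,
)

approve = lambda: ScriptedJudge(fn=lambda i: True)
reject = lambda: ScriptedJudge(fn=lambda i: False)


def run(synth, question, **kw):
    return run_reflection_loop(
        question,
        synth["kb"],
        synth["keyword_index"],
        synth["vector_index"],
        synth["embedder"],
        **kw,
    )


class TestJudgesAndFilters:
    def test_parse_judge_reply_grammar(self):
        assert parse_judge_reply("YES, clearly") is True
        assert parse_judge_reply("no.") is False
        with pytest.raises(ValueError):
            parse_judge_reply("maybe")

    def test_assess_relevance_keeps_approved_in_order(self, synth):
        kb = synth["kb"]
        q = synth["bank"][0].stem
        result = multi_way_recall(
            kb, synth["keyword_index"], synth["vector_index"], q, synth["embedder"]
        )
        keep = {result.entries[0].unit_id, result.entries[2].unit_id}

        class KeySet:
            def judge(self, subject, context):
                return any(kb.chunks[kb.units[u].chunk_id].text in context for u in keep)

        kept, verdicts = assess_relevance(kb, result, q, KeySet())
        assert set(kept) >= keep
        assert len(verdicts) == len(result.entries)

    def test_assess_relevance_all_rejected(self, synth):
        q = synth["bank"][0].stem
        result = multi_way_recall(
            synth["kb"], synth["keyword_index"], synth["vector_index"], q,
            synth["embedder"],
        )
        kept, _ = assess_relevance(synth["kb"], result, q, reject())
        assert kept == []

    def test_judge_failure_is_negative(self):
        class Boom:
            def judge(self, s, c):
                raise RuntimeError("api down")

        verdict = check_support("draft", ["evidence"], Boom())
        assert verdict.verdict is False and "failure" in verdict.rationale

    def test_support_verbatim_draft_passes_lexical_judge(self):
        evidence = ["the draft repeats this evidence text exactly"]
        assert check_support(evidence[0], evidence, LexicalJudge()).verdict

    def test_support_zero_overlap_fails(self):
        assert not check_support("xyzzy", ["totally different words"], LexicalJudge()).verdict

    def test_helpfulness_mirrors_support(self):
        assert check_helpfulness("contains question words", "question words?",
                                 LexicalJudge()).verdict
        assert not check_helpfulness("nothing shared", "zq wv?", LexicalJudge()).verdict


class TestLoopBranches:
    def test_all_approve_answers_in_one_pass(self, synth):
        gen = StaticGenerator(text="the answer")
        suite = BackendSuite(
            generator=gen, relevance_judge=approve(),
            support_judge=approve(), helpfulness_judge=approve(),
        )
        answer, trace = run(synth, synth["bank"][0].stem, backends=suite)
        assert trace.terminal_status == "answered"
        assert gen.calls == 1
        assert answer == "the answer"

    def test_all_approve_equals_plain_rag(self, synth):
        """With reflection effectively disabled the loop is the plain
        recall-and-generate pipeline."""
        suite = BackendSuite(
            relevance_judge=approve(), support_judge=approve(),
            helpfulness_judge=approve(),
        )
        for item in synth["bank"][:5]:
            reflected, trace = run(synth, item.stem, backends=suite)
            plain, _ = answer_plain_rag(
                item.stem, synth["kb"], synth["keyword_index"],
                synth["vector_index"], synth["embedder"],
            )
            assert trace.terminal_status == "answered"
            assert reflected == plain

    def test_empty_recall_enters_decomposition_before_generation(self, synth):
        gen = StaticGenerator(text="x")
        suite = BackendSuite(generator=gen, relevance_judge=reject(),
                             support_judge=approve(), helpfulness_judge=approve())
        _, trace = run(synth, synth["bank"][0].stem, backends=suite,
                       caps=ReflectionCaps(reform_cap=0))
        steps = trace.branch_sequence()
        assert "decompose" in steps
        assert steps.index("decompose") < len(steps)
        assert "generate" not in steps  # nothing relevant ever survived
        assert trace.terminal_status == "cap_exhausted"
        assert gen.calls == 0

    def test_support_rejection_regenerates_then_reformulates(self, synth):
        gen = StaticGenerator(text="draft")
        caps = ReflectionCaps(regen_cap=3, reform_cap=1)
        suite = BackendSuite(
            generator=gen, relevance_judge=approve(),
            support_judge=reject(), helpfulness_judge=approve(),
        )
        _, trace = run(synth, synth["bank"][0].stem, backends=suite, caps=caps)
        steps = trace.branch_sequence()
        first_reform = steps.index("reformulate")
        # exactly 1 + regen_cap generation events before the reformulation branch
        assert steps[:first_reform].count("generate") == 1
        assert steps[:first_reform].count("regenerate") == 3
        assert trace.terminal_status == "cap_exhausted"
        assert trace.best_effort

    def test_reformulator_identity_still_consumes_credit(self, synth):
        class Identity:
            def reformulate(self, q):
                return q

        suite = BackendSuite(
            relevance_judge=approve(), support_judge=approve(),
            helpfulness_judge=reject(), reformulator=Identity(),
        )
        caps = ReflectionCaps(reform_cap=2)
        _, trace = run(synth, synth["bank"][0].stem, backends=suite, caps=caps)
        assert trace.branch_sequence().count("reformulate") == 2
        assert trace.terminal_status == "cap_exhausted"

    def test_decomposed_subquestions_pool_disjoint_units(self, synth):
        """A compound question split on ' and ' recalls the union of both
        sub-questions' surviving evidence."""
        kb, points = synth["kb"], synth["points"]
        keys = sorted(points)
        a, b = points[keys[0]], points[keys[-1]]
        qa = f"what involves {' '.join(a.cluster[:5])}"
        qb = f"what involves {' '.join(b.cluster[:5])}"

        class FirstPassEmpty:
            """Reject everything on the compound question, approve afterwards."""

            def __init__(self):
                self.seen_decompose = False

            def judge(self, subject, context):
                return self.seen_decompose

        judge = FirstPassEmpty()

        class Decomposer:
            def decompose(self, q):
                judge.seen_decompose = True
                return [qa, qb]

        suite = BackendSuite(
            relevance_judge=judge, support_judge=approve(),
            helpfulness_judge=approve(), decomposer=Decomposer(),
        )
        answer, trace = run(synth, f"{qa} and {qb}", backends=suite)
        assert "decompose" in trace.branch_sequence()
        assert trace.terminal_status == "answered"

    def test_answer_can_be_none_when_no_draft_possible(self, synth):
        suite = BackendSuite(relevance_judge=reject())
        answer, trace = run(synth, synth["bank"][0].stem, backends=suite,
                            caps=ReflectionCaps(reform_cap=1, decomp_cap=0))
        assert answer is None
        assert trace.terminal_status == "cap_exhausted"
        assert not trace.best_effort


class TestTermination:
    @given(
        rel=st.integers(0, 2**16 - 1),
        sup=st.integers(0, 2**16 - 1),
        hlp=st.integers(0, 2**16 - 1),
        caps=st.tuples(st.integers(0, 3), st.integers(0, 2), st.integers(0, 1)),
    )
    @settings(max_examples=50, deadline=None)
    def test_halts_within_call_bounds_for_any_judge_table(
        self, synth, rel, sup, hlp, caps
    ):
        """For arbitrary judge behaviors (bitmask truth tables over the call
        index) the loop terminates and the generator-call bound holds."""
        regen, reform, decomp = caps
        c = ReflectionCaps(regen_cap=regen, reform_cap=reform, decomp_cap=decomp)
        gen = StaticGenerator(text="draft words")
        suite = BackendSuite(
            generator=gen,
            relevance_judge=ScriptedJudge(fn=lambda i: bool((rel >> (i % 16)) & 1)),
            support_judge=ScriptedJudge(fn=lambda i: bool((sup >> (i % 16)) & 1)),
            helpfulness_judge=ScriptedJudge(fn=lambda i: bool((hlp >> (i % 16)) & 1)),
        )
        _, trace = run(synth, synth["bank"][1].stem, backends=suite, caps=c)
        assert trace.terminal_status in ("answered", "cap_exhausted")
        assert gen.calls <= max_generator_calls(c)

    def test_trace_replay_reproduces_branch_sequence(self, synth):
        """Feeding the recorded verdicts back through scripted judges yields
        the identical branch sequence (trace soundness)."""
        suite = BackendSuite(
            relevance_judge=ScriptedJudge(fn=lambda i: i % 3 != 0),
            support_judge=ScriptedJudge(fn=lambda i: i % 2 == 1),
            helpfulness_judge=ScriptedJudge(fn=lambda i: True),
            generator=StaticGenerator(text="draft"),
        )
        _, trace = run(synth, synth["bank"][2].stem, backends=suite)
        by_kind = {"relevance": [], "support": [], "helpfulness": []}
        for event in trace.events:
            for v in event.verdicts:
                by_kind[v.kind].append(v.verdict)
        replay_suite = BackendSuite(
            relevance_judge=ScriptedJudge(verdicts=by_kind["relevance"] or [True]),
            support_judge=ScriptedJudge(verdicts=by_kind["support"] or [True]),
            helpfulness_judge=ScriptedJudge(verdicts=by_kind["helpfulness"] or [True]),
            generator=StaticGenerator(text="draft"),
        )
        _, replayed = run(synth, synth["bank"][2].stem, backends=replay_suite)
        assert replayed.branch_sequence() == trace.branch_sequence()
        assert replayed.terminal_status == trace.terminal_status


class TestOfflineBackends:
    def test_conjunction_decomposer(self):
        subs = ConjunctionDecomposer().decompose("what is A and what is B?")
        assert subs == ["what is A?", "what is B?"]

    def test_echo_decomposer_single(self):
        assert ConjunctionDecomposer().decompose("plain question?") == ["plain question?"]

    def test_reformulator_appends_clarifier(self):
        out = ClarifyingReformulator().reformulate("why?")
        assert out.startswith("why?") and len(out) > len("why?")
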