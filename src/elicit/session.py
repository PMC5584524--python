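"""Self-administered elicitation session workflow.

A session runs three sections — introduction (with electronic consent),
training (probability primer, a practice question, a reminder about common
judgement biases) and the questionnaire (demographics, a seed question with
a knowable answer, the main question with live consistency checking and a
face-validity loop, and a certainty rating on a visual analogue scale).

The interactive channel and the clock are injected abstractions so the whole
workflow is testable headlessly from a scripted transcript: the same script
and the same clock always produce an identical session record, which enables
golden-file tests.  The command line binds them to terminal prompts and a
monotonic clock.

Per-section times are recorded for training and questionnaire; the total is
their sum.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

from .hybrid import HistogramDistribution, HybridSummaries, build_histogram
from .quantities import QuantityDefinition
from .validation import RULE_IDS, ValidationReport, confirm_warnings, validate

# ---------------------------------------------------------------------------
# injected abstractions


class ChannelClosed(Exception):
    """The interactive channel ended before the session completed."""


class SessionInterrupted(Exception):
    """Session ended early; carries the partial record (persisted if asked)."""

    def __init__(self, message: str, record: "SessionRecord"):
        super().__init__(message)
        self.record = record


class ScriptedChannel:
    """A prompt channel that replays a fixed list of answers.

    Everything shown and asked is appended to ``transcript`` so tests can
    assert on the dialogue; reading past the script raises
    :class:`ChannelClosed`.
    """

    def __init__(self, answers: list[str]):
        self.answers = list(answers)
        self._pos = 0
        self.transcript: list[tuple[str, str]] = []

    def show(self, text: str) -> None:
        self.transcript.append(("show", text))

    def ask(self, prompt: str) -> str:
        if self._pos >= len(self.answers):
            raise ChannelClosed(f"script exhausted at prompt: {prompt!r}")
        answer = self.answers[self._pos]
        self._pos += 1
        self.transcript.append(("ask", prompt + " -> " + answer))
        return answer


class TerminalChannel:
    """Binds the session to an interactive terminal."""

    def show(self, text: str) -> None:
        print(text)

    def ask(self, prompt: str) -> str:
        try:
            return input(prompt + " ")
        except EOFError as exc:
            raise ChannelClosed("terminal input closed") from exc


class ManualClock:
    """An injectable clock advanced explicitly by tests."""

    def __init__(self, start: float = 0.0):
        self.now = float(start)

    def advance(self, seconds: float) -> None:
        self.now += float(seconds)

    def __call__(self) -> float:
        return self.now


class TickingClock:
    """A scripted clock that advances by fixed increments on each reading."""

    def __init__(self, increments: list[float], start: float = 0.0):
        self._incs = list(increments)
        self.now = float(start)
        self._i = 0

    def __call__(self) -> float:
        value = self.now
        if self._i < len(self._incs):
            self.now += self._incs[self._i]
            self._i += 1
        return value


def monotonic_clock() -> float:
    return _time.monotonic()


# ---------------------------------------------------------------------------
# configuration and record types


@dataclass(frozen=True)
class DemographicItem:
    item_id: str
    prompt: str
    answer_kind: str  # "choice" | "integer" | "free_text"
    choices: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.answer_kind not in ("choice", "integer", "free_text"):
            raise ValueError(f"unknown answer_kind {self.answer_kind!r}")
        if self.answer_kind == "choice" and not self.choices:
            raise ValueError(f"choice item {self.item_id!r} needs choices")


@dataclass(frozen=True)
class SessionConfig:
    """Everything a session needs: texts, questions and demographic items."""

    intro_text: str
    training_text: str
    example_question: QuantityDefinition
    demographic_items: tuple[DemographicItem, ...]
    seed_question: QuantityDefinition
    main_question: QuantityDefinition
    vas_prompt: str = "On a scale of 0-100, how certain are you about your answer?"
    bias_reminder_text: str = (
        "Before you answer, be aware of common judgement biases: anchoring on "
        "the first number that comes to mind, availability of memorable cases, "
        "and overconfidence (ranges that are too narrow). Consider reasons "
        "your first estimate could be wrong."
    )
    seed_answer_kind: str = "single_value"  # or "hybrid"

    def __post_init__(self) -> None:
        names = {
            self.example_question.name,
            self.seed_question.name,
            self.main_question.name,
        }
        if len(names) != 3:
            raise ValueError("example, seed and main questions must be distinct")
        ids = [d.item_id for d in self.demographic_items]
        if len(ids) != len(set(ids)):
            raise ValueError(f"demographic item_ids must be unique, got {ids}")
        if self.seed_answer_kind not in ("single_value", "hybrid"):
            raise ValueError(f"unknown seed_answer_kind {self.seed_answer_kind!r}")


@dataclass(frozen=True)
class RawAnswer:
    """A typed hybrid answer before validation (may be inconsistent)."""

    L: float
    M: float
    H: float
    p: tuple[float, float, float, float]  # fractions as typed (percent / 100)

    def to_json(self) -> dict:
        return {"L": self.L, "M": self.M, "H": self.H, "p": list(self.p)}

    @classmethod
    def from_json(cls, d: dict) -> "RawAnswer":
        return cls(L=d["L"], M=d["M"], H=d["H"], p=tuple(d["p"]))


@dataclass
class SessionRecord:
    """Full transcript of one elicitation session."""

    session_id: str
    mode: str  # "face_to_face" | "distance"
    consent_given: bool
    consent_timestamp: float | None
    demographics: dict = field(default_factory=dict)
    training_attempts: list = field(default_factory=list)  # (RawAnswer, report, accepted)
    seed_answer: object = None  # float or RawAnswer per config
    main_answer_history: list = field(default_factory=list)  # (RawAnswer, report, confirmed)
    final_main_answer: HybridSummaries | None = None
    vas_certainty: float | None = None
    timings: dict = field(default_factory=dict)  # training, questionnaire, total (s)
    status: str = "draft"  # "complete" | "aborted" | "draft"

    def check_invariants(self) -> None:
        if self.status == "complete":
            if not self.consent_given:
                raise ValueError("complete session without consent")
            confirmed = [a for a in self.main_answer_history if a[2]]
            if not confirmed:
                raise ValueError("complete session with no confirmed main answer")
            last = confirmed[-1][0]
            fin = self.final_main_answer
            if fin is None or (fin.L, fin.M, fin.H, fin.p) != (
                last.L,
                last.M,
                last.H,
                last.p,
            ):
                raise ValueError(
                    "final_main_answer does not equal the last confirmed history entry"
                )
            t = self.timings
            if any(t.get(k, -1) < 0 for k in ("training", "questionnaire", "total")):
                raise ValueError("timings must be present and non-negative")
            if abs(t["total"] - (t["training"] + t["questionnaire"])) > 1.0:
                raise ValueError("total must equal training + questionnaire within 1 s")


# ---------------------------------------------------------------------------
# session driver


def _ask_number(channel, prompt: str, *, integer: bool = False) -> float:
    while True:
        raw = channel.ask(prompt)
        try:
            return int(raw) if integer else float(raw)
        except ValueError:
            channel.show(f"Please enter a number (got {raw!r}).")


def _ask_yes_no(channel, prompt: str) -> bool:
    while True:
        raw = channel.ask(prompt + " [yes/no]").strip().lower()
        if raw in ("y", "yes"):
            return True
        if raw in ("n", "no"):
            return False
        channel.show("Please answer yes or no.")


def _elicit_raw(channel, question: QuantityDefinition) -> RawAnswer:
    channel.show(question.question_text)
    unit = (
        f"a count out of {question.n_total}"
        if question.display_mode == "count_out_of_n"
        else "a value on the scale"
    )
    channel.show(
        f"Answer with {unit} between {question.scale_min:g} and {question.scale_max:g}."
    )
    L = _ask_number(channel, "Lower plausible limit L:")
    M = _ask_number(channel, "Most likely value (mode) M:")
    H = _ask_number(channel, "Upper plausible limit H:")
    p = []
    labels = [
        ("L", "(L+M)/2"),
        ("(L+M)/2", "M"),
        ("M", "(M+H)/2"),
        ("(M+H)/2", "H"),
    ]
    channel.show("Allocate probability (in whole percent, summing to 100) to:")
    for lo, hi in labels:
        p.append(_ask_number(channel, f"  interval {lo} to {hi} (%):") / 100.0)
    return RawAnswer(L=L, M=M, H=H, p=tuple(p))


def _answer_loop(channel, question: QuantityDefinition, history: list) -> HybridSummaries:
    """Elicit until an answer passes validation, warnings are confirmed and
    the rendered histogram has face validity; every attempt is recorded."""
    while True:
        raw = _elicit_raw(channel, question)
        report = validate(raw.L, raw.M, raw.H, raw.p, question)
        if report.failed_errors:
            for rid in RULE_IDS:
                c = report[rid]
                if not c.passed:
                    channel.show(f"[{c.severity}] {rid}: {c.message}")
            history.append((raw, report, False))
            channel.show("Please revise your answer.")
            continue
        confirmations = set()
        confirmed_all = True
        for rid in sorted(report.failed_warnings):
            c = report[rid]
            if _ask_yes_no(channel, f"[warning] {c.message}. Keep this answer anyway?"):
                confirmations.add(rid)
            else:
                confirmed_all = False
                break
        if not confirmed_all:
            history.append((raw, report, False))
            channel.show("Please revise your answer.")
            continue
        accepted, msg = confirm_warnings(report, confirmations)
        assert accepted, msg
        summaries = HybridSummaries(L=raw.L, M=raw.M, H=raw.H, p=raw.p)
        channel.show(render_feedback(build_histogram(summaries, question)))
        if _ask_yes_no(channel, "Does this histogram represent your belief?"):
            history.append((raw, report, True))
            return summaries
        history.append((raw, report, False))
        channel.show("Please revise your answer.")


def run_session(
    config: SessionConfig,
    channel,
    clock=monotonic_clock,
    *,
    session_id: str = "session",
    mode: str = "face_to_face",
    draft_path: str | Path | None = None,
) -> SessionRecord:
    """Drive a complete elicitation session over the given channel.

    On a refused consent the session aborts with a partial record flagged
    not analyzable; if the channel closes mid-session a resumable draft is
    persisted to ``draft_path`` (when given) and
    :class:`SessionInterrupted` is raised carrying the partial record.
    """
    if mode not in ("face_to_face", "distance"):
        raise ValueError(f"unknown mode {mode!r}")
    record = SessionRecord(
        session_id=session_id, mode=mode, consent_given=False, consent_timestamp=None
    )
    try:
        # I. introduction and consent
        channel.show(config.intro_text)
        consent = _ask_yes_no(channel, "Do you consent to take part?")
        record.consent_timestamp = clock()
        record.consent_given = consent
        if not consent:
            record.status = "aborted"
            channel.show("Consent refused; the session cannot continue.")
            return record

        # II. training
        t0 = clock()
        channel.show(config.training_text)
        channel.show("Practice question - your answer is not analysed:")
        _answer_loop(channel, config.example_question, record.training_attempts)
        channel.show(config.bias_reminder_text)
        t1 = clock()

        # III. questionnaire
        for item in config.demographic_items:
            if item.answer_kind == "integer":
                value = int(_ask_number(channel, item.prompt, integer=True))
            elif item.answer_kind == "choice":
                while True:
                    raw = channel.ask(f"{item.prompt} ({'/'.join(item.choices)})")
                    if raw in item.choices:
                        value = raw
                        break
                    channel.show(f"Please choose one of: {', '.join(item.choices)}")
            else:
                value = channel.ask(item.prompt)
            record.demographics[item.item_id] = {
                "kind": item.answer_kind,
                "value": value,
            }

        if config.seed_answer_kind == "single_value":
            channel.show(config.seed_question.question_text)
            record.seed_answer = _ask_number(channel, "Your answer:")
        else:
            seed_hist: list = []
            record.seed_answer = RawAnswer(
                *_summaries_tuple(_answer_loop(channel, config.seed_question, seed_hist))
            )

        summaries = _answer_loop(channel, config.main_question, record.main_answer_history)
        record.final_main_answer = summaries

        channel.show(config.vas_prompt)
        while True:
            vas = _ask_number(channel, "Certainty (0-100):")
            if 0 <= vas <= 100:
                break
            channel.show("Please enter a value between 0 and 100.")
        record.vas_certainty = float(vas)
        t2 = clock()

        record.timings = {
            "training": t1 - t0,
            "questionnaire": t2 - t1,
            "total": (t1 - t0) + (t2 - t1),
        }
        record.status = "complete"
        record.check_invariants()
        return record
    except ChannelClosed as exc:
        record.status = "draft"
        if draft_path is not None:
            save_record(record, draft_path)
        raise SessionInterrupted(f"channel closed: {exc}", record) from exc


def _summaries_tuple(s: HybridSummaries):
    return s.L, s.M, s.H, s.p


# ---------------------------------------------------------------------------
# feedback rendering

BAR_WIDTH = 40  # characters for the highest-density bar


def render_feedback(h: HistogramDistribution) -> str:
    """Deterministic fixed-width text bars, one per bin, scaled by density.

    Bars are proportional to probability density (not bin probability), the
    quantity the histogram actually plots; near-zero bins still get a
    one-character bar so every interval stays visible.
    """
    d = h.densities
    top = d.max()
    lines = ["Your belief, as probability density over the four intervals:"]
    for i in range(4):
        width = max(1, int(round(BAR_WIDTH * d[i] / top))) if top > 0 else 1
        lines.append(
            f"[{h.edges[i]:8.4g}, {h.edges[i + 1]:8.4g})  "
            f"{100 * h.probs[i]:5.1f}%  " + "#" * width
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# persistence

_SCHEMA_VERSION = 1

_REQUIRED_FIELDS = [
    "schema_version",
    "session_id",
    "mode",
    "consent_given",
    "consent_timestamp",
    "demographics",
    "training_attempts",
    "seed_answer",
    "main_answer_history",
    "final_main_answer",
    "vas_certainty",
    "timings",
    "status",
]


class RecordParseError(ValueError):
    """A persisted session record does not match the published schema."""


def _attempt_to_json(entry) -> dict:
    raw, report, flag = entry
    return {
        "answer": raw.to_json(),
        "report": report.to_json(),
        "confirmed": bool(flag),
    }


def _attempt_from_json(d: dict, path: str):
    for key in ("answer", "report", "confirmed"):
        if key not in d:
            raise RecordParseError(f"missing field at {path}.{key}")
    return (
        RawAnswer.from_json(d["answer"]),
        ValidationReport.from_json(d["report"]),
        bool(d["confirmed"]),
    )


def record_to_json(record: SessionRecord, *, anonymize: bool = False) -> dict:
    demographics = {}
    for k, v in record.demographics.items():
        if anonymize and v.get("kind") == "free_text":
            continue  # free-text answers may identify the expert
        demographics[k] = dict(v)
    seed = record.seed_answer
    if isinstance(seed, RawAnswer):
        seed = {"kind": "hybrid", **seed.to_json()}
    fin = record.final_main_answer
    return {
        "schema_version": _SCHEMA_VERSION,
        "session_id": record.session_id,
        "mode": record.mode,
        "consent_given": record.consent_given,
        "consent_timestamp": record.consent_timestamp,
        "demographics": demographics,
        "training_attempts": [_attempt_to_json(a) for a in record.training_attempts],
        "seed_answer": seed,
        "main_answer_history": [_attempt_to_json(a) for a in record.main_answer_history],
        "final_main_answer": None
        if fin is None
        else {"L": fin.L, "M": fin.M, "H": fin.H, "p": list(fin.p)},
        "vas_certainty": record.vas_certainty,
        "timings": dict(record.timings),
        "status": record.status,
    }


def save_record(
    record: SessionRecord, path: str | Path, *, anonymize: bool = False
) -> None:
    doc = record_to_json(record, anonymize=anonymize)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def record_from_json(doc: dict) -> SessionRecord:
    if not isinstance(doc, dict):
        raise RecordParseError("record document must be a JSON object at $")
    for f in _REQUIRED_FIELDS:
        if f not in doc:
            raise RecordParseError(f"missing field at $.{f}")
    if doc["schema_version"] != _SCHEMA_VERSION:
        raise RecordParseError(
            f"unsupported schema_version {doc['schema_version']!r} at $.schema_version"
        )
    seed = doc["seed_answer"]
    if isinstance(seed, dict):
        seed = RawAnswer.from_json(seed)
    fin = doc["final_main_answer"]
    final = None
    if fin is not None:
        for key in ("L", "M", "H", "p"):
            if key not in fin:
                raise RecordParseError(f"missing field at $.final_main_answer.{key}")
        final = HybridSummaries(L=fin["L"], M=fin["M"], H=fin["H"], p=tuple(fin["p"]))
    return SessionRecord(
        session_id=doc["session_id"],
        mode=doc["mode"],
        consent_given=doc["consent_given"],
        consent_timestamp=doc["consent_timestamp"],
        demographics=doc["demographics"],
        training_attempts=[
            _attempt_from_json(a, f"$.training_attempts[{i}]")
            for i, a in enumerate(doc["training_attempts"])
        ],
        seed_answer=seed,
        main_answer_history=[
            _attempt_from_json(a, f"$.main_answer_history[{i}]")
            for i, a in enumerate(doc["main_answer_history"])
        ],
        final_main_answer=final,
        vas_certainty=doc["vas_certainty"],
        timings=doc["timings"],
        status=doc["status"],
    )


def load_record(path: str | Path) -> SessionRecord:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RecordParseError(f"invalid JSON in {path}: {exc}") from exc
    return record_from_json(doc)


# ---------------------------------------------------------------------------
# default configuration (a worked questionnaire about alcohol-related
# fatty liver in primary care, usable as a fixture and CLI default)


def default_config() -> SessionConfig:
    """A complete example configuration for a primary-care elicitation.

    The main question asks what proportion of patients diagnosed with
    alcohol-related hepatic steatosis would stop or significantly reduce
    drinking on brief GP advice alone; the seed question (a quantity with a
    knowable answer, used to gauge judgement) asks about last-week alcohol
    consumption in the adult population of Great Britain.
    """
    example = QuantityDefinition(
        name="example_rain",
        question_text=(
            "Practice: out of 100 days like tomorrow, on how many do you think "
            "it would rain in your town?"
        ),
        scale_min=0,
        scale_max=100,
        display_mode="count_out_of_n",
        n_total=100,
    )
    seed = QuantityDefinition(
        name="seed_alcohol_last_week",
        question_text=(
            "Consider all adults (aged 16 and over) in Great Britain. What "
            "percentage of them do you think drank alcohol in the last week?"
        ),
        scale_min=0,
        scale_max=100,
        display_mode="proportion_percent",
    )
    main = QuantityDefinition(
        name="steatosis_reduction",
        question_text=(
            "Around a fifth of heavy drinkers develop fatty liver (hepatic "
            "steatosis). The condition can be fatal if drinking continues but "
            "is reversible if alcohol consumption stops or falls "
            "substantially. GPs can deliver brief (5-10 minute) advice during "
            "a consultation. Consider 100 randomly selected patients in Great "
            "Britain diagnosed with hepatic steatosis due to alcohol. How "
            "many of them would stop OR significantly reduce their drinking "
            "on learning of their diagnosis, with no intervention beyond the "
            "GP's advice?"
        ),
        scale_min=0,
        scale_max=100,
        display_mode="count_out_of_n",
        n_total=100,
    )
    demo = (
        DemographicItem("gender", "Your gender:", "choice", ("female", "male", "other", "prefer_not_to_say")),
        DemographicItem("age_group", "Your age group:", "choice", ("<35", "35-44", "45-54", "55+")),
        DemographicItem("elicitation_experience", "Have you taken part in an elicitation before?", "choice", ("yes", "no")),
        DemographicItem("statistics_knowledge", "Rate your knowledge of statistics (1-5):", "integer"),
        DemographicItem("years_as_gp", "Number of years working as a GP:", "integer"),
        DemographicItem(
            "alcohol_cases_per_month",
            "Approximately how many patients with (known or suspected) "
            "alcohol-related health problems do you see in an average month?",
            "free_text",
        ),
    )
    return SessionConfig(
        intro_text=(
            "Welcome. This questionnaire asks for your expert judgement about "
            "an uncertain quantity. Your answers will be recorded and "
            "anonymised in any public report."
        ),
        training_text=(
            "Training: you will express your belief as a probability "
            "distribution. First give the lowest and highest values you find "
            "plausible (L and H) and your single most likely value (M). The "
            "ranges L-M and M-H are then each split in half, and you spread "
            "100% of probability over the four resulting intervals."
        ),
        example_question=example,
        demographic_items=demo,
        seed_question=seed,
        main_question=main,
    )
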