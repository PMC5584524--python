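"""Session workflow: scripted replay, timing capture, persistence, feedback."""

import json

import pytest

from elicit import (
    HybridSummaries,
    ScriptedChannel,
    build_histogram,
    default_config,
    load_record,
    render_feedback,
    run_session,
    save_record,
)
from elicit.session import (
    RecordParseError,
    SessionInterrupted,
    TickingClock,
    record_to_json,
)

# a complete, well-behaved transcript against the default configuration:
# consent; one valid training attempt (confirmed); six demographic answers;
# seed value; an invalid main answer (sums to 90%), then a valid one
# (confirmed); a VAS rating.
FULL_SCRIPT = [
    "yes",
    "10", "30", "60", "20", "40", "30", "10", "yes",
    "female", "45-54", "no", "4", "12", "about 15",
    "57",
    "20", "40", "80", "10", "40", "30", "10",
    "20", "40", "80", "10", "40", "35", "15", "yes",
    "80",
]


def run_full_session(clock=None):
    cfg = default_config()
    clk = clock if clock is not None else TickingClock([0.0, 300.0, 280.0, 0.0])
    return run_session(
        cfg, ScriptedChannel(FULL_SCRIPT), clk, session_id="demo", mode="distance"
    )


class TestRunSession:
    def test_revision_bookkeeping(self):
        record = run_full_session()
        assert record.status == "complete"
        assert len(record.main_answer_history) == 2
        first, second = record.main_answer_history
        assert first[2] is False and not first[1].overall_valid
        assert second[2] is True and second[1].overall_valid
        assert record.final_main_answer == HybridSummaries(
            20.0, 40.0, 80.0, (0.10, 0.40, 0.35, 0.15)
        )

    def test_timings_from_injected_clock(self):
        record = run_full_session(TickingClock([0.0, 300.0, 280.0, 0.0]))
        assert record.timings == {
            "training": 300.0,
            "questionnaire": 280.0,
            "total": 580.0,
        }

    def test_seed_and_vas_captured(self):
        record = run_full_session()
        assert record.seed_answer == 57.0
        assert record.vas_certainty == 80.0
        assert record.demographics["years_as_gp"]["value"] == 12
        assert record.demographics["alcohol_cases_per_month"]["value"] == "about 15"

    def test_consent_refused_records_nothing(self):
        cfg = default_config()
        record = run_session(cfg, ScriptedChannel(["no"]), TickingClock([0.0]))
        assert record.status == "aborted"
        assert record.consent_given is False
        assert record.demographics == {}
        assert record.training_attempts == []
        assert record.main_answer_history == []
        assert record.final_main_answer is None

    def test_channel_closed_persists_resumable_draft(self, tmp_path):
        cfg = default_config()
        draft = tmp_path / "draft.json"
        with pytest.raises(SessionInterrupted):
            run_session(
                cfg,
                ScriptedChannel(["yes", "10", "30"]),  # dies mid-training
                TickingClock([0.0]),
                draft_path=draft,
            )
        rec = load_record(draft)
        assert rec.status == "draft"
        assert rec.consent_given is True

    def test_warning_confirmation_path(self):
        """A full-range answer needs an explicit confirmation to be kept."""
        cfg = default_config()
        # main question on [0, 100]: L=0, H=100 triggers NOT_FULL_RANGE
        script = [
            "yes",
            "10", "30", "60", "20", "40", "30", "10", "yes",
            "female", "45-54", "no", "4", "12", "about 15",
            "57",
            "0", "40", "100", "10", "40", "35", "15", "yes", "yes",
            "80",
        ]
        record = run_session(
            cfg, ScriptedChannel(script), TickingClock([0.0, 10.0, 10.0, 0.0])
        )
        assert record.status == "complete"
        (raw, report, confirmed), = record.main_answer_history
        assert confirmed and "NOT_FULL_RANGE" in report.failed_warnings

    def test_replay_is_deterministic(self):
        a = record_to_json(run_full_session())
        b = record_to_json(run_full_session())
        assert a == b


class TestRenderFeedback:
    def test_tallest_bar_on_highest_density_bin(self):
        h = build_histogram(HybridSummaries(0.2, 0.4, 0.8, (0.10, 0.40, 0.35, 0.15)))
        lines = render_feedback(h).splitlines()[1:]
        widths = [line.count("#") for line in lines]
        assert widths[1] == max(widths)
        # bars proportional to density (1, 4, 1.75, 0.75)
        assert widths[0] == round(widths[1] / 4)

    def test_rendering_is_deterministic(self):
        h = build_histogram(HybridSummaries(0.2, 0.4, 0.8, (0.10, 0.40, 0.35, 0.15)))
        assert render_feedback(h) == render_feedback(h)

    def test_near_zero_bin_keeps_minimum_bar(self):
        h = build_histogram(HybridSummaries(0.2, 0.4, 0.8, (0.001, 0.499, 0.35, 0.15)))
        lines = render_feedback(h).splitlines()[1:]
        assert min(line.count("#") for line in lines) >= 1


class TestPersistence:
    def test_round_trip_field_for_field(self, tmp_path):
        record = run_full_session()
        path = tmp_path / "record.json"
        save_record(record, path)
        assert record_to_json(load_record(path)) == record_to_json(record)

    def test_golden_record_byte_stable(self, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_record(run_full_session(), p1)
        save_record(run_full_session(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_names_missing_field(self, tmp_path):
        record = run_full_session()
        path = tmp_path / "record.json"
        save_record(record, path)
        doc = json.loads(path.read_text())
        del doc["timings"]
        path.write_text(json.dumps(doc))
        with pytest.raises(RecordParseError, match=r"\$\.timings"):
            load_record(path)

    def test_corrupt_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "record.json"
        path.write_text('{"schema_version": 1, "session_id"')
        with pytest.raises(RecordParseError, match="invalid JSON"):
            load_record(path)

    def test_anonymize_strips_free_text_only(self, tmp_path):
        record = run_full_session()
        path = tmp_path / "anon.json"
        save_record(record, path, anonymize=True)
        doc = json.loads(path.read_text())
        assert "alcohol_cases_per_month" not in doc["demographics"]
        assert "years_as_gp" in doc["demographics"]
        assert doc["final_main_answer"] is not None

    def test_record_invariants_enforced(self):
        record = run_full_session()
        record.timings = {"training": 10.0, "questionnaire": 10.0, "total": 100.0}
        with pytest.raises(ValueError, match="within 1 s"):
            record.check_invariants()


class TestRecordExport:
    def test_completed_records_flatten_to_panel_csv(self, tmp_path):
        from elicit import export_records_csv

        rec = run_full_session()
        path = tmp_path / "answers.csv"
        df = export_records_csv([rec], path)
        assert list(df.columns) == [
            "expert_id", "L", "M", "H", "p1", "p2", "p3", "p4",
            "vas", "training_s", "questionnaire_s",
        ]
        row = df.iloc[0]
        assert row.expert_id == "demo"
        assert (row.L, row.M, row.H) == (20.0, 40.0, 80.0)
        assert [row.p1, row.p2, row.p3, row.p4] == [10.0, 40.0, 35.0, 15.0]
        assert row.vas == 80.0
        assert (row.training_s, row.questionnaire_s) == (300.0, 280.0)
        assert path.exists()

    def test_incomplete_records_skipped(self, tmp_path):
        from elicit import export_records_csv, default_config

        aborted = run_session(
            default_config(), ScriptedChannel(["no"]), TickingClock([0.0])
        )
        df = export_records_csv([aborted], tmp_path / "none.csv")
        assert len(df) == 0
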