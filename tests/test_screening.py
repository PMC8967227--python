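"""Screening orchestration: rows, brackets, redesign deltas, density."""

import dataclasses

import numpy as np
import pytest

from pestiscreen import (
    Bracket,
    Compound,
    DEFAULT_BRACKETS,
    FrameworkConfig,
    bracket_counts,
    compare_redesign,
    density_summary,
    generate,
    GeneratorParams,
    screen,
)
from pestiscreen.errors import (
    ComparabilityError,
    ConfigurationError,
    ValidationError,
)
from pestiscreen.screening import (
    EcotoxSemaphore,
    ElumoSemaphore,
    PhotodegSemaphore,
    ecotox_semaphore,
    elumo_semaphore,
    photodeg_semaphore,
)


def _twin_compounds():
    kwargs = dict(e_homo=-6.0, e_lumo=-0.5, log_d=2.0)
    return [Compound(id="a", **kwargs), Compound(id="b", **kwargs)]


class TestScreen:
    def test_identical_compounds_tie_at_50(self, small_panel):
        report = screen(_twin_compounds(), small_panel)
        assert [r.score for r in report.rows] == [50.0, 50.0]
        a, b = report.rows
        assert dataclasses.asdict(a) | {"compound_id": "b"} == \
            dataclasses.asdict(b) | {"compound_id": "b"}

    def test_single_compound_rejected(self, small_panel):
        with pytest.raises(ValidationError):
            screen(_twin_compounds()[:1], small_panel)

    def test_pair_count_conservation(self, small_panel, small_compounds):
        report = screen(small_compounds, small_panel)
        assert report.n_pairs == len(small_compounds) * len(small_panel)
        assert all(r.n_pairs == len(small_panel) for r in report.rows)

    def test_deterministic_byte_identical_reports(self, tmp_path):
        data = generate(GeneratorParams(n=100, seed=11))
        blobs = []
        for run in ("one", "two"):
            report = screen(data.compounds, data.panel)
            paths = report.write(tmp_path / run)
            blobs.append(tuple(p.read_bytes() for p in paths))
        assert blobs[0] == blobs[1]

    def test_bounds_verdicts_attached_per_declared_category(
            self, small_compounds, small_panel):
        report = screen(small_compounds, small_panel)
        by_id = {r.compound_id: r for r in report.rows}
        assert set(by_id["c1"].bounds) == {"herbicide", "UOP"}
        assert set(by_id["c2"].bounds) == {"insecticide"}
        assert set(by_id["c3"].bounds) == {"ACE"}

    def test_report_json_round_trip(self, tmp_path, small_compounds,
                                    small_panel):
        from pestiscreen import ScreenReport

        report = screen(small_compounds, small_panel)
        report.write(tmp_path)
        back = ScreenReport.from_json(tmp_path / "screen.json")
        assert back.config_hash == report.config_hash
        assert dataclasses.asdict(back.rows[0]) == \
            dataclasses.asdict(report.rows[0])


class TestSemaphores:
    @pytest.mark.parametrize("score,color", [
        (0.0, PhotodegSemaphore.red),
        (19.9, PhotodegSemaphore.red),
        (20.0, PhotodegSemaphore.orange),  # edge goes to the higher bin
        (59.9, PhotodegSemaphore.yellow),
        (80.0, PhotodegSemaphore.green),
        (100.0, PhotodegSemaphore.green),
    ])
    def test_photodeg_quintiles(self, score, color):
        assert photodeg_semaphore(score) is color

    def test_ecotox_binary(self):
        assert ecotox_semaphore(True) is EcotoxSemaphore.light_green
        assert ecotox_semaphore(False) is EcotoxSemaphore.light_red

    @pytest.mark.parametrize("pct,color", [
        (0.5, ElumoSemaphore.black),
        (1.0, ElumoSemaphore.pink),
        (49.9, ElumoSemaphore.pink),
        (50.0, ElumoSemaphore.purple),
        (100.0, ElumoSemaphore.purple),
    ])
    def test_elumo_bins(self, pct, color):
        assert elumo_semaphore(pct) is color


class TestBracketCounts:
    def test_all_in_top_bracket(self, small_panel):
        rows = screen(_twin_compounds(), small_panel).rows
        for r in rows:
            r.score = 100.0
        counts = bracket_counts(rows, (Bracket(90, 100, "top"),))
        assert counts["top"] == 2

    def test_overlapping_brackets_rejected(self, small_panel):
        rows = screen(_twin_compounds(), small_panel).rows
        with pytest.raises(ConfigurationError, match="overlap"):
            bracket_counts(rows, (Bracket(0, 60, "a"), Bracket(50, 100, "b")))

    def test_empty_rows_all_zero(self):
        counts = bracket_counts([], DEFAULT_BRACKETS)
        assert all(v == 0 for v in counts.values())

    def test_counts_sum_to_filtered_rows(self):
        data = generate(GeneratorParams(n=150, seed=5))
        rows = screen(data.compounds, data.panel).rows
        outside = [r for r in rows if not r.in_safe_space]
        counts = bracket_counts(rows, DEFAULT_BRACKETS,
                                predicate=lambda r: not r.in_safe_space)
        assert sum(counts.values()) == len(outside)

    def test_edge_score_goes_to_higher_bracket(self, small_panel):
        rows = screen(_twin_compounds(), small_panel).rows
        rows[0].score = 75.0
        counts = bracket_counts(rows[:1], DEFAULT_BRACKETS)
        assert counts["75-89th"] == 1 and counts["50-74th"] == 0


class TestCompareRedesign:
    def test_identity_comparison(self, small_compounds, small_panel):
        report = screen(small_compounds, small_panel)
        row = report.row("c1")
        delta = compare_redesign(row, row)
        assert delta.d_log_d == 0.0
        assert delta.d_composite_score == 0.0
        assert all(delta.bounds_retained.values())

    def test_halogen_to_methoxy_redesign_deltas(self, small_panel):
        """A lipophilic parent (log D 4.64) and its methoxy analog
        (log D 2.95): the delta is -1.69 and the analog newly satisfies
        the Briggs rule."""
        parent = Compound(id="parent", e_homo=-6.4, e_lumo=-0.34,
                          log_d=4.64)
        analog = Compound(id="analog", e_homo=-6.0, e_lumo=-0.54,
                          log_d=2.95)
        report = screen([parent, analog], small_panel)
        delta = compare_redesign(report.row("parent"), report.row("analog"))
        assert delta.d_log_d == pytest.approx(-1.69)
        assert not report.row("parent").briggs_ok
        assert report.row("analog").briggs_ok

    def test_amine_analog_enters_safe_log_d(self, small_panel):
        analog = Compound(id="amine", e_homo=-5.8, e_lumo=-0.34, log_d=1.61)
        other = Compound(id="o", e_homo=-6.2, e_lumo=-0.3, log_d=4.0)
        report = screen([analog, other], small_panel)
        assert report.row("amine").log_d_ok  # 1.61 < 1.7

    def test_mismatched_config_hash_rejected(self, small_compounds,
                                             small_panel):
        r1 = screen(small_compounds, small_panel)
        r2 = screen(small_compounds, small_panel,
                    FrameworkConfig(marcus_lambda=20.0))
        with pytest.raises(ComparabilityError):
            compare_redesign(r1.row("c1"), r2.row("c2"))


class TestDensitySummary:
    def test_single_bracket_centroid(self, small_panel):
        rows = screen(_twin_compounds(), small_panel).rows
        summaries, vectors = density_summary(
            rows, (Bracket(0, 100, "all"),))
        assert len(summaries) == 1
        assert summaries[0].mean_log_d == pytest.approx(2.0)
        assert vectors == []

    def test_radii_are_half_sd(self):
        data = generate(GeneratorParams(n=200, seed=9))
        rows = screen(data.compounds, data.panel).rows
        summaries, _ = density_summary(rows, (Bracket(0, 100, "all"),))
        ld = np.array([r.log_d for r in rows])
        de = np.array([r.delta_e_ev for r in rows])
        assert summaries[0].radius_log_d == pytest.approx(
            ld.std(ddof=1) / 2.0)
        assert summaries[0].radius_delta_e == pytest.approx(
            de.std(ddof=1) / 2.0)

    def test_coupled_generator_orders_bracket_means_along_delta_e(self):
        """With positive coupling, more photodegradable brackets sit at
        lower delta-E: centroids decrease monotonically with score."""
        data = generate(GeneratorParams(n=2000, seed=13, homo_coupling=0.8))
        rows = screen(data.compounds, data.panel).rows
        summaries, _ = density_summary(rows, DEFAULT_BRACKETS)
        means = [s.mean_delta_e for s in summaries]
        assert means == sorted(means, reverse=True)

    def test_sparse_bracket_omitted(self, small_panel):
        rows = screen(_twin_compounds(), small_panel).rows  # both score 50
        summaries, _ = density_summary(
            rows, (Bracket(0, 50, "lo"), Bracket(50, 100, "hi")))
        assert [s.label for s in summaries] == ["hi"]
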