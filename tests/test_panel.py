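"""Panel assembly, dye swapping, and the two-stage labeling simulation."""

import numpy as np
import pytest

from bstag.errors import SwapRejectedError
from bstag.panel import (
    DEFAULT_DYES,
    Assignment,
    DyeSpec,
    Panel,
    PanelEntry,
    PanelInfeasible,
    PanelPolicy,
    YieldPools,
    apparent_size,
    build_panel,
    dye_swap,
    labeling_yield,
    panel_from_json,
    panel_to_json,
    simulate_labeling,
    validate_panel,
)

DYES = {d.name: d for d in DEFAULT_DYES}


@pytest.fixture()
def figure_panel(ssr_assays, tag_list):
    """The published four-marker single-tube panel."""
    panel = build_panel(ssr_assays, tag_list)
    assert isinstance(panel, Panel)
    return panel


class TestApparentSize:
    def test_arithmetic(self, tag_list):
        assert apparent_size(200, tag_list[0], DyeSpec("X", 0, 0.0)) == 216

    def test_default_dye_shifts_span_13_to_17(self, tag_list):
        shifts = [
            apparent_size(200, tag_list[0], d) - 200 for d in DEFAULT_DYES
        ]
        assert all(13 <= s <= 17 for s in shifts)

    def test_boundary_offset(self, tag_list):
        assert apparent_size(200, tag_list[0], DyeSpec("X", 0, -3.0)) - 200 == 13

    def test_nonpositive_length_rejected(self, tag_list):
        with pytest.raises(ValueError):
            apparent_size(0, tag_list[0], DEFAULT_DYES[0])


class TestBuildPanel:
    def test_published_four_marker_panel_is_feasible(self, figure_panel):
        assert validate_panel(figure_panel) == []
        got = {
            a.entry.name: (a.tag.name, a.dye.name)
            for a in figure_panel.assignments
        }
        assert got == {
            "SSR08A04": ("F9GCC", "VIC"),
            "SSR08A09": ("F9GTC", "PET"),
            "SSR08B15": ("F9GAC", "NED"),
            "SSR08B25": ("F9TAC", "6-FAM"),
        }

    def test_seven_assays_infeasible(self, tag_list):
        entries = [
            PanelEntry(name=f"a{i}", size_range=(100 + 30 * i, 110 + 30 * i))
            for i in range(7)
        ]
        result = build_panel(entries, tag_list)
        assert isinstance(result, PanelInfeasible)

    def test_six_assays_accepted(self, tag_list):
        entries = [
            PanelEntry(name=f"a{i}", size_range=(100 + 40 * i, 110 + 40 * i))
            for i in range(6)
        ]
        result = build_panel(entries, tag_list)
        assert isinstance(result, Panel)
        assert validate_panel(result) == []

    def test_identical_windows_single_dye_conflict(self, tag_list):
        entries = [
            PanelEntry(name="a", size_range=(100, 120)),
            PanelEntry(name="b", size_range=(100, 120)),
        ]
        result = build_panel(entries, tag_list, dye_pool=DEFAULT_DYES[:1])
        assert isinstance(result, PanelInfeasible)
        assert set(result.conflict) == {"a", "b"}

    def test_infeasibility_diagnosis_is_minimal(self, tag_list):
        """Removing any one named conflict member restores feasibility."""
        entries = [
            PanelEntry(name=f"a{i}", size_range=(100, 120)) for i in range(3)
        ]
        result = build_panel(entries, tag_list, dye_pool=DEFAULT_DYES[:2])
        assert isinstance(result, PanelInfeasible)
        for name in result.conflict:
            rest = [e for e in entries if e.name != name]
            assert isinstance(build_panel(rest, tag_list, DEFAULT_DYES[:2]), Panel)


class TestDyeSwap:
    def test_swap_to_same_dye_is_identity(self, figure_panel):
        swapped = dye_swap(figure_panel, "SSR08A04", DYES["VIC"])
        assert swapped == figure_panel

    def test_swap_to_unused_dye_keeps_tags(self, tag_list):
        entries = [
            PanelEntry(name="a", size_range=(100, 120), dye="VIC"),
            PanelEntry(name="b", size_range=(200, 220), dye="PET"),
        ]
        panel = build_panel(entries, tag_list)
        swapped = dye_swap(panel, "a", DYES["NED"])
        assert swapped.assignment("a").dye.name == "NED"
        assert swapped.assignment("a").tag == panel.assignment("a").tag

    def test_conflicting_swap_rejected_atomically(self, tag_list):
        entries = [
            PanelEntry(name="a", size_range=(100, 120), dye="VIC"),
            PanelEntry(name="b", size_range=(105, 125), dye="PET"),
        ]
        panel = build_panel(entries, tag_list)
        with pytest.raises(SwapRejectedError):
            dye_swap(panel, "a", DYES["PET"])
        assert panel.assignment("a").dye.name == "VIC"  # unchanged


class TestSimulateLabeling:
    def test_exclusive_labeling_of_published_panel(self, figure_panel):
        labeled = [(a.tag, a.dye) for a in figure_panel.assignments]
        templates = {
            a.entry.name: [int(sum(a.entry.size_range) // 2)]
            for a in figure_panel.assignments
        }
        peaks = simulate_labeling(figure_panel, templates, labeled)
        dye_of = {a.entry.name: a.dye.name for a in figure_panel.assignments}
        assert len(peaks) == 4
        assert len({p.dye for p in peaks}) == 4
        assert all(p.dye == dye_of[p.assay] for p in peaks)

    def test_mismatched_labeled_primer_gives_no_peaks(self, figure_panel, tags):
        a04 = figure_panel.assignment("SSR08A04")  # carries F9GCC
        single = Panel(assignments=(a04,), policy=figure_panel.policy)
        peaks = simulate_labeling(
            single, {"SSR08A04": [200]}, [(tags["F9GTC"], DYES["PET"])]
        )
        assert peaks == []

    def test_heterozygote_two_peaks_same_dye(self, figure_panel):
        a04 = figure_panel.assignment("SSR08A04")
        single = Panel(assignments=(a04,), policy=figure_panel.policy)
        peaks = simulate_labeling(
            single, {"SSR08A04": [200, 206]}, [(a04.tag, a04.dye)]
        )
        assert len(peaks) == 2
        assert peaks[0].dye == peaks[1].dye
        assert peaks[1].apparent_size - peaks[0].apparent_size == 6

    def test_removing_a_labeled_primer_removes_only_its_peaks(self, figure_panel):
        labeled = [(a.tag, a.dye) for a in figure_panel.assignments]
        templates = {
            a.entry.name: [int(sum(a.entry.size_range) // 2)]
            for a in figure_panel.assignments
        }
        full = simulate_labeling(figure_panel, templates, labeled)
        dropped_assay = figure_panel.assignments[0].entry.name
        reduced = simulate_labeling(figure_panel, templates, labeled[1:])
        assert {p.assay for p in full} - {p.assay for p in reduced} == {dropped_assay}
        assert [p for p in reduced] == [p for p in full if p.assay != dropped_assay]

    def test_exclusivity_over_random_valid_panels(self, tag_list):
        """Fuzz 200 random valid panels: every labeled peak carries the dye
        assigned to its source assay, and cross pairs never label."""
        rng = np.random.default_rng(200)
        for _ in range(200):
            n = int(rng.integers(2, 5))
            sizes = rng.choice(np.arange(80, 400, 40), size=n, replace=False)
            entries = [
                PanelEntry(name=f"m{i}", size_range=(int(s), int(s) + 12))
                for i, s in enumerate(sizes)
            ]
            panel = build_panel(entries, tag_list)
            assert isinstance(panel, Panel)
            assert validate_panel(panel) == []
            labeled = [(a.tag, a.dye) for a in panel.assignments]
            templates = {
                a.entry.name: [int(sum(a.entry.size_range) // 2)]
                for a in panel.assignments
            }
            peaks = simulate_labeling(panel, templates, labeled)
            dye_of = {a.entry.name: a.dye.name for a in panel.assignments}
            assert len(peaks) == n
            assert all(p.dye == dye_of[p.assay] for p in peaks)


class TestLabelingYield:
    def test_zero_cycles(self):
        assert labeling_yield(0) == [0.0]

    def test_full_conversion_plateaus_at_cycle_one(self):
        ys = labeling_yield(4, YieldPools(template=1.0, primer=100.0, conversion=1.0))
        assert ys[1] == ys[2] == ys[3] == ys[4] == 1.0

    def test_default_curve_shape(self):
        """Non-decreasing, concave, near-linear to cycle 3 and flat at 4."""
        ys = labeling_yield(4)
        inc = [ys[i + 1] - ys[i] for i in range(4)]
        assert all(i >= 0 for i in inc)
        assert all(inc[i + 1] <= inc[i] + 1e-12 for i in range(3))  # concave
        assert inc[3] < 0.2 * inc[0]  # plateau at the fourth cycle

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            YieldPools(conversion=0.0)
        with pytest.raises(ValueError):
            YieldPools(template=0.0)


class TestPanelJson:
    def test_roundtrip(self, figure_panel):
        back = panel_from_json(panel_to_json(figure_panel))
        assert back == figure_panel
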