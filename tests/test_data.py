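"""Data loading, validation, correction and restructuring."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmabayes as nb
from nmabayes.data import arrays_to_dataset
from nmabayes.datasets import HEART_FAILURE_TREATMENTS


def _write_wide_heart(heart, path):
    """Render the bundled network in wide layout (one row per study)."""
    k = heart.n_treatments
    lines = [",".join(["study"] + [f"{t}," for t in heart.treatments])]
    for s in heart.studies:
        cells = [""] * (2 * k)
        for a in s.arms:
            cells[2 * (a.treatment - 1)] = str(int(a.events))
            cells[2 * (a.treatment - 1) + 1] = str(int(a.size))
        lines.append(",".join([s.label] + cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestLoading:
    def test_bundled_network_shape(self, heart):
        assert heart.n_studies == 12
        assert heart.n_treatments == 5
        assert heart.treatments == tuple(HEART_FAILURE_TREATMENTS)
        assert heart.reference == 1

    def test_single_arm_study_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study,treatment,events,n\nS1,A,1,10\n")
        with pytest.raises(nb.DataError, match="single-arm"):
            nb.load_long(p)

    def test_disconnected_network_rejected(self):
        rows = [("S1", "A", 1, 10), ("S1", "B", 2, 10),
                ("S2", "C", 1, 10), ("S2", "D", 2, 10)]
        with pytest.raises(nb.DisconnectedNetworkError):
            nb.dataset_from_rows(rows)

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([("S1", "A", 5, 4), ("S1", "B", 1, 10)], "events"),
            ([("S1", "A", 1, 10), ("S1", "A", 2, 10)], "duplicate"),
            ([], "empty"),
        ],
    )
    def test_invalid_rows_rejected(self, rows, match):
        with pytest.raises(nb.DataError, match=match):
            nb.dataset_from_rows(rows)

    def test_wide_equals_long(self, heart, tmp_path):
        p = tmp_path / "wide.csv"
        _write_wide_heart(heart, p)
        wide = nb.load_wide(p, reference="Medical therapy")
        assert wide == heart

    def test_wide_two_arm_row(self, heart, tmp_path):
        p = tmp_path / "wide.csv"
        _write_wide_heart(heart, p)
        wide = nb.load_wide(p, reference="Medical therapy")
        mustic = next(s for s in wide.studies if s.label == "MUSTIC-SR")
        assert [(a.treatment, a.events, a.size) for a in mustic.arms] == [
            (1, 0.0, 29.0), (2, 1.0, 29.0),
        ]

    def test_empty_wide_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(nb.DataError, match="empty"):
            nb.load_wide(p)

    def test_default_reference_is_most_studied(self):
        # B appears in 3 studies, A and C in fewer -> B becomes treatment 1
        rows = [("S1", "A", 1, 10), ("S1", "B", 2, 10),
                ("S2", "B", 1, 10), ("S2", "C", 2, 10),
                ("S3", "B", 3, 10), ("S3", "C", 1, 10)]
        ds = nb.dataset_from_rows(rows)
        assert ds.treatments[0] == "B"
        assert ds.reference == 1

    def test_treatment_cap_warns(self):
        rows = []
        for k in range(1, 16):  # 16 treatments chained pairwise
            rows.append((f"S{k}", f"T{k}", 1, 10))
            rows.append((f"S{k}", f"T{k + 1}", 1, 10))
        with pytest.warns(UserWarning, match="treatments exceeds"):
            nb.dataset_from_rows(rows)


class TestSummarize:
    def test_bundled_totals(self, heart):
        s = nb.summarize(heart)
        assert (s.n_studies, s.n_treatments) == (12, 5)
        assert (s.n_patients, s.n_events) == (8307, 1616)
        assert s.n_studies_with_reference == 8

    def test_direct_sums(self):
        ds = nb.dataset_from_rows([("S", "A", 1, 10), ("S", "B", 2, 10)])
        s = nb.summarize(ds)
        assert (s.n_studies, s.n_treatments, s.n_patients, s.n_events,
                s.n_studies_with_reference) == (1, 2, 20, 3, 1)

    def test_invariant_under_study_order(self, heart):
        rows = [
            (s.label, heart.label(a.treatment), a.events, a.size)
            for s in heart.studies
            for a in s.arms
        ]
        shuffled = nb.dataset_from_rows(
            rows[::-1],
            treatment_order=list(heart.treatments),
            reference="Medical therapy",
        )
        assert nb.summarize(shuffled) == nb.summarize(heart)


class TestNetwork:
    def test_bundled_edges(self, heart):
        net = nb.build_network(heart)
        assert net.edges == {
            (1, 2): 4, (1, 4): 1, (2, 4): 1, (1, 3): 4,
            (1, 5): 1, (3, 5): 2, (3, 4): 3,
        }

    def test_bundled_node_weight(self, heart):
        net = nb.build_network(heart)
        assert net.nodes[1] == 404 + 308 + 225 + 29 + 847 + 490 + 229 + 54

    def test_single_study_edge(self):
        ds = nb.dataset_from_rows([("S", "A", 1, 10), ("S", "B", 2, 10)])
        net = nb.build_network(ds)
        assert net.edges == {(1, 2): 1}

    def test_removing_study_decrements_its_pairs(self, heart):
        full = nb.build_network(heart).edges
        rows = [
            (s.label, heart.label(a.treatment), a.events, a.size)
            for s in heart.studies
            if s.label != "COMPANION"
            for a in s.arms
        ]
        reduced = nb.build_network(
            nb.dataset_from_rows(rows, treatment_order=list(heart.treatments),
                                 reference="Medical therapy")
        ).edges
        for pair in [(1, 2), (1, 4), (2, 4)]:  # COMPANION arms: A, B, D
            assert reduced.get(pair, 0) == full[pair] - 1
        for pair in set(full) - {(1, 2), (1, 4), (2, 4)}:
            assert reduced[pair] == full[pair]


class TestContinuityCorrection:
    def test_equal_arms_get_half(self, heart):
        corrected = nb.apply_continuity_correction(heart)
        mustic = next(s for s in corrected.studies if s.label == "MUSTIC-SR")
        assert [(a.events, a.size) for a in mustic.arms] == [
            (0.5, 30.0), (1.5, 30.0),
        ]
        assert corrected.corrected

    def test_unequal_arms_reciprocal_rule(self):
        ds = nb.dataset_from_rows([("S", "T", 0, 100), ("S", "C", 5, 50)],
                                  treatment_order=["T", "C"], reference="T")
        c = nb.apply_continuity_correction(ds)
        (arm_t, arm_c) = c.studies[0].arms
        assert math.isclose(arm_t.events, 2 / 3)
        assert math.isclose(arm_c.events - 5, 1 / 3)
        assert math.isclose(arm_t.size, 100 + 4 / 3)

    def test_declined_correction_is_identity(self, heart):
        assert nb.apply_continuity_correction(heart, correct=False) == heart

    def test_untouched_without_zero_cells(self, toy2):
        assert nb.apply_continuity_correction(toy2) == toy2

    def test_event_total_increases_by_arm_count_half(self, heart):
        before = nb.summarize(heart).n_events
        after = nb.summarize(nb.apply_continuity_correction(heart)).n_events
        # only MUSTIC-SR (2 equal arms) is affected: +0.5 per arm
        assert math.isclose(after - before, 1.0)

    def test_all_zero_study_warns_but_is_kept(self):
        rows = [("Z", "A", 0, 10), ("Z", "B", 0, 10),
                ("S", "A", 2, 10), ("S", "B", 3, 10)]
        ds = nb.dataset_from_rows(rows)
        with pytest.warns(UserWarning, match="zero events in every arm"):
            c = nb.apply_continuity_correction(ds)
        assert c.n_studies == 2

    @given(
        sizes=st.lists(st.integers(5, 500), min_size=2, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_per_study_correction_sums_to_half_arm_count(self, sizes, data):
        events = [data.draw(st.integers(0, n)) for n in sizes]
        labels = [f"T{k}" for k in range(len(sizes))]
        rows = [("S", lab, e, n) for lab, e, n in zip(labels, events, sizes)]
        ds = nb.dataset_from_rows(rows)
        c = nb.apply_continuity_correction(ds)
        study_before, study_after = ds.studies[0], c.studies[0]
        total_c = sum(
            a2.events - a1.events
            for a1, a2 in zip(study_before.arms, study_after.arms)
        )
        if study_before.has_zero_or_all_event_cell():
            assert math.isclose(total_c, len(sizes) / 2)
        else:
            assert total_c == 0
        for a in study_after.arms:
            assert 0 <= a.events <= a.size


class TestModelArrays:
    def test_datapoint_count(self, heart_arrays):
        assert heart_arrays.n_datapoints == 26

    def test_multiarm_order_baseline_first(self, heart_arrays):
        i = heart_arrays.study_labels.index("COMPANION")
        assert heart_arrays.t[i] == (1, 2, 4)

    def test_round_trip(self, heart, heart_arrays):
        assert arrays_to_dataset(heart_arrays) == heart
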