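"""PSI quantification, evidence filtering and two-track merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicescape.psi import (
    PsiMatrix,
    compute_psi_from_isoforms,
    compute_psi_from_junctions,
    filter_events,
    merge_methods,
    read_psi,
    write_psi,
)

from conftest import make_event


def junction_table(data: dict, samples=("s1",)) -> pd.DataFrame:
    return pd.DataFrame(data, index=list(samples)).T


class TestJunctionPsi:
    def test_skipped_exon_multiplicity_normalization(self):
        """Two inclusion junctions totalling 30 reads against one exclusion
        junction with 10: PSI = (30/2) / (30/2 + 10) = 0.6."""
        ev = make_event()
        counts = junction_table({"j_i1": [14], "j_i2": [16], "j_e": [10]})
        pm = compute_psi_from_junctions(counts, [ev])
        assert pm.psi.loc["evX", "s1"] == pytest.approx(0.6)
        assert pm.evidence.loc["evX", "s1"] == 40

    @pytest.mark.parametrize(
        "inc1,inc2,exc,expected",
        [(0, 0, 7, 0.0), (10, 10, 0, 1.0)],
    )
    def test_boundary_psi(self, inc1, inc2, exc, expected):
        ev = make_event()
        counts = junction_table({"j_i1": [inc1], "j_i2": [inc2], "j_e": [exc]})
        pm = compute_psi_from_junctions(counts, [ev])
        assert pm.psi.loc["evX", "s1"] == expected

    def test_no_support_gives_missing(self):
        ev = make_event()
        counts = junction_table({"j_i1": [0], "j_i2": [0], "j_e": [0]})
        pm = compute_psi_from_junctions(counts, [ev])
        assert np.isnan(pm.psi.loc["evX", "s1"])

    def test_negative_counts_rejected(self):
        ev = make_event()
        counts = junction_table({"j_i1": [-1], "j_i2": [0], "j_e": [5]})
        with pytest.raises(ValueError):
            compute_psi_from_junctions(counts, [ev])

    def test_absent_junction_rejected(self):
        ev = make_event()
        with pytest.raises(KeyError):
            compute_psi_from_junctions(junction_table({"j_i1": [1]}), [ev])

    def test_long_form_input_equivalent(self):
        ev = make_event()
        long = pd.DataFrame(
            {
                "junction_id": ["j_i1", "j_i2", "j_e"],
                "sample": ["s1"] * 3,
                "count": [14, 16, 10],
            }
        )
        pm = compute_psi_from_junctions(long, [ev])
        assert pm.psi.loc["evX", "s1"] == pytest.approx(0.6)


class TestIsoformPsi:
    def test_simple_ratio(self):
        ev = make_event()
        tpm = pd.DataFrame({"s1": [3.0, 1.0]}, index=["txI", "txE"])
        pm = compute_psi_from_isoforms(tpm, [ev])
        assert pm.psi.loc["evX", "s1"] == pytest.approx(0.75)
        assert pm.evidence.loc["evX", "s1"] == pytest.approx(4.0)

    def test_zero_abundance_missing_and_full_inclusion(self):
        ev2 = make_event(inc_iso=("tA", "tB"), exc_iso=("tC",))
        tpm = pd.DataFrame({"s1": [0.0, 0.0, 0.0], "s2": [2.0, 2.0, 0.0]},
                           index=["tA", "tB", "tC"])
        pm = compute_psi_from_isoforms(tpm, [ev2])
        assert np.isnan(pm.psi.loc["evX", "s1"])
        assert pm.psi.loc["evX", "s2"] == 1.0

    def test_negative_tpm_rejected(self):
        ev = make_event()
        tpm = pd.DataFrame({"s1": [-0.1, 1.0]}, index=["txI", "txE"])
        with pytest.raises(ValueError):
            compute_psi_from_isoforms(tpm, [ev])


def _psi_with_evidence(evidence_rows: dict, n_samples: int, method="junction"):
    ev_ids = list(evidence_rows)
    samples = [f"s{i}" for i in range(n_samples)]
    evidence = pd.DataFrame(evidence_rows, index=samples).T
    psi = pd.DataFrame(0.5, index=ev_ids, columns=samples)
    return PsiMatrix(psi, evidence, method)


class TestFiltering:
    def test_twenty_percent_boundary_is_inclusive(self):
        pm = _psi_with_evidence({"a": [5, 5] + [0] * 8}, 10)
        assert list(filter_events(pm).event_ids) == ["a"]

    def test_below_threshold_dropped(self):
        pm = _psi_with_evidence({"a": [5] + [0] * 9}, 10)
        assert list(filter_events(pm).event_ids) == []

    def test_cross_method_detection_rescues(self):
        pm = _psi_with_evidence({"a": [0] * 10}, 10)
        kept = filter_events(pm, also_detected_by_other={"a"})
        assert list(kept.event_ids) == ["a"]

    @given(st.lists(st.integers(0, 12), min_size=10, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_raising_cutoff_never_enlarges_kept_set(self, evid):
        pm = _psi_with_evidence({"a": evid}, 10)
        kept_low = set(filter_events(pm, cutoff=3).event_ids)
        kept_high = set(filter_events(pm, cutoff=8).event_ids)
        assert kept_high <= kept_low


class TestMerging:
    def _tracks(self):
        shared = [make_event(event_id=f"sh{i}", alt=(1000 + i, 1200 + i),
                             sites=(200, 1000 + i, 1200 + i, 2000)) for i in range(5)]
        j_only = [make_event(event_id=f"j{i}", alt=(3000 + i, 3100 + i),
                             sites=(2500, 3000 + i, 3100 + i, 3500)) for i in range(3)]
        i_only = [make_event(event_id=f"i{i}", alt=(4000 + i, 4100 + i),
                             sites=(3900, 4000 + i, 4100 + i, 4500)) for i in range(4)]

        def pm(events, method, fill):
            ids = [e.event_id for e in events]
            psi = pd.DataFrame(fill, index=ids, columns=["s1", "s2"])
            return PsiMatrix(psi, psi * 0 + 10, method, {e.event_id: e for e in events})

        return pm(shared + j_only, "junction", 0.6), pm(shared + i_only, "isoform", 0.7)

    def test_union_counts_and_provenance(self):
        pj, pi = self._tracks()
        merged = merge_methods(pj, pi)
        assert len(merged.event_ids) == 12
        assert (merged.provenance == "both").sum() == 5
        assert (merged.provenance == "junction").sum() == 3
        assert (merged.provenance == "isoform").sum() == 4

    def test_empty_isoform_track_is_identity(self):
        pj, _ = self._tracks()
        merged = merge_methods(pj, None)
        assert set(merged.event_ids) == set(pj.event_ids)
        assert (merged.provenance == "junction").all()

    def test_shared_event_keeps_both_tracks_unaveraged(self):
        pj, pi = self._tracks()
        merged = merge_methods(pj, pi)
        assert merged.junction.psi.loc["sh0", "s1"] == 0.6
        assert merged.isoform.psi.loc["sh0", "s1"] == 0.7

    def test_conflicting_coordinates_rejected(self):
        pj, pi = self._tracks()
        bad = make_event(event_id="sh0", alt=(9000, 9100), sites=(8000, 9000, 9100, 9500))
        pi.events["sh0"] = bad
        with pytest.raises(ValueError):
            merge_methods(pj, pi)

    def test_round_trip_through_tsv(self, tmp_path):
        pj, pi = self._tracks()
        merged = merge_methods(pj, pi)
        path = tmp_path / "psi.tsv"
        write_psi(merged, path)
        back = read_psi(path)
        pd.testing.assert_series_equal(
            back.provenance.sort_index(),
            merged.provenance.sort_index(),
            check_names=False,
        )
        assert back.junction.psi.loc["sh0", "s1"] == 0.6


def test_all_emitted_psi_within_unit_interval(small_cohort):
    from splicescape.simulate import generate_splice_data

    sd = generate_splice_data(small_cohort, 15, seed=2)
    pm = compute_psi_from_junctions(sd.junctions, sd.events)
    vals = pm.psi.to_numpy()
    ok = ~np.isnan(vals)
    assert ((vals[ok] >= 0) & (vals[ok] <= 1)).all()
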