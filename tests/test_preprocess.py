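"""Control-plate filtering, summary endpoints, and dose-group pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zfbmd.preprocess import (
    DoseGroup,
    DoseResponseSeries,
    EmptySeriesError,
    build_series,
    canonical_dose,
    derive_summary_endpoints,
    filter_control_plates,
)


def make_records(rows):
    """rows: (plate, conc, endpoint, incidence, alive[, timepoint])"""
    out = []
    for i, row in enumerate(rows):
        plate, conc, endpoint, inc, alive = row[:5]
        tp = row[5] if len(row) > 5 else (24 if endpoint.endswith("24") else 120)
        out.append(dict(
            plate_id=plate, well_id=f"w{i}", substance_id="C1",
            substance_kind="chemical", concentration=float(conc),
            endpoint=endpoint, incidence=int(inc), alive=int(alive),
            timepoint=tp,
        ))
    return pd.DataFrame(out)


def control_plate(plate, responders, total=32, endpoint="EDEM"):
    return [(plate, 0.0, endpoint, int(i < responders), 1) for i in range(total)]


class TestControlFilter:
    @pytest.mark.parametrize(
        "responders, removed",
        [(17, True),   # 17/32 = 0.531 > 0.5 -> removed
         (16, False),  # exactly 0.5 is not "more than" -> kept
         (0, False)],  # clean controls -> kept
    )
    def test_majority_rule_boundary(self, responders, removed):
        records = make_records(
            control_plate("P1", responders) + [("P1", 5.0, "EDEM", 0, 1)]
        )
        kept, dropped = filter_control_plates(records, 0.5, endpoint="EDEM")
        assert (("P1" in dropped) is removed)
        assert kept.empty is removed

    def test_plate_without_controls_retained(self, caplog):
        records = make_records([("P1", 5.0, "EDEM", 1, 1)] * 4)
        with caplog.at_level("WARNING"):
            kept, dropped = filter_control_plates(records, 0.5, endpoint="EDEM")
        assert dropped == set() and len(kept) == 4
        assert "no vehicle-control wells" in caplog.text

    def test_threshold_one_is_identity_with_surviving_control(self):
        records = make_records(control_plate("P1", 31))
        kept, dropped = filter_control_plates(records, 0.999, endpoint="EDEM")
        assert dropped == set() and len(kept) == len(records)

    def test_per_endpoint_scope(self):
        """A plate bad for one endpoint can stay in for another."""
        records = make_records(
            control_plate("P1", 20, endpoint="EDEM")
            + control_plate("P1", 0, endpoint="AXIS")
        )
        _, dropped_edem = filter_control_plates(records, 0.5, endpoint="EDEM")
        _, dropped_axis = filter_control_plates(records, 0.5, endpoint="AXIS")
        assert dropped_edem == {"P1"} and dropped_axis == set()


class TestSummaryEndpoints:
    def well(self, **incidences):
        rows = []
        for ep, inc in incidences.items():
            rows.append(("P1", 1.0, ep, inc, 1 if not (ep in ("MO24", "MORT") and inc) else 0))
        df = make_records(rows)
        return df.assign(well_id="w0")  # all rows describe one embryo well

    def get(self, df, endpoint):
        sub = df[df["endpoint"] == endpoint]
        assert len(sub) == 1
        return int(sub["incidence"].iloc[0]), int(sub["alive"].iloc[0])

    def test_any24_aggregates_24h_codes(self):
        out = derive_summary_endpoints(self.well(MO24=0, DP24=1, SM24=0, NC24=0))
        assert self.get(out, "ANY24")[0] == 1

    def test_all_components_zero_gives_zero_summaries(self):
        out = derive_summary_endpoints(
            self.well(MO24=0, DP24=0, SM24=0, NC24=0, MORT=0, EDEM=0)
        )
        for ep in ("ANY24", "TOT_MORT", "ANY_MORT", "ANY120"):
            assert self.get(out, ep)[0] == 0

    def test_mortality_propagates_to_totals_not_morphology(self):
        out = derive_summary_endpoints(self.well(MO24=1, MORT=0, EDEM=0))
        assert self.get(out, "TOT_MORT")[0] == 1
        assert self.get(out, "ANY120")[0] == 1
        inc, alive = self.get(out, "ANY_MORT")
        assert (inc, alive) == (0, 0)  # dead well leaves the living denominator

    def test_idempotent(self):
        df = self.well(MO24=0, DP24=1, EDEM=1, MORT=0)
        once = derive_summary_endpoints(df)
        twice = derive_summary_endpoints(once)
        pd.testing.assert_frame_equal(
            once.sort_values(["endpoint"]).reset_index(drop=True),
            twice.sort_values(["endpoint"]).reset_index(drop=True),
        )

    @given(bits=st.lists(st.booleans(), min_size=6, max_size=6))
    def test_monotone_in_components(self, bits):
        """Raising any component 0 -> 1 never flips a summary 1 -> 0."""
        eps = ["MO24", "DP24", "SM24", "NC24", "MORT", "EDEM"]
        base = dict(zip(eps, map(int, bits)))
        out0 = derive_summary_endpoints(self.well(**base))
        for ep in eps:
            if base[ep] == 1:
                continue
            raised = dict(base, **{ep: 1})
            out1 = derive_summary_endpoints(self.well(**raised))
            for summary in ("ANY24", "TOT_MORT", "ANY120"):
                assert self.get(out1, summary)[0] >= self.get(out0, summary)[0]


class TestBuildSeries:
    def test_living_denominator_for_morphology(self):
        # 32 wells at d=10: 4 dead (alive=0), 7 of the 28 living affected
        rows = [("P1", 10.0, "EDEM", 0, 0)] * 4
        rows += [("P1", 10.0, "EDEM", 1, 1)] * 7
        rows += [("P1", 10.0, "EDEM", 0, 1)] * 21
        series = build_series(make_records(rows), "C1", "EDEM")
        (grp,) = series.groups
        assert (grp.n, grp.y, grp.f) == (28, 7, 0.25)

    def test_all_wells_denominator_for_mortality(self):
        # 32 wells, 8 dead: n counts every assayed well
        rows = [("P1", 10.0, "MO24", 1, 0)] * 8 + [("P1", 10.0, "MO24", 0, 1)] * 24
        series = build_series(make_records(rows), "C1", "MO24")
        (grp,) = series.groups
        assert (grp.n, grp.y, grp.f) == (32, 8, 0.25)

    def test_plates_pool_at_same_concentration(self):
        rows = [("P1", 5.0, "EDEM", 1, 1)] * 8 + [("P1", 5.0, "EDEM", 0, 1)] * 24
        rows += [("P2", 5.0, "EDEM", 1, 1)] * 4 + [("P2", 5.0, "EDEM", 0, 1)] * 28
        series = build_series(make_records(rows), "C1", "EDEM")
        (grp,) = series.groups
        assert (grp.n, grp.y) == (64, 12)

    def test_pooling_is_associative(self):
        rng = np.random.default_rng(5)
        plates = []
        for p in range(3):
            for _ in range(16):
                plates.append((f"P{p}", 2.0, "EDEM", int(rng.random() < 0.3), 1))
        full = build_series(make_records(plates), "C1", "EDEM")
        partial_counts = [0, 0]
        for p in range(3):
            sub = make_records([r for r in plates if r[0] == f"P{p}"])
            s = build_series(sub, "C1", "EDEM")
            partial_counts[0] += s.groups[0].n
            partial_counts[1] += s.groups[0].y
        assert (full.groups[0].n, full.groups[0].y) == tuple(partial_counts)

    def test_group_with_no_living_embryos_dropped(self, caplog):
        rows = [("P1", 1.0, "EDEM", 0, 1)] * 4 + [("P1", 5.0, "EDEM", 0, 0)] * 4
        with caplog.at_level("WARNING"):
            series = build_series(make_records(rows), "C1", "EDEM")
        assert [g.d for g in series.groups] == [1.0]
        assert "no living embryos" in caplog.text

    def test_empty_series_raises(self):
        records = make_records([("P1", 1.0, "EDEM", 0, 1)])
        with pytest.raises(EmptySeriesError):
            build_series(records, "C1", "AXIS")

    def test_float_noise_does_not_split_groups(self):
        rows = [("P1", 5.0, "EDEM", 0, 1), ("P1", 5.0 * (1 + 1e-12), "EDEM", 1, 1)]
        series = build_series(make_records(rows), "C1", "EDEM")
        assert series.n_groups == 1

    def test_sum_of_group_n_bounded_by_supplied_wells(self, records):
        series = build_series(records, "CHEM-0001", "EDEM")
        wells = records[records["endpoint"] == "EDEM"]
        assert series.n.sum() <= len(wells)


def test_canonical_dose_six_significant_digits():
    out = canonical_dose([0.0, 1.2345678, 123456.78])
    np.testing.assert_allclose(out, [0.0, 1.23457, 123457.0])


def test_dose_group_invariants():
    with pytest.raises(ValueError):
        DoseGroup(d=1.0, n=5, y=6)
    with pytest.raises(ValueError):
        DoseResponseSeries("C1", "EDEM", (DoseGroup(2.0, 4, 1), DoseGroup(1.0, 4, 1)))
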