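"""Domain types, invariant enforcement and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest

from conftest import DRUGLINES_FIXTURE, VISITS_FIXTURE

from gpcost.errors import SchemaError, ValidationError
from gpcost.io import (frames_from_visits, read_breakdowns, read_visits,
                       load_tariff, save_tariff, visits_from_frames,
                       write_breakdowns)
from gpcost.model import CostBreakdown, DrugLine, PatientVisit, TariffSchedule


class TestTariffSchedule:
    def test_defaults_are_2008_statutory_values(self, tariff):
        assert tariff.tariff_s1_cents == 2200
        assert tariff.tariff_s2_cents == 3200
        assert tariff.ss_consultation_share == 0.70
        assert tariff.lump_sum_cents == 100
        assert tariff.franchise_cents == 25
        assert set(tariff.drug_tiers) == {0.0, 0.35, 0.65, 1.0}

    @pytest.mark.parametrize("bad", [
        {"consultation_tariff_sector2": "10.00"},  # below sector 1
        {"ss_consultation_share": 1.2},
        {"franchise_per_box": "-0.25"},
    ])
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(Exception):
            TariffSchedule(**bad)

    def test_yaml_round_trip(self, tmp_path, tariff):
        path = tmp_path / "tariff.yaml"
        save_tariff(tariff, path)
        again = load_tariff(path)
        assert again.tariff_s2_cents == tariff.tariff_s2_cents
        assert again.drug_tiers == tariff.drug_tiers

    def test_unknown_key_named_in_error(self, tmp_path):
        path = tmp_path / "tariff.yaml"
        path.write_text("consultation_tarrif_sector1: 22.0\n")
        with pytest.raises(SchemaError, match="consultation_tarrif_sector1"):
            load_tariff(path)


class TestReadVisits:
    def test_fixture_reads_fully(self, fixture_files):
        visits = read_visits(*fixture_files)
        assert [v.visit_id for v in visits] == ["v1", "v2", "v3"]
        assert sum(len(v.drug_lines) for v in visits) == 5
        assert visits[1].has_dld and visits[1].drug_lines[0].dld_related
        assert visits[2].gp.sector.value == "NUA"
        assert visits[1].sick_leave_days == 5

    def test_visit_without_lines_allowed(self, tmp_path):
        v = tmp_path / "visits.csv"
        d = tmp_path / "drugs.csv"
        v.write_text(VISITS_FIXTURE.splitlines()[0] + "\n"
                     + VISITS_FIXTURE.splitlines()[1] + "\n")
        d.write_text(DRUGLINES_FIXTURE.splitlines()[0] + "\n")
        visits = read_visits(v, d)
        assert len(visits) == 1 and visits[0].drug_lines == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "visits.csv"
        path.write_text("visit_id,practice_group\nv1,CM\n")
        with pytest.raises(SchemaError, match="sector"):
            read_visits(path)

    def test_unlisted_tier_rejected_with_row(self, fixture_files, tmp_path):
        d = tmp_path / "drugs.csv"
        d.write_text(DRUGLINES_FIXTURE.replace("v1,3.33,2,0.35", "v1,3.33,2,0.50"))
        with pytest.raises(ValidationError, match="row 1.*0.5"):
            read_visits(fixture_files[0], d)

    def test_dld_related_needs_dld_visit(self, fixture_files, tmp_path):
        d = tmp_path / "drugs.csv"
        d.write_text(DRUGLINES_FIXTURE.replace("v1,10.00,1,0.65,0", "v1,10.00,1,0.65,1"))
        with pytest.raises(ValidationError, match="dld_related"):
            read_visits(fixture_files[0], d)

    def test_sick_leave_days_require_flag(self, tmp_path):
        path = tmp_path / "visits.csv"
        path.write_text(VISITS_FIXTURE.replace("v1,CM,S1,40,0,1,0,0", "v1,CM,S1,40,0,1,0,3"))
        with pytest.raises(ValidationError, match="sick_leave"):
            read_visits(path)

    def test_extra_columns_pass_through(self, tmp_path):
        lines = VISITS_FIXTURE.splitlines()
        path = tmp_path / "visits.csv"
        path.write_text(lines[0] + ",gender\n" + lines[1] + ",F\n")
        visits = read_visits(path)
        assert visits[0].extra == {"gender": "F"}

    def test_read_write_read_is_identity(self, fixture_files, tmp_path):
        visits = read_visits(*fixture_files)
        vdf, ddf = frames_from_visits(visits)
        vdf.to_csv(tmp_path / "v.csv", index=False)
        ddf.to_csv(tmp_path / "d.csv", index=False)
        again = read_visits(tmp_path / "v.csv", tmp_path / "d.csv")
        assert again == visits


class TestBreakdownIO:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "b.csv"
        write_breakdowns([], path)
        df = pd.read_csv(path)
        assert len(df) == 0 and "health_expenditure" in df.columns

    def test_cells_formatted_to_the_cent(self, tmp_path):
        b = CostBreakdown("v1", 1440, 760, 2200, 0, 0, 0, 1440, 760, 2200, True)
        path = tmp_path / "b.csv"
        write_breakdowns([b], path)
        text = path.read_text()
        assert "22.00" in text and "14.40" in text and "7.60" in text

    def test_round_trip_random_breakdowns(self, tmp_path):
        rng = np.random.default_rng(7)
        items = []
        for i in range(100):
            c_ss, c_rem = int(rng.integers(0, 3000)), int(rng.integers(0, 3000))
            p_ss, p_rem = int(rng.integers(0, 9000)), int(rng.integers(0, 9000))
            costed = bool(rng.integers(2))
            c = int(costed)
            items.append(CostBreakdown(
                f"v{i}", c_ss if costed else 0, c_rem if costed else 0,
                (c_ss + c_rem) if costed else 0, p_ss, p_rem, p_ss + p_rem,
                c * c_ss + p_ss, c * c_rem + p_rem,
                c * (c_ss + c_rem) + p_ss + p_rem, costed))
        path = tmp_path / "b.csv"
        write_breakdowns(items, path)
        assert read_breakdowns(path) == items


class TestInvariants:
    def test_breakdown_conservation_enforced(self):
        with pytest.raises(ValidationError, match="ss \\+ remaining"):
            CostBreakdown("x", 10, 10, 30, 0, 0, 0, 10, 10, 30, True)

    def test_negative_money_rejected(self):
        with pytest.raises(ValidationError):
            DrugLine("-1.00", 1, 0.35)

    def test_mutated_rows_rejected_others_kept(self, fixture_files, tmp_path):
        """Validation rejects exactly the invariant-violating rows."""
        vdf = pd.read_csv(fixture_files[0])
        ddf = pd.read_csv(fixture_files[1])
        assert len(visits_from_frames(vdf, ddf)) == 3  # clean passes
        bad = ddf.copy()
        bad.loc[4, "n_boxes"] = 0
        with pytest.raises(ValidationError, match="row 4"):
            visits_from_frames(vdf, bad)
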