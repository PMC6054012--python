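import datetime as dt

import numpy as np
import pandas as pd
import pytest

from respdiv.trials import (
    attach_categories,
    categorize_tertiles,
    classify_value,
    impute_missing_cut_dates,
    select_reporting_set,
    unit_id_series,
)

from _oracles import tertile_partition_oracle


def _trial_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["site_id", "experiment_id", "harvest_year", "species", "cultivar",
                 "origin", "annual_dm_yield_kg_ha", "cut1_date", "cut2_date",
                 "last_cut_date"],
    )
    for col in ("cut1_date", "cut2_date", "last_cut_date"):
        df[col] = pd.to_datetime(df[col])
    return df


class TestImputation:
    def test_degenerate_data_collapses_to_group_mean(self):
        # every other cultivar at the site-year cut on DOY 180 (29 June)
        rows = []
        for cv in ("a", "b", "c"):
            rows.append(["s1", "e1", 2005, "timothy", cv, "domestic", 7000,
                         "2005-06-29", "2005-08-01", "2005-09-01"])
        rows.append(["s1", "e1", 2005, "timothy", "d", "domestic", 7000,
                     None, "2005-08-01", "2005-09-01"])
        df = _trial_frame(rows)
        out, log = impute_missing_cut_dates(df)
        assert out.loc[3, "cut1_date"] == pd.Timestamp("2005-06-29")
        assert len(log) == 1
        assert log.iloc[0]["imputed_doy"] == 180

    def test_no_missing_dates_is_identity(self):
        df = _trial_frame(
            [["s1", "e1", 2005, "timothy", "a", "domestic", 7000,
              "2005-06-20", "2005-08-01", "2005-09-01"]]
        )
        out, log = impute_missing_cut_dates(df)
        assert log.empty
        pd.testing.assert_frame_equal(
            out.drop(columns="excluded_reason"), df, check_dtype=False
        )

    def test_site_year_without_any_dates_is_flagged(self):
        rows = [
            ["s1", "e1", 2005, "timothy", "a", "domestic", 7000,
             "2005-06-20", "2005-08-01", "2005-09-01"],
            ["s2", "e1", 2006, "timothy", "a", "domestic", 7000,
             None, None, None],
        ]
        out, _ = impute_missing_cut_dates(_trial_frame(rows))
        assert out.loc[1, "excluded_reason"] == "no_observed_cut_dates_in_site_year"
        assert pd.isna(out.loc[1, "cut1_date"])

    def test_recovery_of_masked_dates(self):
        """Planted site-year effects + species offsets + sd-2 noise are
        recovered with RMSE <= 3 days when ~1% of dates are masked."""
        errors = []
        for rep in range(100):
            rng = np.random.default_rng([77, rep])
            rows, truth = [], []
            species_offset = {"timothy": 0.0, "meadow_fescue": 3.0}
            for s in range(4):
                for y in (2005, 2006):
                    sy_eff = rng.normal(0.0, 5.0)
                    for cv in range(4):
                        sp = "timothy" if cv < 2 else "meadow_fescue"
                        base = 165 + sy_eff + species_offset[sp]
                        doys = [base + rng.normal(0, 2.0),
                                base + 45 + rng.normal(0, 2.0),
                                base + 85 + rng.normal(0, 2.0)]
                        dates = [
                            dt.date(y, 1, 1) + dt.timedelta(days=int(round(v)) - 1)
                            for v in doys
                        ]
                        rows.append([f"s{s}", "e1", y, sp, f"cv{cv}", "domestic",
                                     7000, *[d.isoformat() for d in dates]])
            df = _trial_frame(rows)
            n_cells = len(df) * 3
            n_mask = max(1, int(round(0.01 * n_cells)))
            flat = [(i, c) for i in df.index
                    for c in ("cut1_date", "cut2_date", "last_cut_date")]
            masked = [flat[k] for k in
                      rng.choice(len(flat), n_mask, replace=False)]
            true_vals = {mc: df.at[mc[0], mc[1]] for mc in masked}
            for i, c in masked:
                df.at[i, c] = pd.NaT
            out, log = impute_missing_cut_dates(df)
            for (i, c), truth_date in true_vals.items():
                got = out.at[i, c]
                errors.append((got - truth_date).days)
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse <= 3.0, rmse


class TestReportingSet:
    def _cultivar_frame(self, counts, year=2005):
        rows = []
        for cv, n in counts.items():
            for k in range(n):
                rows.append(["s1", f"e{k}", year, "timothy", cv, "domestic",
                             7000, "2005-06-20", "2005-08-01", "2005-09-01"])
        return _trial_frame(rows)

    def test_twenty_observation_rule(self):
        df = self._cultivar_frame({"old": 19, "new": 20})
        est, reporting = select_reporting_set(df)
        assert reporting == ["new"]
        assert len(est) == 39  # estimation set keeps everything

    def test_masking_excludes_per_variable_only(self):
        df = self._cultivar_frame({"a": 22, "b": 25})
        usable = pd.Series(True, index=df.index)
        usable.iloc[:5] = False  # five of cultivar a's observations unusable
        _, reporting = select_reporting_set(df, usable=usable)
        assert reporting == ["b"]
        _, full = select_reporting_set(df)
        assert full == ["a", "b"]

    def test_outside_year_range_not_reported(self):
        df = self._cultivar_frame({"legacy": 30}, year=1995)
        with pytest.raises(ValueError, match="no cultivar"):
            select_reporting_set(df)

    def test_idempotent(self):
        df = self._cultivar_frame({"a": 25})
        est, rep1 = select_reporting_set(df)
        _, rep2 = select_reporting_set(est)
        assert rep1 == rep2


class TestTertiles:
    def test_printed_breakpoint_example(self):
        # cold-stress-day categories: low 0–10, moderate 11–21, high >21
        assert classify_value(5, (10, 21)) == "low"
        assert classify_value(15, (10, 21)) == "moderate"
        assert classify_value(30, (10, 21)) == "high"

    def test_nine_distinct_units_split_in_thirds(self):
        values = pd.Series({f"u{i}": float(i) for i in range(9)})
        counts = pd.Series(1, index=values.index)
        labels, (b1, b2) = categorize_tertiles(values, counts)
        assert list(labels.value_counts()[["low", "moderate", "high"]]) == [3, 3, 3]
        assert (b1, b2) == (2.0, 5.0)
        # monotone in value
        assert set(labels[values <= b1]) == {"low"}
        assert set(labels[values > b2]) == {"high"}

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n_units = int(rng.integers(3, 13))
            values = rng.choice([1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 13.0], n_units)
            if len(np.unique(values)) < 3:
                continue
            counts = rng.integers(1, 7, n_units)
            s_vals = pd.Series(values, index=[f"u{i}" for i in range(n_units)])
            s_counts = pd.Series(counts, index=s_vals.index)
            labels, _ = categorize_tertiles(s_vals, s_counts)
            total = counts.sum()
            achieved = max(
                abs(s_counts[labels == lab].sum() - total / 3.0)
                for lab in ("low", "moderate", "high")
            )
            assert achieved == pytest.approx(
                tertile_partition_oracle(values, counts)
            )

    def test_ties_stay_together_and_degenerate_raises(self):
        values = pd.Series([1.0, 2.0, 2.0, 2.0, 3.0, 4.0],
                           index=[f"u{i}" for i in range(6)])
        counts = pd.Series(1, index=values.index)
        labels, _ = categorize_tertiles(values, counts)
        tied = labels[values == 2.0]
        assert tied.nunique() == 1
        with pytest.raises(ValueError, match="degenerate"):
            categorize_tertiles(
                pd.Series([5.0, 5.0, 5.0]), pd.Series([1, 1, 1])
            )


class TestAttachCategories:
    def test_unit_label_integrity(self):
        rows = []
        for u in range(6):
            for cv in ("a", "b"):
                rows.append([f"s{u % 3}", f"e{u // 3}", 2005, "timothy", cv,
                             "domestic", 7000, "2005-06-20", "2005-08-01",
                             "2005-09-01"])
        df = _trial_frame(rows)
        uids = sorted(unit_id_series(df).unique())
        unit_values = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=uids
        )
        out, breakpoints = attach_categories(df, unit_values, "GP_TSUM5")
        per_unit = out.groupby("unit")["category"].nunique()
        assert (per_unit == 1).all()
        assert out["variable_id"].eq("GP_TSUM5").all()
        assert breakpoints[0] < breakpoints[1]
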