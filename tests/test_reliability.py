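"""Session averaging, ICC estimation and reliability banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aclscreen.reliability import (
    classify_icc,
    icc_absolute_agreement,
    reliability_report,
    session_average,
)
from aclscreen.simulate import CohortBlueprint, simulate_cohort


def _per_rep(values_by_cell, index="PL"):
    rows = []
    for (subj, sess), vals in values_by_cell.items():
        for r, v in enumerate(vals):
            rows.append(
                {"subject_id": subj, "session_id": sess, "leg": "dominant",
                 "rep": r, "flagged": np.isnan(v), index: v}
            )
    return pd.DataFrame(rows)


class TestSessionAverage:
    def test_plain_mean(self):
        df = _per_rep({("S1", "a"): [1, 2, 3, 4, 5], ("S1", "b"): [2, 2, 2, 2, 2]})
        tbl = session_average(df, "PL")
        assert tbl.values.loc["S1", "a"] == pytest.approx(3.0)

    def test_flagged_reps_excluded(self):
        df = _per_rep({("S1", "a"): [1, 2, 3, 4, np.nan], ("S1", "b"): [1, 1, 1, 1, 1]})
        tbl = session_average(df, "PL")
        assert tbl.values.loc["S1", "a"] == pytest.approx(2.5)

    def test_incomplete_subjects_dropped_and_counted(self):
        df = _per_rep({("S1", "a"): [1], ("S1", "b"): [2], ("S2", "a"): [3]})
        tbl = session_average(df, "PL")
        assert tbl.n == 1 and tbl.n_dropped == 1


class TestIcc:
    def test_identical_sessions_give_one(self):
        x = np.tile([[1.0], [2.0], [3.0]], (1, 3))
        res = icc_absolute_agreement(x)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent" and res.acceptable

    def test_no_subject_variance_gives_nonpositive(self):
        x = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        res = icc_absolute_agreement(x)
        assert res.icc <= 0
        assert res.band == "poor" and not res.acceptable

    def test_zero_total_variance_degenerate(self):
        res = icc_absolute_agreement(np.ones((4, 3)))
        assert res.degenerate and np.isnan(res.icc)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1, (12, 1))
        mine = icc_absolute_agreement(x).icc
        df = pd.DataFrame(
            {"s": np.repeat(np.arange(12), 3), "r": np.tile(np.arange(3), 12), "y": x.ravel()}
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_icc = float(ref.loc[mask, "ICC"].iloc[0])
        assert mine == pytest.approx(ref_icc, abs=1e-10)

    @given(st.floats(-100, 100), st.floats(0.1, 50))
    def test_invariant_to_shift_and_positive_scale(self, shift, scale):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
        a = icc_absolute_agreement(x).icc
        b = icc_absolute_agreement(scale * x + shift).icc
        assert b == pytest.approx(a, rel=1e-8, abs=1e-10)

    def test_monte_carlo_consistency_large_n(self):
        """Estimator mean approaches the variance-component ratio as n grows."""
        ests = []
        for rep in range(200):
            cb = CohortBlueprint(
                index_means={"x": 0.0}, sigma2_subject=0.8, sigma2_session=0.0,
                sigma2_error=0.2, n_subjects=60, n_sessions=3, seed=rep,
            )
            wide = simulate_cohort(cb).pivot(index="subject_id", columns="session_id", values="x")
            ests.append(icc_absolute_agreement(wide.to_numpy()).icc)
        assert np.mean(ests) == pytest.approx(0.8, abs=0.01)


class TestBands:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.96, "excellent"),  # highest reported jump-task value
            (0.65, "good"),       # lowest reported jump-task value
            (0.66, "good"),
            (0.70, "good"),
            (0.60, "good"),       # acceptability boundary is inclusive
            (0.59, "fair"),
            (0.40, "fair"),
            (0.39, "poor"),
            (-0.2, "poor"),
            (0.75, "excellent"),
            (1.0, "excellent"),
        ],
    )
    def test_banding(self, icc, band):
        assert classify_icc(icc) == band

    def test_band_map_is_monotone_step(self):
        order = {"poor": 0, "fair": 1, "good": 2, "excellent": 3}
        grid = [order[classify_icc(v)] for v in np.linspace(-0.5, 1.0, 301)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))


def test_reliability_report_gates_indices():
    rng = np.random.default_rng(3)
    cells = {}
    for s in range(8):
        base = rng.normal(10, 2)
        for j, sess in enumerate("abc"):
            cells[(f"S{s}", sess)] = list(base + rng.normal(0, 0.1, 5))
    df = _per_rep(cells, index="PL")
    df["EA"] = rng.normal(5, 1, len(df))  # pure noise: unreliable
    rep = reliability_report(df, ["PL", "EA"])
    pl = rep.set_index("index").loc["PL"]
    ea = rep.set_index("index").loc["EA"]
    assert pl["acceptable"] and pl["icc"] > 0.9
    assert not ea["acceptable"]
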