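"""Inter-session reliability of the movement indices.

For each index, repetition values are averaged within each subject-session
cell and the intraclass correlation coefficient across sessions is computed
from the two-way ANOVA decomposition (two-way mixed-effects model, absolute
agreement, single measure):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R the between-subjects, MS_C the between-sessions and MS_E the
residual mean squares of the n-subjects x k-sessions table.  Reliability is
banded as poor [0.00, 0.40), fair [0.40, 0.60), good [0.60, 0.75) and
excellent [0.75, 1.0], and an index is acceptable for screening use when
ICC >= 0.60.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ACCEPTABILITY_THRESHOLD = 0.60

#: reliability bands as (lower edge, label); negative estimates band as poor
BANDS = ((0.75, "excellent"), (0.60, "good"), (0.40, "fair"), (-np.inf, "poor"))


@dataclass
class SessionTable:
    """Session-averaged values of one index: rows subjects, columns sessions."""

    values: pd.DataFrame  # index: subject_id, columns: session_id
    index_name: str
    n_dropped: int = 0  # incomplete-case rows removed

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class IccResult:
    icc: float
    model: str
    n: int
    k: int
    band: str
    acceptable: bool
    index_name: str = ""
    degenerate: bool = False


def session_average(
    per_rep: pd.DataFrame,
    index_name: str,
    leg: str = "dominant",
) -> SessionTable:
    """Average valid repetitions within each subject-session cell.

    ``per_rep`` is a tidy table with columns ``subject_id``, ``session_id``,
    ``leg``, ``flagged`` (optional) and one column per index.  Flagged
    repetitions and NaNs are excluded; subjects missing any session are
    dropped (complete cases) with the count reported on the result.
    """
    df = per_rep
    if "leg" in df.columns:
        df = df[df["leg"] == leg]
    if "flagged" in df.columns:
        df = df[~df["flagged"].astype(bool)]
    df = df.dropna(subset=[index_name])
    cell = df.groupby(["subject_id", "session_id"])[index_name].mean()
    wide = cell.unstack("session_id")
    complete = wide.dropna()
    return SessionTable(
        values=complete, index_name=index_name, n_dropped=wide.shape[0] - complete.shape[0]
    )


def icc_absolute_agreement(tbl: SessionTable | pd.DataFrame | np.ndarray) -> IccResult:
    """Single-measure absolute-agreement ICC of a subjects x sessions table."""
    if isinstance(tbl, SessionTable):
        x = tbl.values.to_numpy(dtype=float)
        name = tbl.index_name
    else:
        x = np.asarray(getattr(tbl, "values", tbl), dtype=float)
        name = getattr(tbl, "index_name", "")
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x sessions table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires at least 2 subjects and 2 sessions")
    if np.isnan(x).any():
        raise ValueError("ICC requires a complete matrix")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    model = "two-way mixed, absolute agreement, single measure"
    if denom <= 0 or (ms_r == 0 and ms_c == 0 and ms_e == 0):
        return IccResult(
            icc=float("nan"), model=model, n=n, k=k, band="poor",
            acceptable=False, index_name=name, degenerate=True,
        )
    icc = float((ms_r - ms_e) / denom)
    return IccResult(
        icc=icc,
        model=model,
        n=n,
        k=k,
        band=classify_icc(icc),
        acceptable=icc >= ACCEPTABILITY_THRESHOLD,
        index_name=name,
    )


def classify_icc(icc: float) -> str:
    """Band an ICC point estimate; boundaries are inclusive at the lower edge."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite to classify")
    for lower, label in BANDS:
        if icc >= lower:
            return label
    raise AssertionError("unreachable")


def reliability_report(
    per_rep: pd.DataFrame,
    index_names: list[str],
    leg: str = "dominant",
) -> pd.DataFrame:
    """ICC report for a set of indices (one row each).

    Columns: index, icc, band, acceptable, n, k, n_dropped.  Indices that
    pass the acceptability gate (ICC >= 0.60) feed the downstream case-study
    comparisons.
    """
    rows = []
    for name in index_names:
        tbl = session_average(per_rep, name, leg=leg)
        res = icc_absolute_agreement(tbl)
        rows.append(
            {
                "index": name,
                "icc": res.icc,
                "band": res.band,
                "acceptable": res.acceptable,
                "n": res.n,
                "k": res.k,
                "n_dropped": tbl.n_dropped,
            }
        )
    return pd.DataFrame(rows)
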