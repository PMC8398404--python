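"""Case-study inference over reliability-gated indices.

Three comparisons mirror a return-to-play screening workflow:

* the injured athlete's pre-injury (PRE) values against the uninjured
  control group (CG), one Welch two-sample t-test per index;
* a one-way ANOVA across the athlete's sessions per index, followed -- only
  when the omnibus test is significant -- by pairwise t-tests with
  Bonferroni correction;
* each post-operative session against CG, again per-index t-tests.

Significance is declared at alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ComparisonResult:
    index_name: str
    test: str  # "t_test" | "anova" | "bonferroni_pair"
    statistic: float
    p_value: float
    significant: bool
    groups: tuple[str, ...]
    group_means_sds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "test": self.test,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "group_means_sds": {g: list(v) for g, v in self.group_means_sds.items()},
        }


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def compare_to_reference(
    athlete_values,
    cg_values,
    index_name: str = "",
    alpha: float = ALPHA,
    labels: tuple[str, str] = ("athlete", "CG"),
) -> ComparisonResult:
    """Welch two-sample two-sided t-test of athlete values against CG values."""
    a = np.asarray(athlete_values, dtype=float)
    b = np.asarray(cg_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        index_name=index_name,
        test="t_test",
        statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        groups=labels,
        group_means_sds={labels[0]: _mean_sd(a), labels[1]: _mean_sd(b)},
    )


def pairwise_bonferroni(
    groups: dict[str, np.ndarray],
    index_name: str = "",
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """All pairwise Welch t-tests with Bonferroni-adjusted p-values.

    Adjusted p = raw p times the number of pairs, capped at 1.
    """
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(groups[names[i]], dtype=float)
            b = np.asarray(groups[names[j]], dtype=float)
            t, p = stats.ttest_ind(a, b, equal_var=False)
            p_adj = min(1.0, float(p) * m)
            out.append(
                ComparisonResult(
                    index_name=index_name,
                    test="bonferroni_pair",
                    statistic=float(t),
                    p_value=p_adj,
                    significant=bool(p_adj < alpha),
                    groups=(names[i], names[j]),
                    group_means_sds={names[i]: _mean_sd(a), names[j]: _mean_sd(b)},
                )
            )
    return out


def longitudinal_anova(
    session_values: dict[str, np.ndarray],
    index_name: str = "",
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """One-way ANOVA across sessions, Bonferroni post hoc when significant.

    Returns the omnibus result first; pairwise results follow only when the
    omnibus p-value is below ``alpha``.  Degenerate inputs (a session with
    zero variance everywhere) propagate scipy's NaN statistics and suppress
    the post hoc.
    """
    if len(session_values) < 2:
        raise ValueError("need at least 2 sessions")
    arrays = [np.asarray(v, dtype=float) for v in session_values.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each session needs at least 2 values")
    f, p = stats.f_oneway(*arrays)
    omnibus = ComparisonResult(
        index_name=index_name,
        test="anova",
        statistic=float(f),
        p_value=float(p),
        significant=bool(np.isfinite(p) and p < alpha),
        groups=tuple(session_values),
        group_means_sds={g: _mean_sd(np.asarray(v, float)) for g, v in session_values.items()},
    )
    results = [omnibus]
    if omnibus.significant:
        results.extend(pairwise_bonferroni(session_values, index_name, alpha))
    return results


def build_case_report(
    pre: dict[str, np.ndarray],
    posts: dict[str, dict[str, np.ndarray]],
    cg: dict[str, np.ndarray],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Mean (SD) table of every group/session with significance vs CG.

    ``pre`` and each entry of ``posts`` map index name -> athlete repetition
    values; ``cg`` maps index name -> per-subject control values.  The
    result is tidy: one row per (index, group), columns ``mean``, ``sd``,
    ``significant_vs_cg`` (NaN-safe booleans; CG rows carry False).
    """
    rows = []
    for name, cg_vals in cg.items():
        cg_vals = np.asarray(cg_vals, dtype=float)
        mu, sd = _mean_sd(cg_vals)
        rows.append(
            {"index": name, "group": "CG", "mean": mu, "sd": sd, "significant_vs_cg": False}
        )
        for label, values in [("PRE", pre.get(name))] + [
            (s, posts[s].get(name)) for s in posts
        ]:
            if values is None:
                continue
            res = compare_to_reference(values, cg_vals, name, alpha, labels=(label, "CG"))
            mu, sd = _mean_sd(np.asarray(values, float))
            rows.append(
                {
                    "index": name,
                    "group": label,
                    "mean": mu,
                    "sd": sd,
                    "significant_vs_cg": res.significant,
                }
            )
    return pd.DataFrame(rows)
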