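"""Statistical battery: Pearson chi-square, Mann-Whitney U, Mann-Kendall.

Chi-square (with optional Yates continuity correction on 2x2 tables) and
Mann-Whitney delegate to scipy.stats behind a typed result surface;
Mann-Kendall is implemented here (S statistic, tie-corrected variance,
continuity-corrected normal Z).  :func:`reproduce_study_tables` recomputes
the engagement/break statistics from the embedded published count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("contingency table needs at least 1 row and 2 columns")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count grid")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("grand total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool
    expected: np.ndarray


@dataclass(frozen=True)
class RankTestResult:
    statistic_U: float
    statistic_W: float  # rank-sum of sample 1 minus its minimum == U of sample 1
    p_value: float
    method: Literal["exact", "normal approximation"]


@dataclass(frozen=True)
class TrendResult:
    S: int
    var_S: float
    Z: float
    p_value: float


def chi_square(table: ContingencyTable, yates: bool = True) -> ChiSquareResult:
    """Pearson chi-square test of independence.

    The 0.5 Yates continuity correction is applied only to 2x2 tables and
    only when ``yates`` is true (the convention needed to reproduce published
    2x2 statistics computed with standard software).
    """
    obs = table.array
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("chi-square needs at least a 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    is_2x2 = obs.shape == (2, 2)
    res = sps.chi2_contingency(obs, correction=yates and is_2x2)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        correction_applied=yates and is_2x2,
        expected=np.asarray(res.expected_freq),
    )


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> RankTestResult:
    """Mann-Whitney U test; U and W both follow the sample-1 convention.

    U counts pairs (x_i, y_j) with x_i > y_j (ties count one half), which
    equals the rank-sum of sample 1 minus n1(n1+1)/2 — the quantity many
    packages print as W.  The null distribution is exact for small tie-free
    samples and a tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = not has_ties and x.size <= 8 and y.size <= 8
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    u1 = float(res.statistic)
    return RankTestResult(
        statistic_U=u1,
        statistic_W=u1,
        p_value=float(res.pvalue),
        method="exact" if exact else "normal approximation",
    )


def mann_kendall(series: Sequence[float]) -> TrendResult:
    """Mann-Kendall test for a monotonic trend in an ordered series.

    S sums sign(x_j - x_i) over all i < j; its variance uses the standard
    tie correction, and Z applies the +/-1 continuity correction (Z = 0 when
    S = 0).  The p-value is two-sided normal.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 observations")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float((tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)).sum())
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TrendResult(S=s, var_S=var_s, Z=float(z), p_value=float(min(p, 1.0)))


# --------------------------------------------------------------------------
# Published count tables of the source study (message-type x break,
# framing x break, engagement x arm, gender/age x engagement) and the
# statistics printed for them.

STUDY_TABLES: dict[str, dict] = {
    "chi2_message_type_break": {
        "table": ContingencyTable(
            ("context_aware", "static"),
            ("did_not_break", "broke"),
            ((2447, 2781), (901, 224)),
        ),
        "yates": True,
        "printed": 410.1,
    },
    "chi2_framing_break": {
        "table": ContingencyTable(
            ("gain_framed", "loss_framed", "self_efficacy"),
            ("did_not_break", "broke"),
            ((1467, 1591), (672, 807), (308, 383)),
        ),
        "yates": False,
        "printed": 4.2,
    },
    "chi2_engagement_arm": {
        "table": ContingencyTable(
            ("inactive", "semiactive", "active"),
            ("control", "intervention"),
            ((11, 1), (12, 12), (6, 16)),
        ),
        "yates": False,
        "printed": 12.9,
    },
    "chi2_gender_engagement": {
        "table": ContingencyTable(
            ("male", "female"),
            ("inactive", "semiactive", "active"),
            ((1, 5, 6), (0, 7, 10)),
        ),
        "yates": False,
        "printed": 1.5,
    },
    "chi2_age_engagement": {
        "table": ContingencyTable(
            ("23-30", "31-39"),
            ("inactive", "semiactive", "active"),
            ((0, 9, 12), (1, 3, 4)),
        ),
        "yates": False,
        "printed": 2.7,
    },
}

STUDY_PROPORTIONS: dict[str, dict] = {
    "pct_gain_framed": {"num": 3058, "den": 5228, "printed": 58.49},
    "pct_loss_framed": {"num": 1479, "den": 5228, "printed": 28.29},
    "pct_self_efficacy": {"num": 691, "den": 5228, "printed": 13.22},
    "pct_context_aware_broke": {"num": 2781, "den": 5228, "printed": 53.19},
}

CHI2_TOLERANCE = 0.2   # printed to one decimal
PCT_TOLERANCE = 0.005  # printed to two decimals


def reproduce_study_tables() -> list[dict]:
    """Recompute every embedded published statistic and compare to print.

    Returns one record per statistic:
    ``{test_id, recomputed, printed, tolerance, pass}``.
    """
    report: list[dict] = []
    for test_id, spec in STUDY_TABLES.items():
        result = chi_square(spec["table"], yates=spec["yates"])
        report.append(
            {
                "test_id": test_id,
                "recomputed": round(result.statistic, 4),
                "printed": spec["printed"],
                "tolerance": CHI2_TOLERANCE,
                "pass": abs(result.statistic - spec["printed"]) <= CHI2_TOLERANCE,
            }
        )
    for test_id, spec in STUDY_PROPORTIONS.items():
        pct = 100.0 * spec["num"] / spec["den"]
        report.append(
            {
                "test_id": test_id,
                "recomputed": round(pct, 4),
                "printed": spec["printed"],
                "tolerance": PCT_TOLERANCE,
                "pass": abs(round(pct, 2) - spec["printed"]) <= PCT_TOLERANCE,
            }
        )
    return report
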