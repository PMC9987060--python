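"""One-way ANOVA and pairwise comparisons from printed summary statistics.

Morphometric tables usually print only group mean +/- SE and n.  The
classic one-way ANOVA F statistic and all pairwise Welch t-tests are
exactly recoverable from those summaries (SD = SE * sqrt(n)), so the
significance-letter pattern of such a table can be reproduced without the
raw measurements.  Letters are assigned by descending mean: two groups
share a letter iff their pairwise Welch test is non-significant at alpha.

No multiplicity correction is applied to the pairwise tests; with three
groups and a highly significant omnibus F this matches the usual
"different letters differ at the 0.01 level" convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean, standard error, sample size."""

    label: str
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2")
        if self.se <= 0:
            raise ValueError(f"group {self.label!r}: SE must be positive")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd**2


def anova_oneway_summary(groups: list[GroupSummary]) -> tuple[float, float]:
    """One-way ANOVA (F, p) reconstructed from group summaries.

    F has (k-1, N-k) degrees of freedom with k groups and N total
    observations; between-group SS uses the printed means, within-group SS
    the recovered SDs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    k = len(groups)
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    variances = np.array([g.var for g in groups])
    N = ns.sum()
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * variances).sum()
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    if ms_within == 0:
        return (float("inf"), 0.0) if ms_between > 0 else (0.0, 1.0)
    F = ms_between / ms_within
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


def welch_t_summary(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float, float]:
    """Welch two-sample t-test from summaries: (t, df, p two-sided)."""
    se2_1 = g1.var / g1.n  # == g1.se**2
    se2_2 = g2.var / g2.n
    denom = np.sqrt(se2_1 + se2_2)
    t = (g1.mean - g2.mean) / denom
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (g1.n - 1) + se2_2**2 / (g2.n - 1)
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def pairwise_letters(
    groups: list[GroupSummary], alpha: float = 0.01
) -> dict[str, str]:
    """Compact letter display from all pairwise Welch tests.

    Groups are ordered by descending mean; letters are generated so that
    two groups share a letter iff their pairwise test has p >= alpha.
    Every group receives at least one letter.
    """
    order = sorted(groups, key=lambda g: -g.mean)
    k = len(order)
    nonsig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        nonsig[i, i] = True
        for j in range(i + 1, k):
            _, _, p = welch_t_summary(order[i], order[j])
            nonsig[i, j] = nonsig[j, i] = p >= alpha

    # maximal runs of mutually non-significant groups, scanned in mean order
    letter_sets: list[set[int]] = []
    for i in range(k):
        grp = {i}
        for j in range(i + 1, k):
            if all(nonsig[j, m] for m in grp):
                grp.add(j)
            else:
                break
        if not any(grp <= prev for prev in letter_sets):
            letter_sets.append(grp)

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g.label: [] for g in order}
    for letter, members in zip(alphabet, letter_sets):
        for m in sorted(members):
            letters[order[m].label].append(letter)
    return {label: "".join(ls) for label, ls in letters.items()}


# ---------------------------------------------------------------------------
# Reference morphometric summary table
# ---------------------------------------------------------------------------

#: Published body-size summaries (mean +/- SE, micrometres) for worker bees
#: of the three geographic populations SZ (n=50), WC (n=50) and MK (n=30):
#: forewing length/width (FL, FB), sternum and tergum measures (L6, T6, S3,
#: T3+T4), femur and tibia lengths (Fe, Ti) and basitarsus length/width
#: (ML, MT).  Used as the worked example for summary-based ANOVA.
WORKER_MORPHOMETRY: dict[str, list[GroupSummary]] = {
    indicator: [
        GroupSummary("SZ", sz_m, sz_se, 50),
        GroupSummary("WC", wc_m, wc_se, 50),
        GroupSummary("MK", mk_m, mk_se, 30),
    ]
    for indicator, (sz_m, sz_se, wc_m, wc_se, mk_m, mk_se) in {
        "FL": (8331.13, 26.53, 8074.91, 27.68, 8882.34, 28.50),
        "FB": (2791.07, 9.08, 2735.01, 9.07, 3031.05, 16.88),
        "L6": (2257.05, 11.71, 2153.16, 10.91, 2415.90, 7.09),
        "T6": (2720.43, 13.67, 2523.80, 10.81, 2916.17, 16.17),
        "S3": (2359.32, 10.33, 2221.33, 8.87, 2490.51, 13.15),
        "T3+T4": (3567.59, 15.91, 3415.16, 16.41, 3729.79, 16.99),
        "Fe": (2329.92, 12.12, 2267.87, 7.95, 2504.20, 21.66),
        "Ti": (2759.91, 17.55, 2691.96, 16.66, 3074.32, 21.23),
        "ML": (1924.61, 11.36, 1853.14, 9.20, 2038.29, 14.37),
        "MT": (1055.57, 4.84, 1040.64, 6.15, 1095.52, 7.14),
    }.items()
}


def read_summary_table(path: str) -> dict[str, list[GroupSummary]]:
    """Read a TSV of printed summaries: indicator, group, mean, se, n."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"indicator", "group", "mean", "se", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    out: dict[str, list[GroupSummary]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.indicator), []).append(
            GroupSummary(str(row.group), float(row.mean), float(row.se), int(row.n))
        )
    return out
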