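"""Well-level statistical battery: one-way ANOVA + Tukey HSD, Mann-Whitney + BH.

Statistical units are wells (each data point is a well), never cells.  The
false-discovery family is the list of contrasts supplied in one call — the
per-figure-panel analogue (all dose x group contrasts of one experiment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment: str
    n_per_group: tuple[int, ...]


def anova_tukey(groups: dict[str, Sequence[float]]) -> list[ComparisonResult]:
    """One-way ANOVA across groups, then all pairwise Tukey HSD contrasts.

    The first result row carries the omnibus F test; subsequent rows carry the
    Tukey-adjusted pairwise comparisons.
    """
    labels = sorted(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 2 or any(d.size < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(d) == 0 for d in data):
        raise ValueError("zero within-group variance in all groups")

    f_stat, f_p = sps.f_oneway(*data)
    results = [ComparisonResult(
        contrast="omnibus:" + "|".join(labels), test="one-way ANOVA",
        statistic=float(f_stat), p_raw=float(f_p), p_adjusted=float(f_p),
        adjustment="none", n_per_group=tuple(d.size for d in data))]

    tukey = sps.tukey_hsd(*data)
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            results.append(ComparisonResult(
                contrast=f"{labels[i]} vs {labels[j]}",
                test="Tukey HSD",
                statistic=float(tukey.statistic[i, j]),
                p_raw=float(tukey.pvalue[i, j]),
                p_adjusted=float(tukey.pvalue[i, j]),
                adjustment="tukey",
                n_per_group=(data[i].size, data[j].size)))
    return results


def mannwhitney_fdr(
    pairs: Sequence[tuple[str, Sequence[float], Sequence[float]]],
) -> list[ComparisonResult]:
    """Two-sided Mann-Whitney U per contrast, Benjamini-Hochberg across the family.

    The U statistic is exact for group sizes <= 8 with no ties, and the
    tie-corrected normal approximation otherwise.  All-tied data yields p = 1.
    """
    if not pairs:
        return []
    stats, raw = [], []
    meta = []
    for label, a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 3 or b.size < 3:
            raise ValueError(f"contrast {label!r}: each sample needs n >= 3")
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = a.size * b.size / 2.0, 1.0
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                   use_continuity=False)
            u, p = float(res.statistic), float(min(res.pvalue, 1.0))
        stats.append(u)
        raw.append(p)
        meta.append((label, method, (a.size, b.size)))

    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    return [
        ComparisonResult(
            contrast=label, test=f"Mann-Whitney U ({method})",
            statistic=u, p_raw=p, p_adjusted=float(q),
            adjustment="fdr_bh", n_per_group=n)
        for (label, method, n), u, p, q in zip(meta, stats, raw, adjusted)
    ]


def results_to_frame(results: Sequence[ComparisonResult]):
    """Tabulate comparison results for CSV output."""
    import pandas as pd

    return pd.DataFrame([{
        "contrast": r.contrast, "test": r.test, "statistic": r.statistic,
        "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
        "adjustment": r.adjustment,
        "n_per_group": "|".join(map(str, r.n_per_group)),
    } for r in results])
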