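"""Group-comparison and correlation statistics for image-derived measures.

Abundance fractions from sets of Type-1 and Type-2 images are compared with
a Welch two-sample t-test (two groups) or one-way ANOVA with Bonferroni and
Scheffe a-posteriori pairwise decisions (more groups), after an optional
normalising transform — the arcsine-square-root for percent data, the log
for strictly positive skewed data.  Pearson product-moment correlation with
its two-sided t-distributed p-value serves the area-area association
analyses (e.g. SRM area vs CaCO3 precipitate area per image).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, ParameterError

__all__ = ["GroupComparison", "compare_groups", "correlate"]

TRANSFORMS = ("none", "arcsine-sqrt", "log")


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "arcsine-sqrt":
        if (values < 0).any() or (values > 100).any():
            raise ParameterError("arcsine-sqrt expects percent values in [0, 100]")
        return np.arcsin(np.sqrt(values / 100.0))
    if transform == "log":
        if (values <= 0).any():
            raise ParameterError("log transform expects strictly positive values")
        return np.log(values)
    raise ParameterError(f"unknown transform {transform!r}; one of {TRANSFORMS}")


@dataclass
class GroupComparison:
    """Result of a two-group or multi-group comparison.

    Group means and standard errors are reported on the original scale; the
    test itself runs on the transformed scale.  ``posthoc`` (multi-group
    only) holds one row per group pair with the Bonferroni and Scheffe
    decisions at the chosen alpha.
    """

    groups: pd.DataFrame  # label, n, mean, se
    design: str
    transform: str
    statistic: float
    df: tuple
    p_value: float
    alpha: float
    posthoc: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"{self.design} comparison (transform: {self.transform})"]
        for row in self.groups.itertuples(index=False):
            lines.append(
                f"  {row.label}: n={row.n}, mean={row.mean:.3f} (SE {row.se:.3f})"
            )
        stat_name = "t" if self.design == "two-group" else "F"
        df_txt = ", ".join(f"{d:g}" for d in self.df)
        lines.append(
            f"  {stat_name} = {self.statistic:.4f}, df = ({df_txt}), p = {self.p_value:.4g}"
        )
        if self.posthoc is not None and len(self.posthoc):
            lines.append("  post-hoc pairwise decisions (alpha = %.2f):" % self.alpha)
            for row in self.posthoc.itertuples(index=False):
                lines.append(
                    f"    {row.group_a} vs {row.group_b}: "
                    f"Bonferroni {'different' if row.bonferroni_reject else 'ns'}, "
                    f"Scheffe {'different' if row.scheffe_reject else 'ns'}"
                )
        return "\n".join(lines)


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    design: str | None = None,
    transform: str = "none",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare group means with the appropriate parametric test.

    Two groups: Welch (unequal-variance) t-test on the transformed values.
    More groups: one-way ANOVA, followed by Bonferroni-corrected pooled-MSE
    pairwise t-tests and Scheffe pairwise contrasts, both at ``alpha``.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise DegenerateInputError("need at least 2 groups")
    raw = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in raw.items():
        if len(v) < 2:
            raise DegenerateInputError(f"group {k!r} has n < 2")
    trans = {k: _apply_transform(v, transform) for k, v in raw.items()}
    if all(np.var(v) == 0 for v in trans.values()):
        means = [v.mean() for v in trans.values()]
        if len(set(means)) == 1 and len(labels) > 2:
            raise DegenerateInputError("all groups constant and identical")

    if design is None:
        design = "two-group" if len(labels) == 2 else "multi-group"
    if design not in ("two-group", "multi-group"):
        raise ParameterError("design must be 'two-group' or 'multi-group'")
    if design == "two-group" and len(labels) != 2:
        raise ParameterError("two-group design needs exactly 2 groups")

    groups_table = pd.DataFrame(
        {
            "label": labels,
            "n": [len(raw[k]) for k in labels],
            "mean": [float(raw[k].mean()) for k in labels],
            "se": [float(raw[k].std(ddof=1) / math.sqrt(len(raw[k]))) for k in labels],
        }
    )

    if design == "two-group":
        a, b = trans[labels[0]], trans[labels[1]]
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            # identical spread-free groups: no evidence of difference
            stat = 0.0 if a.mean() == b.mean() else np.inf
            p = 1.0 if a.mean() == b.mean() else 0.0
            df_w = float(len(a) + len(b) - 2)
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            stat, p, df_w = float(res.statistic), float(res.pvalue), float(res.df)
        return GroupComparison(
            groups=groups_table,
            design=design,
            transform=transform,
            statistic=stat,
            df=(df_w,),
            p_value=p,
            alpha=alpha,
        )

    # one-way ANOVA on the transformed scale
    arrays = [trans[k] for k in labels]
    k = len(arrays)
    n_total = sum(len(v) for v in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise DegenerateInputError("zero within-group variance: F undefined")
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    f_stat = ms_between / mse
    p = float(sps.f.sf(f_stat, df_b, df_w))

    # post-hoc pairwise decisions
    m = k * (k - 1) // 2
    f_crit_scheffe = float(sps.f.isf(alpha, df_b, df_w))
    rows = []
    for (i, la), (j, lb) in itertools.combinations(enumerate(labels), 2):
        va, vb = arrays[i], arrays[j]
        diff = va.mean() - vb.mean()
        se = math.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p_unadj = 2 * float(sps.t.sf(abs(t), df_w))
        p_bonf = min(p_unadj * m, 1.0)
        # Scheffe: the pairwise contrast F compared to (k-1) F_crit
        f_pair = t**2
        rows.append(
            (
                la,
                lb,
                float(diff),
                float(t),
                p_bonf,
                p_bonf < alpha,
                f_pair > df_b * f_crit_scheffe,
            )
        )
    posthoc = pd.DataFrame(
        rows,
        columns=[
            "group_a",
            "group_b",
            "mean_diff",
            "t",
            "p_bonferroni",
            "bonferroni_reject",
            "scheffe_reject",
        ],
    )
    return GroupComparison(
        groups=groups_table,
        design=design,
        transform=transform,
        statistic=float(f_stat),
        df=(float(df_b), float(df_w)),
        p_value=p,
        alpha=alpha,
        posthoc=posthoc,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-distributed p.

    Symmetric in (x, y) and invariant to affine rescaling of either
    variable (sign follows the slope).  Requires at least 3 paired values
    and non-zero variance in both.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya):
        raise ParameterError("x and y must have equal length")
    if len(xa) < 3:
        raise ParameterError("need at least 3 paired values")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)
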