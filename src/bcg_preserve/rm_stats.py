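"""One-way repeated-measures ANOVA and Bonferroni post-hoc contrasts.

The omnibus test is a standard within-subject one-way ANOVA with
Greenhouse-Geisser sphericity correction (delegated to pingouin); post-hoc
inference is a paired t-test of every non-reference condition against the
reference, with p-values multiplied by the number of contrasts and capped
at one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RMDesign", "RMResult", "rm_anova", "bonferroni_posthoc"]


@dataclass
class RMDesign:
    """Complete subjects-by-conditions value matrix."""

    values: np.ndarray            # subjects x conditions, no missing cells
    conditions: list
    reference: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x conditions")
        if self.values.shape[1] != len(self.conditions):
            raise ValueError("condition names must match the value columns")
        if self.values.shape[0] < 3 or self.values.shape[1] < 2:
            raise ValueError("need >= 3 subjects and >= 2 conditions")
        if np.isnan(self.values).any():
            raise ValueError("incomplete design: missing cells are not imputed")
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not a condition")


@dataclass
class RMResult:
    """Omnibus F with sphericity correction plus per-contrast adjusted p."""

    F: float
    df1: float                    # epsilon-corrected numerator df
    df2: float                    # epsilon-corrected denominator df
    epsilon: float
    p: float                      # omnibus p at the corrected dfs
    contrasts: dict = field(default_factory=dict)  # condition -> adjusted p


def rm_anova(design: RMDesign, correction: str = "gg") -> RMResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    With ``correction='none'`` the uncorrected dfs and p are reported
    (epsilon = 1).
    """
    n_sub, k = design.values.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n_sub), k),
        "condition": np.tile(np.asarray(design.conditions, dtype=object), n_sub),
        "value": design.values.ravel(),
    })
    import pingouin as pg
    res = pg.rm_anova(data=long, dv="value", within="condition",
                      subject="subject", correction=True, detailed=True)
    row = res.iloc[0]
    F = float(row["F"])
    eps = float(row["eps"]) if correction == "gg" else 1.0
    if not np.isfinite(eps) or eps <= 0:
        eps = 1.0  # k = 2 or degenerate covariance: no correction possible
    eps = min(1.0, max(eps, 1.0 / (k - 1)))
    df1, df2 = eps * (k - 1), eps * (k - 1) * (n_sub - 1)
    if not np.isfinite(F) or F < 1e-12:
        # identical conditions (zero between- or within-condition variance)
        F, p = 0.0, 1.0
    else:
        p = float(stats.f.sf(F, df1, df2))
    result = RMResult(F=F, df1=df1, df2=df2, epsilon=eps, p=p)
    result.contrasts = bonferroni_posthoc(design)
    return result


def bonferroni_posthoc(design: RMDesign) -> dict:
    """Paired t of each non-reference condition vs the reference.

    Raw two-sided p-values are multiplied by the number of contrasts and
    capped at 1.
    """
    ref_idx = design.conditions.index(design.reference)
    others = [c for c in design.conditions if c != design.reference]
    m = len(others)
    out = {}
    for cond in others:
        i = design.conditions.index(cond)
        d = design.values[:, i] - design.values[:, ref_idx]
        if np.allclose(d, d[0]):
            p = 1.0 if np.allclose(d, 0) else 0.0
            if not np.allclose(d, 0):
                # constant nonzero difference: t is infinite, p -> 0
                p = 0.0
        else:
            _, p = stats.ttest_rel(design.values[:, i], design.values[:, ref_idx])
        out[cond] = min(1.0, float(p) * m)
    return out
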