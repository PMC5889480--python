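"""Summary statistics and hypothesis tests for per-cell data.

The analysis unit is the cell: values enter tests one per cell, with
animal ids carried for bookkeeping (``n`` animals, ``c`` cells).  No
mixed-model nesting is attempted.  Reporting follows the mean +/- SEM
convention with asterisk notation: * p < 0.05, ** p < 0.01,
*** p < 0.001, **** p < 0.0001, ns otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ValidationError

__all__ = ["GroupResult", "mean_sem", "paired_t", "anova_dunnett",
           "star_label"]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                    (5e-2, "*"))


@dataclass
class GroupResult:
    """One comparison's summary line."""

    name: str
    mean: float
    sem: float
    n_animals: int
    c_cells: int
    test: str
    statistic: float
    p: float
    stars: str


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and standard error (SD / sqrt(k), SD with ddof=1)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValidationError("mean_sem needs at least 2 values")
    return float(values.mean()), \
        float(values.std(ddof=1) / np.sqrt(values.size))


def paired_t(pre_values, post_values) -> tuple[float, float]:
    """Two-sided paired Student's t test on per-cell differences.

    Identical vectors return (0, 1).  Non-zero differences with zero
    variance leave p undefined; (NaN, NaN) is returned with a warning.
    """
    pre = np.asarray(pre_values, dtype=np.float64)
    post = np.asarray(post_values, dtype=np.float64)
    if pre.shape != post.shape or pre.size < 2:
        raise ValidationError("paired_t needs equal-length vectors, >= 2")
    d = post - pre
    sd = d.std(ddof=1)
    k = d.size
    if sd == 0.0:
        if np.all(d == 0):
            return 0.0, 1.0
        warnings.warn("zero-variance non-zero differences: p undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    t = d.mean() / (sd / np.sqrt(k))
    p = 2.0 * sps.t.sf(abs(t), k - 1)
    return float(t), float(p)


def anova_dunnett(control_group, treatment_groups,
                  labels: list[str] | None = None,
                  random_state: int | None = 0) -> list[GroupResult]:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs control.

    Adjusted p-values come from the multivariate-t distribution of the
    Dunnett statistics (scipy); with unbalanced groups the underlying
    integration is stochastic, so a seed fixes reproducibility.
    Returns one GroupResult per treatment group, p multiplicity-
    adjusted.
    """
    control = np.asarray(control_group, dtype=np.float64)
    groups = [np.asarray(g, dtype=np.float64) for g in treatment_groups]
    if len(groups) < 1:
        raise ValidationError("need at least one treatment group")
    for g in [control] + groups:
        if g.size < 2:
            raise ValidationError("each group needs >= 2 values")
        if g.std(ddof=1) == 0:
            warnings.warn("degenerate (constant) group in ANOVA",
                          stacklevel=2)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]

    f_stat, anova_p = sps.f_oneway(control, *groups)
    rng = np.random.default_rng(random_state)
    res = sps.dunnett(*groups, control=control, random_state=rng)

    out = []
    for i, g in enumerate(groups):
        m, s = mean_sem(g)
        p = float(res.pvalue[i])
        out.append(GroupResult(
            name=labels[i], mean=m, sem=s,
            n_animals=1, c_cells=int(g.size),
            test="ANOVA+Dunnett",
            statistic=float(res.statistic[i]),
            p=p, stars=star_label(p),
        ))
    return out


def star_label(p: float) -> str:
    """Asterisk notation for a p-value.

    ns if p >= 0.05; then *, **, ***, **** at p < 0.05, 0.01, 0.001,
    0.0001.  Raises for p outside [0, 1].
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    for thr, label in _STAR_THRESHOLDS:
        if p < thr:
            return label
    return "ns"
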