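"""Group comparisons and distribution summaries for morphometric read-outs.

Group contrasts use Welch's unequal-variance t test (two-sided), the
appropriate default when wild-type and dystrophic samples differ in spread as
much as in mean.  The unit of analysis follows the measurement: cryosections
for collagen fractions, single fibers for CAS/VD, whole muscles or strips for
mechanics.  No multiple-testing correction is applied by default (single
contrast per muscle); alpha = 0.05 is reported, not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "welch_t", "distribution_summary"]


@dataclass
class GroupComparison:
    """One two-group Welch contrast, with everything a report needs."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    direction: str  # "a>b", "a<b" or "a=b"

    def to_record(self) -> dict:
        return {
            "group_a": self.label_a,
            "group_b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "direction": self.direction,
        }


def welch_t(
    sample_a,
    sample_b,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Welch's unequal-variance t test with Welch-Satterthwaite df, two-sided.

    Identical samples give t = 0, p = 1; two samples that are each constant
    (zero variance in both) leave the statistic undefined and raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            raise ValueError("zero variance in both samples: t undefined")
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        sa, sb = va / a.size, vb / b.size
        df = (sa + sb) ** 2 / (
            sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
        )
    diff = a.mean() - b.mean()
    direction = f"{labels[0]}>{labels[1]}" if diff > 0 else (
        f"{labels[0]}<{labels[1]}" if diff < 0 else f"{labels[0]}={labels[1]}"
    )
    return GroupComparison(
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=t_stat,
        df=float(df),
        p=p,
        direction=direction,
    )


def distribution_summary(values, bins) -> dict:
    """Histogram counts plus mean/SD/median of a per-fiber value population."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    counts, edges = np.histogram(v, bins=bins)
    return {
        "counts": counts,
        "bin_edges": np.asarray(edges, dtype=float),
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
    }
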