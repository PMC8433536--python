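"""Gene-level copy-number-loss calls from CBS scores and group comparisons.

A gene is called lost in a sample when its circular-binary-segmentation
log-ratio is strictly below the cutoff (default −0.5).  Samples are assigned
to disjoint groups by which 8-oxoG-repair glycosylase is lost (MUTYH, OGG1,
both, or neither), and group differences in C>A substitution fraction are
tested with a two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .variant_io import GeneCBSRecord

DEFAULT_CBS_CUTOFF = -0.5

GROUP_MUTYH = "MUTYH_CNL"
GROUP_OGG1 = "OGG1_CNL"
GROUP_WT = "WT"
GROUP_BOTH = "BOTH"


@dataclass(frozen=True)
class CNLCall:
    sample_id: str
    gene: str
    cbs: float
    is_loss: bool


@dataclass
class GroupComparison:
    """Two-group mean comparison on a per-sample statistic.

    ``df`` is the Welch–Satterthwaite degrees of freedom for the Welch
    variant, or nx + ny − 2 for the pooled Student variant.
    """

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t: float
    df: float
    p: float
    welch: bool = True


def call_cnl(
    records: list[GeneCBSRecord], cutoff: float = DEFAULT_CBS_CUTOFF
) -> list[CNLCall]:
    """Strict-inequality loss calls: loss iff cbs < cutoff."""
    return [
        CNLCall(r.sample_id, r.gene, r.cbs, bool(r.cbs < cutoff)) for r in records
    ]


class GroupAssignmentError(ValueError):
    """A sample lacks a call for one of the grouping genes."""


def assign_groups(
    calls: list[CNLCall], genes: tuple[str, str] = ("MUTYH", "OGG1")
) -> dict[str, str]:
    """Map each sample to MUTYH_CNL / OGG1_CNL / WT / BOTH.

    Samples losing both genes are flagged BOTH and reported separately: the
    two-group CNL-vs-WT contrasts keep the groups disjoint.
    """
    gene_a, gene_b = genes
    by_sample: dict[str, dict[str, bool]] = {}
    for call in calls:
        by_sample.setdefault(call.sample_id, {})[call.gene] = call.is_loss
    groups = {}
    for sample_id, losses in sorted(by_sample.items()):
        missing = [g for g in genes if g not in losses]
        if missing:
            raise GroupAssignmentError(
                f"sample {sample_id!r} has no CBS call for {missing[0]!r}"
            )
        a, b = losses[gene_a], losses[gene_b]
        if a and b:
            groups[sample_id] = GROUP_BOTH
        elif a:
            groups[sample_id] = GROUP_MUTYH
        elif b:
            groups[sample_id] = GROUP_OGG1
        else:
            groups[sample_id] = GROUP_WT
    return groups


def welch_t_test(
    x, y, labels: tuple[str, str] = ("x", "y"), welch: bool = True
) -> GroupComparison:
    """Two-sided unpaired t-test; Welch correction by default.

    Welch: t = (x̄−ȳ)/√(sx²/nx + sy²/ny) with Welch–Satterthwaite df.
    With both sample variances zero and equal means, the difference is exactly
    zero and p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        df = (
            se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
            if se2 > 0
            else float(nx + ny - 2)
        )
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = float(nx + ny - 2)
    if se2 == 0:
        t = 0.0 if mx == my else np.inf * np.sign(mx - my)
        p = 1.0 if mx == my else 0.0
    else:
        t = (mx - my) / np.sqrt(se2)
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return GroupComparison(
        group_labels=labels,
        n=(nx, ny),
        means=(float(mx), float(my)),
        t=float(t),
        df=float(df),
        p=p,
        welch=welch,
    )


def cnl_vs_wt_comparisons(
    groups: dict[str, str], ca_fraction: dict[str, float]
) -> dict[str, GroupComparison]:
    """Welch tests of C>A fraction for MUTYH-CNL vs WT and OGG1-CNL vs WT.

    BOTH-group samples are excluded from both contrasts.
    """
    pools: dict[str, list[float]] = {GROUP_MUTYH: [], GROUP_OGG1: [], GROUP_WT: []}
    for sample_id, group in groups.items():
        if group in pools and sample_id in ca_fraction:
            pools[group].append(ca_fraction[sample_id])
    out = {}
    for group in (GROUP_MUTYH, GROUP_OGG1):
        if len(pools[group]) >= 2 and len(pools[GROUP_WT]) >= 2:
            out[group] = welch_t_test(
                pools[group], pools[GROUP_WT], labels=(group, GROUP_WT)
            )
    return out
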