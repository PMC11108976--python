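"""Comparison of Pearson correlations with layered multiple-testing control.

Implements the Fisher z test for independent (between-group) correlations,
the Dunn & Clark z test for dependent overlapping (within-group)
correlations with the intercorrelation-aware covariance term, and Zou's
confidence intervals for the correlation difference in both settings.
Families of comparisons get Benjamini-Hochberg FDR across target regions
with a Bonferroni-adjusted significance threshold on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import AssociationMatrix
from .errors import ValidationError
from .regions import RegionRegistry

__all__ = [
    "fisher_rz", "independent_groups_test", "dunn_dependent_overlapping_test",
    "bh_fdr", "decide_alpha", "run_profile_comparisons",
    "CorrComparison", "ComparisonFamily", "AlphaDecision", "ProfileComparisons",
]


def fisher_rz(r: float) -> float:
    """Fisher r-to-z transform, 0.5 * ln((1+r)/(1-r))."""
    if not abs(r) < 1:
        raise ValidationError(f"fisher_rz requires |r| < 1, got {r}")
    return math.atanh(r)


def _check_r(name: str, r: float) -> float:
    r = float(r)
    if not abs(r) < 1:
        raise ValidationError(f"{name} must satisfy |r| < 1, got {r}")
    return r


@dataclass(frozen=True)
class CorrComparison:
    """One correlation comparison: inputs, test statistic, p, and Zou CI."""

    kind: str  # {"independent", "dependent_overlapping"}
    r1: float
    r2: float
    n1: int
    statistic: float
    p_raw: float
    ci_low: float
    ci_high: float
    r12: float | None = None  # intercorrelation (dependent case only)
    n2: int | None = None  # second group size (independent case only)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "dependent_overlapping":
            if self.r12 is None or self.n2 is not None:
                raise ValidationError("dependent case requires r12 and no n2")
        elif self.kind == "independent":
            if self.n2 is None or self.r12 is not None:
                raise ValidationError("independent case requires n2 and no r12")
        else:
            raise ValidationError(f"unknown comparison kind {self.kind!r}")
        if self.ci_low > self.ci_high:
            raise ValidationError("ci_low > ci_high")


def _fisher_ci(r: float, n: int, alpha: float) -> tuple[float, float]:
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit / math.sqrt(n - 3)
    z = math.atanh(r)
    return math.tanh(z - half), math.tanh(z + half)


def independent_groups_test(
    r1: float, n1: int, r2: float, n2: int,
    alpha: float = 0.05, labels: tuple[str, ...] = (),
) -> CorrComparison:
    """Fisher z test of r1 vs r2 from two independent groups, with Zou CI."""
    r1, r2 = _check_r("r1", r1), _check_r("r2", r2)
    if n1 <= 3 or n2 <= 3:
        raise ValidationError(f"group sizes must exceed 3, got n1={n1}, n2={n2}")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    l1, u1 = _fisher_ci(r1, n1, alpha)
    l2, u2 = _fisher_ci(r2, n2, alpha)
    diff = r1 - r2
    lower = diff - math.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    upper = diff + math.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return CorrComparison(
        kind="independent", r1=r1, r2=r2, n1=int(n1), n2=int(n2),
        statistic=float(z), p_raw=float(p), ci_low=lower, ci_high=upper,
        labels=tuple(labels),
    )


def _dunn_c(r_jk: float, r_jh: float, r_kh: float) -> float:
    """Covariance term between the two Fisher-transformed sample correlations."""
    num = (
        r_kh * (1 - r_jk**2 - r_jh**2)
        - 0.5 * r_jk * r_jh * (1 - r_jk**2 - r_jh**2 - r_kh**2)
    )
    return num / ((1 - r_jk**2) * (1 - r_jh**2))


def dunn_dependent_overlapping_test(
    r_jk: float, r_jh: float, r_kh: float, n: int,
    alpha: float = 0.05, labels: tuple[str, ...] = (),
) -> CorrComparison:
    """Dunn & Clark z test of two overlapping correlations from one sample.

    Compares r_jk vs r_jh (sharing variable j); r_kh is the
    intercorrelation of the non-shared variables and enters the
    covariance term c.  The Zou CI uses the same c as cross-term.
    """
    r_jk, r_jh, r_kh = (_check_r("r_jk", r_jk), _check_r("r_jh", r_jh),
                        _check_r("r_kh", r_kh))
    if n <= 3:
        raise ValidationError(f"n must exceed 3, got {n}")
    triple = np.array([[1, r_jk, r_jh], [r_jk, 1, r_kh], [r_jh, r_kh, 1]])
    if np.linalg.eigvalsh(triple).min() < -1e-10:
        raise ValidationError(
            f"(r_jk={r_jk}, r_jh={r_jh}, r_kh={r_kh}) is not a valid "
            "(positive semi-definite) correlation triple"
        )
    c = _dunn_c(r_jk, r_jh, r_kh)
    if c >= 1:
        raise ValidationError(f"degenerate comparison: c={c} >= 1")
    z = (math.atanh(r_jk) - math.atanh(r_jh)) * math.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * stats.norm.sf(abs(z))
    l1, u1 = _fisher_ci(r_jk, n, alpha)
    l2, u2 = _fisher_ci(r_jh, n, alpha)
    diff = r_jk - r_jh
    lower = diff - math.sqrt(
        (r_jk - l1) ** 2 + (u2 - r_jh) ** 2 - 2 * c * (r_jk - l1) * (u2 - r_jh)
    )
    upper = diff + math.sqrt(
        (u1 - r_jk) ** 2 + (r_jh - l2) ** 2 - 2 * c * (u1 - r_jk) * (r_jh - l2)
    )
    return CorrComparison(
        kind="dependent_overlapping", r1=r_jk, r2=r_jh, r12=r_kh, n1=int(n),
        statistic=float(z), p_raw=float(p), ci_low=lower, ci_high=upper,
        labels=tuple(labels),
    )


def bh_fdr(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` lets the family size exceed the number of supplied p-values
    (used when correcting for the full region count); defaults to len(p).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_fdr: empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("bh_fdr: p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValidationError(f"bh_fdr: family size m={m} smaller than {k} p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.minimum(adjusted, 1.0)
    # guard against float rounding pushing adjusted below raw
    return np.maximum(out, p)


#: Printed (rounded) thresholds as they appear in the analysis write-up.
_PRINTED_THRESHOLDS = {
    ("three_nuclei", "within_group"): 0.003,
    ("three_nuclei", "between_group"): 0.008,
    ("nine_nuclei", "within_group"): 0.0003,
    ("nine_nuclei", "between_group"): 0.003,
}


@dataclass(frozen=True)
class AlphaDecision:
    divisor: int
    threshold: float  # exact, alpha / divisor
    printed: float  # rounded value as conventionally reported


def decide_alpha(analysis: str, family: str, alpha: float = 0.05) -> AlphaDecision:
    """Bonferroni threshold for the number of subnuclei comparisons.

    Within-group families compare all unordered nucleus pairs
    (C(6,2)=15 or C(18,2)=153); between-group families compare each
    nucleus across groups (6 or 18).
    """
    n_nuclei = {"three_nuclei": 6, "nine_nuclei": 18}.get(analysis)
    if n_nuclei is None:
        raise ValidationError(f"unknown analysis {analysis!r}")
    if family == "within_group":
        divisor = n_nuclei * (n_nuclei - 1) // 2
    elif family == "between_group":
        divisor = n_nuclei
    else:
        raise ValidationError(f"unknown family {family!r}")
    return AlphaDecision(
        divisor=divisor, threshold=alpha / divisor,
        printed=_PRINTED_THRESHOLDS.get((analysis, family), alpha / divisor),
    )


@dataclass
class ComparisonFamily:
    """One family of comparisons (87 targets) sharing FDR + Bonferroni control."""

    label: str
    comparisons: list[CorrComparison]
    fdr_m: int
    bonferroni_m: int
    alpha_threshold: float
    p_fdr: np.ndarray = field(init=False)
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p_raw = [c.p_raw for c in self.comparisons]
        self.p_fdr = bh_fdr(p_raw, m=self.fdr_m)
        self.significant = self.p_fdr <= self.alpha_threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, pf, sig in zip(self.comparisons, self.p_fdr, self.significant):
            rows.append({
                "family": self.label,
                "labels": "|".join(comp.labels),
                "kind": comp.kind,
                "r1": comp.r1, "r2": comp.r2,
                "r12": float("nan") if comp.r12 is None else comp.r12,
                "n1": comp.n1,
                "n2": float("nan") if comp.n2 is None else comp.n2,
                "statistic": comp.statistic,
                "p_raw": comp.p_raw, "p_fdr": pf,
                "ci_low": comp.ci_low, "ci_high": comp.ci_high,
                "significant": bool(sig),
            })
        return pd.DataFrame(rows)


@dataclass
class ProfileComparisons:
    """Within-group and between-group comparison families for one analysis."""

    analysis: str
    within: dict[str, list[ComparisonFamily]]  # group -> one family per nucleus pair
    between: list[ComparisonFamily]  # one family per nucleus

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for group, families in self.within.items():
            for fam in families:
                df = fam.to_frame()
                df.insert(0, "scope", f"within:{group}")
                frames.append(df)
        for fam in self.between:
            df = fam.to_frame()
            df.insert(0, "scope", "between")
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_profile_comparisons(
    assoc_by_group: Mapping[str, AssociationMatrix],
    registry: RegionRegistry,
    analysis: str,
    alpha: float = 0.05,
    fdr_family_size: int | None = None,
) -> ProfileComparisons:
    """All within- and between-group profile comparisons for one analysis.

    For every unordered nucleus pair and each of the 87 targets, a
    dependent-overlapping comparison within each group; for every nucleus
    and target, an independent comparison between groups.  FDR is applied
    per family over the targets (family size defaults to the target
    count, 87); the Bonferroni threshold from :func:`decide_alpha` is
    applied on top.
    """
    if len(assoc_by_group) != 2:
        raise ValidationError("exactly two groups required")
    nuclei = registry.nuclei_for(analysis)
    targets = registry.profile_targets()
    matrices = list(assoc_by_group.values())
    for assoc in matrices:
        missing = [r for r in nuclei + targets if r not in assoc.region_ids]
        if missing:
            raise ValidationError(
                f"association matrix for group {assoc.group!r} lacks regions: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
    if matrices[0].region_ids != matrices[1].region_ids:
        raise ValidationError("groups must share region ordering")
    fdr_m = fdr_family_size if fdr_family_size is not None else len(targets)

    within_alpha = decide_alpha(analysis, "within_group", alpha)
    between_alpha = decide_alpha(analysis, "between_group", alpha)

    within: dict[str, list[ComparisonFamily]] = {}
    for group, assoc in assoc_by_group.items():
        families = []
        for nuc1, nuc2 in combinations(nuclei, 2):
            r12 = assoc.value(nuc1, nuc2)
            comps = [
                dunn_dependent_overlapping_test(
                    assoc.value(nuc1, t), assoc.value(nuc2, t), r12, assoc.n,
                    alpha=alpha, labels=(nuc1, nuc2, t),
                )
                for t in targets
            ]
            families.append(ComparisonFamily(
                label=f"{nuc1} vs {nuc2}", comparisons=comps, fdr_m=fdr_m,
                bonferroni_m=within_alpha.divisor,
                alpha_threshold=within_alpha.threshold,
            ))
        within[str(group)] = families

    a, b = matrices
    between = []
    for nuc in nuclei:
        comps = [
            independent_groups_test(
                a.value(nuc, t), a.n, b.value(nuc, t), b.n,
                alpha=alpha, labels=(nuc, str(a.group), str(b.group), t),
            )
            for t in targets
        ]
        between.append(ComparisonFamily(
            label=f"{nuc}: {a.group} vs {b.group}", comparisons=comps, fdr_m=fdr_m,
            bonferroni_m=between_alpha.divisor,
            alpha_threshold=between_alpha.threshold,
        ))
    return ProfileComparisons(analysis=analysis, within=within, between=between)
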