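"""Between-group comparison of nucleus volumes via covariate-adjusted OLS.

One linear model per region: volume ~ intercept + group + age + sex + tbv.
The group coefficient (case minus control, mm^3) is reported with its
95% CI and two-tailed p; the Bonferroni threshold divides alpha by the
number of tests (6 for three nuclei, 18 for nine).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .regions import CohortTable

DEFAULT_COVARIATES = ("age", "sex", "tbv")


@dataclass(frozen=True)
class VolumeComparison:
    region_id: str
    beta_group: float  # mm^3, case vs control
    ci_low: float
    ci_high: float
    p: float
    alpha_bonf: float
    n: int
    median_control: float
    iqr_control: float
    median_case: float
    iqr_case: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.beta_group <= self.ci_high:
            raise ValidationError("group beta outside its own CI")

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha_bonf


def compare_volumes(
    cohort: CohortTable,
    regions: Sequence[str] | None = None,
    analysis: str = "nine_nuclei",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> list[VolumeComparison]:
    """Fit the per-region group-effect models and apply Bonferroni control.

    ``regions`` defaults to the analysis' nucleus set from the cohort's
    registry (18 subnuclei or 6 composites; composites must have been
    aggregated beforehand).
    """
    if regions is None:
        regions = cohort.registry.nuclei_for(analysis)
    regions = list(regions)
    missing = [r for r in regions if r not in cohort.volumes.columns]
    if missing:
        raise ValidationError(f"regions not present in cohort: {missing}")
    cohort.require_inferential_sizes()
    groups = cohort.group_labels
    if len(groups) != 2:
        raise ValidationError("exactly two groups required")
    control, case = groups
    alpha_bonf = alpha / len(regions)

    cov = cohort.covariates
    group_ind = (cov["group"] == case).astype(float).to_numpy()
    X = np.column_stack(
        [group_ind] + [cov[c].to_numpy(dtype=float) for c in covariates]
    )
    X = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular design matrix (collinear covariates)")

    idx_control = cov["group"] == control
    idx_case = cov["group"] == case
    out: list[VolumeComparison] = []
    for region in regions:
        y = cohort.volumes[region].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int(alpha=alpha)[1]
        vc = cohort.volumes.loc[idx_control, region]
        vp = cohort.volumes.loc[idx_case, region]
        out.append(VolumeComparison(
            region_id=region,
            beta_group=float(fit.params[1]),
            ci_low=float(ci[0]), ci_high=float(ci[1]),
            p=float(fit.pvalues[1]),
            alpha_bonf=alpha_bonf,
            n=len(y),
            median_control=float(vc.median()),
            iqr_control=float(vc.quantile(0.75) - vc.quantile(0.25)),
            median_case=float(vp.median()),
            iqr_case=float(vp.quantile(0.75) - vp.quantile(0.25)),
        ))
    return out


def volume_table(comparisons: Sequence[VolumeComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "region": c.region_id,
            "median_control": c.median_control, "iqr_control": c.iqr_control,
            "median_case": c.median_case, "iqr_case": c.iqr_case,
            "beta": c.beta_group, "ci_low": c.ci_low, "ci_high": c.ci_high,
            "p": c.p, "alpha_bonf": c.alpha_bonf, "significant": c.significant,
        }
        for c in comparisons
    ])
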