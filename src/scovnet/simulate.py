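"""Synthetic morphometry cohorts with known ground truth.

Cohorts are drawn from group-specific multivariate-normal latent scores
whose correlation targets come from a latent-factor construction
(global integration, lobe communities, homotopic left/right pairs, and
an amygdala system), which keeps every target matrix positive definite
by construction.  Latent scores are scaled to realistic regional
means/SDs (amygdala subnuclei scales follow published nucleus-volume
medians; cortical/subcortical scales are generic) and linear age/sex/TBV
effects are added on top.

Scenarios inject known effects — a nucleus-region covariance difference,
a hub-strength boost (the boosted nucleus becomes the sole bridge
between the amygdala block and the cortex in cases), or a group volume
shift — so every downstream stage can be validated against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .regions import CohortTable, RegionRegistry, canonical_registry

logger = logging.getLogger(__name__)

# Marginal scales (median, IQR) for the 18 subnuclei and the amygdalae, mm^3.
_NUCLEUS_SCALES = {
    "left-accessory-basal": (261, 37), "left-anterior-amygdaloid-area": (50, 8),
    "left-basal": (336, 176), "left-central": (42, 10),
    "left-cortical": (23, 6), "left-cortico-amygdaloid-transition": (178, 26),
    "left-lateral": (641, 108), "left-medial": (17, 7),
    "left-paralaminar": (50, 8),
    "right-accessory-basal": (271, 46), "right-anterior-amygdaloid-area": (54, 9),
    "right-basal": (368, 172), "right-central": (48, 12),
    "right-cortical": (25, 7), "right-cortico-amygdaloid-transition": (181, 29),
    "right-lateral": (655, 94), "right-medial": (19, 9),
    "right-paralaminar": (49, 8),
    "Left-Amygdala": (1530, 270), "Right-Amygdala": (1699, 280),
}
_SUBCORTICAL_SCALES = {
    "Hippocampus": (4200, 450), "Thalamus-Proper": (7500, 800),
    "Caudate": (3600, 450), "Putamen": (5000, 600), "Pallidum": (2000, 250),
    "Accumbens-area": (600, 100), "VentralDC": (4000, 400),
    "Cerebellum-Cortex": (52000, 5500), "Brain-Stem": (21000, 2200),
}
_DEFAULT_CORTICAL = (6000, 900)
_DEFAULT_SUBCORTICAL = (900, 140)

_LOBES = {
    "frontal": ("superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
                "parsopercularis", "parsorbitalis", "parstriangularis",
                "lateralorbitofrontal", "medialorbitofrontal", "precentral",
                "paracentral"),
    "temporal": ("superiortemporal", "middletemporal", "inferiortemporal",
                 "transversetemporal", "entorhinal", "fusiform",
                 "parahippocampal", "temporalpole"),
    "parietal": ("postcentral", "superiorparietal", "inferiorparietal",
                 "supramarginal", "precuneus"),
    "occipital": ("lateraloccipital", "lingual", "pericalcarine", "cuneus"),
    "cingulate": ("caudalanteriorcingulate", "rostralanteriorcingulate",
                  "posteriorcingulate", "isthmuscingulate", "insula"),
}
_SUBCORTICAL_NAMES = ("Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
                      "Hippocampus", "Accumbens-area", "VentralDC")

# Factor loadings of the base (control) covariance model.
_G_CORTEX = 0.55  # global integration factor
_G_AMYGDALA = 0.45
_COMM_LOADING = 0.50
_AMYG_COMM_LOADING = 0.65
_HOMOTOPIC_LOADING = 0.45
# Injection loadings (validated by recovery simulations).
_HUB_LOADING = 0.75
_CORR_TARGET_LOADING = 0.70
_CORR_TARGET_COMM_LOADING = 0.40
_CORR_SOURCE_COMM_LOADING = 0.50
_BASELINE_AMYG_CORTEX = _G_AMYGDALA * _G_CORTEX  # 0.2475


def _community_of(rid: str) -> str:
    for lobe, labels in _LOBES.items():
        if any(rid.endswith(l) for l in labels):
            return lobe
    base = rid.replace("Left-", "").replace("Right-", "")
    if base in _SUBCORTICAL_NAMES:
        return "subcortical"
    if rid.startswith(("left-", "right-")) or "Amygdala" in rid:
        return "amygdala"
    return "midline"  # cerebellum, brain stem, corpus callosum segments


def _homolog(rid: str) -> str | None:
    for a, b in (("ctx-lh-", "ctx-rh-"), ("Left-", "Right-"), ("left-", "right-")):
        if rid.startswith(a):
            return b + rid[len(a):]
        if rid.startswith(b):
            return a + rid[len(b):]
    return None


@dataclass(frozen=True)
class InjectedEffect:
    """A known group difference planted in the case group.

    corr_diff: raise r(region, target) to ``magnitude`` for each listed
    region.  hub_boost: decouple the amygdala block from the cortex and
    make the single listed region a bridge with r ≈ ``magnitude`` to the
    temporal/hippocampal block.  volume_diff: add ``magnitude`` mm^3 to
    the case-group mean of each listed region.
    """

    kind: str  # {"corr_diff", "volume_diff", "hub_boost"}
    regions: tuple[str, ...]
    magnitude: float
    target: str | None = None  # partner region, corr_diff only


def _factor_correlation(
    region_ids: list[str], injected: Sequence[InjectedEffect] = ()
) -> np.ndarray:
    """Correlation matrix from the latent-factor model, with injections."""
    p = len(region_ids)
    idx = {r: i for i, r in enumerate(region_ids)}
    comm = {r: _community_of(r) for r in region_ids}
    am_ids = [r for r in region_ids if comm[r] == "amygdala"]
    near_ids = [r for r in region_ids
                if comm[r] == "temporal" or r.endswith("Hippocampus")]

    hub_effects = [e for e in injected if e.kind == "hub_boost"]
    corr_effects = [e for e in injected if e.kind == "corr_diff"]
    hub = None
    if hub_effects:
        if len(hub_effects) > 1 or len(hub_effects[0].regions) != 1:
            raise ValidationError("exactly one hub_boost region supported")
        hub = hub_effects[0].regions[0]
        if _community_of(hub) != "amygdala":
            raise ValidationError("hub_boost region must be an amygdala node")
    corr_sources: set[str] = set()
    corr_targets: set[str] = set()
    for e in corr_effects:
        if e.target is None:
            raise ValidationError("corr_diff needs a target region")
        corr_sources.update(e.regions)
        corr_targets.add(e.target)
    no_homotopic = corr_sources | corr_targets | ({hub} if hub else set())

    cols: list[np.ndarray] = []
    g = np.full(p, _G_CORTEX)
    for r in am_ids:
        g[idx[r]] = 0.0 if (hub and r != hub) else _G_AMYGDALA
    cols.append(g)

    for c in sorted(set(comm.values())):
        v = np.zeros(p)
        lam = _AMYG_COMM_LOADING if c == "amygdala" else _COMM_LOADING
        for r, i in idx.items():
            if comm[r] != c:
                continue
            v[i] = lam
            if r == hub:
                v[i] = _G_AMYGDALA
            elif r in corr_sources:
                v[i] = min(lam, _CORR_SOURCE_COMM_LOADING)
            elif r in corr_targets:
                v[i] = _CORR_TARGET_COMM_LOADING
        cols.append(v)

    done: set[str] = set()
    for r, i in idx.items():
        h = _homolog(r)
        if h is None or h not in idx or h in done:
            continue
        done.add(r)
        if r in no_homotopic or h in no_homotopic:
            continue
        v = np.zeros(p)
        v[i] = v[idx[h]] = _HOMOTOPIC_LOADING
        cols.append(v)

    if hub:
        near_loading = (hub_effects[0].magnitude - _BASELINE_AMYG_CORTEX) / _HUB_LOADING
        if not 0 < near_loading < 1:
            raise ValidationError(
                f"hub_boost magnitude {hub_effects[0].magnitude} out of the "
                "representable range"
            )
        v = np.zeros(p)
        v[idx[hub]] = _HUB_LOADING
        for r in near_ids:
            v[idx[r]] = near_loading
        cols.append(v)

    for e in corr_effects:
        source_loading = (e.magnitude - _BASELINE_AMYG_CORTEX) / _CORR_TARGET_LOADING
        if not 0 < source_loading < 1:
            raise ValidationError(
                f"corr_diff magnitude {e.magnitude} out of the representable range"
            )
        v = np.zeros(p)
        v[idx[e.target]] = _CORR_TARGET_LOADING
        for r in e.regions:
            v[idx[r]] = source_loading
        cols.append(v)

    L = np.column_stack(cols)
    ss = (L**2).sum(axis=1)
    if ss.max() >= 1:
        worst = region_ids[int(ss.argmax())]
        raise ValidationError(
            f"factor loadings for {worst!r} exceed unit variance "
            f"(sum of squares {ss.max():.3f}); reduce injection magnitudes"
        )
    R = L @ L.T + np.diag(1 - ss)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class CohortScenario:
    """Full generative description of a two-group synthetic cohort."""

    name: str
    registry: RegionRegistry
    region_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    corr_control: np.ndarray
    corr_case: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_tbv: np.ndarray
    mean_shift_case: np.ndarray
    injected: tuple[InjectedEffect, ...] = ()
    n_control: int = 71
    n_case: int = 67
    age_mean: float = 37.0
    age_sd: float = 12.0
    age_min: float = 18.0
    sex_p: float = 0.72  # P(sex == 1)
    tbv_mean: float = 1.52e6
    tbv_sd: float = 1.5e5

    def __post_init__(self) -> None:
        p = len(self.region_ids)
        for name, M in (("control", self.corr_control), ("case", self.corr_case)):
            if M.shape != (p, p):
                raise ValidationError(f"{name} correlation matrix shape mismatch")
            lam = np.linalg.eigvalsh(M).min()
            if lam <= 1e-10:
                raise ValidationError(
                    f"{name} target correlation matrix is not positive definite "
                    f"(smallest eigenvalue {lam:.3e})"
                )


@dataclass
class GroundTruth:
    scenario: str
    region_ids: list[str]
    corr_control: np.ndarray
    corr_case: np.ndarray
    means: np.ndarray
    mean_shift_case: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_tbv: np.ndarray
    injected: tuple[InjectedEffect, ...]
    truncated_values: int = 0


def _region_scales(registry: RegionRegistry) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = registry.noncomposite_ids
    means, sds = [], []
    for entry in registry.entries:
        rid = entry.region_id
        if entry.region_class == "amygdala_composite":
            continue
        if rid in _NUCLEUS_SCALES:
            med, iqr = _NUCLEUS_SCALES[rid]
        elif entry.region_class == "cortical":
            med, iqr = _DEFAULT_CORTICAL
        else:
            base = rid.replace("Left-", "").replace("Right-", "")
            med, iqr = _SUBCORTICAL_SCALES.get(base) or _SUBCORTICAL_SCALES.get(
                rid, _DEFAULT_SUBCORTICAL)
        sd = min(iqr / 1.349, med / 4.0)  # cap keeps draws positive
        means.append(float(med))
        sds.append(float(sd))
    return ids, np.array(means), np.array(sds)


def build_scenario(
    name: str,
    registry: RegionRegistry | None = None,
    injected: Sequence[InjectedEffect] = (),
    n_control: int = 71,
    n_case: int = 67,
    identity_correlations: bool = False,
    zero_covariate_effects: bool = False,
) -> CohortScenario:
    """Assemble a scenario from the factor covariance model plus injections.

    ``identity_correlations`` replaces both target matrices with the
    identity (useful for sampling-noise baselines);
    ``zero_covariate_effects`` turns off the age/sex/TBV loadings.
    """
    registry = registry or canonical_registry()
    region_ids, means, sds = _region_scales(registry)
    p = len(region_ids)

    known = {"corr_diff", "hub_boost", "volume_diff"}
    for e in injected:
        if e.kind not in known:
            raise ValidationError(f"unknown injected effect kind {e.kind!r}")

    if identity_correlations:
        base = np.eye(p)
        corr_case = np.eye(p)
        if any(e.kind != "volume_diff" for e in injected):
            raise ValidationError(
                "identity_correlations only supports volume_diff injections"
            )
    else:
        base = _factor_correlation(region_ids)
        corr_case = (_factor_correlation(region_ids, injected)
                     if any(e.kind in ("corr_diff", "hub_boost") for e in injected)
                     else base.copy())

    mean_shift = np.zeros(p)
    idx = {r: i for i, r in enumerate(region_ids)}
    for e in injected:
        if e.kind == "volume_diff":
            for rid in e.regions:
                mean_shift[idx[rid]] += e.magnitude

    if zero_covariate_effects:
        beta_age = np.zeros(p)
        beta_sex = np.zeros(p)
        beta_tbv = np.zeros(p)
    else:
        # covariate loadings proportional to regional scale
        beta_age = -0.004 * means  # mm^3 per year
        beta_sex = -0.05 * means
        beta_tbv = 0.6 * means / 1.52e6

    return CohortScenario(
        name=name, registry=registry, region_ids=region_ids,
        means=means, sds=sds, corr_control=base, corr_case=corr_case,
        beta_age=beta_age, beta_sex=beta_sex, beta_tbv=beta_tbv,
        mean_shift_case=mean_shift, injected=tuple(injected),
        n_control=n_control, n_case=n_case,
    )


def generate_cohort(scenario: CohortScenario, seed: int) -> CohortTable:
    """Draw one cohort; deterministic per seed, ground truth attached."""
    rng = np.random.default_rng(seed)
    p = len(scenario.region_ids)
    rows_vol, rows_cov, index = [], [], []
    truncated = 0
    a = (scenario.age_min - scenario.age_mean) / scenario.age_sd
    for group, n, corr, shift in (
        ("control", scenario.n_control, scenario.corr_control, 0.0),
        ("case", scenario.n_case, scenario.corr_case, scenario.mean_shift_case),
    ):
        L = np.linalg.cholesky(corr)
        Z = rng.standard_normal((n, p)) @ L.T
        age = stats.truncnorm.rvs(a, np.inf, loc=scenario.age_mean,
                                  scale=scenario.age_sd, size=n, random_state=rng)
        sex = rng.binomial(1, scenario.sex_p, size=n).astype(float)
        tbv = rng.normal(scenario.tbv_mean, scenario.tbv_sd, size=n)
        vols = (
            scenario.means + shift + scenario.sds * Z
            + np.outer(age - scenario.age_mean, scenario.beta_age)
            + np.outer(sex - scenario.sex_p, scenario.beta_sex)
            + np.outer(tbv - scenario.tbv_mean, scenario.beta_tbv)
        )
        below = vols < 1.0
        truncated += int(below.sum())
        vols = np.where(below, 1.0, vols)
        for i in range(n):
            sid = f"{group[0]}{len(index):04d}"
            index.append(sid)
            rows_vol.append(vols[i])
            rows_cov.append({"group": group, "age": age[i], "sex": sex[i],
                             "tbv": tbv[i]})
    if truncated:
        logger.info("truncated %d non-positive volume draws at 1 mm^3", truncated)
    volumes = pd.DataFrame(rows_vol, index=index, columns=scenario.region_ids)
    covariates = pd.DataFrame(rows_cov, index=index)
    truth = GroundTruth(
        scenario=scenario.name, region_ids=list(scenario.region_ids),
        corr_control=scenario.corr_control, corr_case=scenario.corr_case,
        means=scenario.means, mean_shift_case=scenario.mean_shift_case,
        beta_age=scenario.beta_age, beta_sex=scenario.beta_sex,
        beta_tbv=scenario.beta_tbv, injected=scenario.injected,
        truncated_values=truncated,
    )
    return CohortTable(volumes=volumes, covariates=covariates,
                       registry=scenario.registry, ground_truth=truth)


#: Achieved bridge correlation of the boosted hub with the temporal block.
HUB_MAGNITUDE = 0.585
#: Achieved case-group correlation of the injected nucleus-region pairs.
CORR_DIFF_MAGNITUDE = 0.70
#: Case-group mean shift for the volume scenario (mm^3).
VOLUME_DIFF_MAGNITUDE = -50.0


def scenario_library(registry: RegionRegistry | None = None) -> dict[str, CohortScenario]:
    """The shipped scenario set.

    A-null: identical groups.  B-hub: the right basal nucleus becomes
    the sole bridge between the amygdala block and the cortex in cases.
    C-corr-diff: left-BLA constituents' covariance with the left
    superior temporal gyrus raised in cases.  D-volume-diff: a 50 mm^3
    deficit of the left lateral nucleus in cases.
    """
    registry = registry or canonical_registry()
    bla_left = ("left-accessory-basal", "left-basal", "left-lateral",
                "left-paralaminar")
    return {
        "A-null": build_scenario("A-null", registry),
        "B-hub": build_scenario(
            "B-hub", registry,
            injected=[InjectedEffect("hub_boost", ("right-basal",), HUB_MAGNITUDE)],
        ),
        "C-corr-diff": build_scenario(
            "C-corr-diff", registry,
            injected=[InjectedEffect("corr_diff", bla_left, CORR_DIFF_MAGNITUDE,
                                     target="ctx-lh-superiortemporal")],
        ),
        "D-volume-diff": build_scenario(
            "D-volume-diff", registry,
            injected=[InjectedEffect("volume_diff", ("left-lateral",),
                                     VOLUME_DIFF_MAGNITUDE)],
        ),
    }
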