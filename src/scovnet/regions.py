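"""Region inventory and cohort table I/O.

The canonical registry holds 105 non-composite regions — 63 cortical,
24 subcortical and 18 amygdala subnuclei (9 per hemisphere) — plus the
6 per-hemisphere composite nuclei (BLA, CMA, SFA) built by summing
subnucleus volumes.  Region identifiers follow FreeSurfer conventions
(``ctx-lh-superiortemporal``, ``Left-Amygdala``); subnuclei use plain
hyphenated names (``left-basal``).  The exact 87-region target list used
in the source analyses is not published, so the shipped registry is a
reconstruction that is exact in its class counts and subnucleus naming.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

REGISTRY_VERSION = "1.0"

#: Minimum per-group sample size required by inferential operations.
MIN_INFERENTIAL_GROUP_SIZE = 10

SUBNUCLEUS_NAMES = (
    "anterior-amygdaloid-area",
    "cortico-amygdaloid-transition",
    "accessory-basal",
    "basal",
    "central",
    "cortical",
    "lateral",
    "medial",
    "paralaminar",
)

#: Composite (cytoarchitectonic subfield) membership, per hemisphere.
COMPOSITE_MEMBERS = {
    "BLA": ("accessory-basal", "basal", "lateral", "paralaminar"),
    "CMA": ("central", "medial"),
    "SFA": ("anterior-amygdaloid-area", "cortico-amygdaloid-transition", "cortical"),
}

# 31 DKT cortical labels per hemisphere.  The published count of 63 cortical
# regions exceeds the 62 bilateral DKT labels by one; a single extra real
# FreeSurfer label (left temporal pole) is included to match the count.
_DKT_CORTICAL = (
    "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus", "entorhinal",
    "fusiform", "inferiorparietal", "inferiortemporal", "isthmuscingulate",
    "lateraloccipital", "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "parahippocampal", "paracentral", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "transversetemporal", "insula",
)
_EXTRA_CORTICAL = ("ctx-lh-temporalpole",)

_SUBCORTICAL_BILATERAL = (
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area", "VentralDC", "Cerebellum-Cortex",
)
_SUBCORTICAL_MIDLINE = (
    "Brain-Stem", "CC_Posterior", "CC_Mid_Posterior", "CC_Central",
    "CC_Mid_Anterior", "CC_Anterior",
)

COVARIATE_COLUMNS = ("group", "age", "sex", "tbv")


def normalize_region_id(name: str) -> str:
    """Normalize a column header for registry matching.

    Lowercases and collapses ``_``, ``.``, whitespace runs to ``-`` so that
    e.g. ``Left_Basal`` and ``left-basal`` resolve identically.
    """
    return re.sub(r"[\s_.]+", "-", str(name).strip()).lower()


@dataclass(frozen=True)
class RegionEntry:
    region_id: str
    hemisphere: str  # {left, right, midline}
    region_class: str  # {cortical, subcortical, amygdala_subnucleus, amygdala_composite}
    parent_composite: str | None = None


@dataclass(frozen=True)
class RegionRegistry:
    """Named inventory of regions with hemisphere, class and composite grouping."""

    entries: tuple[RegionEntry, ...]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        ids = [e.region_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate region_ids in registry: {dupes}")

    # -- selection helpers -------------------------------------------------
    def ids(self, region_class: str | None = None) -> list[str]:
        return [
            e.region_id
            for e in self.entries
            if region_class is None or e.region_class == region_class
        ]

    @property
    def cortical(self) -> list[str]:
        return self.ids("cortical")

    @property
    def subcortical(self) -> list[str]:
        return self.ids("subcortical")

    @property
    def subnuclei(self) -> list[str]:
        return self.ids("amygdala_subnucleus")

    @property
    def composites(self) -> list[str]:
        return self.ids("amygdala_composite")

    @property
    def noncomposite_ids(self) -> list[str]:
        return [e.region_id for e in self.entries if e.region_class != "amygdala_composite"]

    def profile_targets(self) -> list[str]:
        """The 87 non-amygdala-subnuclei regions each profile correlates against."""
        return self.cortical + self.subcortical

    def nuclei_for(self, analysis: str) -> list[str]:
        """Nucleus node set: 6 composites (three_nuclei) or 18 subnuclei (nine_nuclei)."""
        if analysis == "three_nuclei":
            return self.composites
        if analysis == "nine_nuclei":
            return self.subnuclei
        raise ValidationError(
            f"analysis must be 'three_nuclei' or 'nine_nuclei', got {analysis!r}"
        )

    def graph_nodes(self, analysis: str) -> list[str]:
        """Node set for topology: 87 targets + nuclei (93 or 105 nodes)."""
        return self.profile_targets() + self.nuclei_for(analysis)

    def composite_members(self, composite_id: str) -> list[str]:
        members = [
            e.region_id for e in self.entries if e.parent_composite == composite_id
        ]
        if not members:
            raise ValidationError(f"unknown composite: {composite_id!r}")
        return members

    def resolve(self, column: str) -> str | None:
        """Map a raw column header to a registry region_id, or None."""
        return self._normalized_map().get(normalize_region_id(column))

    def _normalized_map(self) -> dict[str, str]:
        return {normalize_region_id(e.region_id): e.region_id for e in self.entries}

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "region_id": e.region_id,
                    "hemisphere": e.hemisphere,
                    "region_class": e.region_class,
                    "parent_composite": e.parent_composite,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionRegistry":
        payload = json.loads(Path(path).read_text())
        return cls(
            entries=tuple(RegionEntry(**e) for e in payload["entries"]),
            version=payload.get("version", REGISTRY_VERSION),
        )


def canonical_registry() -> RegionRegistry:
    """Build the canonical 105-region registry (plus 6 composite entries)."""
    entries: list[RegionEntry] = []
    for hemi, prefix in (("left", "ctx-lh-"), ("right", "ctx-rh-")):
        for name in _DKT_CORTICAL:
            entries.append(RegionEntry(prefix + name, hemi, "cortical"))
    for rid in _EXTRA_CORTICAL:
        entries.append(RegionEntry(rid, "left", "cortical"))
    for hemi, prefix in (("left", "Left-"), ("right", "Right-")):
        for name in _SUBCORTICAL_BILATERAL:
            entries.append(RegionEntry(prefix + name, hemi, "subcortical"))
    for rid in _SUBCORTICAL_MIDLINE:
        entries.append(RegionEntry(rid, "midline", "subcortical"))
    member_to_composite = {
        m: comp for comp, members in COMPOSITE_MEMBERS.items() for m in members
    }
    for hemi in ("left", "right"):
        for name in SUBNUCLEUS_NAMES:
            comp_id = f"{hemi}-{member_to_composite[name]}"
            entries.append(
                RegionEntry(f"{hemi}-{name}", hemi, "amygdala_subnucleus", comp_id)
            )
    for hemi in ("left", "right"):
        for comp in COMPOSITE_MEMBERS:
            entries.append(RegionEntry(f"{hemi}-{comp}", hemi, "amygdala_composite"))
    return RegionRegistry(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Subject-by-region volumes joined to covariates and group labels.

    ``volumes`` is indexed by subject_id with one mm^3 column per region;
    ``covariates`` shares the index and carries group, age, sex (0/1) and tbv.
    """

    volumes: pd.DataFrame
    covariates: pd.DataFrame
    registry: RegionRegistry
    sex_coding: Mapping[str, int] = field(default_factory=lambda: {"male": 0, "female": 1})
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        if not self.volumes.index.equals(self.covariates.index):
            raise ValidationError("volumes and covariates must share subject index")
        if self.volumes.index.has_duplicates:
            dupes = sorted(self.volumes.index[self.volumes.index.duplicated()].unique())
            raise ValidationError(f"duplicate subject_id(s): {dupes}")
        missing = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise ValidationError(f"covariate table missing columns: {missing}")
        if (self.volumes.to_numpy(dtype=float) <= 0).any():
            bad = self.volumes.columns[(self.volumes <= 0).any(axis=0)].tolist()
            raise ValidationError(f"non-positive volumes in regions: {bad}")
        if (self.covariates["age"] <= 0).any() or (self.covariates["tbv"] <= 0).any():
            raise ValidationError("age and tbv must be positive")
        if not set(self.covariates["sex"].unique()) <= {0, 1}:
            raise ValidationError("sex must be coded {0, 1}")

    @property
    def n_subjects(self) -> int:
        return len(self.volumes)

    @property
    def group_labels(self) -> list[str]:
        """Group labels with the reference (control-like) group first."""
        labels = sorted(self.covariates["group"].unique().tolist())
        for control_like in ("control", "nec", "hc"):
            if control_like in [str(l).lower() for l in labels]:
                labels.sort(key=lambda l: str(l).lower() != control_like)
                break
        return labels

    def group_sizes(self) -> dict[str, int]:
        counts = self.covariates["group"].value_counts()
        return {label: int(counts[label]) for label in self.group_labels}

    def subjects_in(self, group: str) -> pd.Index:
        mask = self.covariates["group"] == group
        if not mask.any():
            raise ValidationError(f"unknown group label: {group!r}")
        return self.covariates.index[mask]

    def require_inferential_sizes(self, minimum: int = MIN_INFERENTIAL_GROUP_SIZE) -> None:
        sizes = self.group_sizes()
        if len(sizes) != 2:
            raise ValidationError(f"exactly two groups required, found {list(sizes)}")
        small = {g: n for g, n in sizes.items() if n < minimum}
        if small:
            raise ValidationError(
                f"group sizes below the minimum of {minimum} for inference: {small}"
            )

    def write(self, volumes_path: str | Path, covariates_path: str | Path) -> None:
        """Write volumes and covariates back to CSV (round-trip safe)."""
        self.volumes.to_csv(volumes_path, index_label="subject_id")
        self.covariates.to_csv(covariates_path, index_label="subject_id")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _find_column(df: pd.DataFrame, wanted: str) -> str | None:
    for col in df.columns:
        if normalize_region_id(col) == wanted:
            return col
    return None


def load_cohort(
    volumes_path: str | Path,
    covariates_path: str | Path,
    registry: RegionRegistry,
    sex_coding: Mapping[str, int] | None = None,
) -> CohortTable:
    """Load and validate a cohort from a wide volume table plus covariates.

    Headers are matched to registry ids case-insensitively with separators
    normalized.  Unrecognized volume columns are logged and ignored; any
    missing non-composite region is an error.  Subjects are joined on
    subject_id; rows present in only one file are an error.
    """
    vol_raw = _read_table(volumes_path)
    cov_raw = _read_table(covariates_path)

    sid_col = _find_column(vol_raw, "subject-id") or _find_column(vol_raw, "subject")
    if sid_col is None:
        raise ValidationError(f"{volumes_path}: no subject_id column")
    vol_raw = vol_raw.set_index(vol_raw[sid_col].astype(str)).drop(columns=[sid_col])
    if vol_raw.index.has_duplicates:
        dupes = sorted(vol_raw.index[vol_raw.index.duplicated()].unique())
        raise ValidationError(f"duplicate subject_id(s) in volumes: {dupes}")

    rename: dict[str, str] = {}
    unrecognized: list[str] = []
    for col in vol_raw.columns:
        rid = registry.resolve(col)
        if rid is None:
            unrecognized.append(col)
        else:
            rename[col] = rid
    if unrecognized:
        logger.warning("ignoring %d unrecognized volume columns: %s",
                       len(unrecognized), unrecognized)
    volumes = vol_raw[list(rename)].rename(columns=rename)

    required = registry.noncomposite_ids
    missing = [r for r in required if r not in volumes.columns]
    if missing:
        raise ValidationError(f"volume table missing region columns: {missing}")
    volumes = volumes[[r for r in registry.ids() if r in volumes.columns]].astype(float)

    sid_col = _find_column(cov_raw, "subject-id") or _find_column(cov_raw, "subject")
    if sid_col is None:
        raise ValidationError(f"{covariates_path}: no subject_id column")
    cov_raw = cov_raw.set_index(cov_raw[sid_col].astype(str)).drop(columns=[sid_col])
    cov_cols = {}
    for wanted in COVARIATE_COLUMNS:
        col = _find_column(cov_raw, wanted)
        if col is None:
            raise ValidationError(f"covariate table missing column: {wanted!r}")
        cov_cols[wanted] = cov_raw[col]
    covariates = pd.DataFrame(cov_cols)

    coding = dict(sex_coding or {"male": 0, "m": 0, "female": 1, "f": 1})
    if covariates["sex"].dtype == object:
        covariates["sex"] = covariates["sex"].map(
            lambda s: coding.get(str(s).strip().lower(), s)
        )
    covariates["sex"] = pd.to_numeric(covariates["sex"], errors="raise")
    covariates["age"] = pd.to_numeric(covariates["age"], errors="raise")
    covariates["tbv"] = pd.to_numeric(covariates["tbv"], errors="raise")

    only_vol = volumes.index.difference(covariates.index)
    only_cov = covariates.index.difference(volumes.index)
    if len(only_vol) or len(only_cov):
        raise ValidationError(
            f"subject mismatch between tables: volumes-only={list(only_vol)}, "
            f"covariates-only={list(only_cov)}"
        )
    covariates = covariates.loc[volumes.index]
    return CohortTable(volumes=volumes, covariates=covariates, registry=registry,
                       sex_coding=coding)


# ---------------------------------------------------------------------------
# IQR quality check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCFlag:
    subject_id: str
    group: str
    region_id: str
    value: float
    lower_fence: float
    upper_fence: float


@dataclass
class QCReport:
    flags: list[QCFlag]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [f.__dict__ for f in self.flags],
            columns=["subject_id", "group", "region_id", "value",
                     "lower_fence", "upper_fence"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def iqr_qc(cohort: CohortTable, regions: Sequence[str]) -> QCReport:
    """Flag volumes outside Q1 - 1.5 IQR / Q3 + 1.5 IQR within each group.

    Quartiles use linear interpolation.  The cohort is never mutated;
    flagged values are reported for inspection, not excluded.
    """
    regions = list(regions)
    if not regions:
        raise ValidationError("iqr_qc: empty region subset")
    unknown = [r for r in regions if r not in cohort.volumes.columns]
    if unknown:
        raise ValidationError(f"iqr_qc: unknown regions {unknown}")
    flags: list[QCFlag] = []
    for group in cohort.group_labels:
        idx = cohort.subjects_in(group)
        if len(idx) < 4:
            raise ValidationError(
                f"iqr_qc: group {group!r} has {len(idx)} subjects, need >= 4"
            )
        sub = cohort.volumes.loc[idx, regions]
        q1 = sub.quantile(0.25, interpolation="linear")
        q3 = sub.quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        out = (sub.lt(lo, axis=1)) | (sub.gt(hi, axis=1))
        for sid, rid in zip(*np.nonzero(out.to_numpy())):
            region = regions[rid]
            flags.append(QCFlag(
                subject_id=str(idx[sid]), group=str(group), region_id=region,
                value=float(sub.iat[sid, rid]),
                lower_fence=float(lo[region]), upper_fence=float(hi[region]),
            ))
    return QCReport(flags=flags)


def aggregate_composites(cohort: CohortTable, registry: RegionRegistry) -> CohortTable:
    """Add the 6 composite-nucleus columns (sums of constituent subnuclei).

    Existing composite columns are recomputed, making the operation
    idempotent; all original columns are retained.
    """
    volumes = cohort.volumes.copy()
    for comp in registry.composites:
        members = registry.composite_members(comp)
        missing = [m for m in members if m not in volumes.columns]
        if missing:
            raise ValidationError(
                f"cannot build composite {comp!r}: missing constituents {missing}"
            )
        volumes[comp] = volumes[members].sum(axis=1)
    return replace(cohort, volumes=volumes)
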