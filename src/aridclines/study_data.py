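"""Plant-level data model: derived traits, fitness, standardization, I/O.

The unit of observation is one experimental plant grown in a common garden
(a 1-litre pot in a glasshouse or open field), assigned to a ``wet`` or
``dry`` watering treatment. Each plant carries raw measurements (leaf
counts, leaf fresh/dry mass, gas exchange, biomass fractions, metabolite
concentrations, flowering day) from which the 13 registry traits are
derived, plus a seed count that defines fecundity fitness.

Source populations are indexed by an aridity score, potential
evapotranspiration divided by mean annual precipitation (PET/MAP), so that
larger values mean drier source sites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .traits import DEFAULT_TRAITS, TRAIT_NAMES, TraitSpec

logger = logging.getLogger(__name__)

__all__ = [
    "EXPERIMENTS",
    "TREATMENTS",
    "FIELD_BLOCK_SENTINEL",
    "RAW_SCHEMA",
    "AridityRecord",
    "StandardizedTraits",
    "ValidationReport",
    "compute_aridity",
    "derive_traits",
    "estimate_total_seeds",
    "relative_fitness",
    "transform_and_standardize",
    "trait_correlations",
    "read_plant_table",
    "read_aridity_table",
    "write_results",
]

EXPERIMENTS = ("glasshouse2018", "field2019")
TREATMENTS = ("wet", "dry")

#: Block is a glasshouse-only design factor; field rows carry this sentinel.
FIELD_BLOCK_SENTINEL = "none"

#: Mandatory columns of a raw plant table. ``seed_count`` may be given
#: directly instead of (seeds_per_gram, capitula_dw_g).
RAW_SCHEMA = (
    "plant_id", "experiment", "population", "patch", "block", "treatment",
    "leaf_count_wk0", "leaf_count_wk8", "fv_fm", "photosynthesis",
    "stomatal_conductance", "leaf_area_cm2", "leaf_fw_g", "leaf_dw_g",
    "shoot_dw_g", "root_dw_g", "days_to_flowering",
    "chlorogenic_acid", "phenolic_acid", "flavonoid",
)


@dataclass(frozen=True)
class AridityRecord:
    """Source-site water balance for one population.

    ``aridity = pet / map`` (dimensionless); larger = drier source site.
    """

    population: str
    pet: float
    map: float

    @property
    def aridity(self) -> float:
        return compute_aridity(self.pet, self.map)


def compute_aridity(pet: float, map: float) -> float:
    """Aridity index of a source location: PET / mean annual precipitation.

    Parameters
    ----------
    pet : potential evapotranspiration, mm / yr (> 0).
    map : mean annual precipitation, mm / yr (> 0).
    """
    if not np.isfinite(pet) or pet <= 0:
        raise ValueError(f"pet must be a positive real, got {pet!r}")
    if not np.isfinite(map) or map <= 0:
        raise ValueError(f"map must be a positive real, got {map!r}")
    return pet / map


def estimate_total_seeds(seeds_per_gram: float, total_capitula_dry_mass: float) -> int:
    """Total seed count of a plant from the per-gram seed density of its
    bagged capitula and the dry mass of the remaining capitula.

    Returns the product rounded to the nearest integer (fractional seeds are
    meaningless for the count models downstream).
    """
    if seeds_per_gram < 0:
        raise ValueError(f"seeds_per_gram must be >= 0, got {seeds_per_gram}")
    if total_capitula_dry_mass < 0:
        raise ValueError(
            f"total_capitula_dry_mass must be >= 0, got {total_capitula_dry_mass}"
        )
    return int(np.rint(seeds_per_gram * total_capitula_dry_mass))


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived trait columns from raw measurements.

    growth_rate       = (leaf_count_wk8 - leaf_count_wk0) / 8   [leaves/wk]
    succulence        = (leaf_fw_g - leaf_dw_g) / leaf_dw_g
    sla               = leaf_area_cm2 / leaf_dw_g               [cm2/g]
    leaf_size         = leaf_area_cm2
    biomass           = shoot_dw_g + root_dw_g                  [g]
    root_shoot_ratio  = root_dw_g / shoot_dw_g

    Records with a zero denominator (leaf or shoot dry mass) are flagged in
    a boolean ``derivation_ok`` column, excluded from the returned table,
    and counted in a log message. Row order of the survivors is preserved.
    """
    out = records.copy()
    bad = (out["leaf_dw_g"] <= 0) | (out["shoot_dw_g"] <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "derive_traits: excluding %d record(s) with non-positive dry mass: %s",
            n_bad, list(out.loc[bad, "plant_id"]),
        )
    out = out.loc[~bad].copy()
    out["growth_rate"] = (out["leaf_count_wk8"] - out["leaf_count_wk0"]) / 8.0
    out["succulence"] = (out["leaf_fw_g"] - out["leaf_dw_g"]) / out["leaf_dw_g"]
    out["sla"] = out["leaf_area_cm2"] / out["leaf_dw_g"]
    out["leaf_size"] = out["leaf_area_cm2"]
    out["biomass"] = out["shoot_dw_g"] + out["root_dw_g"]
    out["root_shoot_ratio"] = out["root_dw_g"] / out["shoot_dw_g"]
    if "seed_count" not in out.columns and {"seeds_per_gram", "capitula_dw_g"} <= set(out.columns):
        out["seed_count"] = [
            estimate_total_seeds(s, m)
            for s, m in zip(out["seeds_per_gram"], out["capitula_dw_g"])
        ]
    if "seed_count" in out.columns:
        out["reproduced"] = out["seed_count"] > 0
    return out


def relative_fitness(records: pd.DataFrame, group: str = "treatment") -> pd.DataFrame:
    """Relative fitness w = seed_count / mean(seed_count within group).

    Zero seed counts stay 0; within each group the returned values average
    exactly 1. An all-zero group raises (relative fitness is undefined).
    """
    if "seed_count" not in records.columns:
        raise ValueError("records lack a seed_count column")
    out = records.copy()
    means = out.groupby(group)["seed_count"].transform("mean")
    zero_groups = out.loc[means <= 0, group].unique()
    if len(zero_groups):
        raise ValueError(
            f"relative fitness undefined: zero mean seed count in group(s) "
            f"{sorted(map(str, zero_groups))}"
        )
    out["relative_fitness"] = out["seed_count"] / means
    return out


@dataclass
class StandardizedTraits:
    """Traits transformed and z-scored within experiment x treatment groups.

    ``values`` holds one column per registry trait, ``groups`` the group key
    of each row, and ``group_means`` / ``group_sds`` the post-transform
    moments used, so the scaling is invertible.
    """

    plant_ids: pd.Series
    values: pd.DataFrame               # n x 13, registry order
    groups: pd.DataFrame               # n x 2: experiment, treatment
    design: pd.DataFrame               # n x 3: population, patch, block
    group_means: pd.DataFrame          # (experiment, treatment) x 13
    group_sds: pd.DataFrame
    transforms: dict[str, str]

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def destandardize(self) -> pd.DataFrame:
        """Undo the z-scoring (but not the variance-stabilizing transform)."""
        key = pd.MultiIndex.from_frame(self.groups)
        mu = self.group_means.loc[key].to_numpy()
        sd = self.group_sds.loc[key].to_numpy()
        return pd.DataFrame(
            self.values.to_numpy() * sd + mu,
            index=self.values.index, columns=self.values.columns,
        )


def _apply_transform(x: pd.Series, how: str, trait: str) -> pd.Series:
    if how == "none":
        return x
    if how == "log":
        if (x <= 0).any():
            raise ValueError(f"log transform of non-positive values in trait {trait!r}")
        return np.log(x)
    if how == "sqrt":
        if (x < 0).any():
            raise ValueError(f"sqrt transform of negative values in trait {trait!r}")
        return np.sqrt(x)
    raise ValueError(f"unknown transform {how!r}")


def _auto_transform(x: pd.Series, skew_threshold: float) -> str:
    """Data-driven transform rule: transform when |sample skewness| exceeds
    the threshold — log if strictly positive, sqrt if non-negative."""
    if abs(sps.skew(x, bias=False)) <= skew_threshold:
        return "none"
    if (x > 0).all():
        return "log"
    if (x >= 0).all():
        return "sqrt"
    return "none"


def transform_and_standardize(
    records: pd.DataFrame,
    trait_specs: Sequence[TraitSpec] = DEFAULT_TRAITS,
    *,
    transform: str = "registry",
    skew_threshold: float = 1.0,
) -> StandardizedTraits:
    """Variance-stabilize, then z-score each trait within experiment x
    treatment groups (mean 0, SD 1 per group).

    ``transform`` is one of ``"registry"`` (use each TraitSpec's static
    default), ``"auto"`` (transform a trait when its |sample skewness|
    exceeds ``skew_threshold``), or ``"none"``.
    """
    if transform not in ("registry", "auto", "none"):
        raise ValueError(f"unknown transform mode {transform!r}")
    names = [t.name for t in trait_specs]
    missing = [n for n in names if n not in records.columns]
    if missing:
        raise ValueError(f"records lack derived trait column(s): {missing}")

    transforms: dict[str, str] = {}
    cols: dict[str, pd.Series] = {}
    for spec in trait_specs:
        x = records[spec.name].astype(float)
        if transform == "registry":
            how = spec.transform
        elif transform == "auto":
            how = _auto_transform(x, skew_threshold)
        else:
            how = "none"
        transforms[spec.name] = how
        cols[spec.name] = _apply_transform(x, how, spec.name)
    transformed = pd.DataFrame(cols, index=records.index)

    groups = records[["experiment", "treatment"]].copy()
    keys = [groups["experiment"].rename("experiment"),
            groups["treatment"].rename("treatment")]
    grouped = transformed.groupby(keys)
    mu = grouped.transform("mean")
    sd = grouped.transform("std", ddof=1)
    degenerate = sd.min(axis=0)
    for trait in names:
        if not np.isfinite(degenerate[trait]) or degenerate[trait] <= 0:
            bad = sd[trait][~(sd[trait] > 0)].index[0] if (sd[trait] <= 0).any() else None
            raise ValueError(
                f"zero within-group variance for trait {trait!r}"
                + (f" in group {bad}" if bad is not None else "")
            )
    z = (transformed - mu) / sd
    group_means = grouped.mean()
    group_sds = grouped.std(ddof=1)
    group_means.index.names = ["experiment", "treatment"]
    group_sds.index.names = ["experiment", "treatment"]
    design_cols = [c for c in ("population", "patch", "block") if c in records.columns]
    return StandardizedTraits(
        plant_ids=records["plant_id"].copy(),
        values=z,
        groups=groups,
        design=records[design_cols].copy(),
        group_means=group_means,
        group_sds=group_sds,
        transforms=transforms,
    )


def trait_correlations(std: StandardizedTraits) -> dict[tuple[str, str], pd.DataFrame]:
    """Pearson correlation matrix of the 13 traits within each
    experiment x treatment group (>= 3 plants per group required)."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    key = pd.MultiIndex.from_frame(std.groups)
    for grp, idx in std.values.groupby(key).groups.items():
        block = std.values.loc[idx]
        if len(block) < 3:
            raise ValueError(f"need >= 3 plants per group, got {len(block)} in {grp}")
        out[grp] = block.corr(method="pearson")
    return out


@dataclass(frozen=True)
class ValidationReport:
    n_rows: int
    missing_per_column: dict[str, int]
    warnings: tuple[str, ...] = ()


def read_plant_table(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a plant table CSV, validating the documented schema.

    Returns the typed table and a validation report (row and missing-value
    counts). A missing mandatory column raises a schema error naming it.
    """
    path = Path(path)
    df = pd.read_csv(path)
    design = ("plant_id", "experiment", "population", "patch", "block", "treatment")
    missing_cols = [c for c in design if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory column(s) {missing_cols}")
    raw_missing = [c for c in RAW_SCHEMA if c not in df.columns]
    derived_missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if raw_missing and derived_missing:
        # either a full raw-measurement table or a derived-trait table is fine
        raise ValueError(
            f"{path}: missing mandatory column(s) "
            f"{raw_missing if len(raw_missing) <= len(derived_missing) else derived_missing}"
        )
    has_fitness_inputs = (
        "seed_count" in df.columns
        or {"seeds_per_gram", "capitula_dw_g"} <= set(df.columns)
    )
    if not raw_missing and not has_fitness_inputs and "field2019" in set(df["experiment"]):
        raise ValueError(
            f"{path}: need either seed_count or (seeds_per_gram, capitula_dw_g)"
        )
    bad_exp = set(df["experiment"].unique()) - set(EXPERIMENTS)
    if bad_exp:
        raise ValueError(f"{path}: unknown experiment value(s) {sorted(bad_exp)}")
    bad_trt = set(df["treatment"].unique()) - set(TREATMENTS)
    if bad_trt:
        raise ValueError(f"{path}: unknown treatment value(s) {sorted(bad_trt)}")
    numeric = [c for c in (*RAW_SCHEMA, *TRAIT_NAMES, "seed_count",
                           "seeds_per_gram", "capitula_dw_g")
               if c in df.columns and c not in design]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad_row = next(
                i for i, v in enumerate(df[col])
                if not isinstance(v, (int, float, np.number)) and not _is_number(v)
            )
            raise ValueError(
                f"{path}: unparseable value in column {col!r} at data row "
                f"{bad_row + 2} (1-based, including header)"
            ) from exc
    report = ValidationReport(
        n_rows=len(df),
        missing_per_column={c: int(df[c].isna().sum()) for c in df.columns},
    )
    return df, report


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_aridity_table(path: str | Path) -> dict[str, AridityRecord]:
    """Read ``aridity.csv`` (columns population, pet, map) into records."""
    df = pd.read_csv(path)
    missing = [c for c in ("population", "pet", "map") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    out = {}
    for _, row in df.iterrows():
        rec = AridityRecord(str(row["population"]), float(row["pet"]), float(row["map"]))
        rec.aridity  # validate positivity up front
        out[rec.population] = rec
    return out


def write_results(out_dir: str | Path, tables: Mapping[str, pd.DataFrame],
                  manifest: Mapping | None = None) -> list[Path]:
    """Write one tidy CSV per named table plus an optional JSON run
    manifest; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(p)
    return written
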