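"""Registry of the 13 drought-resistance traits and their strategy modules.

Annual plants cope with seasonal drought through three broad strategies:

* **escape** — grow fast, flower early, finish reproduction before the dry
  season (growth rate, photosystem-II efficiency Fv/Fm, photosynthetic
  assimilation rate, final biomass, days to flowering);
* **avoidance** — conserve water during drought (root-to-shoot ratio, leaf
  size, leaf succulence, specific leaf area, stomatal conductance);
* **tolerance** — withstand physiological drought stress, e.g. via
  antioxidant phenolics (chlorogenic acid, a phenolic acid, a flavonoid).

Every trait vector in this package (cline slopes, selection gradients,
selection differences) is ordered by this registry, and the three modules
partition it 5/5/3.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TraitSpec",
    "DEFAULT_TRAITS",
    "TRAIT_NAMES",
    "STRATEGY_MODULES",
    "module_members",
    "trait_registry",
]

STRATEGY_MODULES = ("escape", "avoidance", "tolerance")
_TRANSFORMS = ("none", "log", "sqrt")


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: its name, strategy module, and variance-
    stabilizing transform applied before standardization."""

    name: str
    strategy_module: str
    transform: str = "none"
    direction_note: str = ""

    def __post_init__(self) -> None:
        if self.strategy_module not in STRATEGY_MODULES:
            raise ValueError(
                f"unknown strategy module {self.strategy_module!r} for trait "
                f"{self.name!r}; expected one of {STRATEGY_MODULES}"
            )
        if self.transform not in _TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r} for trait {self.name!r}"
            )


# Concentration-like traits default to a log transform; everything else is
# left untouched. The actual transform choice is data-driven at run time
# (see study_data.transform_and_standardize's skewness rule) and this
# registry only records the static default.
DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("growth_rate", "escape", "none", "leaves per week, higher = faster"),
    TraitSpec("fv_fm", "escape", "none", "dark-adapted PSII maximum yield"),
    TraitSpec("photosynthesis", "escape", "none", "CO2 assimilation rate"),
    TraitSpec("biomass", "escape", "none", "total dry mass at harvest"),
    TraitSpec("days_to_flowering", "escape", "none", "later = slower phenology"),
    TraitSpec("root_shoot_ratio", "avoidance", "none", "allocation belowground"),
    TraitSpec("leaf_size", "avoidance", "none", "area of largest leaf"),
    TraitSpec("succulence", "avoidance", "none", "(FW - DW)/DW water content"),
    TraitSpec("sla", "avoidance", "none", "leaf area per dry mass"),
    TraitSpec("stomatal_conductance", "avoidance", "none", "water-loss rate"),
    TraitSpec("chlorogenic_acid", "tolerance", "log", "antioxidant phenolic"),
    TraitSpec("phenolic_acid", "tolerance", "log", "antioxidant phenolic"),
    TraitSpec("flavonoid", "tolerance", "log", "antioxidant flavonoid"),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in DEFAULT_TRAITS)

_EXPECTED_MODULE_SIZES = {"escape": 5, "avoidance": 5, "tolerance": 3}


def trait_registry() -> tuple[TraitSpec, ...]:
    """Return the default 13-trait registry (escape 5, avoidance 5,
    tolerance 3), validating the partition."""
    sizes = {m: sum(t.strategy_module == m for t in DEFAULT_TRAITS)
             for m in STRATEGY_MODULES}
    if sizes != _EXPECTED_MODULE_SIZES:  # pragma: no cover - registry constant
        raise RuntimeError(f"trait registry corrupted: module sizes {sizes}")
    return DEFAULT_TRAITS


def module_members(module: str) -> tuple[str, ...]:
    """Names of the traits belonging to one strategy module, in registry
    order."""
    if module not in STRATEGY_MODULES:
        raise ValueError(
            f"unknown strategy module {module!r}; expected one of {STRATEGY_MODULES}"
        )
    return tuple(t.name for t in DEFAULT_TRAITS if t.strategy_module == module)
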