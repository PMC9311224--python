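"""Angles and norms of multivariate trait vectors.

The central comparison statistic of this package is the angle

    theta = arccos( u . v / (||u|| ||v||) )    (degrees, in [0, 180])

between two 13-dimensional trait vectors — e.g. clinal-divergence slopes
from two experiments, selection-gradient vectors from two watering
treatments, or clinal divergence versus the selection difference
Delta-beta = beta_dry - beta_wet. An acute angle (less than orthogonal)
means the two vectors point the same way through trait space; the Euclidean
norm measures the overall magnitude of divergence or selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .traits import TRAIT_NAMES, module_members

__all__ = [
    "TraitVector",
    "VectorComparison",
    "angle_between",
    "vector_norm",
    "subset_by_module",
    "standardize_for_display",
]

VECTOR_KINDS = ("cline_slope", "selection_gradient", "differential_selection", "generic")


@dataclass(frozen=True)
class TraitVector:
    """An ordered real vector over named traits.

    ``kind`` documents what the components are (cline slopes per unit
    aridity, selection gradients in relative fitness per trait SD, or their
    difference); it does not affect the geometry.
    """

    names: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"
    scale_note: str = "standardized trait units"

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ValueError(
                f"values must be 1-D with one entry per name; got shape "
                f"{self.values.shape} for {len(self.names)} names"
            )
        if self.kind not in VECTOR_KINDS:
            raise ValueError(f"unknown vector kind {self.kind!r}")

    @classmethod
    def from_registry(cls, values: Sequence[float], kind: str = "generic") -> "TraitVector":
        return cls(TRAIT_NAMES, np.asarray(values, float), kind)

    def __len__(self) -> int:
        return len(self.names)

    def __sub__(self, other: "TraitVector") -> "TraitVector":
        _check_matching(self, other)
        return TraitVector(self.names, self.values - other.values, "generic")


def _check_matching(u: TraitVector, v: TraitVector) -> None:
    if u.names != v.names:
        raise ValueError(
            "trait registries do not match (names or order differ): "
            f"{u.names} vs {v.names}"
        )


def vector_norm(u: TraitVector | np.ndarray) -> float:
    """Euclidean norm of a trait vector."""
    x = u.values if isinstance(u, TraitVector) else np.asarray(u, float)
    return float(np.linalg.norm(x))


def angle_between(u: TraitVector | np.ndarray, v: TraitVector | np.ndarray) -> float:
    """Angle between two trait vectors in degrees, in [0, 180].

    Computed in a form equivalent to arccos of the clamped cosine
    u.v/(|u||v|) but numerically exact at the parallel/antiparallel
    limits, so near-parallel vectors return 0 (or 180) rather than NaN.
    A zero-norm argument raises: the angle is undefined.
    """
    if isinstance(u, TraitVector) and isinstance(v, TraitVector):
        _check_matching(u, v)
    x = u.values if isinstance(u, TraitVector) else np.asarray(u, float)
    y = v.values if isinstance(v, TraitVector) else np.asarray(v, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("angle undefined for a zero-norm vector")
    # Kahan's formulation: equivalent to arccos of the clamped cosine but
    # exact at 0 and 180 for (anti)parallel inputs and stable near them.
    xh, yh = x / nx, y / ny
    theta = 2.0 * math.atan2(np.linalg.norm(xh - yh), np.linalg.norm(xh + yh))
    return math.degrees(theta)


def subset_by_module(u: TraitVector, module: str) -> TraitVector:
    """Restrict a registry-ordered vector to one strategy module
    (escape: 5 traits, avoidance: 5, tolerance: 3)."""
    members = module_members(module)  # raises on unknown module
    idx = [u.names.index(m) for m in members if m in u.names]
    if len(idx) != len(members):
        missing = [m for m in members if m not in u.names]
        raise ValueError(f"vector lacks module trait(s) {missing}")
    return TraitVector(tuple(u.names[i] for i in idx), u.values[idx], u.kind)


def standardize_for_display(u: TraitVector) -> TraitVector:
    """Zero-mean unit-variance rescaling of the components, for plotting
    contrasts only — never feed the result into angle/norm inference, since
    the recentring changes angles."""
    if len(u) < 2:
        raise ValueError("need >= 2 components to standardize")
    sd = float(np.std(u.values, ddof=1))
    if sd == 0 or np.ptp(u.values) == 0:
        raise ValueError("zero variance across components; display scaling undefined")
    return TraitVector(u.names, (u.values - u.values.mean()) / sd, u.kind,
                       "display-standardized (zero mean, unit variance)")


@dataclass
class VectorComparison:
    """Two trait vectors with their angle, norms and (optionally) posterior
    summaries filled in by the uncertainty machinery.

    ``alignment_verdict`` is decided solely by whether the 95% credible
    interval of the angle excludes 90 degrees.
    """

    vector_u: TraitVector
    vector_v: TraitVector
    angle_deg: float
    norm_u: float
    norm_v: float
    angle_summary: Optional[object] = None   # CredibleSummary
    norm_u_summary: Optional[object] = None
    norm_v_summary: Optional[object] = None
    n_draws_dropped: int = 0

    @property
    def alignment_verdict(self) -> str:
        if self.angle_summary is None:
            return "orthogonal_indistinguishable"
        lo, hi = self.angle_summary.lower95, self.angle_summary.upper95
        if hi < 90.0:
            return "less_than_orthogonal"
        if lo > 90.0:
            return "greater_than_orthogonal"
        return "orthogonal_indistinguishable"

    def to_dict(self) -> dict:
        d = {
            "traits": list(self.vector_u.names),
            "u": self.vector_u.values.tolist(),
            "v": self.vector_v.values.tolist(),
            "kind_u": self.vector_u.kind,
            "kind_v": self.vector_v.kind,
            "angle_deg": self.angle_deg,
            "norm_u": self.norm_u,
            "norm_v": self.norm_v,
            "alignment_verdict": self.alignment_verdict,
            "n_draws_dropped": self.n_draws_dropped,
        }
        for key, s in (("angle", self.angle_summary),
                       ("norm_u", self.norm_u_summary),
                       ("norm_v", self.norm_v_summary)):
            if s is not None:
                d[f"{key}_posterior"] = {
                    "mean": s.mean, "lower95": s.lower95,
                    "upper95": s.upper95, "n_draws": s.n_draws,
                }
        return d
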