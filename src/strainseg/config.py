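"""Run configuration: every free parameter of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["Config", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


@dataclass
class Config:
    """All tunable parameters of the segmentation pipeline.

    Attributes
    ----------
    threshold : intensity cutoff for foreground extraction; chosen
        conservatively low so faint structure is not lost.
    e0 : modulus scale. Only relative strain matters for segmentation,
        so the default of 1 is fine in any consistent unit system.
    poisson_ratio : single Poisson ratio for all elements; 0.3 is the
        standard engineering value for bone-like solids.
    plane : "stress" (thin free slice, default) or "strain".
    spring_factor : ground-spring coefficient as a fraction of the
        largest stiffness diagonal entry; kept far below the softest
        elastic (hinge) mode so only rigid-body motion is pinned.
    von_mises_convention : "equivalent" or "deviatoric" (constant
        rescale; does not change the segmentation).
    max_iter, opt_rtol, armijo_c, armijo_backtrack : load-optimizer
        controls (iteration cap, relative-improvement stop, Armijo
        sufficient-increase parameter, backtrack factor).
    connectivity : 4 (default) or 8, used for components and repair.
    skip_theta : an ROI whose weakness falls below ``skip_theta`` times
        the maximum weakness is considered doubtful and skipped.
    max_removals_factor : destruction iteration cap as a multiple of
        the ROI area.
    solver_cutoff : dof count above which the direct factorization is
        replaced by preconditioned conjugate gradients.
    seed : used only by phantom generation; analysis is deterministic.
    """

    threshold: float = 50.0
    e0: float = 1.0
    poisson_ratio: float = 0.3
    plane: str = "stress"
    spring_factor: float = 1e-11
    von_mises_convention: str = "equivalent"
    max_iter: int = 200
    opt_rtol: float = 1e-6
    armijo_c: float = 1e-4
    armijo_backtrack: float = 0.5
    connectivity: int = 4
    skip_theta: float = 0.1
    max_removals_factor: float = 2.0
    solver_cutoff: int = 400_000
    seed: int = 0
    schema_version: int = field(default=SCHEMA_VERSION)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.e0 <= 0:
            raise ValueError("e0 must be positive")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.plane not in ("stress", "strain"):
            raise ValueError("plane must be 'stress' or 'strain'")
        if self.spring_factor <= 0:
            raise ValueError("spring_factor must be positive")
        if self.von_mises_convention not in ("equivalent", "deviatoric"):
            raise ValueError("unknown von Mises convention")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.armijo_c < 1) or not (0 < self.armijo_backtrack < 1):
            raise ValueError("Armijo parameters must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0 < self.skip_theta < 1):
            raise ValueError("skip_theta must lie in (0, 1)")
        if self.max_removals_factor <= 0:
            raise ValueError("max_removals_factor must be positive")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema version {self.schema_version}"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
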