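"""Parameter containers for the agent-based primordium model.

The model represents the posterior lateral line primordium as a column of
point agents ("turtles"): a leading Wnt-active domain (WNTERs), a trailing
FGF-active domain (FGFERs), and — in runs with a shrinking Wnt system — a
third breed (DEPOSITERs) of trailing agents that have lost migratory
capacity and are left behind.

Lengths are in grid units (initial lattice spacing = 1); speeds are
displacements per step.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum


class AgentBreed(IntEnum):
    WNTER = 0
    FGFER = 1
    DEPOSITER = 2


@dataclass(frozen=True)
class SpringParams:
    """Spring-like link parameters for one agent breed.

    A link at length ``l`` pulls each endpoint a distance
    ``spring_constant * (l - spring_length)`` toward the other (pushing when
    compressed), while nearby agents repel each other with displacement
    ``repulsion_constant / l**2``.  Links rupture beyond ``break_threshold``
    and are removed at random with per-step probability ``turnover_rate``.
    """

    spring_constant: float = 0.18
    spring_length: float = 0.5
    repulsion_constant: float = 0.05
    break_threshold: float = 3.6
    turnover_rate: float = 0.005

    def __post_init__(self) -> None:
        if not (self.break_threshold >= self.spring_length > 0):
            raise ValueError("require break_threshold >= spring_length > 0")
        if not (0.0 <= self.turnover_rate <= 1.0):
            raise ValueError("turnover_rate must be a probability")


#: Depositers keep FGFER spring behavior but a low break threshold, so the
#: advancing primordium detaches from them.
_DEPOSITER_SPRINGS = SpringParams(break_threshold=0.8, turnover_rate=0.005)


@dataclass(frozen=True)
class ABMParams:
    """Full configuration of the agent-based model.

    Defaults reproduce the published column geometry (150 agents, 5 wide and
    30 long, leading 60% Wnt) and speed/spring constants (w = 0.018,
    f = 0.016, s = 0.18); the remaining rates and radii are calibrated
    defaults (see the package methods note).
    """

    column_width: int = 5
    column_length: int = 30
    spacing: float = 1.0
    wnt_fraction: float = 0.6
    speed_wnt: float = 0.018
    speed_fgf: float = 0.016
    link_radius_by_breed: dict[AgentBreed, float] = field(
        default_factory=lambda: {
            AgentBreed.WNTER: 3.2,
            AgentBreed.FGFER: 3.2,
            AgentBreed.DEPOSITER: 3.2,
        }
    )
    springs_by_breed: dict[AgentBreed, SpringParams] = field(
        default_factory=lambda: {
            AgentBreed.WNTER: SpringParams(),
            AgentBreed.FGFER: SpringParams(),
            AgentBreed.DEPOSITER: _DEPOSITER_SPRINGS,
        }
    )
    density_radius: float = 1.0
    density_threshold: int = 5
    proliferation_rate_by_breed: dict[AgentBreed, float] = field(
        default_factory=lambda: {
            AgentBreed.WNTER: 0.0,
            AgentBreed.FGFER: 0.0,
            AgentBreed.DEPOSITER: 0.0,
        }
    )
    shrinkage_enabled: bool = False
    wnt_shrink_rate: float = 0.002
    length_factor: float = 1.6
    displacement_cap: float = 0.5
    repulsion_floor: float = 1e-3
    daughter_offset: float = 0.2
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if self.column_width <= 0 or self.column_length <= 0:
            raise ValueError("column dimensions must be positive")
        if not (0.0 <= self.wnt_fraction <= 1.0):
            raise ValueError("wnt_fraction must lie in [0, 1]")
        if self.length_factor <= 1.0:
            raise ValueError("length_factor must exceed 1")
        if self.wnt_shrink_rate < 0 or self.density_radius <= 0:
            raise ValueError("rates and radii must be non-negative")
        for b in AgentBreed:
            if b not in self.link_radius_by_breed:
                raise ValueError(f"missing link radius for {b.name}")
            if b not in self.springs_by_breed:
                raise ValueError(f"missing spring params for {b.name}")
        for rate in self.proliferation_rate_by_breed.values():
            if not (0.0 <= rate <= 1.0):
                raise ValueError("proliferation rates must be probabilities")

    def with_overrides(self, **kwargs) -> "ABMParams":
        return replace(self, **kwargs)

    @property
    def n_agents_init(self) -> int:
        return self.column_width * self.column_length

    @property
    def max_link_radius(self) -> float:
        return max(self.link_radius_by_breed.values())
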