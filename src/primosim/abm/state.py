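"""State container for the agent-based model.

Agents are stored as flat arrays indexed by agent id (ids are stable; agents
are only ever appended by proliferation, never removed — a "deposited" agent
simply stops moving and loses its links).  Links are an (M, 2) integer array
of id pairs with ``links[:, 0] < links[:, 1]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ABMParams, AgentBreed


@dataclass
class ABMState:
    pos: np.ndarray  # (N, 2) float64; x = migration axis
    breed: np.ndarray  # (N,) int8, AgentBreed values
    links: np.ndarray  # (M, 2) int64, each row sorted
    neighbor_count: np.ndarray  # (N,) int64
    flagged_dense: np.ndarray  # (N,) bool
    step_index: int = 0
    wnt_domain_length: float = 0.0

    @property
    def n_agents(self) -> int:
        return self.pos.shape[0]

    @property
    def n_links(self) -> int:
        return self.links.shape[0]

    def breed_counts(self) -> dict[AgentBreed, int]:
        return {b: int(np.sum(self.breed == b)) for b in AgentBreed}

    def validate(self) -> None:
        """Raise if structural invariants are violated."""
        if not np.all(np.isfinite(self.pos)):
            raise ValueError("non-finite agent position")
        if self.links.size:
            if np.any(self.links[:, 0] >= self.links[:, 1]):
                raise ValueError("link rows must be sorted pairs of distinct ids")
            if np.any(self.links >= self.n_agents) or np.any(self.links < 0):
                raise ValueError("link endpoint references missing agent")
            keys = self.links[:, 0] * self.n_agents + self.links[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise ValueError("duplicate link")
        if self.wnt_domain_length < 0:
            raise ValueError("wnt_domain_length must be >= 0")

    def copy(self) -> "ABMState":
        return ABMState(
            pos=self.pos.copy(),
            breed=self.breed.copy(),
            links=self.links.copy(),
            neighbor_count=self.neighbor_count.copy(),
            flagged_dense=self.flagged_dense.copy(),
            step_index=self.step_index,
            wnt_domain_length=self.wnt_domain_length,
        )

    def to_frame(self):
        """Agent table as a pandas DataFrame (snapshot output schema)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n_agents),
                "breed": [AgentBreed(b).name for b in self.breed],
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "neighbor_count": self.neighbor_count,
                "flagged_dense": self.flagged_dense,
            }
        )


def empty_state(n: int) -> ABMState:
    return ABMState(
        pos=np.zeros((n, 2)),
        breed=np.zeros(n, dtype=np.int8),
        links=np.zeros((0, 2), dtype=np.int64),
        neighbor_count=np.zeros(n, dtype=np.int64),
        flagged_dense=np.zeros(n, dtype=bool),
    )
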