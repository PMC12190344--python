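"""Dynamics of the agent-based primordium model.

One step applies, in order: breed-specific forward migration, link breakage
(turnover + over-stretch), link re-formation within breed radii, one
spring-relaxation sweep (linear spring attraction, inverse-square repulsion,
capped displacement), proliferation, Wnt-domain shrinkage with Depositer
re-specification, and density classification.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .params import ABMParams, AgentBreed, SpringParams
from .state import ABMState, empty_state

__all__ = [
    "init_abm",
    "step_abm",
    "apply_spring_forces",
    "update_links",
    "proliferate",
    "shrink_and_deposit",
    "density_classify",
]


def init_abm(params: ABMParams) -> ABMState:
    """Build the initial rectangular column of agents.

    Agents sit on a regular grid ``column_width`` wide (y) and
    ``column_length`` long (x, the migration axis).  Rows in the leading
    ``wnt_fraction`` of the column length are WNTERs, the trailing rest
    FGFERs.  Links are created with the same radius rule used during a run.
    """
    nx, ny = params.column_length, params.column_width
    state = empty_state(nx * ny)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    state.pos[:, 0] = xs.ravel() * params.spacing
    state.pos[:, 1] = ys.ravel() * params.spacing
    # leading = large x; the leading wnt_fraction of rows are WNTERs
    first_wnt_row = int(np.ceil(nx * (1.0 - params.wnt_fraction)))
    row = xs.ravel()
    state.breed = np.where(
        row >= first_wnt_row, AgentBreed.WNTER, AgentBreed.FGFER
    ).astype(np.int8)
    state.wnt_domain_length = params.wnt_fraction * nx * params.spacing
    state = update_links(state, params, rng=None)
    state = density_classify(state, params)
    return state


def _pair_springs(state: ABMState, params: ABMParams, pairs: np.ndarray):
    """Effective spring parameters for each id pair.

    Per-breed parameters are combined symmetrically: spring constant, rest
    length and repulsion are averaged; the break threshold is the minimum and
    the turnover rate the maximum of the two breeds' values, so a link
    touching a Depositer inherits its low break threshold.
    """
    nb = len(AgentBreed)
    sp = [params.springs_by_breed[AgentBreed(b)] for b in range(nb)]
    s = np.array([p.spring_constant for p in sp])
    L = np.array([p.spring_length for p in sp])
    r = np.array([p.repulsion_constant for p in sp])
    brk = np.array([p.break_threshold for p in sp])
    to = np.array([p.turnover_rate for p in sp])
    bi = state.breed[pairs[:, 0]]
    bj = state.breed[pairs[:, 1]]
    return (
        0.5 * (s[bi] + s[bj]),
        0.5 * (L[bi] + L[bj]),
        0.5 * (r[bi] + r[bj]),
        np.minimum(brk[bi], brk[bj]),
        np.maximum(to[bi], to[bj]),
    )


def _link_lengths(state: ABMState, pairs: np.ndarray) -> np.ndarray:
    d = state.pos[pairs[:, 0]] - state.pos[pairs[:, 1]]
    return np.hypot(d[:, 0], d[:, 1])


def update_links(
    state: ABMState, params: ABMParams, rng: np.random.Generator | None
) -> ABMState:
    """Break over-stretched/turned-over links, then re-make links in radius.

    A pair is linkable if its distance is within the larger of the two
    breeds' link radii (either agent may initiate the link).  Passing
    ``rng=None`` skips stochastic turnover (used at initialization).
    """
    links = state.links
    if links.size:
        _, _, _, brk, to = _pair_springs(state, params, links)
        keep = _link_lengths(state, links) <= brk
        if rng is not None:
            keep &= rng.random(len(links)) >= to
        links = links[keep]

    tree = cKDTree(state.pos)
    cand = tree.query_pairs(params.max_link_radius, output_type="ndarray")
    if cand.size:
        cand.sort(axis=1)
        radii = np.array(
            [params.link_radius_by_breed[AgentBreed(b)] for b in range(len(AgentBreed))]
        )
        rmax = np.maximum(radii[state.breed[cand[:, 0]]], radii[state.breed[cand[:, 1]]])
        cand = cand[_link_lengths(state, cand) <= rmax]
    if cand.size:
        n = state.n_agents
        have = set((links[:, 0] * n + links[:, 1]).tolist()) if links.size else set()
        keys = cand[:, 0] * n + cand[:, 1]
        new = cand[[k not in have for k in keys.tolist()]]
        links = np.vstack([links, new]) if links.size else new
    state.links = np.asarray(links, dtype=np.int64).reshape(-1, 2)
    return state


def apply_spring_forces(state: ABMState, params: ABMParams) -> ABMState:
    """One relaxation sweep of the spring/repulsion layout.

    Each linked pair at length ``l`` pulls both endpoints a distance
    ``s * (l - L)`` toward each other (pushing apart when compressed); every
    pair within link radius additionally repels with displacement
    ``r / l**2`` per agent.  Coincident agents are repelled at the floor
    distance; per-agent displacement is capped for stability.
    """
    disp = np.zeros_like(state.pos)
    eps = params.repulsion_floor

    if state.links.size:
        pairs = state.links
        s, L, _, _, _ = _pair_springs(state, params, pairs)
        d = state.pos[pairs[:, 1]] - state.pos[pairs[:, 0]]
        l = np.maximum(np.hypot(d[:, 0], d[:, 1]), eps)
        u = d / l[:, None]
        pull = (s * (l - L))[:, None] * u
        np.add.at(disp, pairs[:, 0], pull)
        np.add.at(disp, pairs[:, 1], -pull)

    tree = cKDTree(state.pos)
    near = tree.query_pairs(params.max_link_radius, output_type="ndarray")
    if near.size:
        near.sort(axis=1)
        _, _, r, _, _ = _pair_springs(state, params, near)
        d = state.pos[near[:, 1]] - state.pos[near[:, 0]]
        l = np.maximum(np.hypot(d[:, 0], d[:, 1]), eps)
        u = d / l[:, None]
        push = (r / l**2)[:, None] * u
        np.add.at(disp, near[:, 0], -push)
        np.add.at(disp, near[:, 1], push)

    norm = np.hypot(disp[:, 0], disp[:, 1])
    over = norm > params.displacement_cap
    if np.any(over):
        disp[over] *= (params.displacement_cap / norm[over])[:, None]
    state.pos = state.pos + disp
    return state


def proliferate(
    state: ABMState, params: ABMParams, rng: np.random.Generator
) -> ABMState:
    """Divide WNTERs/FGFERs with their breed's per-step probability.

    Daughters appear at a uniform random offset within ``daughter_offset`` of
    the mother, inherit her breed, and start unlinked (they acquire links at
    the next link-remake pass).  Depositers never divide.
    """
    rates = np.array(
        [params.proliferation_rate_by_breed[AgentBreed(b)] for b in range(len(AgentBreed))]
    )
    rates = rates.copy()
    rates[AgentBreed.DEPOSITER] = 0.0
    p = rates[state.breed]
    draws = rng.random(state.n_agents)
    mothers = np.nonzero(draws < p)[0]
    if len(mothers) == 0:
        return state
    theta = rng.random(len(mothers)) * 2 * np.pi
    rad = params.daughter_offset * np.sqrt(rng.random(len(mothers)))
    offset = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    state.pos = np.vstack([state.pos, state.pos[mothers] + offset])
    state.breed = np.concatenate([state.breed, state.breed[mothers]])
    state.neighbor_count = np.concatenate(
        [state.neighbor_count, np.zeros(len(mothers), dtype=np.int64)]
    )
    state.flagged_dense = np.concatenate(
        [state.flagged_dense, np.zeros(len(mothers), dtype=bool)]
    )
    return state


def shrink_and_deposit(state: ABMState, params: ABMParams) -> ABMState:
    """Shrink the Wnt domain and re-specify out-of-bounds FGFERs.

    The permitted primordium length is ``length_factor`` times the current
    Wnt-domain length, measured trailing-ward from the leading edge (the
    largest x among non-Depositer agents).  FGFERs strictly beyond it become
    Depositers: zero speed, no proliferation, low link break thresholds.
    """
    state.wnt_domain_length = max(0.0, state.wnt_domain_length - params.wnt_shrink_rate)
    active = state.breed != AgentBreed.DEPOSITER
    if not np.any(active):
        return state
    leading = float(state.pos[active, 0].max())
    cutoff = leading - params.length_factor * state.wnt_domain_length
    out = (state.breed == AgentBreed.FGFER) & (state.pos[:, 0] < cutoff)
    state.breed[out] = AgentBreed.DEPOSITER
    return state


def density_classify(state: ABMState, params: ABMParams) -> ABMState:
    """Count neighbors within ``density_radius``; flag counts strictly above
    ``density_threshold`` (the cyan high-density highlight)."""
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(params.density_radius, output_type="ndarray")
    counts = np.zeros(state.n_agents, dtype=np.int64)
    if pairs.size:
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    state.neighbor_count = counts
    state.flagged_dense = counts > params.density_threshold
    return state


def step_abm(
    state: ABMState, params: ABMParams, rng: np.random.Generator
) -> ABMState:
    """Advance the model by one iteration (sub-steps in fixed order)."""
    speeds = np.zeros(len(AgentBreed))
    speeds[AgentBreed.WNTER] = params.speed_wnt
    speeds[AgentBreed.FGFER] = params.speed_fgf
    state.pos[:, 0] += speeds[state.breed]

    state = update_links(state, params, rng)
    state = apply_spring_forces(state, params)
    state = proliferate(state, params, rng)
    if params.shrinkage_enabled:
        state = shrink_and_deposit(state, params)
    state = density_classify(state, params)
    state.step_index += 1
    return state
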