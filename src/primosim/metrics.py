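"""Cluster/rosette quantification and primordium kinematics.

The readouts operationalize what the models show visually: groups of
high-density agents in the agent-based model, and groups of apically
constricted compartments in the Cellular Potts model.  A cluster counts as a
rosette when it has at least a minimum number of members (default 3); the
thresholds are exposed so they can be reported alongside the counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .abm.params import ABMParams, AgentBreed
from .abm.state import ABMState

__all__ = [
    "RosetteReport",
    "abm_cluster_count",
    "detect_rosettes_cpm",
    "primordium_extent",
    "edge_velocity_series",
]


@dataclass
class RosetteReport:
    """Detected clusters at one time point.

    ``clusters`` maps each retained cluster to its member ids, size, and
    centroid; clusters are ordered by centroid x.  ``n_rosettes`` counts the
    clusters that met the minimum-size rule.
    """

    time: int
    clusters: list[dict] = field(default_factory=list)
    n_rosettes: int = 0
    primordium_length: float = 0.0
    leading_edge_x: float = 0.0
    trailing_edge_x: float = 0.0

    @property
    def sizes(self) -> list[int]:
        return [c["size"] for c in self.clusters]

    @property
    def centroids(self) -> list[tuple[float, float]]:
        return [c["centroid"] for c in self.clusters]


def _components_to_clusters(
    members: np.ndarray, labels: np.ndarray, positions: np.ndarray, min_size: int
) -> list[dict]:
    clusters = []
    for lab in np.unique(labels):
        ids = members[labels == lab]
        if len(ids) < min_size:
            continue
        cen = positions[labels == lab].mean(axis=0)
        clusters.append(
            {"members": ids.tolist(), "size": int(len(ids)), "centroid": (float(cen[0]), float(cen[1]))}
        )
    clusters.sort(key=lambda c: c["centroid"][0])
    return clusters


def abm_cluster_count(state: ABMState, params: ABMParams) -> RosetteReport:
    """Count dense-agent clusters in an agent-based model state.

    Clusters are connected components of density-flagged agents under the
    adjacency "within ``density_radius``"; components smaller than
    ``min_cluster_size`` are discarded.  Requires ``density_classify`` to
    have run on the state.
    """
    flagged = np.nonzero(state.flagged_dense)[0]
    report = RosetteReport(time=state.step_index)
    lead, trail, length = primordium_extent(state)
    report.leading_edge_x, report.trailing_edge_x = lead, trail
    report.primordium_length = length
    if len(flagged) == 0:
        return report
    pos = state.pos[flagged]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(params.density_radius, output_type="ndarray")
    m = len(flagged)
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    _, labels = connected_components(adj, directed=False)
    report.clusters = _components_to_clusters(
        flagged, labels, pos, params.min_cluster_size
    )
    report.n_rosettes = len(report.clusters)
    return report


def detect_rosettes_cpm(state, min_apical_members: int = 3) -> RosetteReport:
    """Detect rosettes as clusters of apical (fgfapi) compartments.

    Two apical compartments belong to the same cluster when they share
    lattice boundary (order-1 adjacency) or are joined by an active
    apical-apical spring link; clusters with at least ``min_apical_members``
    members count as rosettes.
    """
    api_ids = np.array(
        [cid for cid in state.cell_ids() if state.type_name_of(cid) == "fgfapi"],
        dtype=np.int64,
    )
    report = RosetteReport(time=state.mcs)
    lead, trail, length = primordium_extent(state)
    report.leading_edge_x, report.trailing_edge_x = lead, trail
    report.primordium_length = length
    if len(api_ids) == 0:
        return report
    index = {cid: k for k, cid in enumerate(api_ids)}
    m = len(api_ids)
    rows, cols = [], []
    contact = state.contact_pairs()  # set of sorted (cell_id, cell_id) order-1 pairs
    for a, b in contact:
        if a in index and b in index:
            rows.append(index[a])
            cols.append(index[b])
    for link in state.active_links():
        if link.cell_a in index and link.cell_b in index:
            rows.append(index[link.cell_a])
            cols.append(index[link.cell_b])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, labels = connected_components(adj, directed=False)
    coms = np.array([state.center_of_mass(cid) for cid in api_ids])
    # unwrap apical centroids around the periodic x-axis before clustering
    # centroids are only reported, not used for adjacency, so raw coms suffice
    report.clusters = _components_to_clusters(api_ids, labels, coms, min_apical_members)
    report.n_rosettes = len(report.clusters)
    return report


def _unwrapped_span(xs: np.ndarray, width: float) -> tuple[float, float]:
    """Leading/trailing x of a point set on a circle of circumference width.

    Chooses the circular shift that minimizes the span (equivalently, cuts
    the largest empty gap) and returns edges in unwrapped coordinates.
    """
    xs = np.sort(np.mod(xs, width))
    if len(xs) == 1:
        return float(xs[0]), float(xs[0])
    gaps = np.diff(np.concatenate([xs, [xs[0] + width]]))
    cut = int(np.argmax(gaps))
    if cut == len(xs) - 1:  # largest gap is the wrap-around one: no unwrap needed
        return float(xs[-1]), float(xs[0])
    # occupied arc runs xs[cut+1] .. xs[-1], wraps, continues .. xs[cut]
    return float(xs[cut] + width), float(xs[cut + 1])


def primordium_extent(state) -> tuple[float, float, float]:
    """(leading_edge_x, trailing_edge_x, length) of the primordium.

    For the agent-based model: extremal x over non-Depositer agents.  For
    the lattice model: extremal x over primordium-type pixels, unwrapped
    across the periodic x-boundary by cutting the largest empty gap.
    """
    if isinstance(state, ABMState):
        active = state.breed != AgentBreed.DEPOSITER
        if not np.any(active):
            raise ValueError("empty primordium: no non-Depositer agents")
        xs = state.pos[active, 0]
        lead, trail = float(xs.max()), float(xs.min())
        return lead, trail, lead - trail
    # CPM state: primordium-type pixels on the periodic-x lattice
    xs = state.primordium_pixel_xs()
    if len(xs) == 0:
        raise ValueError("empty primordium: no primordium-type pixels")
    occupied = np.unique(xs)
    lead, trail = _unwrapped_span(occupied.astype(float), float(state.width))
    return lead, trail, lead - trail


def edge_velocity_series(
    reports: list[RosetteReport], window: int = 1
) -> dict[str, np.ndarray]:
    """Centered finite-difference edge velocities over a report series.

    ``window`` is the half-width in report indices; velocity at index i uses
    reports i-window and i+window.  Returns arrays aligned with the interior
    reports, plus the corresponding times.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports")
    if 2 * window >= len(reports):
        raise ValueError("window larger than series")
    t = np.array([r.time for r in reports], dtype=float)
    lead = np.array([r.leading_edge_x for r in reports])
    trail = np.array([r.trailing_edge_x for r in reports])
    lo = slice(None, -2 * window)
    hi = slice(2 * window, None)
    dt = t[hi] - t[lo]
    return {
        "time": t[window:-window] if window else t,
        "leading": (lead[hi] - lead[lo]) / dt,
        "trailing": (trail[hi] - trail[lo]) / dt,
    }
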