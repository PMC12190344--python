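"""2D Cellular Potts (Glazier-Graner-Hogeweg) engine.

Each cell is the set of lattice pixels carrying its id; the configuration
evolves by random pixel-copy attempts accepted against the energy

    J = sum_cells lambda*(v - V)^2  +  sum_cells beta*(a - A)^2
        + sum_{unlike neighbor pixel pairs} H_ij
        + sum_{active spring links} lambda_ij*(l_ij - L_ij)^2

with Boltzmann acceptance P = 1 for dJ <= h, exp(-(dJ - h)/T) otherwise.
Migratory force enters as an extra work term proportional to the
center-of-mass x-displacement of the moved cell (negative coefficients
favor +x motion); it biases acceptance but is not part of J.

The lattice is periodic in x and closed in y.  Contact energies are counted
over the neighbor shells up to ``neighbor_order`` (default 3, i.e. 12
offsets); pixel copies are attempted between order-1 (axial) neighbors.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = [
    "EngineParams",
    "CellTypeParams",
    "FPPLink",
    "LinkClass",
    "CPMState",
    "neighbor_offsets",
    "accept_probability",
    "external_force_bias",
    "hamiltonian",
    "delta_J",
    "monte_carlo_step",
    "update_fpp_links",
]

MEDIUM = "Medium"


@dataclass(frozen=True)
class EngineParams:
    temperature: float = 20.0
    threshold: float = 0.0  # energy threshold h of the acceptance rule
    neighbor_order: int = 3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.neighbor_order not in (1, 2, 3):
            raise ValueError("neighbor_order must be 1, 2 or 3")


@dataclass(frozen=True)
class CellTypeParams:
    """Target geometry and penalties of one cell type.

    ``lambda_volume``/``target_volume`` and ``lambda_surface``/
    ``target_surface`` parameterize the quadratic size constraints;
    ``migration_force_x`` is the external-potential coefficient (a negative
    value drives the cell along +x); ``frozen`` pins every pixel of the type.
    """

    type_name: str
    lambda_volume: float = 0.0
    target_volume: float = 0.0
    lambda_surface: float = 0.0
    target_surface: float = 0.0
    migration_force_x: float = 0.0
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.lambda_volume < 0 or self.lambda_surface < 0:
            raise ValueError("penalties must be >= 0")
        if self.target_volume < 0 or self.target_surface < 0:
            raise ValueError("targets must be >= 0")


@dataclass
class FPPLink:
    """Breakable spring between two cells (or compartments).

    Contributes ``strength * (l - target_length)**2`` to the energy while
    active, where ``l`` is the center-to-center distance with minimal-image
    unwrapping in x.  External links rupture when stretched strictly beyond
    ``max_length``; internal (intra-composite) links never break.  Reformable
    links re-form when the two cells regain shared boundary.
    """

    cell_a: int
    cell_b: int
    strength: float
    target_length: float
    max_length: float
    internal: bool = False
    reformable: bool = False
    active: bool = True

    def __post_init__(self) -> None:
        if self.cell_a == self.cell_b:
            raise ValueError("link endpoints must be distinct")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.max_length < self.target_length:
            raise ValueError("max_length must be >= target_length")


@dataclass(frozen=True)
class LinkClass:
    """Reformable-link template for a pair of cell types: any unlinked pair
    of these types gaining shared boundary is linked with these parameters."""

    type_a: str
    type_b: str
    strength: float
    target_length: float
    max_length: float


class CPMState:
    """Lattice, per-cell caches, parameter tables and link ledger."""

    def __init__(
        self,
        width: int,
        height: int,
        types: list[CellTypeParams],
        contact_external: dict[tuple[str, str], float],
        contact_internal: dict[tuple[str, str], float] | None = None,
        engine: EngineParams | None = None,
    ):
        if width <= 0 or height <= 0:
            raise ValueError("lattice dimensions must be positive")
        names = [t.type_name for t in types]
        if MEDIUM in names:
            raise ValueError("Medium type is implicit; do not declare it")
        self.width = width
        self.height = height
        self.engine = engine or EngineParams()
        self.types = [CellTypeParams(MEDIUM)] + list(types)
        self.type_index = {t.type_name: i for i, t in enumerate(self.types)}
        nt = len(self.types)
        self._lam_v = np.array([t.lambda_volume for t in self.types])
        self._tgt_v = np.array([t.target_volume for t in self.types])
        self._lam_s = np.array([t.lambda_surface for t in self.types])
        self._tgt_s = np.array([t.target_surface for t in self.types])
        self._force_x = np.array([t.migration_force_x for t in self.types])
        self._frozen = np.array([t.frozen for t in self.types])

        self._ext = np.zeros((nt, nt))
        seen = np.zeros((nt, nt), dtype=bool)
        for (a, b), e in contact_external.items():
            ia, ib = self.type_index[a], self.type_index[b]
            self._ext[ia, ib] = self._ext[ib, ia] = e
            seen[ia, ib] = seen[ib, ia] = True
        missing = [
            (self.types[i].type_name, self.types[j].type_name)
            for i in range(nt)
            for j in range(i, nt)
            if not seen[i, j] and not (i == 0 and j == 0)
        ]
        if missing:
            raise ValueError(f"contact table incomplete; missing pairs: {missing}")
        # internal energies default to the external value where unspecified
        self._int = self._ext.copy()
        for (a, b), e in (contact_internal or {}).items():
            ia, ib = self.type_index[a], self.type_index[b]
            self._int[ia, ib] = self._int[ib, ia] = e

        self.lattice = np.zeros((height, width), dtype=np.int64)
        self.cell_type_idx = [0]  # cell id -> type index; id 0 is Medium
        self.cell_composite = [-1]
        self.links: list[FPPLink] = []
        self.link_classes: list[LinkClass] = []
        self.mcs = 0
        self.primordium_types: set[str] = set()
        self._finalized = False

    # ---------------------------------------------------------------- build
    def add_cell(self, type_name: str, composite_id: int = -1) -> int:
        if type_name == MEDIUM:
            raise ValueError("Medium is cell id 0 and cannot be added")
        if composite_id >= 0 and type_name == MEDIUM:
            raise ValueError("Medium can never be a composite member")
        self.cell_type_idx.append(self.type_index[type_name])
        self.cell_composite.append(composite_id)
        return len(self.cell_type_idx) - 1

    def paint(self, cell_id: int, x0: int, x1: int, y0: int, y1: int) -> None:
        """Assign the rectangle [x0, x1) x [y0, y1) to cell_id (x wraps)."""
        xs = np.arange(x0, x1) % self.width
        self.lattice[y0:y1, xs] = cell_id

    def add_link(
        self,
        cell_a: int,
        cell_b: int,
        strength: float,
        target_length: float,
        max_length: float,
        internal: bool = False,
        reformable: bool = False,
    ) -> FPPLink:
        link = FPPLink(
            cell_a, cell_b, strength, target_length, max_length,
            internal=internal, reformable=reformable,
        )
        self.links.append(link)
        self._dirty_links = True
        return link

    def add_link_class(self, cls: LinkClass) -> None:
        self.link_classes.append(cls)

    def finalize(self) -> None:
        """Compute caches from the painted lattice; call once after building."""
        (
            self._vol,
            self._surf,
            self._sumc,
            self._sums,
            self._sumy,
        ) = K.recompute_caches(self.lattice, self.n_cells)
        if np.any(self._vol[1:] == 0):
            empty = np.nonzero(self._vol[1:] == 0)[0] + 1
            raise ValueError(f"cells with no pixels after painting: {empty.tolist()}")
        self._type_idx_arr = np.array(self.cell_type_idx, dtype=np.int64)
        self._comp_arr = np.array(self.cell_composite, dtype=np.int64)
        self._dirty_links = True
        self._finalized = True

    # ------------------------------------------------------------ accessors
    @property
    def n_cells(self) -> int:
        return len(self.cell_type_idx)

    def cell_ids(self) -> list[int]:
        return list(range(1, self.n_cells))

    def type_name_of(self, cell_id: int) -> str:
        return self.types[self.cell_type_idx[cell_id]].type_name

    def volume_of(self, cell_id: int) -> int:
        return int(self._vol[cell_id])

    def surface_of(self, cell_id: int) -> int:
        return int(self._surf[cell_id])

    def center_of_mass(self, cell_id: int) -> tuple[float, float]:
        """(x, y) center of mass; x is the circular mean on the periodic axis."""
        v = self._vol[cell_id]
        if v == 0:
            raise ValueError(f"cell {cell_id} has no pixels")
        x = K._com_x(self._sumc[cell_id], self._sums[cell_id], self.width)
        return float(x), float(self._sumy[cell_id] / v)

    def active_links(self) -> list[FPPLink]:
        return [l for l in self.links if l.active]

    def link_length(self, link: FPPLink) -> float:
        return self.link_length_between(link.cell_a, link.cell_b)

    def link_length_between(self, cell_a: int, cell_b: int) -> float:
        """Center-to-center distance with minimal-image unwrapping in x."""
        ax, ay = self.center_of_mass(cell_a)
        bx, by = self.center_of_mass(cell_b)
        dx = K._wrap_dx(ax - bx, self.width)
        return float(np.hypot(dx, ay - by))

    def contact_pairs(self) -> set[tuple[int, int]]:
        """Sorted cell-id pairs sharing order-1 boundary (the neighbor ledger)."""
        lat = self.lattice
        h_a = lat.ravel()
        h_b = np.roll(lat, -1, axis=1).ravel()
        v_a = lat[:-1].ravel()
        v_b = lat[1:].ravel()
        a = np.concatenate([h_a, v_a])
        b = np.concatenate([h_b, v_b])
        mask = a != b
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        return set(zip(lo.tolist(), hi.tolist()))

    def primordium_pixel_xs(self) -> np.ndarray:
        """x-coordinates of pixels belonging to primordium cell types."""
        idx = [self.type_index[t] for t in self.primordium_types]
        mask = np.isin(self._type_idx_arr[self.lattice], idx)
        return np.nonzero(mask.any(axis=0))[0]

    # ------------------------------------------------------------- internals
    def _sync_link_arrays(self) -> None:
        if not getattr(self, "_dirty_links", True) and hasattr(self, "_link_a"):
            # active flags may change without re-adding links; refresh cheaply
            self._link_active = np.array(
                [l.active for l in self.links], dtype=np.bool_
            )
            return
        n = len(self.links)
        self._link_a = np.array([l.cell_a for l in self.links], dtype=np.int64)
        self._link_b = np.array([l.cell_b for l in self.links], dtype=np.int64)
        self._link_strength = np.array([l.strength for l in self.links])
        self._link_target = np.array([l.target_length for l in self.links])
        self._link_active = np.array([l.active for l in self.links], dtype=np.bool_)
        # CSR of link indices per cell
        counts = np.zeros(self.n_cells + 1, dtype=np.int64)
        for l in self.links:
            counts[l.cell_a + 1] += 1
            counts[l.cell_b + 1] += 1
        ptr = np.cumsum(counts)
        idx = np.zeros(ptr[-1], dtype=np.int64)
        fill = ptr[:-1].copy()
        for li, l in enumerate(self.links):
            idx[fill[l.cell_a]] = li
            fill[l.cell_a] += 1
            idx[fill[l.cell_b]] = li
            fill[l.cell_b] += 1
        self._cell_link_ptr = ptr
        self._cell_link_idx = idx
        self._dirty_links = False

    def _kernel_args(self):
        self._sync_link_arrays()
        return (
            self.lattice,
            self._type_idx_arr,
            self._comp_arr,
            self._vol,
            self._surf,
            self._lam_v,
            self._tgt_v,
            self._lam_s,
            self._tgt_s,
            self._ext,
            self._int,
            self._sumc,
            self._sums,
            self._sumy,
            self._force_x,
            self._link_a,
            self._link_b,
            self._link_strength,
            self._link_target,
            self._link_active,
            self._cell_link_ptr,
            self._cell_link_idx,
        )

    def refresh_caches(self) -> None:
        """Recompute all caches from the raw lattice (exact)."""
        (
            self._vol,
            self._surf,
            self._sumc,
            self._sums,
            self._sumy,
        ) = K.recompute_caches(self.lattice, self.n_cells)


# -------------------------------------------------------------------- ops
def neighbor_offsets(order: int) -> list[tuple[int, int]]:
    """Square-lattice neighbor shells: 4 axial, +4 diagonal, +4 distance-2
    axial for orders 1, 2, 3."""
    if order not in (1, 2, 3):
        raise ValueError("neighbor order must be 1, 2 or 3")
    n = {1: 4, 2: 8, 3: 12}[order]
    return [(int(dx), int(dy)) for dx, dy in zip(K.DX3[:n], K.DY3[:n])]


def accept_probability(delta: float, engine: EngineParams) -> float:
    """Boltzmann acceptance: 1 for delta <= h, exp(-(delta - h)/T) above."""
    if delta <= engine.threshold:
        return 1.0
    return float(np.exp(-(delta - engine.threshold) / engine.temperature))


def external_force_bias(
    delta: float, migration_force_x: float, com_displacement_x: float
) -> float:
    """Add the migration-potential work term to an energy change.

    ``migration_force_x`` is the moved cell's coefficient; a negative value
    makes +x center-of-mass displacement lower the effective energy.
    """
    return delta + migration_force_x * com_displacement_x


def hamiltonian(state: CPMState) -> float:
    """Total energy J, recomputed from the raw lattice (not the caches)."""
    vol, surf, sumc, sums, sumy = K.recompute_caches(state.lattice, state.n_cells)
    t = state._type_idx_arr
    e = float(np.sum(state._lam_v[t] * (vol - state._tgt_v[t]) ** 2))
    e += float(np.sum(state._lam_s[t] * (surf - state._tgt_s[t]) ** 2))
    e += float(
        K.contact_energy_total(state.lattice, t, state._comp_arr, state._ext, state._int)
    )
    for link in state.links:
        if not link.active:
            continue
        va, vb = vol[link.cell_a], vol[link.cell_b]
        if va == 0 or vb == 0:
            continue
        ax = K._com_x(sumc[link.cell_a], sums[link.cell_a], state.width)
        bx = K._com_x(sumc[link.cell_b], sums[link.cell_b], state.width)
        dx = K._wrap_dx(ax - bx, state.width)
        dy = sumy[link.cell_a] / va - sumy[link.cell_b] / vb
        l = np.hypot(dx, dy)
        e += link.strength * (l - link.target_length) ** 2
    return e


def delta_J(
    state: CPMState, source_pixel: tuple[int, int], target_pixel: tuple[int, int]
) -> float:
    """Energy change of copying the source pixel's owner onto the target.

    Computed incrementally from the caches; equals
    ``hamiltonian(after) - hamiltonian(before)``.  Excludes the migration
    bias (see :func:`external_force_bias`).  A same-owner attempt returns 0.
    """
    sx, sy = source_pixel
    tx, ty = target_pixel
    new = int(state.lattice[sy, sx % state.width])
    if new == int(state.lattice[ty, tx % state.width]):
        return 0.0
    d_ham, _, _, _ = K.copy_delta(
        state.lattice, tx % state.width, ty, new, *state._kernel_args()[1:]
    )
    return float(d_ham)


def monte_carlo_step(state: CPMState, rng: np.random.Generator) -> int:
    """One MCS: width*height pixel-copy attempts, then link bookkeeping.

    Returns the number of accepted copies.
    """
    n = state.width * state.height
    rand_pix = rng.integers(0, n, size=n)
    rand_dir = rng.integers(0, 4, size=n)
    rand_u = rng.random(n)
    accepted = K.run_mcs(
        *state._kernel_args(),
        state._frozen,
        state.engine.temperature,
        state.engine.threshold,
        rand_pix,
        rand_dir,
        rand_u,
    )
    state.mcs += 1
    update_fpp_links(state)
    return int(accepted)


def update_fpp_links(state: CPMState) -> None:
    """Break over-stretched external links; re-form reformable ones on contact.

    External links strictly longer than ``max_length`` are deactivated
    (internal links are exempt, mimicking intracellular cytoskeleton).  For
    every reformable link class, unlinked eligible cell pairs currently
    sharing boundary gain (or regain) a link with the class parameters.
    """
    changed = False
    for link in state.links:
        if link.active and not link.internal:
            if state.link_length(link) > link.max_length:
                link.active = False
                changed = True
    if state.link_classes:
        contact = state.contact_pairs()
        existing = {
            (min(l.cell_a, l.cell_b), max(l.cell_a, l.cell_b)): l for l in state.links
        }
        for cls in state.link_classes:
            ia = state.type_index[cls.type_a]
            ib = state.type_index[cls.type_b]
            for a, b in contact:
                if a == 0:
                    continue
                ta, tb = state.cell_type_idx[a], state.cell_type_idx[b]
                if not ((ta == ia and tb == ib) or (ta == ib and tb == ia)):
                    continue
                prior = existing.get((a, b))
                if prior is None:
                    state.add_link(
                        a, b, cls.strength, cls.target_length, cls.max_length,
                        reformable=True,
                    )
                    changed = True
                elif prior.reformable and not prior.active:
                    # re-formed adhesions take the class parameters
                    prior.strength = cls.strength
                    prior.target_length = cls.target_length
                    prior.max_length = cls.max_length
                    prior.active = True
                    changed = True
    if changed:
        state._dirty_links = True
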