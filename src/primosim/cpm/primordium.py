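"""Side-view primordium scene for the Cellular Potts engine, and the
published in-silico experiments on it.

The scene stacks, bottom to top: a muscle band (5 cell rows thick, to keep
the rigid lower boundary away from the tissue), a thin ECM layer, the
primordium itself resting on the ECM (leading Wnt cells and trailing
three-compartment FGF cells: apical over lateral over basal, apical side
facing the skin), superficial sheath cells on top of the primordium, and a
skin band.  Medium fills the rest.  Migration is along +x (periodic).

Apical constriction is realized by a small apical target volume plus short,
strong, breakable-and-reformable apical-apical spring links; rosettes emerge
as clusters of apical compartments.

All numeric type/contact/link values here are calibrated defaults: the
published model states the energy function and qualitative parameter
relations but not the numbers, so these were chosen to satisfy the adhesion
hierarchy and reproduce the reported rosette behavior (see docs/methods.md).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import (
    CPMState,
    CellTypeParams,
    EngineParams,
    LinkClass,
    update_fpp_links,
)

__all__ = [
    "SceneSpec",
    "ScenarioSpec",
    "SCENARIOS",
    "build_primordium_scene",
    "validate_adhesion_hierarchy",
    "apply_scenario",
]

PRIMORDIUM_TYPES = ("Wnt", "fgfapi", "fgflat", "fgfbas", "sheath")

#: Rendering palette (matches the published color scheme).
PALETTE = {
    "Medium": (0, 0, 0),
    "Wnt": (60, 90, 230),
    "fgfapi": (220, 40, 40),
    "fgflat": (40, 170, 60),
    "fgfbas": (250, 150, 190),
    "sheath": (240, 220, 60),
    "skin": (150, 230, 150),
    "ECM": (150, 100, 50),
    "muscle": (235, 235, 235),
}


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, composition and calibrated energy parameters of the scene.

    The default is the full-size 800 x 300 lattice; :meth:`desk` returns the
    reduced 400 x 150 configuration used for routine runs and calibration.
    """

    width: int = 800
    height: int = 300
    n_wnt: int = 10
    n_fgf: int = 20
    n_sheath: int = 6
    # cell geometry, pixels
    muscle_rows: int = 5
    muscle_cell_h: int = 20
    muscle_cell_w: int = 80
    ecm_h: int = 12
    ecm_cell_w: int = 50
    fgf_w: int = 11
    api_h: int = 12
    lat_h: int = 36
    bas_h: int = 12
    wnt_w: int = 18
    sheath_h: int = 16
    skin_h: int = 40
    skin_cell_w: int = 80
    trailing_x: int = 120  # x of the trailing edge of the FGF column
    api_target_factor: float = 0.55  # apical constriction: target below build size
    # penalties (per-type overrides win over the global values)
    lambda_volume: float = 2.0
    lambda_surface: float = 0.3
    surface_slack: float = 1.15
    # stiff substrate layers resist being plowed by the migrating tissue
    lambda_volume_by_type: dict = field(
        default_factory=lambda: {"ECM": 10.0, "muscle": 4.0}
    )
    lambda_surface_by_type: dict = field(
        default_factory=lambda: {"ECM": 1.0, "muscle": 0.6}
    )
    # migration force coefficients (negative drives +x); the energy bias per
    # copied pixel scales as force / volume, so full-scale cells (4x the
    # pixel count of the desk scale) carry 4x the desk coefficients
    force_wnt: float = -8800.0
    force_sheath: float = -1600.0
    force_fgfbas: float = -880.0
    # contact energies (lower = more adhesive)
    contacts: dict = field(
        default_factory=lambda: {
            ("Wnt", "Wnt"): 4.0,
            ("fgfapi", "fgfapi"): 4.0,
            ("fgflat", "fgflat"): 4.0,
            ("fgfbas", "fgfbas"): 4.0,
            ("sheath", "sheath"): 4.0,
            ("Wnt", "fgfapi"): 12.0,
            ("Wnt", "fgflat"): 8.0,
            ("Wnt", "fgfbas"): 10.0,
            ("Wnt", "sheath"): 6.0,
            ("fgfapi", "fgflat"): 12.0,
            ("fgfapi", "fgfbas"): 12.0,
            ("fgfapi", "sheath"): 12.0,
            ("fgflat", "fgfbas"): 12.0,
            ("fgflat", "sheath"): 12.0,
            ("fgfbas", "sheath"): 12.0,
            ("skin", "skin"): 4.0,
            ("ECM", "ECM"): 2.0,
            ("muscle", "muscle"): 2.0,
            ("skin", "sheath"): 14.0,
            ("ECM", "fgfbas"): 12.0,
            ("skin", "Wnt"): 24.0,
            ("skin", "fgfapi"): 24.0,
            ("skin", "fgflat"): 26.0,
            ("skin", "fgfbas"): 26.0,
            ("ECM", "Wnt"): 22.0,
            ("ECM", "fgfapi"): 28.0,
            ("ECM", "fgflat"): 26.0,
            ("ECM", "sheath"): 40.0,
            ("ECM", "muscle"): 12.0,
            ("ECM", "skin"): 30.0,
            ("skin", "muscle"): 30.0,
            ("muscle", "Wnt"): 30.0,
            ("muscle", "fgfapi"): 30.0,
            ("muscle", "fgflat"): 30.0,
            ("muscle", "fgfbas"): 30.0,
            ("muscle", "sheath"): 30.0,
            ("Medium", "Wnt"): 40.0,
            ("Medium", "fgfapi"): 40.0,
            ("Medium", "fgflat"): 40.0,
            ("Medium", "fgfbas"): 50.0,
            ("Medium", "sheath"): 50.0,
            ("Medium", "skin"): 25.0,
            ("Medium", "ECM"): 25.0,
            ("Medium", "muscle"): 25.0,
        }
    )
    # internal (intra-composite) compartment contact energies
    contacts_internal: dict = field(
        default_factory=lambda: {
            ("fgfapi", "fgflat"): 1.0,
            ("fgflat", "fgfbas"): 1.0,
            ("fgfapi", "fgfbas"): 40.0,
        }
    )
    # link parameters: (strength, target_length, max_length) per class;
    # None target = distance at build time; max_length as a multiple of it
    link_skin: tuple = (4.0, None, 3.0)
    link_ecm: tuple = (20.0, None, 2.0)
    link_wnt: tuple = (2.0, None, 3.0)
    link_fgflat: tuple = (3.0, None, 3.0)
    link_fgfapi: tuple = (10.0, 0.3, 1.4)  # target/max as fractions of build distance
    # reach of apical links re-formed on contact (max as fraction of build
    # distance); longer than the build-time chain links so that a re-formed
    # adhesion can reel a neighboring apical cluster in before rupturing
    link_fgfapi_reform_max: float = 1.8
    link_bridge: tuple = (8.0, None, 3.0)
    link_internal: tuple = (20.0, None, 5.0)
    engine: EngineParams = field(default_factory=EngineParams)

    @classmethod
    def desk(cls, **overrides) -> "SceneSpec":
        """Reduced 400 x 150 scene (half-scale geometry, 16 FGF cells)."""
        base = dict(
            width=400,
            height=150,
            n_wnt=6,
            n_fgf=16,
            n_sheath=4,
            muscle_cell_h=10,
            muscle_cell_w=40,
            ecm_h=6,
            ecm_cell_w=25,
            fgf_w=7,
            api_h=6,
            lat_h=18,
            bas_h=6,
            wnt_w=12,
            sheath_h=8,
            skin_h=20,
            skin_cell_w=40,
            trailing_x=60,
            force_wnt=-2200.0,
            force_sheath=-400.0,
            force_fgfbas=-220.0,
        )
        base.update(overrides)
        return cls(**base)

    def with_overrides(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


def _type_params(spec: SceneSpec) -> list[CellTypeParams]:
    def tp(name, w, h, force=0.0, vol_factor=1.0):
        return CellTypeParams(
            name,
            lambda_volume=spec.lambda_volume_by_type.get(name, spec.lambda_volume),
            target_volume=w * h * vol_factor,
            lambda_surface=spec.lambda_surface_by_type.get(name, spec.lambda_surface),
            target_surface=2 * (w + h) * spec.surface_slack,
            migration_force_x=force,
        )

    prim_len = spec.n_fgf * spec.fgf_w + spec.n_wnt * spec.wnt_w
    sheath_w = prim_len // spec.n_sheath
    fgf_h = spec.api_h + spec.lat_h + spec.bas_h
    return [
        tp("muscle", spec.muscle_cell_w, spec.muscle_cell_h),
        tp("ECM", spec.ecm_cell_w, spec.ecm_h),
        tp("skin", spec.skin_cell_w, spec.skin_h),
        tp("Wnt", spec.wnt_w, fgf_h, force=spec.force_wnt),
        tp("fgfapi", spec.fgf_w, spec.api_h, vol_factor=spec.api_target_factor),
        tp("fgflat", spec.fgf_w, spec.lat_h),
        tp("fgfbas", spec.fgf_w, spec.bas_h, force=spec.force_fgfbas),
        tp("sheath", sheath_w, spec.sheath_h, force=spec.force_sheath),
    ]


def build_primordium_scene(spec: SceneSpec) -> CPMState:
    """Tile the lattice and instantiate every cell and link of the scene."""
    prim_len = spec.n_fgf * spec.fgf_w + spec.n_wnt * spec.wnt_w
    muscle_top = spec.muscle_rows * spec.muscle_cell_h
    ecm_top = muscle_top + spec.ecm_h
    fgf_h = spec.api_h + spec.lat_h + spec.bas_h
    prim_top = ecm_top + fgf_h
    sheath_top = prim_top + spec.sheath_h
    skin_top = sheath_top + spec.skin_h
    if skin_top > spec.height:
        raise ValueError("scene layers exceed lattice height")
    if prim_len >= spec.width:
        raise ValueError("primordium composition cannot tile the lattice width")

    st = CPMState(
        spec.width,
        spec.height,
        _type_params(spec),
        spec.contacts,
        spec.contacts_internal,
        spec.engine,
    )
    st.primordium_types = set(PRIMORDIUM_TYPES)

    # --- environment layers ---
    muscle_ids = []
    for row in range(spec.muscle_rows):
        for k in range(spec.width // spec.muscle_cell_w):
            cid = st.add_cell("muscle")
            st.paint(
                cid,
                k * spec.muscle_cell_w,
                (k + 1) * spec.muscle_cell_w,
                row * spec.muscle_cell_h,
                (row + 1) * spec.muscle_cell_h,
            )
            muscle_ids.append(cid)
    ecm_ids = []
    for k in range(spec.width // spec.ecm_cell_w):
        cid = st.add_cell("ECM")
        st.paint(cid, k * spec.ecm_cell_w, (k + 1) * spec.ecm_cell_w, muscle_top, ecm_top)
        ecm_ids.append(cid)
    skin_ids = []
    for k in range(spec.width // spec.skin_cell_w):
        cid = st.add_cell("skin")
        st.paint(cid, k * spec.skin_cell_w, (k + 1) * spec.skin_cell_w, sheath_top, skin_top)
        skin_ids.append(cid)

    # --- primordium: trailing FGF column then leading Wnt cells ---
    x = spec.trailing_x
    fgf_cells = []  # (api, lat, bas) per composite cell, trailing to leading
    for k in range(spec.n_fgf):
        comp = k + 1
        bas = st.add_cell("fgfbas", composite_id=comp)
        lat = st.add_cell("fgflat", composite_id=comp)
        api = st.add_cell("fgfapi", composite_id=comp)
        st.paint(bas, x, x + spec.fgf_w, ecm_top, ecm_top + spec.bas_h)
        st.paint(lat, x, x + spec.fgf_w, ecm_top + spec.bas_h, ecm_top + spec.bas_h + spec.lat_h)
        st.paint(api, x, x + spec.fgf_w, ecm_top + spec.bas_h + spec.lat_h, prim_top)
        fgf_cells.append((api, lat, bas))
        x += spec.fgf_w
    wnt_ids = []
    for k in range(spec.n_wnt):
        cid = st.add_cell("Wnt")
        st.paint(cid, x, x + spec.wnt_w, ecm_top, prim_top)
        wnt_ids.append(cid)
        x += spec.wnt_w
    sheath_w = prim_len // spec.n_sheath
    sheath_ids = []
    sx = spec.trailing_x
    for k in range(spec.n_sheath):
        cid = st.add_cell("sheath")
        x1 = spec.trailing_x + prim_len if k == spec.n_sheath - 1 else sx + sheath_w
        st.paint(cid, sx, x1, prim_top, sheath_top)
        sheath_ids.append(cid)
        sx += sheath_w

    st.finalize()

    # --- links ---
    def chain(ids, strength, target, maxfac):
        for a, b in zip(ids, ids[1:]):
            d = st.link_length_between(a, b)
            st.add_link(a, b, strength, target if target is not None else d, maxfac * d)

    def ring(ids, strength, target, maxfac):
        # bands span the periodic x-axis, so close the chain into a ring
        chain(ids, strength, target, maxfac)
        d = st.link_length_between(ids[-1], ids[0])
        st.add_link(ids[-1], ids[0], strength, target if target is not None else d, maxfac * d)

    s, t, mf = spec.link_skin
    ring(skin_ids, s, t, mf)
    s, t, mf = spec.link_ecm
    ring(ecm_ids, s, t, mf)
    s, t, mf = spec.link_wnt
    chain(wnt_ids, s, t, mf)
    s, t, mf = spec.link_fgflat
    chain([c[1] for c in fgf_cells], s, t, mf)

    # apical-apical: short, strong, breakable and reformable on contact
    s, tfrac, mfrac = spec.link_fgfapi
    api_ids = [c[0] for c in fgf_cells]
    d0 = st.link_length_between(api_ids[0], api_ids[1])
    api_target = tfrac * d0
    api_max = mfrac * d0
    for a, b in zip(api_ids, api_ids[1:]):
        st.add_link(a, b, s, api_target, api_max, reformable=True)
    st.add_link_class(
        LinkClass("fgfapi", "fgfapi", s, api_target, spec.link_fgfapi_reform_max * d0)
    )

    # bridge: last Wnt cell to first fgflat from the leading end
    s, t, mf = spec.link_bridge
    lead_lat = fgf_cells[-1][1]
    d = st.link_length_between(wnt_ids[0], lead_lat)
    st.add_link(wnt_ids[0], lead_lat, s, t if t is not None else d, mf * d)

    # intracellular compartment links (never break)
    s, t, mf = spec.link_internal
    for api, lat, bas in fgf_cells:
        for a, b in ((api, lat), (lat, bas)):
            d = st.link_length_between(a, b)
            st.add_link(a, b, s, t if t is not None else d, mf * d, internal=True)

    update_fpp_links(st)
    return st


def validate_adhesion_hierarchy(spec: SceneSpec) -> dict:
    """Check the assumed adhesion ordering of the contact table.

    In contact-energy terms (lower energy = stronger adhesion): (i) each
    primordium type adheres most to its own type; (ii) primordium-internal
    pairs adhere more than primordium-skin/ECM pairs; (iii) the sheath-skin
    and fgfbas-ECM attachments are stronger than other primordium-substrate
    contacts but weaker than primordium-internal cohesion.  Returns an
    itemized pass/fail report.
    """
    c = {}
    for (a, b), e in spec.contacts.items():
        c[(a, b)] = c[(b, a)] = e
    prim = PRIMORDIUM_TYPES
    report = {}
    same_ok = True
    for t in prim:
        own = c[(t, t)]
        for u in prim + ("skin", "ECM", "Medium"):
            if u != t and (t, u) in c and c[(t, u)] < own:
                same_ok = False
    report["same_type_strongest"] = same_ok
    internal_max = max(c[(a, b)] for a in prim for b in prim)
    substrate_min = min(
        min(c[(t, "skin")] for t in prim), min(c[(t, "ECM")] for t in prim)
    )
    report["internal_cohesion_over_substrate"] = internal_max <= substrate_min
    anchors = (c[("sheath", "skin")], c[("fgfbas", "ECM")])
    other_substrate = min(
        min(c[(t, "skin")] for t in prim if t != "sheath"),
        min(c[(t, "ECM")] for t in prim if t != "fgfbas"),
    )
    report["anchors_attached_but_detachable"] = (
        max(anchors) < other_substrate and min(anchors) >= internal_max
    )
    report["all_pass"] = all(v for k, v in report.items() if k != "all_pass")
    return report


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario: a time-ordered schedule of parameter overrides."""

    name: str
    schedule: tuple = ()  # tuple of (mcs_time, action, payload)

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.schedule]
        if times != sorted(times):
            raise ValueError("schedule events must be time-ordered")


#: Cell types whose migration force the stalling scenarios switch off.  The
#: default stalls the whole motile machinery (leading Wnt cells plus the
#: sheath and basal-foot forces they guide); the `_wnt_only` preset stalls
#: just the leading cells, for sensitivity analysis.
STALL_TYPES = ("Wnt", "sheath", "fgfbas")


def _default_scenarios(stall_time: int = 1200, recover_time: int = 2400,
                       boost_time: int = 300) -> dict[str, ScenarioSpec]:
    def stall_events(t, types):
        return tuple((t, "set_force", (name, 0.0)) for name in types)

    def recover_events(t, types):
        return tuple((t, "restore_force", (name,)) for name in types)

    return {
        "wildtype": ScenarioSpec("wildtype"),
        "stall_leading": ScenarioSpec(
            "stall_leading", stall_events(stall_time, STALL_TYPES)
        ),
        "stall_leading_wnt_only": ScenarioSpec(
            "stall_leading_wnt_only", stall_events(stall_time, ("Wnt",))
        ),
        "stall_then_recover": ScenarioSpec(
            "stall_then_recover",
            stall_events(stall_time, STALL_TYPES)
            + recover_events(recover_time, STALL_TYPES),
        ),
        "boost_lat_contractility": ScenarioSpec(
            "boost_lat_contractility",
            ((boost_time, "boost_lat", (8.0, 0.2, 0.25)),)
        ),
    }


SCENARIOS = _default_scenarios()


def apply_scenario(state: CPMState, scenario: ScenarioSpec, t: int) -> None:
    """Apply any scenario events scheduled at MCS time t (in place)."""
    for when, action, payload in scenario.schedule:
        if when != t:
            continue
        if action == "set_force":
            tname, value = payload
            ti = state.type_index[tname]
            if not hasattr(state, "_saved_force"):
                state._saved_force = {}
            state._saved_force.setdefault(tname, float(state._force_x[ti]))
            state._force_x[ti] = value
        elif action == "restore_force":
            (tname,) = payload
            ti = state.type_index[tname]
            state._force_x[ti] = state._saved_force[tname]
        elif action == "boost_lat":
            # contractility: stiffen lateral-lateral links AND shorten their
            # rest length (a stronger spring at unchanged length exerts no
            # extra pull), while making lateral contacts more adhesive
            strength_factor, contact_factor, target_factor = payload
            ti = state.type_index["fgflat"]
            state._ext[ti, ti] *= contact_factor
            for link in state.links:
                a = state.cell_type_idx[link.cell_a]
                b = state.cell_type_idx[link.cell_b]
                if a == ti and b == ti and not link.internal:
                    link.strength *= strength_factor
                    link.target_length *= target_factor
            state._dirty_links = True
        else:
            raise ValueError(f"unknown scenario action: {action}")
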