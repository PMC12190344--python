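"""Unit and oracle tests of the Cellular Potts engine.

The central check compares the engine's incremental energy change for a
pixel copy against an independent brute-force Hamiltonian written here from
scratch (plain Python loops over all pixel pairs and cells).
"""
import math

import numpy as np
import pytest

from primosim.cpm.engine import (
    CPMState,
    CellTypeParams,
    EngineParams,
    accept_probability,
    delta_J,
    external_force_bias,
    hamiltonian,
    monte_carlo_step,
    neighbor_offsets,
    update_fpp_links,
)

W, H = 20, 14


def two_type_state(seed=0, n_cells=3, links=(), engine=None, force_x=()):
    rng = np.random.default_rng(seed)
    fx = dict(force_x)
    types = [
        CellTypeParams("A", 2.0, 20, 0.5, 18, migration_force_x=fx.get("A", 0.0)),
        CellTypeParams("B", 1.0, 30, 0.2, 22, migration_force_x=fx.get("B", 0.0)),
    ]
    ext = {
        ("A", "A"): 4.0,
        ("A", "B"): 6.0,
        ("B", "B"): 3.0,
        ("A", "Medium"): 8.0,
        ("B", "Medium"): 9.0,
        ("Medium", "Medium"): 0.0,
    }
    st = CPMState(W, H, types, ext, engine=engine)
    ids = [st.add_cell("A" if i % 2 == 0 else "B") for i in range(n_cells)]
    st.lattice[:] = rng.integers(0, n_cells + 1, size=(H, W))
    st.finalize()
    for a, b, s, t, m in links:
        st.add_link(ids[a], ids[b], s, t, m)
    return st, ids


# ---------------------------------------------------------------- oracle
def brute_force_hamiltonian(st):
    """Independent full-energy computation: nested loops, no engine code."""
    lat = st.lattice
    height, width = lat.shape
    # volumes and boundary-pair surfaces
    vol = {c: 0 for c in range(st.n_cells)}
    surf = {c: 0 for c in range(st.n_cells)}
    for y in range(height):
        for x in range(width):
            vol[lat[y, x]] += 1
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                qy = y + dy
                if qy < 0 or qy >= height:
                    continue
                if lat[qy, (x + dx) % width] != lat[y, x]:
                    surf[lat[y, x]] += 1
    e = 0.0
    for c in range(st.n_cells):
        t = st.types[st.cell_type_idx[c]]
        e += t.lambda_volume * (vol[c] - t.target_volume) ** 2
        e += t.lambda_surface * (surf[c] - t.target_surface) ** 2
    # contact over order-3 shell, each unordered pair once
    shell = neighbor_offsets(3)
    for y in range(height):
        for x in range(width):
            c1 = lat[y, x]
            for dx, dy in shell:
                if dy < 0 or (dy == 0 and dx <= 0):
                    continue
                qy = y + dy
                if qy < 0 or qy >= height:
                    continue
                c2 = lat[qy, (x + dx) % width]
                if c1 == c2:
                    continue
                t1, t2 = st.cell_type_idx[c1], st.cell_type_idx[c2]
                comp1, comp2 = st.cell_composite[c1], st.cell_composite[c2]
                table = st._int if (comp1 >= 0 and comp1 == comp2) else st._ext
                e += table[t1, t2]
    # spring links on circular-mean centers
    def com(c):
        xs = [x for y in range(height) for x in range(width) if lat[y, x] == c]
        ys = [y for y in range(height) for x in range(width) if lat[y, x] == c]
        ang = [2 * math.pi * x / width for x in xs]
        cx = math.atan2(
            sum(math.sin(a) for a in ang), sum(math.cos(a) for a in ang)
        ) * width / (2 * math.pi) % width
        return cx, sum(ys) / len(ys)

    for link in st.links:
        if not link.active or vol[link.cell_a] == 0 or vol[link.cell_b] == 0:
            continue
        ax, ay = com(link.cell_a)
        bx, by = com(link.cell_b)
        dx = ax - bx
        dx -= width * math.floor(dx / width + 0.5)
        l = math.hypot(dx, ay - by)
        e += link.strength * (l - link.target_length) ** 2
    return e


class TestHamiltonian:
    def test_single_cell_at_targets_zero_energy(self):
        types = [CellTypeParams("A", 2.0, 12, 0.5, 16)]
        ext = {("A", "A"): 0.0, ("A", "Medium"): 0.0, ("Medium", "Medium"): 0.0}
        st = CPMState(W, H, types, ext)
        cid = st.add_cell("A")
        st.paint(cid, 5, 9, 5, 8)  # 4x3 = 12 pixels, boundary pairs 2*(4+3)=14? no: 14
        st.finalize()
        assert st.volume_of(cid) == 12
        # surface of a 4x3 rectangle interior to the lattice: 2*(4+3) = 14
        types = [CellTypeParams("A", 2.0, 12, 0.5, st.surface_of(cid))]
        st2 = CPMState(W, H, types, ext)
        cid = st2.add_cell("A")
        st2.paint(cid, 5, 9, 5, 8)
        st2.finalize()
        assert hamiltonian(st2) == pytest.approx(0.0, abs=1e-12)

    def test_volume_deviation_term(self):
        """v = V + 2 with lambda = 2 and every other term off gives 8."""
        types = [CellTypeParams("A", 2.0, 10, 0.0, 0)]
        ext = {("A", "A"): 0.0, ("A", "Medium"): 0.0, ("Medium", "Medium"): 0.0}
        st = CPMState(W, H, types, ext)
        cid = st.add_cell("A")
        st.paint(cid, 0, 12, 5, 6)  # 12 pixels = V + 2
        st.finalize()
        assert hamiltonian(st) == pytest.approx(8.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_scenes(self, seed):
        st, ids = two_type_state(seed, links=[(0, 1, 0.5, 3.0, 50.0), (1, 2, 0.2, 5.0, 50.0)])
        assert hamiltonian(st) == pytest.approx(brute_force_hamiltonian(st), rel=1e-12)

    def test_periodic_x_translation_invariance(self):
        st, _ = two_type_state(3, links=[(0, 1, 0.5, 3.0, 50.0)])
        e0 = hamiltonian(st)
        for k in (1, 7, 13):
            st.lattice = np.roll(st.lattice, k, axis=1)
            st.refresh_caches()
            assert hamiltonian(st) == pytest.approx(e0, rel=1e-9)
            st.lattice = np.roll(st.lattice, -k, axis=1)
            st.refresh_caches()


class TestDeltaJ:
    def test_same_owner_copy_is_zero(self):
        st, _ = two_type_state(0)
        # find two axial neighbors with equal owner
        lat = st.lattice
        for y in range(H):
            for x in range(W):
                if lat[y, x] == lat[y, (x + 1) % W]:
                    assert delta_J(st, (x, y), ((x + 1) % W, y)) == 0.0
                    return
        pytest.skip("no same-owner neighbor pair in fixture")

    def test_isolated_growth_volume_only(self):
        types = [CellTypeParams("A", 2.0, 10, 0.0, 0)]
        ext = {("A", "A"): 0.0, ("A", "Medium"): 0.0, ("Medium", "Medium"): 0.0}
        st = CPMState(W, H, types, ext)
        cid = st.add_cell("A")
        st.paint(cid, 4, 4 + 8, 6, 7)  # v = 8, V = 10
        st.finalize()
        d = delta_J(st, (4, 6), (3, 6))  # grow by one pixel
        v = 8
        assert d == pytest.approx(2.0 * ((v + 1 - 10) ** 2 - (v - 10) ** 2), abs=1e-9)

    def test_equals_full_hamiltonian_difference_everywhere(self):
        """The central oracle: incremental dJ == H(after) - H(before) on 100
        randomized attempts over randomized small scenes."""
        rng = np.random.default_rng(99)
        checked = 0
        for seed in range(10):
            st, _ = two_type_state(
                seed, links=[(0, 1, 0.5, 3.0, 50.0), (1, 2, 0.2, 5.0, 50.0)]
            )
            while True:
                x, y = int(rng.integers(W)), int(rng.integers(H))
                dx, dy = neighbor_offsets(1)[rng.integers(4)]
                tx, ty = (x + dx) % W, y + dy
                if not (0 <= ty < H):
                    continue
                if st.lattice[y, x] == st.lattice[ty, tx]:
                    continue
                d = delta_J(st, (x, y), (tx, ty))
                before = brute_force_hamiltonian(st)
                old = st.lattice[ty, tx]
                st.lattice[ty, tx] = st.lattice[y, x]
                after = brute_force_hamiltonian(st)
                st.lattice[ty, tx] = old
                assert d == pytest.approx(after - before, abs=1e-9)
                checked += 1
                if checked % 10 == 0:
                    break
        assert checked >= 100


class TestAcceptProbability:
    def test_threshold_branch(self):
        eng = EngineParams(temperature=20.0, threshold=0.0)
        assert accept_probability(0.0, eng) == 1.0
        assert accept_probability(-5.0, eng) == 1.0
        eng_h = EngineParams(temperature=20.0, threshold=2.5)
        assert accept_probability(2.5, eng_h) == 1.0

    def test_one_temperature_above_threshold_is_inverse_e(self):
        eng = EngineParams(temperature=20.0, threshold=0.0)
        assert accept_probability(20.0, eng) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_monotone_decreasing_in_delta_increasing_in_T(self):
        eng = EngineParams(temperature=20.0)
        deltas = np.linspace(-5, 100, 50)
        probs = [accept_probability(d, eng) for d in deltas]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        hot = EngineParams(temperature=40.0)
        assert accept_probability(30.0, hot) > accept_probability(30.0, eng)
        # continuity at the threshold
        assert accept_probability(1e-12, eng) == pytest.approx(1.0, abs=1e-9)


class TestNeighborOffsets:
    @pytest.mark.parametrize("order,count", [(1, 4), (2, 8), (3, 12)])
    def test_shell_sizes(self, order, count):
        offs = neighbor_offsets(order)
        assert len(offs) == len(set(offs)) == count
        # shells are sorted by squared distance
        d2 = [dx * dx + dy * dy for dx, dy in offs]
        assert d2 == sorted(d2)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            neighbor_offsets(4)


class TestMonteCarloStep:
    def test_pixel_conservation_and_cache_coherence(self, rng):
        from primosim.cpm._kernels import recompute_caches

        st, _ = two_type_state(1, links=[(0, 1, 0.5, 3.0, 50.0)])
        for _ in range(10):
            monte_carlo_step(st, rng)
            assert st._vol.sum() == W * H
        vol, surf, sumc, sums, sumy = recompute_caches(st.lattice, st.n_cells)
        assert np.array_equal(vol, st._vol)
        assert np.array_equal(surf, st._surf)
        assert np.allclose(sumc, st._sumc, atol=1e-9)
        assert np.allclose(sums, st._sums, atol=1e-9)
        assert np.allclose(sumy, st._sumy, atol=1e-9)

    def test_frozen_types_never_modified(self, rng):
        types = [
            CellTypeParams("A", 2.0, 20, 0.0, 0),
            CellTypeParams("ice", frozen=True),
        ]
        ext = {
            ("A", "A"): 4.0,
            ("A", "ice"): 6.0,
            ("ice", "ice"): 0.0,
            ("A", "Medium"): 8.0,
            ("ice", "Medium"): 5.0,
            ("Medium", "Medium"): 0.0,
        }
        st = CPMState(W, H, types, ext)
        a = st.add_cell("A")
        ice = st.add_cell("ice")
        st.paint(a, 2, 7, 2, 6)
        st.paint(ice, 10, 15, 2, 6)
        st.finalize()
        frozen_mask = st.lattice == ice
        for _ in range(20):
            monte_carlo_step(st, rng)
        assert np.array_equal(st.lattice == ice, frozen_mask)

    def test_all_frozen_lattice_unchanged(self, rng):
        types = [CellTypeParams("ice", frozen=True)]
        ext = {("ice", "ice"): 0.0, ("ice", "Medium"): 5.0, ("Medium", "Medium"): 0.0}
        st = CPMState(W, H, types, ext)
        # freeze the Medium as well by tiling everything with ice cells
        c1 = st.add_cell("ice")
        c2 = st.add_cell("ice")
        st.paint(c1, 0, W, 0, 7)
        st.paint(c2, 0, W, 7, H)
        st.finalize()
        before = st.lattice.copy()
        for _ in range(5):
            monte_carlo_step(st, rng)
        assert np.array_equal(st.lattice, before)

    def test_zero_temperature_limit_only_downhill(self):
        """At T -> 0+ with h = 0 the energy never increases."""
        eng = EngineParams(temperature=1e-9, threshold=0.0)
        st, _ = two_type_state(2, engine=eng)
        rng = np.random.default_rng(5)
        e = hamiltonian(st)
        for _ in range(5):
            monte_carlo_step(st, rng)
            e2 = hamiltonian(st)
            assert e2 <= e + 1e-6
            e = e2

    def test_free_cell_relaxes_to_target_volume(self):
        """A single unconstrained-adhesion cell equilibrates near v = V."""
        types = [CellTypeParams("A", 2.0, 40, 0.0, 0)]
        ext = {("A", "A"): 0.0, ("A", "Medium"): 0.0, ("Medium", "Medium"): 0.0}
        st = CPMState(W, H, types, ext)
        cid = st.add_cell("A")
        st.paint(cid, 8, 12, 5, 9)  # 16 pixels, target 40
        st.finalize()
        rng = np.random.default_rng(11)
        vols = []
        for t in range(700):
            monte_carlo_step(st, rng)
            if t >= 200:
                vols.append(st.volume_of(cid))
        assert np.mean(vols) == pytest.approx(40, rel=0.10)


class TestExternalForce:
    def test_zero_coefficient_leaves_delta(self):
        assert external_force_bias(3.0, 0.0, 1.5) == 3.0

    def test_negative_coefficient_favors_forward_motion(self):
        assert external_force_bias(0.0, -10.0, +0.5) < 0
        # linearity and sign symmetry
        assert external_force_bias(0.0, -10.0, +0.5) == -external_force_bias(
            0.0, -10.0, -0.5
        )

    def test_driven_cell_migrates_forward(self, rng):
        types = [CellTypeParams("A", 2.0, 16, 0.3, 18, migration_force_x=-500.0)]
        ext = {("A", "A"): 0.0, ("A", "Medium"): 4.0, ("Medium", "Medium"): 0.0}
        st = CPMState(60, 20, types, ext, engine=EngineParams(temperature=10.0))
        cid = st.add_cell("A")
        st.paint(cid, 5, 9, 8, 12)
        st.finalize()
        x = st.center_of_mass(cid)[0]
        total = 0.0
        for _ in range(60):
            monte_carlo_step(st, rng)
            x2 = st.center_of_mass(cid)[0]
            total += (x2 - x + 30) % 60 - 30  # per-step minimal-image unwrap
            x = x2
        assert total > 3.0


class TestLinkBookkeeping:
    def make_linked_pair(self, gap, strength=1.0, target=3.0, max_length=6.0, **kw):
        types = [CellTypeParams("A", 2.0, 8, 0.0, 0)]
        ext = {("A", "A"): 4.0, ("A", "Medium"): 8.0, ("Medium", "Medium"): 0.0}
        st = CPMState(40, 12, types, ext)
        c1 = st.add_cell("A")
        c2 = st.add_cell("A")
        st.paint(c1, 4, 8, 4, 6)
        st.paint(c2, 8 + gap, 12 + gap, 4, 6)
        st.finalize()
        link = st.add_link(c1, c2, strength, target, max_length, **kw)
        return st, link

    def test_link_at_exactly_max_length_retained(self):
        st, link = self.make_linked_pair(gap=0)
        st.links[0] = type(link)(
            link.cell_a, link.cell_b, 1.0, 3.0, st.link_length(link)
        )
        update_fpp_links(st)
        assert st.links[0].active

    def test_overstretched_external_link_breaks(self):
        st, link = self.make_linked_pair(gap=10, max_length=6.0)
        assert st.link_length(link) > 6.0
        update_fpp_links(st)
        assert not link.active

    def test_internal_link_never_breaks(self):
        st, link = self.make_linked_pair(gap=10, max_length=6.0, internal=True)
        update_fpp_links(st)
        assert link.active

    def test_reformable_class_links_on_contact(self):
        from primosim.cpm.engine import LinkClass

        st, _ = self.make_linked_pair(gap=0)
        st.links.clear()
        st._dirty_links = True
        st.add_link_class(LinkClass("A", "A", 2.0, 3.0, 6.0))
        update_fpp_links(st)  # the two cells share boundary
        assert len(st.active_links()) == 1
        assert st.active_links()[0].reformable
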