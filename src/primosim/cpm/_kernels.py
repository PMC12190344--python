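"""Numba kernels for the Cellular Potts engine.

All kernels operate on flat per-cell arrays indexed by cell id (id 0 is the
Medium).  The lattice is indexed ``lat[y, x]`` with periodic wrapping in x
and a closed boundary in y.

Centers of mass along the periodic x-axis use the circular mean: each pixel
contributes ``cos(2*pi*x/W)`` and ``sin(2*pi*x/W)`` to per-cell sums, and
``com_x = atan2(S, C) * W / (2*pi) mod W``.  This is the canonical x-center
definition throughout the package (full Hamiltonian and incremental delta
agree by construction).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi

# order-1 copy neighborhood (axial)
DX1 = np.array([1, -1, 0, 0], dtype=np.int64)
DY1 = np.array([0, 0, 1, -1], dtype=np.int64)
# order-3 contact shell: 4 axial + 4 diagonal + 4 distance-2 axial
DX3 = np.array([1, -1, 0, 0, 1, 1, -1, -1, 2, -2, 0, 0], dtype=np.int64)
DY3 = np.array([0, 0, 1, -1, 1, -1, 1, -1, 0, 0, 2, -2], dtype=np.int64)


@njit(cache=True, inline="always")
def _wrap_dx(d, width):
    """Minimal-image signed x-separation on a ring of circumference width."""
    return d - width * math.floor(d / width + 0.5)


@njit(cache=True, inline="always")
def _com_x(c, s, width):
    ang = math.atan2(s, c)
    x = ang * width / TWO_PI
    if x < 0.0:
        x += width
    return x


@njit(cache=True, inline="always")
def _pair_energy(c1, c2, type_idx, comp, ext, internal):
    if c1 == c2:
        return 0.0
    t1 = type_idx[c1]
    t2 = type_idx[c2]
    if comp[c1] >= 0 and comp[c1] == comp[c2]:
        return internal[t1, t2]
    return ext[t1, t2]


@njit(cache=True)
def copy_delta(
    lat,
    x,
    y,
    new,
    type_idx,
    comp,
    vol,
    surf,
    lam_v,
    tgt_v,
    lam_s,
    tgt_s,
    ext,
    internal,
    sumc,
    sums,
    sumy,
    force_x,
    link_a,
    link_b,
    link_strength,
    link_target,
    link_active,
    cell_link_ptr,
    cell_link_idx,
):
    """Energy change of copying owner ``new`` onto pixel (x, y).

    Returns ``(d_ham, d_force, dsurf_new, dsurf_old)`` where ``d_ham`` is the
    Hamiltonian difference (volume + surface + contact + spring-link terms)
    and ``d_force`` the external migration-potential work term.  The caller
    adds them for the acceptance decision; ``delta_J`` proper is ``d_ham``.
    """
    height, width = lat.shape
    old = lat[y, x]
    if old == new:
        return 0.0, 0.0, 0, 0

    d_ham = 0.0
    # --- volume terms (Medium id 0 carries lam_v = 0 by construction) ---
    tn = type_idx[new]
    to = type_idx[old]
    vn = vol[new]
    vo = vol[old]
    d_ham += lam_v[tn] * ((vn + 1 - tgt_v[tn]) ** 2 - (vn - tgt_v[tn]) ** 2)
    d_ham += lam_v[to] * ((vo - 1 - tgt_v[to]) ** 2 - (vo - tgt_v[to]) ** 2)

    # --- surface terms: scan the order-1 neighbors of the flipped pixel ---
    n_new = 0  # in-bounds neighbors owned by `new`
    n_old = 0
    n_tot = 0
    for k in range(4):
        qx = (x + DX1[k]) % width
        qy = y + DY1[k]
        if qy < 0 or qy >= height:
            continue
        n_tot += 1
        w = lat[qy, qx]
        if w == new:
            n_new += 1
        elif w == old:
            n_old += 1
    dsurf_new = (n_tot - n_new) - n_new
    dsurf_old = n_old - (n_tot - n_old)
    sn = surf[new]
    so = surf[old]
    d_ham += lam_s[tn] * ((sn + dsurf_new - tgt_s[tn]) ** 2 - (sn - tgt_s[tn]) ** 2)
    d_ham += lam_s[to] * ((so + dsurf_old - tgt_s[to]) ** 2 - (so - tgt_s[to]) ** 2)

    # --- contact term over the order-3 shell ---
    for k in range(12):
        qx = (x + DX3[k]) % width
        qy = y + DY3[k]
        if qy < 0 or qy >= height:
            continue
        w = lat[qy, qx]
        d_ham += _pair_energy(new, w, type_idx, comp, ext, internal) - _pair_energy(
            old, w, type_idx, comp, ext, internal
        )

    # --- center-of-mass moves: spring links and migration potential ---
    cx = math.cos(TWO_PI * x / width)
    sx = math.sin(TWO_PI * x / width)
    d_force = 0.0

    # new owner gains the pixel
    ncx_new = sumc[new] + cx
    nsx_new = sums[new] + sx
    nsy_new = sumy[new] + y
    # old owner loses it
    ncx_old = sumc[old] - cx
    nsx_old = sums[old] - sx
    nsy_old = sumy[old] - y

    new_has_com = new != 0
    old_has_com = old != 0 and vo > 1  # vanished cell keeps no center

    comx_new_b = comx_new_a = comy_new_b = comy_new_a = 0.0
    comx_old_b = comx_old_a = comy_old_b = comy_old_a = 0.0
    if new_has_com:
        if vn > 0:
            comx_new_b = _com_x(sumc[new], sums[new], width)
            comy_new_b = sumy[new] / vn
        comx_new_a = _com_x(ncx_new, nsx_new, width)
        comy_new_a = nsy_new / (vn + 1)
        if vn > 0:
            d_force += force_x[tn] * _wrap_dx(comx_new_a - comx_new_b, width)
    if old_has_com:
        comx_old_b = _com_x(sumc[old], sums[old], width)
        comy_old_b = sumy[old] / vo
        comx_old_a = _com_x(ncx_old, nsx_old, width)
        comy_old_a = nsy_old / (vo - 1)
        d_force += force_x[to] * _wrap_dx(comx_old_a - comx_old_b, width)

    # spring links touching either moved cell (links between the two handled once)
    for which in range(2):
        c = new if which == 0 else old
        if c == 0:
            continue
        if which == 1 and old == new:
            break
        for p in range(cell_link_ptr[c], cell_link_ptr[c + 1]):
            li = cell_link_idx[p]
            if not link_active[li]:
                continue
            a = link_a[li]
            b = link_b[li]
            if which == 1 and (a == new or b == new):
                continue  # already counted from the `new` side
            # endpoint coordinates before/after
            axb, ayb, axa, aya = _endpoint_com(
                a, new, old, vn, vo, new_has_com, old_has_com,
                comx_new_b, comy_new_b, comx_new_a, comy_new_a,
                comx_old_b, comy_old_b, comx_old_a, comy_old_a,
                sumc, sums, sumy, vol, width,
            )
            bxb, byb, bxa, bya = _endpoint_com(
                b, new, old, vn, vo, new_has_com, old_has_com,
                comx_new_b, comy_new_b, comx_new_a, comy_new_a,
                comx_old_b, comy_old_b, comx_old_a, comy_old_a,
                sumc, sums, sumy, vol, width,
            )
            dxb = _wrap_dx(axb - bxb, width)
            dxa = _wrap_dx(axa - bxa, width)
            l_before = math.sqrt(dxb * dxb + (ayb - byb) ** 2)
            l_after = math.sqrt(dxa * dxa + (aya - bya) ** 2)
            tgt = link_target[li]
            d_ham += link_strength[li] * (
                (l_after - tgt) ** 2 - (l_before - tgt) ** 2
            )
    return d_ham, d_force, dsurf_new, dsurf_old


@njit(cache=True, inline="always")
def _endpoint_com(
    c, new, old, vn, vo, new_has_com, old_has_com,
    comx_new_b, comy_new_b, comx_new_a, comy_new_a,
    comx_old_b, comy_old_b, comx_old_a, comy_old_a,
    sumc, sums, sumy, vol, width,
):
    """(x_before, y_before, x_after, y_after) of link endpoint cell c."""
    if c == new:
        if vn > 0:
            return comx_new_b, comy_new_b, comx_new_a, comy_new_a
        # cell appearing from nothing: length change counted from after-state only
        return comx_new_a, comy_new_a, comx_new_a, comy_new_a
    if c == old:
        if old_has_com:
            return comx_old_b, comy_old_b, comx_old_a, comy_old_a
        x = _com_x(sumc[c], sums[c], width)
        y = sumy[c] / vol[c]
        return x, y, x, y  # vanishing cell: freeze its link contribution
    if vol[c] == 0:
        return 0.0, 0.0, 0.0, 0.0  # empty partner: no length change
    x = _com_x(sumc[c], sums[c], width)
    y = sumy[c] / vol[c]
    return x, y, x, y


@njit(cache=True)
def apply_copy(
    lat, x, y, new, vol, surf, sumc, sums, sumy, dsurf_new, dsurf_old
):
    old = lat[y, x]
    height, width = lat.shape
    lat[y, x] = new
    vol[new] += 1
    vol[old] -= 1
    surf[new] += dsurf_new
    surf[old] += dsurf_old
    cx = math.cos(TWO_PI * x / width)
    sx = math.sin(TWO_PI * x / width)
    sumc[new] += cx
    sums[new] += sx
    sumy[new] += y
    sumc[old] -= cx
    sums[old] -= sx
    sumy[old] -= y


@njit(cache=True)
def run_mcs(
    lat,
    type_idx,
    comp,
    vol,
    surf,
    lam_v,
    tgt_v,
    lam_s,
    tgt_s,
    ext,
    internal,
    sumc,
    sums,
    sumy,
    force_x,
    link_a,
    link_b,
    link_strength,
    link_target,
    link_active,
    cell_link_ptr,
    cell_link_idx,
    frozen,
    temperature,
    threshold,
    rand_pix,
    rand_dir,
    rand_u,
):
    """One Monte Carlo step: len(rand_pix) pixel-copy attempts.

    Each attempt picks a random source pixel and one of its 4 axial
    neighbors as the copy target; the source owner is copied onto the target
    with probability 1 if the (biased) energy change is at or below the
    threshold, else exp(-(delta - h)/T).  Returns the number of accepted
    copies.
    """
    height, width = lat.shape
    accepted = 0
    for k in range(len(rand_pix)):
        idx = rand_pix[k]
        sx_ = idx % width
        sy_ = idx // width
        tx = (sx_ + DX1[rand_dir[k]]) % width
        ty = sy_ + DY1[rand_dir[k]]
        if ty < 0 or ty >= height:
            continue
        new = lat[sy_, sx_]
        old = lat[ty, tx]
        if new == old:
            continue
        if frozen[type_idx[new]] or frozen[type_idx[old]]:
            continue
        if old != 0 and vol[old] <= 1:
            continue  # cells never vanish: reject copies emptying a cell
        d_ham, d_force, dsn, dso = copy_delta(
            lat, tx, ty, new, type_idx, comp, vol, surf,
            lam_v, tgt_v, lam_s, tgt_s, ext, internal,
            sumc, sums, sumy, force_x,
            link_a, link_b, link_strength, link_target, link_active,
            cell_link_ptr, cell_link_idx,
        )
        delta = d_ham + d_force
        if delta <= threshold:
            ok = True
        else:
            ok = rand_u[k] < math.exp(-(delta - threshold) / temperature)
        if ok:
            apply_copy(lat, tx, ty, new, vol, surf, sumc, sums, sumy, dsn, dso)
            accepted += 1
    return accepted


@njit(cache=True)
def recompute_caches(lat, n_cells):
    """Exact volumes, surfaces and center-of-mass sums from the raw lattice."""
    height, width = lat.shape
    vol = np.zeros(n_cells, dtype=np.int64)
    surf = np.zeros(n_cells, dtype=np.int64)
    sumc = np.zeros(n_cells)
    sums = np.zeros(n_cells)
    sumy = np.zeros(n_cells)
    for y in range(height):
        for x in range(width):
            c = lat[y, x]
            vol[c] += 1
            sumc[c] += math.cos(TWO_PI * x / width)
            sums[c] += math.sin(TWO_PI * x / width)
            sumy[c] += y
            for k in range(4):
                qx = (x + DX1[k]) % width
                qy = y + DY1[k]
                if qy < 0 or qy >= height:
                    continue
                if lat[qy, qx] != c:
                    surf[c] += 1
    return vol, surf, sumc, sums, sumy


@njit(cache=True)
def contact_energy_total(lat, type_idx, comp, ext, internal):
    """Contact term of the Hamiltonian: unlike-owner pairs up to order 3,
    each unordered pair counted once (positive half-shell)."""
    height, width = lat.shape
    total = 0.0
    for y in range(height):
        for x in range(width):
            c = lat[y, x]
            for k in range(12):
                dx = DX3[k]
                dy = DY3[k]
                # positive half-shell: count each unordered pair once
                if dy < 0 or (dy == 0 and dx <= 0):
                    continue
                qx = (x + dx) % width
                qy = y + dy
                if qy < 0 or qy >= height:
                    continue
                total += _pair_energy(c, lat[qy, qx], type_idx, comp, ext, internal)
    return total
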