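"""Numba kernel for Eden growth on a square lattice.

The kernel is geometry-agnostic: the caller supplies a flat neighbour
table (``-1`` marks directions that leave the lattice), so the same event
loop serves bounded (1+1)- and (2+1)-dimensional strips with periodic
transverse boundaries as well as the unbounded radial colony.

Bookkeeping per event is incremental: a *growth-candidate* set (empty
sites adjacent to at least one occupied site) and the *boundary* set
(occupied sites adjacent to at least one empty site) are maintained as
swap-remove lists with position indices, giving O(neighbourhood) updates
and O(1) uniform sampling.  The three integer counters live in a small
array (``cnt``) so the helper closures can mutate them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
HIT_EDGE = 1       # growth or diffusion reached a guard site: enlarge lattice
CAPACITY_FULL = 2  # cell arrays exhausted before the stop condition

_NCAND, _NBND, _YOUNG = 0, 1, 2


@njit(inline="always")
def _set_add(lst, pos, n, s):  # pragma: no cover - numba
    lst[n] = s
    pos[s] = n
    return n + 1


@njit(inline="always")
def _occ_after(s, dest, occ):  # pragma: no cover - numba
    """Occupancy of site ``s`` once the mover sits at ``dest``."""
    if s < 0:
        return False
    if s == dest:
        return True
    return occ[s] >= 0


@njit(inline="always")
def _set_remove(lst, pos, n, s):  # pragma: no cover - numba
    i = pos[s]
    last = lst[n - 1]
    lst[i] = last
    pos[last] = i
    pos[s] = -1
    return n - 1


# growth-site selection rules
SITE_UNIFORM = 0  # uniform over empty perimeter sites (Eden C)
BOND_UNIFORM = 1  # uniform over (occupied, empty) neighbour pairs (Eden A)
CELL_UNIFORM = 2  # uniform over boundary cells, then empty neighbour (Eden B)


@njit(cache=True)
def run_eden(nbr, diag, depth, is_edge, founder_sites, p_move, stop_gen,
             complete_target, width_every, seed, max_cells,
             variant):  # pragma: no cover
    """Run one Eden realization; see ``eden.simulate_eden`` for semantics.

    ``diag`` holds the four diagonal neighbours (NE, NW, SW, SE with the
    axes ordered as in ``nbr``), used by the diffusion connectivity guard.
    Returns ``(status, parent, generation, site_of, occ, widths, n_events)``.
    """
    np.random.seed(seed)
    nsites, nn = nbr.shape

    occ = np.full(nsites, -1, np.int32)
    cand_list = np.empty(nsites, np.int32)
    cand_pos = np.full(nsites, -1, np.int32)
    bnd_list = np.empty(nsites, np.int32)
    bnd_pos = np.full(nsites, -1, np.int32)
    cnt = np.zeros(3, np.int64)  # n_cand, n_bnd, boundary cells < target

    parent = np.empty(max_cells, np.int32)
    generation = np.empty(max_cells, np.int32)
    site_of = np.empty(max_cells, np.int32)
    n_cells = 0

    n_width_cap = max_cells // width_every + 2 if width_every > 0 else 0
    widths = np.empty(n_width_cap, np.float64)
    n_widths = 0

    scratch = np.empty(nn, np.int32)
    status = OK

    # ---- local helpers (closures over the state arrays) ----------------
    def _still_boundary(s):
        for t in range(nn):
            nb = nbr[s, t]
            if nb >= 0 and occ[nb] < 0:
                return True
        return False

    def _has_occupied_neighbour(s):
        for t in range(nn):
            nb = nbr[s, t]
            if nb >= 0 and occ[nb] >= 0:
                return True
        return False

    def _occupy(site, cid):
        occ[site] = cid
        if cand_pos[site] >= 0:
            cnt[_NCAND] = _set_remove(cand_list, cand_pos, cnt[_NCAND], site)
        has_empty = False
        for t in range(nn):
            nb = nbr[site, t]
            if nb < 0:
                continue
            if occ[nb] < 0:
                has_empty = True
                if cand_pos[nb] < 0:
                    cnt[_NCAND] = _set_add(cand_list, cand_pos, cnt[_NCAND], nb)
            elif bnd_pos[nb] >= 0 and not _still_boundary(nb):
                cnt[_NBND] = _set_remove(bnd_list, bnd_pos, cnt[_NBND], nb)
                if complete_target >= 0 and generation[occ[nb]] < complete_target:
                    cnt[_YOUNG] -= 1
        if has_empty:
            cnt[_NBND] = _set_add(bnd_list, bnd_pos, cnt[_NBND], site)
            if complete_target >= 0 and generation[cid] < complete_target:
                cnt[_YOUNG] += 1

    def _vacate(site):
        cid = occ[site]
        occ[site] = -1
        if bnd_pos[site] >= 0:
            cnt[_NBND] = _set_remove(bnd_list, bnd_pos, cnt[_NBND], site)
            if complete_target >= 0 and generation[cid] < complete_target:
                cnt[_YOUNG] -= 1
        for t in range(nn):
            nb = nbr[site, t]
            if nb < 0:
                continue
            if occ[nb] >= 0:
                if bnd_pos[nb] < 0:
                    cnt[_NBND] = _set_add(bnd_list, bnd_pos, cnt[_NBND], nb)
                    if complete_target >= 0 and generation[occ[nb]] < complete_target:
                        cnt[_YOUNG] += 1
            elif cand_pos[nb] >= 0 and not _has_occupied_neighbour(nb):
                cnt[_NCAND] = _set_remove(cand_list, cand_pos, cnt[_NCAND], nb)
        if cand_pos[site] < 0 and _has_occupied_neighbour(site):
            cnt[_NCAND] = _set_add(cand_list, cand_pos, cnt[_NCAND], site)

    # ---- founders -------------------------------------------------------
    for i in range(founder_sites.size):
        s = founder_sites[i]
        parent[n_cells] = -1
        generation[n_cells] = 0
        site_of[n_cells] = s
        _occupy(s, n_cells)
        n_cells += 1

    n_events = 0
    if not (complete_target >= 0 and cnt[_YOUNG] == 0):
        while True:
            if cnt[_NCAND] == 0 or n_cells >= max_cells:
                status = CAPACITY_FULL
                break

            # ---- one growth event --------------------------------------
            if variant == CELL_UNIFORM:
                # pick a reproducing boundary cell, then one of its empty
                # neighbours (retry until a boundary cell is drawn; every
                # boundary cell has at least one empty neighbour)
                bs = bnd_list[np.random.randint(0, cnt[_NBND])]
                ke = 0
                for t in range(nn):
                    nb = nbr[bs, t]
                    if nb >= 0 and occ[nb] < 0:
                        scratch[ke] = nb
                        ke += 1
                site = scratch[np.random.randint(0, ke)]
                pid = occ[bs]
            else:
                while True:
                    site = cand_list[np.random.randint(0, cnt[_NCAND])]
                    kocc = 0
                    for t in range(nn):
                        nb = nbr[site, t]
                        if nb >= 0 and occ[nb] >= 0:
                            scratch[kocc] = nb
                            kocc += 1
                    if variant == SITE_UNIFORM:
                        break
                    # bond-uniform: accept the site with probability
                    # proportional to its number of occupied neighbours
                    if np.random.randint(0, nn) < kocc:
                        break
                pid = occ[scratch[np.random.randint(0, kocc)]]
            g = generation[pid] + 1
            cid = n_cells
            parent[cid] = pid
            generation[cid] = g
            site_of[cid] = site
            n_cells += 1
            _occupy(site, cid)
            n_events += 1
            if is_edge[site]:
                status = HIT_EDGE
                break

            if width_every > 0 and n_events % width_every == 0:
                nb_ = cnt[_NBND]
                m = 0.0
                for i in range(nb_):
                    m += depth[bnd_list[i]]
                m /= nb_
                v = 0.0
                for i in range(nb_):
                    d = depth[bnd_list[i]] - m
                    v += d * d
                widths[n_widths] = np.sqrt(v / nb_)
                n_widths += 1

            if complete_target >= 0:
                if cnt[_YOUNG] == 0:
                    break
            elif g >= stop_gen:
                break

            # ---- optional diffusion hops --------------------------------
            # p_move is the expected number of hop attempts per growth
            # event; the fractional part is realized stochastically
            n_hops = 0
            if p_move > 0.0:
                n_hops = int(p_move)
                if np.random.random() < p_move - n_hops:
                    n_hops += 1
            for _ in range(n_hops):
                bsite = bnd_list[np.random.randint(0, cnt[_NBND])]
                ke = 0
                for t in range(nn):
                    nb = nbr[bsite, t]
                    if nb >= 0 and occ[nb] < 0:
                        scratch[ke] = nb
                        ke += 1
                if ke > 0:
                    dest = scratch[np.random.randint(0, ke)]
                    # connectivity guard part 1: the destination must keep
                    # an occupied neighbour besides the mover
                    ok = False
                    for t in range(nn):
                        nb = nbr[dest, t]
                        if nb >= 0 and nb != bsite and occ[nb] >= 0:
                            ok = True
                            break
                    # part 2: vacating the origin must not split the
                    # cluster.  With the destination counted as occupied,
                    # the origin has to be a "simple point": its occupied
                    # von-Neumann neighbours (cyclic order E,N,W,S) must
                    # form a single arc, where consecutive edge neighbours
                    # are linked iff the diagonal between them is occupied.
                    if ok:
                        e0 = _occ_after(nbr[bsite, 0], dest, occ)
                        e1 = _occ_after(nbr[bsite, 2], dest, occ)
                        e2 = _occ_after(nbr[bsite, 1], dest, occ)
                        e3 = _occ_after(nbr[bsite, 3], dest, occ)
                        d0 = _occ_after(diag[bsite, 0], dest, occ)
                        d1 = _occ_after(diag[bsite, 1], dest, occ)
                        d2 = _occ_after(diag[bsite, 2], dest, occ)
                        d3 = _occ_after(diag[bsite, 3], dest, occ)
                        arcs = 0
                        if e0 and not (d0 and e1):
                            arcs += 1
                        if e1 and not (d1 and e2):
                            arcs += 1
                        if e2 and not (d2 and e3):
                            arcs += 1
                        if e3 and not (d3 and e0):
                            arcs += 1
                        ok = arcs <= 1
                    if ok:
                        mover = occ[bsite]
                        _vacate(bsite)
                        _occupy(dest, mover)
                        site_of[mover] = dest
                        if is_edge[dest]:
                            status = HIT_EDGE
                            break
            if status == HIT_EDGE:
                break

    return (status, parent[:n_cells], generation[:n_cells],
            site_of[:n_cells], occ, widths[:n_widths], n_events)
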