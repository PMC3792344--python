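"""Numba hot loop for the bond-fluctuation-method (BFM) Monte-Carlo sweep.

The kernel mirrors, move for move, the reference semantics of
:func:`minratchet.lattice.attempt_move` and
:func:`minratchet.tethering.update_tethers`; the pure-Python versions are the
readable contract, this module is the throughput path used by ``run_mcs``.

Conventions baked in here (shared with :mod:`minratchet.lattice`):

- a monomer at integer position ``p`` occupies the 8 lattice sites of the
  unit cube ``p + {0,1}^3``; valid positions are ``0 .. L-1`` per axis and
  the site grid has ``L+1`` planes per axis;
- one Monte-Carlo step (MCS) is ``M`` proposed single-monomer moves, where
  ``M`` is the total monomer count over all rings, each proposal uniform
  over monomers and the 6 axial unit directions;
- the tether field update runs once at the end of every MCS;
- randomness is consumed only where a decision actually needs it: a zero
  binding probability draws nothing, and the force Metropolis layer draws
  nothing when the applied force is zero.  This makes the no-tether and
  zero-force paths bitwise identical to their disabled counterparts.
"""

import math

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def _bond_ok(dx, dy, dz):
    # allowed BFM bond set <=> squared length in {4,5,6,9,10}
    s = dx * dx + dy * dy + dz * dz
    return s >= 4 and s <= 10 and s != 7 and s != 8


@njit(cache=True)
def run_kernel(
    pos,            # (M,3) int64, mutated in place
    occ,            # (2, Lx+1, Ly+1, Lz+1) uint8, per-polymer site occupancy
    tethered,       # (M,) bool
    release_mcs,    # (M,) int64
    clock0,         # int64 MCS clock before this call
    n_mcs,          # int64 sweeps to run
    Lx, Ly, Lz,     # box dims (positions go 0..L-1)
    n_poly, N,      # rings and monomers per ring (M = n_poly*N)
    interchain,     # bool: enforce cross-ring excluded volume
    field_table,    # (n_slots, Lx) float64 binding prob per axial position
    slot_of_mcs,    # (period,) int64: clock % period -> slot index
    dwell_mean,     # float64 mean tether dwell (MCS)
    d_b,            # int64 border distance for tether eligibility
    force,          # float64 attractive force f in U = f*d (kT per lattice unit)
    cm_limit,       # float64: if >0, reject x-moves taking |cm_x - Lx/2| beyond it
    record_every,   # int64: if >0, record relative axial CMs every so many MCS
    cm_out,         # (n_rec, n_poly) float64 output buffer
    bind_x,         # (Lx,) int64: binding events per axial position
    events,         # (cap, 4) int64 optional event log (mcs, poly, monomer, x)
    rng,            # np.random.Generator
):
    M = n_poly * N
    M6 = M * 6
    period = slot_of_mcs.shape[0]
    n_slots = field_table.shape[0]
    cap = events.shape[0]

    # running sums of x positions per ring, for O(1) CM bookkeeping
    sumx = np.zeros(2, dtype=np.int64)
    for i in range(M):
        sumx[i // N] += pos[i, 0]

    clock = clock0
    n_events = np.int64(0)
    dwell_sum = np.int64(0)
    n_rec = np.int64(0)
    n_logged = np.int64(0)
    half_x = 0.5 * Lx

    for _ in range(n_mcs):
        for _prop in range(M):
            u = rng.random()
            r = int(u * M6)
            if r >= M6:
                r = M6 - 1
            i = r // 6
            dcode = r - 6 * i
            axis = dcode >> 1
            sgn = 1 if (dcode & 1) == 1 else -1

            if tethered[i]:
                continue

            p = i // N
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]

            if axis == 0:
                nx = x + sgn
                if nx < 0 or nx > Lx - 1:
                    continue
                lead = x + 2 if sgn > 0 else x - 1
                blocked = False
                for v in range(2):
                    for w in range(2):
                        if occ[p, lead, y + v, z + w] != 0:
                            blocked = True
                        elif interchain and n_poly == 2 and occ[1 - p, lead, y + v, z + w] != 0:
                            blocked = True
                if blocked:
                    continue
                nxp, nyp, nzp = nx, y, z
            elif axis == 1:
                ny = y + sgn
                if ny < 0 or ny > Ly - 1:
                    continue
                lead = y + 2 if sgn > 0 else y - 1
                blocked = False
                for v in range(2):
                    for w in range(2):
                        if occ[p, x + v, lead, z + w] != 0:
                            blocked = True
                        elif interchain and n_poly == 2 and occ[1 - p, x + v, lead, z + w] != 0:
                            blocked = True
                if blocked:
                    continue
                nxp, nyp, nzp = x, ny, z
            else:
                nz = z + sgn
                if nz < 0 or nz > Lz - 1:
                    continue
                lead = z + 2 if sgn > 0 else z - 1
                blocked = False
                for v in range(2):
                    for w in range(2):
                        if occ[p, x + v, y + w, lead] != 0:
                            blocked = True
                        elif interchain and n_poly == 2 and occ[1 - p, x + v, y + w, lead] != 0:
                            blocked = True
                if blocked:
                    continue
                nxp, nyp, nzp = x, y, nz

            # both ring bonds must stay in the allowed set
            local = i - p * N
            iprev = p * N + (local - 1) % N
            inext = p * N + (local + 1) % N
            if not _bond_ok(pos[iprev, 0] - nxp, pos[iprev, 1] - nyp, pos[iprev, 2] - nzp):
                continue
            if not _bond_ok(pos[inext, 0] - nxp, pos[inext, 1] - nyp, pos[inext, 2] - nzp):
                continue

            if axis == 0:
                if cm_limit > 0.0:
                    new_cm = (sumx[p] + sgn) / N + 0.5 - half_x
                    if abs(new_cm) > cm_limit:
                        continue
                if force > 0.0 and n_poly == 2:
                    d_old = abs(sumx[0] - sumx[1]) / N
                    if p == 0:
                        d_new = abs(sumx[0] + sgn - sumx[1]) / N
                    else:
                        d_new = abs(sumx[0] - sumx[1] - sgn) / N
                    du = force * (d_new - d_old)
                    if du > 0.0 and rng.random() >= math.exp(-du):
                        continue

            # accept: update occupancy planes, position, CM sum
            if axis == 0:
                trail = x if sgn > 0 else x + 1
                lead_set = nxp + 1 if sgn > 0 else nxp
                for v in range(2):
                    for w in range(2):
                        occ[p, trail, y + v, z + w] = 0
                        occ[p, lead_set, y + v, z + w] = 1
                sumx[p] += sgn
            elif axis == 1:
                trail = y if sgn > 0 else y + 1
                lead_set = nyp + 1 if sgn > 0 else nyp
                for v in range(2):
                    for w in range(2):
                        occ[p, x + v, trail, z + w] = 0
                        occ[p, x + v, lead_set, z + w] = 1
            else:
                trail = z if sgn > 0 else z + 1
                lead_set = nzp + 1 if sgn > 0 else nzp
                for v in range(2):
                    for w in range(2):
                        occ[p, x + v, y + w, trail] = 0
                        occ[p, x + v, y + w, lead_set] = 1
            pos[i, 0] = nxp
            pos[i, 1] = nyp
            pos[i, 2] = nzp

        clock += 1

        # tether field update (release, then stochastic binding at the border)
        slot = slot_of_mcs[clock % period] if period > 0 else 0
        if n_slots > 0:
            for i in range(M):
                if tethered[i] and release_mcs[i] <= clock:
                    tethered[i] = False
                if not tethered[i]:
                    y = pos[i, 1]
                    z = pos[i, 2]
                    gap_y = y if y < Ly - 1 - y else Ly - 1 - y
                    gap_z = z if z < Lz - 1 - z else Lz - 1 - z
                    gap = gap_y if gap_y < gap_z else gap_z
                    if gap < d_b:
                        prob = field_table[slot, pos[i, 0]]
                        if prob > 0.0 and rng.random() < prob:
                            tethered[i] = True
                            uu = rng.random()
                            # geometric dwell (support >= 1) with mean dwell_mean
                            q = 1.0 / dwell_mean
                            if q >= 1.0:
                                k = np.int64(1)
                            else:
                                k = np.int64(math.ceil(math.log1p(-uu) / math.log1p(-q)))
                                if k < 1:
                                    k = np.int64(1)
                            release_mcs[i] = clock + k
                            bind_x[pos[i, 0]] += 1
                            n_events += 1
                            dwell_sum += k
                            if n_logged < cap:
                                events[n_logged, 0] = clock
                                events[n_logged, 1] = i // N
                                events[n_logged, 2] = i - (i // N) * N
                                events[n_logged, 3] = pos[i, 0]
                                n_logged += 1

        if record_every > 0 and clock % record_every == 0 and n_rec < cm_out.shape[0]:
            for pp in range(n_poly):
                cm_out[n_rec, pp] = ((sumx[pp] / N + 0.5) - half_x) / Lx
            n_rec += 1

    return clock, n_events, dwell_sum, n_rec, n_logged
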