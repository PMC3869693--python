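"""Numba kernel for the discrete vacancy-hopping single-file model.

The chain is deliberately simple enough to re-implement by brute force in a
test.  One time step of length ``dt`` performs, in order:

1. *Buffer birth/death* (both reservoir slabs): every buffer particle dies
   with probability ``death_p``; with probability ``birth_p = buf_mean *
   death_p`` (and while below capacity) a fresh particle is born.
2. *Entry attempts*: for each pore end, with probability ``q/2`` (q =
   hop_rate * dt) and if the end site is empty and the adjacent buffer is
   non-empty, a uniformly chosen buffer particle moves onto the end site
   with Metropolis acceptance ``min(1, a * exp(-U_end))`` where ``a`` is the
   dimensionless reservoir activity and ``U`` is in kT units.
3. *Hop sweep*: the occupied sites (snapshot at the start of the sweep) are
   visited in a random order; each particle picks a direction (+/-1 with
   probability 1/2) and with probability ``q`` attempts the move.  Moves to
   an occupied site are rejected (hard-core, no passing); interior moves are
   accepted with ``min(1, exp(-(U_tgt - U_src)))``; moves beyond an end
   leave the pore with acceptance ``min(1, exp(U_src) / a)`` into the
   adjacent buffer.
4. Every ``save_every`` steps a frame is recorded: pore particles at their
   site centres, buffer particles at ideal-gas (uniform) z inside their
   slab.

With this Metropolis pairing the stationary occupancy of site i is the
grand-canonical product value a*exp(-U_i) / (1 + a*exp(-U_i)) up to the
weak coupling through finite buffers.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_hopping(n_steps, save_every, n_sites, U, q, a,
                buf_mean, death_p, cap, seed,
                site_z, z_lo, z_hi, buf_len,
                rec_frame, rec_id, rec_z):
    np.random.seed(seed)
    occ = np.full(n_sites, -1, np.int64)
    buf_id = np.full((2, cap), -1, np.int64)
    buf_n = np.zeros(2, np.int64)
    next_id = 0
    birth_p = buf_mean * death_p

    # initial configuration near the product-measure guess (burn-in discards
    # the remainder of the relaxation)
    for i in range(n_sites):
        w = a * np.exp(-U[i])
        if np.random.random() < w / (1.0 + w):
            occ[i] = next_id
            next_id += 1
    for s in range(2):
        m = int(buf_mean)
        if m < 1:
            m = 1
        for _ in range(m):
            buf_id[s, buf_n[s]] = next_id
            next_id += 1
            buf_n[s] += 1

    order = np.empty(n_sites, np.int64)
    n_rec = 0
    frame = 0
    for step in range(n_steps):
        # 1. buffer birth/death
        for s in range(2):
            k = 0
            while k < buf_n[s]:
                if np.random.random() < death_p:
                    buf_id[s, k] = buf_id[s, buf_n[s] - 1]
                    buf_n[s] -= 1
                else:
                    k += 1
            if buf_n[s] < cap and np.random.random() < birth_p:
                buf_id[s, buf_n[s]] = next_id
                next_id += 1
                buf_n[s] += 1
        # 2. entries
        for s in range(2):
            if np.random.random() < 0.5 * q:
                end = 0 if s == 0 else n_sites - 1
                if occ[end] < 0 and buf_n[s] > 0:
                    acc = a * np.exp(-U[end])
                    if acc > 1.0:
                        acc = 1.0
                    if np.random.random() < acc:
                        j = np.random.randint(buf_n[s])
                        occ[end] = buf_id[s, j]
                        buf_id[s, j] = buf_id[s, buf_n[s] - 1]
                        buf_n[s] -= 1
        # 3. hop sweep in random order over the occupied-site snapshot
        m = 0
        for i in range(n_sites):
            if occ[i] >= 0:
                order[m] = i
                m += 1
        for i in range(m - 1, 0, -1):
            j = np.random.randint(i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for t in range(m):
            i = order[t]
            if occ[i] < 0:
                continue
            if np.random.random() >= q:
                continue
            d = 1 if np.random.random() < 0.5 else -1
            tgt = i + d
            if 0 <= tgt < n_sites:
                if occ[tgt] < 0:
                    dU = U[tgt] - U[i]
                    if dU <= 0.0 or np.random.random() < np.exp(-dU):
                        occ[tgt] = occ[i]
                        occ[i] = -1
            else:
                s = 0 if tgt < 0 else 1
                if buf_n[s] < cap:
                    acc = np.exp(U[i]) / a
                    if acc > 1.0:
                        acc = 1.0
                    if np.random.random() < acc:
                        buf_id[s, buf_n[s]] = occ[i]
                        buf_n[s] += 1
                        occ[i] = -1
        # 4. record
        if step % save_every == 0:
            for i in range(n_sites):
                if occ[i] >= 0:
                    rec_frame[n_rec] = frame
                    rec_id[n_rec] = occ[i]
                    rec_z[n_rec] = site_z[i]
                    n_rec += 1
            for s in range(2):
                for k in range(buf_n[s]):
                    if s == 0:
                        z = z_lo - buf_len * np.random.random()
                    else:
                        z = z_hi + buf_len * np.random.random()
                    rec_frame[n_rec] = frame
                    rec_id[n_rec] = buf_id[s, k]
                    rec_z[n_rec] = z
                    n_rec += 1
            frame += 1
    return n_rec, frame
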