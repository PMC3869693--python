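"""Brute-force pure-python re-implementation of the vacancy-hopping chain.

Mirrors the documented update rules of ``poreflux._hopping`` step by step
(buffer birth/death, Metropolis entries, random-order hop sweep with
hard-core rejection and Metropolis exits) without any of the production
kernel's bookkeeping; used as the independent oracle for occupancy and
flux statistics.
"""

import math
import random


def run_oracle(n_steps, n_sites, U, q, a, buf_mean, death_p, seed, record_every=1):
    """Returns (occupancy samples, completed crossing count).

    ``U`` is per-site energy in kT units.  Crossings are counted directly on
    particle identities: a particle entering at one end and exiting at the
    other increments the count.
    """
    rng = random.Random(seed)
    occ = [None] * n_sites  # entry side label (0 bottom / 1 top) or None
    buf = [int(buf_mean), int(buf_mean)]  # population counts (ideal, well mixed)
    birth_p = buf_mean * death_p
    occupancies = []
    crossings = 0
    for i in range(n_sites):
        w = a * math.exp(-U[i])
        if rng.random() < w / (1.0 + w):
            occ[i] = -1  # unknown origin
    for step in range(n_steps):
        for s in (0, 1):
            survivors = 0
            for _ in range(buf[s]):
                if not rng.random() < death_p:
                    survivors += 1
            buf[s] = survivors
            if rng.random() < birth_p:
                buf[s] += 1
        for s in (0, 1):
            if rng.random() < 0.5 * q:
                end = 0 if s == 0 else n_sites - 1
                if occ[end] is None and buf[s] > 0:
                    if rng.random() < min(1.0, a * math.exp(-U[end])):
                        occ[end] = s
                        buf[s] -= 1
        filled = [i for i in range(n_sites) if occ[i] is not None]
        rng.shuffle(filled)
        for i in filled:
            if occ[i] is None:
                continue
            if rng.random() >= q:
                continue
            d = 1 if rng.random() < 0.5 else -1
            tgt = i + d
            if 0 <= tgt < n_sites:
                if occ[tgt] is None:
                    dU = U[tgt] - U[i]
                    if dU <= 0.0 or rng.random() < math.exp(-dU):
                        occ[tgt] = occ[i]
                        occ[i] = None
            else:
                s = 0 if tgt < 0 else 1
                if rng.random() < min(1.0, math.exp(U[i]) / a):
                    if occ[i] == 1 - s:  # entered at the far end
                        crossings += 1
                    buf[s] += 1
                    occ[i] = None
        if step % record_every == 0:
            occupancies.append(sum(1 for v in occ if v is not None))
    return occupancies, crossings
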