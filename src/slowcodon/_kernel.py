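"""Compiled Gillespie kernel for the extended-particle exclusion process.

State is the ordered vector of ribosome A-site positions (1-based codon
indices), ``pos[0]`` being the frontmost (3'-most) ribosome.  Dynamics:

* initiation at codon 1 with rate ``alpha_on`` iff codons 1..footprint are
  clear of A-sites (equivalently the rearmost A-site exceeds the footprint);
* a ribosome with A-site at codon i hops to i+1 with rate ``omega[i]``
  (the rate of the codon being entered, 0-based array) iff the A-site gap to
  the ribosome ahead exceeds the footprint;
* premature drop-off anywhere with rate ``gamma`` per ribosome;
* termination from the last codon with rate ``alpha_off``.

Occupancies are accumulated as exact time integrals split over ``n_batches``
equal batches after ``burn_in``; termination events are counted per batch.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def gillespie_tasep(omega, alpha_on, alpha_off, gamma, footprint,
                    burn_in, batch_time, n_batches, seed):
    L = omega.shape[0]
    max_r = L // footprint + 2
    pos = np.zeros(max_r, dtype=np.int64)
    rates = np.zeros(max_r, dtype=np.float64)
    n = 0
    rho_a = np.zeros((n_batches, L))       # A-site occupancy time integrals
    rho_c = np.zeros((n_batches, L))       # footprint-coverage time integrals
    term = np.zeros(n_batches)
    n_events = 0

    np.random.seed(seed)
    t = 0.0
    t_end = burn_in + batch_time * n_batches

    while t < t_end:
        init_ok = (n == 0) or (pos[n - 1] > footprint)
        r_init = alpha_on if init_ok else 0.0
        total = r_init + gamma * n
        for k in range(n):
            if pos[k] == L:
                rk = alpha_off
            elif k == 0 or pos[k - 1] - pos[k] > footprint:
                rk = omega[pos[k]]  # codon being entered is pos[k]+1, 0-based index pos[k]
            else:
                rk = 0.0
            rates[k] = rk
            total += rk

        if total <= 0.0:
            t_next = t_end  # absorbing empty lattice (alpha_on == 0)
        else:
            t_next = t + (-np.log(np.random.random()) / total)

        # accumulate occupancy over [t, min(t_next, t_end)) into batches
        b = t_next if t_next < t_end else t_end
        if b > burn_in and n > 0:
            a = t if t > burn_in else burn_in
            i0 = int((a - burn_in) / batch_time)
            i1 = int((b - burn_in) / batch_time)
            if i1 > n_batches - 1:
                i1 = n_batches - 1
            for bi in range(i0, i1 + 1):
                lo = burn_in + bi * batch_time
                hi = lo + batch_time
                seg_lo = a if a > lo else lo
                seg_hi = b if b < hi else hi
                w = seg_hi - seg_lo
                if w > 0.0:
                    for k in range(n):
                        p = pos[k] - 1
                        rho_a[bi, p] += w
                        stop = p + footprint
                        if stop > L:
                            stop = L
                        for c in range(p, stop):
                            rho_c[bi, c] += w

        if t_next >= t_end or total <= 0.0:
            break
        t = t_next
        n_events += 1

        u = np.random.random() * total
        if u < r_init:
            pos[n] = 1
            n += 1
        elif u < r_init + gamma * n:
            j = int((u - r_init) / gamma)
            if j > n - 1:
                j = n - 1
            for k in range(j, n - 1):
                pos[k] = pos[k + 1]
            n -= 1
        else:
            u -= r_init + gamma * n
            j = n - 1
            for k in range(n):
                if u < rates[k]:
                    j = k
                    break
                u -= rates[k]
            if pos[j] == L:
                # termination (only the frontmost can sit at L)
                for k in range(j, n - 1):
                    pos[k] = pos[k + 1]
                n -= 1
                if t >= burn_in:
                    bi = int((t - burn_in) / batch_time)
                    if bi > n_batches - 1:
                        bi = n_batches - 1
                    term[bi] += 1.0
            else:
                pos[j] += 1

    return rho_a / batch_time, rho_c / batch_time, term / batch_time, n_events
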