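"""Numba inner loops for the secondary-structure dynamic programs.

All kernels work on integer-encoded sequences (A=0, C=1, G=2, T/U=3) and
pre-Boltzmannized weight tables. The partition-function kernel optionally
reuses a previously filled unconstrained table set: when a blocked region
[ra, rb) is given together with reference arrays, intervals that do not
intersect the region are copied instead of recomputed, which roughly halves
the cost of per-site accessibility scans.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TURN = 3  # minimum unpaired bases in a hairpin loop
INF = 1e30


@njit(cache=True)
def fill_pf(enc, canp, stw, hpw, buw, ilw, mla, mlb, mlc, maxloop,
            ra, rb, qb0, qm0, qm10, q0, have_ref):
    n = enc.shape[0]
    Qb = np.zeros((n, n))
    Qm = np.zeros((n, n))
    Qm1 = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i in range(n):
        Q[i, i] = 1.0
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            if have_ref and (j < ra or i >= rb):
                Qb[i, j] = qb0[i, j]
                Qm[i, j] = qm0[i, j]
                Qm1[i, j] = qm10[i, j]
                Q[i, j] = q0[i, j]
                continue
            a = enc[i]
            b = enc[j]
            qb = 0.0
            blocked = (ra <= i < rb) or (ra <= j < rb)
            if canp[a, b] and d >= TURN + 1 and not blocked:
                qb = hpw[d - 1]
                kmax = i + 1 + maxloop
                if kmax > j - TURN - 2:
                    kmax = j - TURN - 2
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = j - 1 - (maxloop - g1)
                    if lmin < k + TURN + 1:
                        lmin = k + TURN + 1
                    for l in range(lmin, j):
                        qkl = Qb[k, l]
                        if qkl > 0.0:
                            g2 = j - l - 1
                            if g1 == 0 and g2 == 0:
                                w = stw[a, enc[i + 1]]
                            elif g1 == 0 or g2 == 0:
                                w = buw[g1 + g2]
                            else:
                                w = ilw[g1 + g2]
                            qb += w * qkl
                s = 0.0
                for u in range(i + 2, j - TURN - 1):
                    qm_left = Qm[i + 1, u - 1]
                    if qm_left > 0.0:
                        s += qm_left * Qm1[u, j - 1]
                qb += mla * s
            Qb[i, j] = qb
            Qm1[i, j] = Qm1[i, j - 1] * mlc + qb * mlb
            qm = 0.0
            cpow = 1.0
            for k in range(i, j - TURN):
                q1k = Qm1[k, j]
                if q1k > 0.0:
                    inner = cpow
                    if k > i:
                        inner += Qm[i, k - 1]
                    qm += inner * q1k
                cpow *= mlc
            Qm[i, j] = qm
            q = Q[i, j - 1]
            for k in range(i, j - TURN):
                qbk = Qb[k, j]
                if qbk > 0.0:
                    if k > i:
                        q += Q[i, k - 1] * qbk
                    else:
                        q += qbk
            Q[i, j] = q
    return Q, Qb, Qm, Qm1


@njit(cache=True)
def fill_mfe(enc, canp, ste, hpe, bue, ile, mla, mlb, mlc, maxloop):
    n = enc.shape[0]
    Eb = np.full((n, n), INF)
    Em = np.full((n, n), INF)
    Em1 = np.full((n, n), INF)
    F = np.zeros(n)
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            a = enc[i]
            b = enc[j]
            eb = INF
            if canp[a, b] and d >= TURN + 1:
                eb = hpe[d - 1]
                kmax = i + 1 + maxloop
                if kmax > j - TURN - 2:
                    kmax = j - TURN - 2
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = j - 1 - (maxloop - g1)
                    if lmin < k + TURN + 1:
                        lmin = k + TURN + 1
                    for l in range(lmin, j):
                        ekl = Eb[k, l]
                        if ekl < INF:
                            g2 = j - l - 1
                            if g1 == 0 and g2 == 0:
                                w = ste[a, enc[i + 1]]
                            elif g1 == 0 or g2 == 0:
                                w = bue[g1 + g2]
                            else:
                                w = ile[g1 + g2]
                            if w + ekl < eb:
                                eb = w + ekl
                for u in range(i + 2, j - TURN - 1):
                    eml = Em[i + 1, u - 1]
                    if eml < INF:
                        e1 = Em1[u, j - 1]
                        if e1 < INF and mla + eml + e1 < eb:
                            eb = mla + eml + e1
            Eb[i, j] = eb
            e1 = Em1[i, j - 1] + mlc
            if eb + mlb < e1:
                e1 = eb + mlb
            Em1[i, j] = e1
            em = INF
            for k in range(i, j - TURN):
                e1k = Em1[k, j]
                if e1k < INF:
                    cand = (k - i) * mlc + e1k
                    if k > i and Em[i, k - 1] < INF:
                        alt = Em[i, k - 1] + e1k
                        if alt < cand:
                            cand = alt
                    if cand < em:
                        em = cand
            Em[i, j] = em
    for j in range(1, n):
        best = F[j - 1]
        for k in range(0, j - TURN):
            if Eb[k, j] < INF:
                prev = F[k - 1] if k > 0 else 0.0
                if prev + Eb[k, j] < best:
                    best = prev + Eb[k, j]
        F[j] = best
    return F, Eb, Em, Em1


@njit(cache=True)
def fill_dimer(ea, eb_s, canp, stw, buw, ilw, maxloop):
    """Interaction-only partition function between two strands.

    C[i, j] sums Boltzmann weights over interaction structures whose
    outermost (smallest-i) pair is (i, j); consecutive pairs are separated
    by at most ``maxloop`` unpaired bases in total.
    """
    na = ea.shape[0]
    nb = eb_s.shape[0]
    C = np.zeros((na, nb))
    total = 0.0
    for i in range(na - 1, -1, -1):
        for j in range(nb):
            if not canp[ea[i], eb_s[j]]:
                continue
            c = 1.0
            kmax = i + 1 + maxloop
            if kmax > na - 1:
                kmax = na - 1
            for k in range(i + 1, kmax + 1):
                g1 = k - i - 1
                lmin = j - 1 - (maxloop - g1)
                if lmin < 0:
                    lmin = 0
                for l in range(lmin, j):
                    ckl = C[k, l]
                    if ckl > 0.0:
                        g2 = j - l - 1
                        if g1 == 0 and g2 == 0:
                            w = stw[ea[i], ea[i + 1]]
                        elif g1 == 0 or g2 == 0:
                            w = buw[g1 + g2]
                        else:
                            w = ilw[g1 + g2]
                        c += w * ckl
            C[i, j] = c
            total += c
    return total
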