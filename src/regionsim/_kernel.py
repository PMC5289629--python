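"""Compiled inner loop of the Wright-Fisher engine.

The kernel consumes the ``np.random.Generator`` stream in exactly the
same order as the pure-numpy loop in :mod:`regionsim.simulate`, so the
two engines are bit-for-bit interchangeable (the test suite asserts
this).  Gametes are stored sparsely as fixed-width lists of mutation
ids (per-gamete mutation counts are of order one at the simulated
mutation rates), which keeps the per-generation cost proportional to
the number of carried mutations rather than to gametes x sites.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

# model codes
_AC, _GBR, _MR = 0, 1, 2


@njit(cache=True)
def _hap_effect_sum(ids, glen, eff, row):
    s = 0.0
    for t in range(glen[row]):
        s += eff[ids[row, t]]
    return s


@njit(cache=True)
def _diploid_genval(ids, glen, eff, r0, r1, model, h):
    if model == _AC:
        return _hap_effect_sum(ids, glen, eff, r0) + _hap_effect_sum(
            ids, glen, eff, r1
        )
    if model == _GBR:
        return np.sqrt(
            _hap_effect_sum(ids, glen, eff, r0) * _hap_effect_sum(ids, glen, eff, r1)
        )
    # MR: per-site zygosity by scanning the (short) partner list
    acc = 0.0
    for t in range(glen[r0]):
        m = ids[r0, t]
        hom = False
        for u in range(glen[r1]):
            if ids[r1, u] == m:
                hom = True
                break
        acc += np.log1p(2.0 * eff[m]) if hom else np.log1p(h * eff[m])
    for u in range(glen[r1]):
        m = ids[r1, u]
        shared = False
        for t in range(glen[r0]):
            if ids[r0, t] == m:
                shared = True
                break
        if not shared:
            acc += np.log1p(h * eff[m])
    return np.exp(acc) - 1.0


@njit(cache=True)
def _run_kernel(
    rng,
    sizes,
    mu_n,
    mu_c,
    lam,
    rrate,
    sigma_e,
    sigma_s,
    p_opt,
    model,
    h,
    record_interval,
):
    n_gens = sizes.shape[0] - 1
    max_gam = 2 * np.max(sizes)
    site_cap = 64
    gcap = 16
    fix_cap = 64
    n_sites = 0
    n_fix = 0

    ids = np.zeros((max_gam, gcap), dtype=np.int32)
    ids2 = np.zeros((max_gam, gcap), dtype=np.int32)
    glen = np.zeros(max_gam, dtype=np.int32)
    glen2 = np.zeros(max_gam, dtype=np.int32)
    pos = np.zeros(site_cap)
    eff = np.zeros(site_cap)
    org = np.zeros(site_cap, dtype=np.int64)
    counts = np.zeros(site_cap, dtype=np.int64)
    remap = np.zeros(site_cap, dtype=np.int64)
    fix_pos = np.zeros(fix_cap)
    fix_eff = np.zeros(fix_cap)
    fix_org = np.zeros(fix_cap, dtype=np.int64)
    fix_gen = np.zeros(fix_cap, dtype=np.int64)

    n_rec_max = n_gens // record_interval + 2
    records = np.zeros((n_rec_max, 8))
    n_rec = 0

    nmax = int(np.max(sizes))
    g = np.zeros(nmax)
    p = np.zeros(nmax)
    cum = np.zeros(nmax)
    inv2ss = 1.0 / (2.0 * sigma_s * sigma_s)

    for gen in range(n_gens + 1):
        n_dip = sizes[gen]
        for i in range(n_dip):
            g[i] = _diploid_genval(ids, glen, eff, 2 * i, 2 * i + 1, model, h)
            e = rng.normal(0.0, sigma_e) if sigma_e > 0.0 else 0.0
            p[i] = g[i] + e

        if gen % record_interval == 0 or gen == n_gens:
            mg = 0.0
            mp = 0.0
            for i in range(n_dip):
                mg += g[i]
                mp += p[i]
            mg /= n_dip
            mp /= n_dip
            vg = 0.0
            wsum_seg = 0.0
            for i in range(n_dip):
                vg += (g[i] - mg) ** 2
                wsum_seg += np.exp(-g[i] * g[i] * inv2ss)
            vg /= n_dip
            mean_muts = 0.0
            for r in range(2 * n_dip):
                for t in range(glen[r]):
                    if eff[ids[r, t]] > 0.0:
                        mean_muts += 1.0
            mean_muts /= n_dip
            sfix = 0.0
            logprod_fix = 0.0
            for k in range(n_fix):
                if fix_eff[k] > 0.0:
                    sfix += fix_eff[k]
                    logprod_fix += np.log1p(2.0 * fix_eff[k])
            if model == _AC:
                gfix = 2.0 * sfix
            elif model == _GBR:
                gfix = sfix
            else:
                gfix = np.exp(logprod_fix) - 1.0
            wsum_tot = 0.0
            for i in range(n_dip):
                if model == _AC:
                    gt = g[i] + gfix
                elif model == _GBR:
                    s1 = sfix + _hap_effect_sum(ids, glen, eff, 2 * i)
                    s2 = sfix + _hap_effect_sum(ids, glen, eff, 2 * i + 1)
                    gt = np.sqrt(s1 * s2)
                else:
                    gt = (g[i] + 1.0) * (gfix + 1.0) - 1.0
                wsum_tot += np.exp(-gt * gt * inv2ss)
            records[n_rec, 0] = gen
            records[n_rec, 1] = n_dip
            records[n_rec, 2] = vg
            records[n_rec, 3] = mean_muts
            records[n_rec, 4] = mp
            records[n_rec, 5] = 1.0 - wsum_seg / n_dip
            records[n_rec, 6] = 1.0 - np.exp(-gfix * gfix * inv2ss)
            records[n_rec, 7] = 1.0 - wsum_tot / n_dip
            n_rec += 1

        if gen == n_gens:
            break

        # --- selection: rejection sampling of parental gametes ---
        # fitness values lie in (0, 1], so w_max = 1 is a valid
        # rejection envelope; a single integer draw over gametes yields
        # both the parent (cand >> 1) and the transmitted gamete.
        total = 0.0
        for i in range(n_dip):
            d = p[i] - p_opt
            cum[i] = np.exp(-d * d * inv2ss)  # reused as per-diploid fitness
            total += cum[i]
        if total <= 0.0:
            return (
                np.zeros((0, 0), dtype=np.uint8),
                pos[:0],
                eff[:0],
                org[:0],
                fix_pos[:0],
                fix_eff[:0],
                fix_org[:0],
                fix_gen[:0],
                records[:0],
                -1,
            )
        n_gam = 2 * sizes[gen + 1]
        rows = np.empty(n_gam, dtype=np.int64)
        pend = np.empty(n_gam, dtype=np.int64)
        cand = np.empty(n_gam, dtype=np.int64)
        uu = np.empty(n_gam)
        for o in range(n_gam):
            pend[o] = o
        n_pend = n_gam
        while n_pend > 0:
            for t in range(n_pend):
                cand[t] = rng.integers(0, 2 * n_dip)
            for t in range(n_pend):
                uu[t] = rng.random()
            w2 = 0
            for t in range(n_pend):
                if uu[t] < cum[cand[t] >> 1]:
                    rows[pend[t]] = cand[t]
                else:
                    pend[w2] = pend[t]
                    w2 += 1
            n_pend = w2
        for o in range(n_gam):
            src = rows[o]
            ln = glen[src]
            for t in range(ln):
                ids2[o, t] = ids[src, t]
            glen2[o] = ln

        # --- crossovers (Poisson-thinned over all offspring gametes) ---
        if rrate > 0.0:
            k_tot = rng.poisson(rrate * n_gam)
            if k_tot > 0:
                xrows = np.empty(k_tot, dtype=np.int64)
                for t in range(k_tot):
                    xrows[t] = rng.integers(0, n_gam)
                pts = np.empty(k_tot)
                for t in range(k_tot):
                    pts[t] = rng.random()
                order = np.argsort(xrows)
                t = 0
                while t < k_tot:
                    o = xrows[order[t]]
                    t2 = t
                    while t2 < k_tot and xrows[order[t2]] == o:
                        t2 += 1
                    xo = np.sort(pts[order[t:t2]])
                    ra = rows[o]
                    rb = rows[o] ^ 1  # the sibling gamete of the same parent
                    while glen[ra] + glen[rb] > gcap:  # merged list may be wider
                        new_gcap = gcap * 2
                        nids = np.zeros((max_gam, new_gcap), dtype=np.int32)
                        nids2 = np.zeros((max_gam, new_gcap), dtype=np.int32)
                        nids[:, :gcap] = ids
                        nids2[:, :gcap] = ids2
                        ids, ids2, gcap = nids, nids2, new_gcap
                    w = 0
                    for src_row, want_odd in ((ra, 0), (rb, 1)):
                        for q in range(glen[src_row]):
                            m = ids[src_row, q]
                            nx = 0
                            for x in range(xo.shape[0]):
                                if xo[x] <= pos[m]:
                                    nx += 1
                            if nx % 2 == want_odd:
                                ids2[o, w] = m
                                w += 1
                    glen2[o] = w
                    t = t2

        # --- mutation ---
        n_neu = rng.poisson(mu_n * n_gam) if mu_n > 0.0 else 0
        n_cau = rng.poisson(mu_c * n_gam) if mu_c > 0.0 else 0
        n_new = n_neu + n_cau
        if n_new > 0:
            if n_sites + n_new > site_cap:
                new_cap = site_cap
                while n_sites + n_new > new_cap:
                    new_cap *= 2
                npos = np.zeros(new_cap)
                neff = np.zeros(new_cap)
                norg = np.zeros(new_cap, dtype=np.int64)
                npos[:n_sites] = pos[:n_sites]
                neff[:n_sites] = eff[:n_sites]
                norg[:n_sites] = org[:n_sites]
                pos, eff, org = npos, neff, norg
                counts = np.zeros(new_cap, dtype=np.int64)
                remap = np.zeros(new_cap, dtype=np.int64)
                site_cap = new_cap
            for t in range(n_new):
                while True:
                    x = rng.random()
                    clash = False
                    for j in range(n_sites + t):
                        if pos[j] == x:
                            clash = True
                            break
                    if not clash:
                        break
                pos[n_sites + t] = x
                eff[n_sites + t] = 0.0
                org[n_sites + t] = gen + 1
            for t in range(n_neu, n_new):
                eff[n_sites + t] = rng.exponential(lam)
            for t in range(n_new):
                tgt = rng.integers(0, n_gam)
                if glen2[tgt] >= gcap:  # grow gamete width
                    new_gcap = gcap * 2
                    nids = np.zeros((max_gam, new_gcap), dtype=np.int32)
                    nids2 = np.zeros((max_gam, new_gcap), dtype=np.int32)
                    nids[:, :gcap] = ids
                    nids2[:, :gcap] = ids2
                    ids, ids2, gcap = nids, nids2, new_gcap
                ids2[tgt, glen2[tgt]] = n_sites + t
                glen2[tgt] += 1
            n_sites += n_new

        # --- prune lost and fixed sites, renumber ids ---
        for j in range(n_sites):
            counts[j] = 0
        for o in range(n_gam):
            for t in range(glen2[o]):
                counts[ids2[o, t]] += 1
        wcol = 0
        changed = False
        for j in range(n_sites):
            cnt = counts[j]
            if cnt == 0:
                remap[j] = -1
                changed = True
            elif cnt == n_gam:
                if n_fix >= fix_cap:
                    fc = fix_cap * 2
                    fp = np.zeros(fc)
                    fe = np.zeros(fc)
                    fo = np.zeros(fc, dtype=np.int64)
                    fg = np.zeros(fc, dtype=np.int64)
                    fp[:n_fix] = fix_pos[:n_fix]
                    fe[:n_fix] = fix_eff[:n_fix]
                    fo[:n_fix] = fix_org[:n_fix]
                    fg[:n_fix] = fix_gen[:n_fix]
                    fix_pos, fix_eff, fix_org, fix_gen, fix_cap = fp, fe, fo, fg, fc
                fix_pos[n_fix] = pos[j]
                fix_eff[n_fix] = eff[j]
                fix_org[n_fix] = org[j]
                fix_gen[n_fix] = gen + 1
                n_fix += 1
                remap[j] = -1
                changed = True
            else:
                remap[j] = wcol
                if wcol != j:
                    pos[wcol] = pos[j]
                    eff[wcol] = eff[j]
                    org[wcol] = org[j]
                wcol += 1
        if changed:
            for o in range(n_gam):
                w = 0
                for t in range(glen2[o]):
                    r = remap[ids2[o, t]]
                    if r >= 0:
                        ids2[o, w] = np.int32(r)
                        w += 1
                glen2[o] = w
        n_sites = wcol

        tmp_i, tmp_l = ids, glen
        ids, glen = ids2, glen2
        ids2, glen2 = tmp_i, tmp_l

    # --- dense occupancy of the final generation ---
    n_gam_final = 2 * sizes[n_gens]
    occ = np.zeros((n_gam_final, n_sites), dtype=np.uint8)
    for o in range(n_gam_final):
        for t in range(glen[o]):
            occ[o, ids[o, t]] = 1
    return (
        occ,
        pos[:n_sites].copy(),
        eff[:n_sites].copy(),
        org[:n_sites].copy(),
        fix_pos[:n_fix].copy(),
        fix_eff[:n_fix].copy(),
        fix_org[:n_fix].copy(),
        fix_gen[:n_fix].copy(),
        records[:n_rec].copy(),
        0,
    )
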