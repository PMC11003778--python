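"""Numba kernels: the packed-array generation loop.

The population is stored CSR-style: ``sites`` (global linear coordinates,
chromosome * L + position, sorted within each individual), ``homs`` (homolog
0/1 per insertion), and ``indptr`` (N+1 offsets). Per-individual metadata are
flat arrays (sex, modifier allele per homolog of the modifier chromosome,
fitness). One call advances the population up to ``n_gens`` generations of
the selection -> reproduction -> silencing -> transposition -> ectopic ->
fitness cycle, recording per-generation summaries, and stops early on TE
loss, population crash, or extinction of a reproducible sex.

Exact-sampling shortcuts (distributionally identical to per-copy draws) are
used when per-copy silencing magnitudes are not consumed elsewhere:

* additive fitness with b > 0: sum_i M_i ~ Poisson(a' n^2);
* transposition with k > 0, b = 0: the duplication count is
  Binomial(n, u * E[max(0, 1 - kM)]) with M ~ Poisson(a' n).

Per-copy M is drawn explicitly when both channels are active, when
multiplicative fitness needs per-copy factors, or when ectopic suppression
must compare each copy's M against the threshold T.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# terminal statuses
COMPLETED = 0
TE_LOSS = 1
POPULATION_CRASH = 2
EXTINCT = 3

CRASH_MEAN_FITNESS = 1e-3

# fitness modes
ADDITIVE = 0
MULTIPLICATIVE = 1
SYNERGISTIC = 2

# modifier directions
MOD_NONE = 0
MOD_ENHANCE = 1
MOD_WEAKEN = 2


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _a_eff(a, mod_dir, copies):
    """Effective silencing scale a' = a * (1 +/- 0.5 * H), H = copies / 2."""
    if mod_dir == MOD_NONE or copies == 0:
        return a
    h = 0.5 * copies
    if mod_dir == MOD_ENHANCE:
        return a * (1.0 + 0.5 * h)
    return a * (1.0 - 0.5 * h)


@njit(cache=True)
def _mean_dup_prob(u, k, lam):
    """u * E[max(0, 1 - k*M)] for M ~ Poisson(lam), by finite series."""
    if k <= 0.0:
        return u
    if lam <= 0.0:
        return u
    m_max = int(1.0 / k)  # terms with 1 - k*m > 0
    pmf = np.exp(-lam)
    acc = 0.0
    m = 0
    while m <= m_max:
        f = 1.0 - k * m
        if f > 0.0:
            acc += f * pmf
        m += 1
        pmf *= lam / m
    return u * acc


@njit(cache=True)
def _gamete(sites, homs, lo, hi, mod0, mod1, L, n_chroms, r, mod_site,
            out_sites):
    """Draw one recombinant gamete from parent slice [lo, hi).

    Writes transmitted global sites (sorted) into out_sites; returns
    (count, modifier_allele). Crossovers form a Poisson process of rate r
    per bp (count ~ Poisson(r*L), uniform positions, no interference),
    generated in increasing order via exponential spacings; the gamete takes
    alternating homolog segments from a uniformly chosen starting homolog,
    and chromosomes assort independently.
    """
    count = 0
    modifier = 0
    p = lo
    for c in range(n_chroms):
        chrom_start = c * L
        chrom_end = chrom_start + L
        parity = np.random.randint(0, 2)
        has_mod = chrom_start <= mod_site < chrom_end
        if r <= 0.0:
            while p < hi and sites[p] < chrom_end:
                if homs[p] == parity:
                    out_sites[count] = sites[p]
                    count += 1
                p += 1
            if has_mod:
                modifier = mod0 if parity == 0 else mod1
        else:
            scale = 1.0 / r
            nxt = chrom_start + np.random.exponential(scale)
            mod_done = not has_mod
            while p < hi and sites[p] < chrom_end:
                pos = sites[p]
                if not mod_done and mod_site < pos:
                    while nxt <= mod_site:
                        parity ^= 1
                        nxt += np.random.exponential(scale)
                    modifier = mod0 if parity == 0 else mod1
                    mod_done = True
                while nxt <= pos:
                    parity ^= 1
                    nxt += np.random.exponential(scale)
                if homs[p] == parity:
                    out_sites[count] = sites[p]
                    count += 1
                p += 1
            if not mod_done:
                while nxt <= mod_site:
                    parity ^= 1
                    nxt += np.random.exponential(scale)
                modifier = mod0 if parity == 0 else mod1
    return count, modifier


@njit(cache=True)
def _occupied(sites, homs, lo, hi, site, hom):
    """Binary search: is (site, hom) present in the sorted slice [lo, hi)?"""
    a, b = lo, hi
    while a < b:
        mid = (a + b) // 2
        if sites[mid] < site:
            a = mid + 1
        else:
            b = mid
    while a < hi and sites[a] == site:
        if homs[a] == hom:
            return True
        a += 1
    return False


@njit(cache=True)
def simulate_chunk(sites, homs, indptr, sex, mod0, mod1, fitness,
                   have_fitness,
                   N, L, n_chroms, u, s, r, mode, a, b, k,
                   mod_dir, mod_site, r_e, suppress, T,
                   n_gens, seed, crash_patience,
                   rec_mean_n, rec_mean_w, rec_mod_freq):
    """Advance up to n_gens generations; see module docstring.

    Returns (sites, homs, indptr, sex, mod0, mod1, fitness, status,
    gens_recorded). Records are written for generations 0..gens_recorded-1 of
    this chunk (index 0 = entering population).
    """
    np.random.seed(seed)
    n_sites_total = n_chroms * L
    need_M = (b > 0.0 and k > 0.0) or (suppress and r_e > 0.0) or \
             (mode == MULTIPLICATIVE and b > 0.0)

    # fitness of the entering population (silencing draw + fitness only)
    if not have_fitness:
        for i in range(N):
            n_i = indptr[i + 1] - indptr[i]
            fitness[i] = _static_fitness(n_i, mode, s, b,
                                         _a_eff(a, mod_dir, mod0[i] + mod1[i]))

    status = COMPLETED
    gens_done = 0
    low_fitness_run = 0
    low_anchor_n = 0.0
    M_arr = np.zeros(0, dtype=np.int64)

    for gen in range(n_gens + 1):
        total = indptr[N]
        mean_n = total / N
        sum_w = 0.0
        for i in range(N):
            sum_w += fitness[i]
        mean_w = sum_w / N
        mods = 0
        for i in range(N):
            mods += mod0[i] + mod1[i]
        rec_mean_n[gen] = mean_n
        rec_mean_w[gen] = mean_w
        rec_mod_freq[gen] = mods / (2.0 * N)
        gens_done = gen + 1

        if total == 0:
            status = TE_LOSS
            break
        # crash = runaway accumulation: mean fitness *staying* below 0.1%
        # while copy number keeps growing. Selection acts on relative
        # fitness, so brief dips during the overshoot into equilibrium, or a
        # contained truncation-selection plateau with tiny absolute fitness,
        # are not a crash
        if mean_w < CRASH_MEAN_FITNESS:
            if low_fitness_run == 0:
                low_anchor_n = mean_n
            low_fitness_run += 1
            if low_fitness_run >= crash_patience:
                if mean_n > low_anchor_n * 1.05:
                    status = POPULATION_CRASH
                    break
                low_fitness_run = 0
        else:
            low_fitness_run = 0
        if gen == n_gens:
            status = COMPLETED
            break

        # --- parent sampling (fitness-weighted, within each sex) ---------
        n_f = 0
        n_m = 0
        for i in range(N):
            if sex[i] == 0:
                n_f += 1
            else:
                n_m += 1
        if n_f == 0 or n_m == 0:
            status = EXTINCT
            break
        f_idx = np.empty(n_f, dtype=np.int64)
        m_idx = np.empty(n_m, dtype=np.int64)
        f_cum = np.empty(n_f, dtype=np.float64)
        m_cum = np.empty(n_m, dtype=np.float64)
        fi = 0
        mi = 0
        facc = 0.0
        macc = 0.0
        for i in range(N):
            if sex[i] == 0:
                f_idx[fi] = i
                facc += fitness[i]
                f_cum[fi] = facc
                fi += 1
            else:
                m_idx[mi] = i
                macc += fitness[i]
                m_cum[mi] = macc
                mi += 1
        if facc <= 0.0 or macc <= 0.0:
            status = EXTINCT
            break

        # --- offspring construction -------------------------------------
        cur_max = 0
        for i in range(N):
            c_i = indptr[i + 1] - indptr[i]
            if c_i > cur_max:
                cur_max = c_i
        gam_buf_m = np.empty(cur_max, dtype=np.int64)
        gam_buf_p = np.empty(cur_max, dtype=np.int64)
        dup_buf = np.empty(2 * cur_max + 8, dtype=np.int64)  # encoded site*2+hom

        cap = total * 2 + 16 * N
        new_sites = np.empty(cap, dtype=np.int64)
        new_homs = np.empty(cap, dtype=np.uint8)
        new_indptr = np.empty(N + 1, dtype=np.int64)
        new_indptr[0] = 0
        new_sex = np.empty(N, dtype=np.uint8)
        new_mod0 = np.empty(N, dtype=np.uint8)
        new_mod1 = np.empty(N, dtype=np.uint8)
        new_fit = np.empty(N, dtype=np.float64)

        out = 0
        for child in range(N):
            # sample mother and father proportional to fitness
            x = np.random.random() * facc
            loa, hib = 0, n_f - 1
            while loa < hib:
                mid = (loa + hib) // 2
                if f_cum[mid] < x:
                    loa = mid + 1
                else:
                    hib = mid
            mom = f_idx[loa]
            x = np.random.random() * macc
            loa, hib = 0, n_m - 1
            while loa < hib:
                mid = (loa + hib) // 2
                if m_cum[mid] < x:
                    loa = mid + 1
                else:
                    hib = mid
            dad = m_idx[loa]

            gm, mod_m = _gamete(sites, homs, indptr[mom], indptr[mom + 1],
                                mod0[mom], mod1[mom], L, n_chroms, r,
                                mod_site, gam_buf_m)
            gp, mod_p = _gamete(sites, homs, indptr[dad], indptr[dad + 1],
                                mod0[dad], mod1[dad], L, n_chroms, r,
                                mod_site, gam_buf_p)
            n_pre = gm + gp

            copies = mod_m + mod_p
            aeff = _a_eff(a, mod_dir, copies)

            # ensure room: pre-copies + worst-case duplications (u <= 1)
            need = out + 2 * n_pre + 4
            if need > cap:
                newcap = cap * 2
                while newcap < need:
                    newcap *= 2
                tmp_s = np.empty(newcap, dtype=np.int64)
                tmp_h = np.empty(newcap, dtype=np.uint8)
                tmp_s[:out] = new_sites[:out]
                tmp_h[:out] = new_homs[:out]
                new_sites = tmp_s
                new_homs = tmp_h
                cap = newcap

            # merge gametes: maternal -> homolog 0, paternal -> homolog 1
            ia = 0
            ib = 0
            base = out
            while ia < gm or ib < gp:
                if ib >= gp or (ia < gm and gam_buf_m[ia] <= gam_buf_p[ib]):
                    new_sites[out] = gam_buf_m[ia]
                    new_homs[out] = 0
                    ia += 1
                else:
                    new_sites[out] = gam_buf_p[ib]
                    new_homs[out] = 1
                    ib += 1
                out += 1

            # --- silencing draw (offspring's own copies) -----------------
            lam = aeff * n_pre
            sum_M = 0
            if need_M and n_pre > 0:
                M_arr = np.empty(n_pre, dtype=np.int64)
                for j in range(n_pre):
                    M_arr[j] = np.random.poisson(lam)
                    sum_M += M_arr[j]

            # --- transposition ------------------------------------------
            d = 0
            if u > 0.0 and n_pre > 0:
                if need_M:
                    for j in range(n_pre):
                        uj = u * (1.0 - k * M_arr[j])
                        if uj > 0.0 and np.random.random() < uj:
                            d += 1
                elif k > 0.0:
                    d = np.random.binomial(n_pre, _mean_dup_prob(u, k, lam))
                else:
                    d = np.random.binomial(n_pre, u)
            if d > 0:
                if d > dup_buf.shape[0]:
                    dup_buf = np.empty(2 * d + 8, dtype=np.int64)
                dup = dup_buf[:d]  # encoded key: site * 2 + homolog
                for j in range(d):
                    while True:
                        cand = np.random.randint(0, n_sites_total)
                        ch = np.random.randint(0, 2)
                        if not _occupied(new_sites, new_homs, base, out,
                                         cand, np.uint8(ch)):
                            break
                    dup[j] = cand * 2 + ch
                # sort new copies and resolve (rare) collisions among them
                dup.sort()
                ok = False
                while not ok:
                    ok = True
                    for j in range(1, d):
                        if dup[j] == dup[j - 1]:
                            ok = False
                            while True:
                                cand = np.random.randint(0, n_sites_total)
                                ch = np.random.randint(0, 2)
                                if not _occupied(new_sites, new_homs, base,
                                                 out, cand, np.uint8(ch)):
                                    break
                            dup[j] = cand * 2 + ch
                    if not ok:
                        dup.sort()
                # merge duplications into the sorted genome (in place,
                # back-to-front)
                end = out + d
                ia = out - 1       # last pre-existing entry
                ib = d - 1
                w = end - 1
                if need_M:
                    M_new = np.zeros(n_pre + d, dtype=np.int64)
                else:
                    M_new = M_arr  # placeholder, never read
                while w >= base:
                    if ib < 0 or (ia >= base and new_sites[ia] > (dup[ib] >> 1)):
                        new_sites[w] = new_sites[ia]
                        new_homs[w] = new_homs[ia]
                        if need_M:
                            M_new[w - base] = M_arr[ia - base]
                        ia -= 1
                    else:
                        new_sites[w] = dup[ib] >> 1
                        new_homs[w] = np.uint8(dup[ib] & 1)
                        ib -= 1
                    w -= 1
                if need_M:
                    M_arr = M_new
                out = end
            n_post = n_pre + d

            # --- ectopic recombination (dominant lethal) ----------------
            viable = True
            if r_e > 0.0 and n_post > 1:
                h = 0
                j = base
                while j < out:
                    if j + 1 < out and new_sites[j + 1] == new_sites[j]:
                        j += 2  # homozygous site: both copies paired
                        continue
                    if suppress:
                        if M_arr[j - base] <= T:
                            h += 1
                    else:
                        h += 1
                    j += 1
                if h >= 2:  # an exchange needs a partner copy
                    p_inv = 1.0 - (1.0 - r_e) ** h
                    if np.random.random() < p_inv:
                        viable = False

            # --- fitness -------------------------------------------------
            if not viable:
                w_i = 0.0
            elif n_post == 0:
                w_i = 1.0
            elif mode == SYNERGISTIC:
                w_i = 1.0 - s * float(n_post) * float(n_post)
            elif mode == ADDITIVE:
                if b > 0.0:
                    if not need_M and n_pre > 0:
                        sum_M = np.random.poisson(lam * n_pre)
                    w_i = 1.0 - s * n_post - s * b * sum_M
                else:
                    w_i = 1.0 - s * n_post
            else:  # multiplicative
                if b > 0.0:
                    w_i = (1.0 - s) ** d
                    for j in range(n_pre):
                        f = 1.0 - s * (1.0 + b * M_arr[j])
                        w_i *= f if f > 0.0 else 0.0
                        if w_i <= 0.0:
                            break
                else:
                    w_i = (1.0 - s) ** n_post
            if w_i < 0.0:
                w_i = 0.0
            elif w_i > 1.0:
                w_i = 1.0

            new_indptr[child + 1] = out
            new_sex[child] = np.uint8(0 if np.random.random() < 0.5 else 1)
            new_mod0[child] = mod_m
            new_mod1[child] = mod_p
            new_fit[child] = w_i

        sites = new_sites[:out].copy()
        homs = new_homs[:out].copy()
        indptr = new_indptr
        sex = new_sex
        mod0 = new_mod0
        mod1 = new_mod1
        fitness = new_fit

    return sites, homs, indptr, sex, mod0, mod1, fitness, status, gens_done


@njit(cache=True, inline="always")
def _static_fitness(n_i, mode, s, b, aeff):
    """Fitness of a standing individual: silencing draw + fitness, no
    transposition/ectopic (used for founders entering a chunk)."""
    if n_i == 0:
        return 1.0
    if mode == SYNERGISTIC:
        w = 1.0 - s * float(n_i) * float(n_i)
    elif mode == ADDITIVE:
        if b > 0.0:
            sum_M = np.random.poisson(aeff * n_i * n_i)
            w = 1.0 - s * n_i - s * b * sum_M
        else:
            w = 1.0 - s * n_i
    else:
        if b > 0.0:
            w = 1.0
            for _ in range(n_i):
                m = np.random.poisson(aeff * n_i)
                f = 1.0 - s * (1.0 + b * m)
                w *= f if f > 0.0 else 0.0
        else:
            w = (1.0 - s) ** n_i
    if w < 0.0:
        return 0.0
    if w > 1.0:
        return 1.0
    return w


@njit(cache=True)
def init_population_packed(N, L, n_chroms, n0, seed):
    """Found N individuals with n0 copies each at distinct uniform sites."""
    np.random.seed(seed)
    n_sites_total = n_chroms * L
    sites = np.empty(N * n0, dtype=np.int64)
    homs = np.empty(N * n0, dtype=np.uint8)
    indptr = np.empty(N + 1, dtype=np.int64)
    indptr[0] = 0
    sex = np.empty(N, dtype=np.uint8)
    for i in range(N):
        base = i * n0
        for j in range(n0):
            while True:
                cand = np.random.randint(0, n_sites_total)
                dup = False
                for q in range(base, base + j):
                    if sites[q] == cand:
                        dup = True
                        break
                if not dup:
                    break
            sites[base + j] = cand
            homs[base + j] = np.uint8(np.random.randint(0, 2))
        seg = sites[base:base + n0]
        order = np.argsort(seg)
        sites[base:base + n0] = seg[order]
        homs[base:base + n0] = homs[base:base + n0][order]
        indptr[i + 1] = base + n0
        sex[i] = np.uint8(0 if np.random.random() < 0.5 else 1)
    # guarantee both sexes exist (N >= 2)
    all_same = True
    for i in range(1, N):
        if sex[i] != sex[0]:
            all_same = False
            break
    if all_same:
        sex[N - 1] = np.uint8(1 - sex[0])
    return sites, homs, indptr, sex
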