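"""Jit-compiled generation loop.

One replicate of the conflict-with-decoy life cycle runs entirely inside a
single compiled function so that full-size populations (N = 10,000 for
15,000 generations) complete in tens of seconds.  The algebra duplicates
:mod:`decoysim.conflict_model` exactly; the slower, stage-by-stage NumPy
implementation in :mod:`decoysim.population` is the readable reference and
the two are cross-checked in the test suite.

Three exact optimizations keep the inner loops cheap:

* allelic sums are integers on ``0 .. 2*allele_max``, so each generation
  the mating rate is evaluated once per occupied (female, decoy) x (male)
  phenotype class and encounters index the resulting table;
* random numbers come from an inlined PCG32 generator (the same family as
  NumPy's default bit generator), far cheaper per draw than calling out to
  a generator object;
* mutations are rare (``mu`` ~ 5e-5), so the Bernoulli process over the 8N
  transmitted alleles is sampled by geometric gap-skipping, which is
  distribution-exact and O(number of mutations).

``decoy_mode`` selects the code path: 1 evaluates the full three-locus
model, 2 runs the same three-locus path with decoy activity clamped to
zero, and 0 is the plain two-locus conflict whose rate computation never
consults the decoy.  All paths consume random numbers identically, so a
clamped run is bit-identical to the two-locus path under the same seed.
"""

import numpy as np
from numba import njit

__all__ = ["run_replicate_compiled"]

_U64 = np.uint64
_PCG_MULT = _U64(6364136223846793005)
_PCG_INC = _U64(1442695040888963407)
_INV_2_32 = 1.0 / 4294967296.0


@njit(cache=True, inline="always")
def _pcg_next(state):
    # PCG32 (XSH-RR): 64-bit LCG state, 32-bit output
    state = state * _PCG_MULT + _PCG_INC
    xorshifted = np.uint32(((state >> _U64(18)) ^ state) >> _U64(27))
    rot = np.uint32(state >> _U64(59))
    out = np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31)))
    )
    return state, out


@njit(cache=True, inline="always")
def _pcg_seed(seed):
    state = _U64(0)
    state, _ = _pcg_next(state)
    state = state + _U64(seed)
    state, _ = _pcg_next(state)
    return state


@njit(cache=True, inline="always")
def _rand_f(state):
    # uniform on [0, 1) with 2^-32 resolution
    state, out = _pcg_next(state)
    return state, out * _INV_2_32


@njit(cache=True, inline="always")
def _rand_below(state, n):
    # uniform integer on [0, n) (multiply-shift; bias < n / 2^32)
    state, out = _pcg_next(state)
    return state, np.int64((_U64(out) * _U64(n)) >> _U64(32))


@njit(cache=True)
def _class_rate(sf, sd, sm, norm_div, P_opt, s_p, x_p, si, xi, sd_, xd, c0, D_opt, decoy_mode):
    # mating rate for one (female-sum, decoy-sum, male-sum) phenotype class
    zf = sf / (2.0 * norm_div)
    zm = sm / (2.0 * norm_div)
    d = abs(zm - zf)
    P = np.exp(-((d / s_p) ** x_p))
    if decoy_mode == 0:
        return P
    zd = sd / (2.0 * norm_div)
    lo = min(zm, zf)
    hi = max(zm, zf)
    theta = 1 if (lo < zd < hi) else 0
    if decoy_mode == 2:
        theta = 0
    if theta == 0:
        return P
    dev = abs(d - D_opt)
    pdev = (dev / sd_) ** xd
    if pdev > 1.0:
        pdev = 1.0
    q = 1.0 - ((abs(zf - zd) / d) / si) ** xi
    if q < 0.0:
        q = 0.0
    pi = c0 * q + pdev
    cap = pdev + c0
    if cap > 1.0:
        cap = 1.0
    if pi > cap:
        pi = cap
    Pm = min(P, P_opt) - P_opt * pi
    if Pm < 0.0:
        Pm = 0.0
    return Pm


@njit(cache=True)
def _run_replicate(
    seed,
    n_gen,
    N,
    n_enc,
    mu,
    jump_prob,
    allele_max,
    init_alleles,
    P_opt,
    B_max,
    s_w,
    x_w,
    s_p,
    x_p,
    si,
    xi,
    sd,
    xd,
    c0,
    D_opt,
    norm_div,
    decoy_mode,
):
    rs = _pcg_seed(seed)
    F = N // 2
    M = N - F
    KS = 2 * allele_max + 1  # allelic sums live on 0 .. 2*allele_max

    alleles = np.empty((N, 4, 2), np.int64)
    for i in range(N):
        for l in range(4):
            alleles[i, l, 0] = init_alleles[l]
            alleles[i, l, 1] = init_alleles[l]
    new_alleles = np.empty_like(alleles)

    traj = np.zeros((n_gen + 1, 4))
    mean_rate = np.zeros(n_gen)
    for l in range(4):
        traj[0, l] = alleles[:, l, :].mean()

    mates = np.empty((F, n_enc), np.int64)
    n_mates = np.empty(F, np.int64)
    W = np.empty(F)

    # phenotype-class machinery (generation-stamped, allocated once)
    stamp_f = np.full(KS * KS, -1, np.int64)
    id_f = np.empty(KS * KS, np.int64)
    stamp_m = np.full(KS, -1, np.int64)
    id_m = np.empty(KS, np.int64)
    fc_sf = np.empty(F, np.int64)
    fc_sd = np.empty(F, np.int64)
    mc_sm = np.empty(KS, np.int64)
    cf = np.empty(F, np.int64)
    cmale = np.empty(M, np.int64)
    Pmat = np.empty((F, KS))

    # fecundity of a mated female depends only on her mating count
    W_of_count = np.empty(n_enc + 1)
    W_of_count[0] = 0.0
    for k in range(1, n_enc + 1):
        r = k / n_enc
        W_of_count[k] = B_max * np.exp(-((abs(r - P_opt) / s_w) ** x_w))

    log1m_mu = np.log(1.0 - mu) if 0.0 < mu < 1.0 else 0.0

    for g in range(n_gen):
        # register occupied phenotype classes
        n_fc = 0
        for i in range(F):
            key = (alleles[i, 1, 0] + alleles[i, 1, 1]) * KS + (
                alleles[i, 2, 0] + alleles[i, 2, 1]
            )
            if stamp_f[key] != g:
                stamp_f[key] = g
                id_f[key] = n_fc
                fc_sf[n_fc] = key // KS
                fc_sd[n_fc] = key % KS
                n_fc += 1
            cf[i] = id_f[key]
        n_mc = 0
        for j in range(M):
            key = alleles[F + j, 0, 0] + alleles[F + j, 0, 1]
            if stamp_m[key] != g:
                stamp_m[key] = g
                id_m[key] = n_mc
                mc_sm[n_mc] = key
                n_mc += 1
            cmale[j] = id_m[key]
        for a in range(n_fc):
            for b in range(n_mc):
                Pmat[a, b] = _class_rate(
                    fc_sf[a], fc_sd[a], mc_sm[b], norm_div,
                    P_opt, s_p, x_p, si, xi, sd, xd, c0, D_opt, decoy_mode,
                )

        # encounters and mating
        total_matings = 0
        wtot = 0.0
        for i in range(F):
            k = 0
            row = Pmat[cf[i]]
            for e in range(n_enc):
                rs, j = _rand_below(rs, M)
                rs, u = _rand_f(rs)
                if u < row[cmale[j]]:
                    mates[i, k] = j
                    k += 1
            n_mates[i] = k
            total_matings += k
            W[i] = W_of_count[k]
            wtot += W[i]
        mean_rate[g] = total_matings / (F * n_enc)

        if wtot <= 0.0:
            return traj[: g + 1], mean_rate[:g], -1

        # reproduction: mothers ~ fecundity, sires uniform over mate multiset
        cw = np.cumsum(W)
        for o in range(N):
            rs, u = _rand_f(rs)
            m = np.searchsorted(cw, u * wtot)
            if m >= F:
                m = F - 1
            while W[m] == 0.0 and m < F - 1:
                # u landed exactly on a boundary shared with a zero-weight
                # female (possible at the generator's resolution)
                m += 1
            rs, pick = _rand_below(rs, n_mates[m])
            sire = F + mates[m, pick]
            rs, bits = _rand_below(rs, 256)
            for l in range(4):
                new_alleles[o, l, 0] = alleles[m, l, (bits >> (2 * l)) & 1]
                new_alleles[o, l, 1] = alleles[sire, l, (bits >> (2 * l + 1)) & 1]

        # mutation: exact Bernoulli(mu) process over the 8N transmitted
        # alleles, sampled by geometric gap-skipping; a mutation is a +-1
        # step (reflecting at the boundaries) or, with probability
        # jump_prob, a large-effect change to a uniform random allele
        if mu >= 1.0:
            for idx in range(8 * N):
                o = idx >> 3
                l = (idx >> 1) & 3
                c = idx & 1
                rs, u = _rand_f(rs)
                if u < jump_prob:
                    # large-effect step: magnitude uniform on 2..4
                    rs, mag = _rand_below(rs, 3)
                    step = (mag + 2) if u < 0.5 * jump_prob else -(mag + 2)
                else:
                    step = 1 if u < jump_prob + 0.5 * (1.0 - jump_prob) else -1
                a1 = new_alleles[o, l, c] + step
                if a1 < 0:
                    a1 = -a1
                elif a1 > allele_max:
                    a1 = 2 * allele_max - a1
                new_alleles[o, l, c] = a1
        elif mu > 0.0:
            idx = -1
            while True:
                rs, u = _rand_f(rs)
                idx += 1 + np.int64(np.log(1.0 - u) / log1m_mu)
                if idx >= 8 * N:
                    break
                o = idx >> 3
                l = (idx >> 1) & 3
                c = idx & 1
                rs, u = _rand_f(rs)
                if u < jump_prob:
                    # large-effect step: magnitude uniform on 2..4
                    rs, mag = _rand_below(rs, 3)
                    step = (mag + 2) if u < 0.5 * jump_prob else -(mag + 2)
                else:
                    step = 1 if u < jump_prob + 0.5 * (1.0 - jump_prob) else -1
                a1 = new_alleles[o, l, c] + step
                if a1 < 0:
                    a1 = -a1
                elif a1 > allele_max:
                    a1 = 2 * allele_max - a1
                new_alleles[o, l, c] = a1

        tmp = alleles
        alleles = new_alleles
        new_alleles = tmp
        for l in range(4):
            traj[g + 1, l] = alleles[:, l, :].mean()

    return traj, mean_rate, 0


def run_replicate_compiled(seed, config, params, decoy_mode):
    """Run one replicate through the compiled loop.

    ``decoy_mode``: 1 full model, 2 decoy clamped inactive, 0 two-locus
    code path.  Returns (trajectory array (G+1, 4), per-generation mean
    realized mating rate, status flag: 0 ok, -1 aborted with no mated
    female).
    """
    init = np.array(
        [
            config.initial_alleles["male"],
            config.initial_alleles["female"],
            config.initial_alleles["decoy"],
            config.initial_alleles["neutral"],
        ],
        dtype=np.int64,
    )
    norm_div = float(params.allele_max) if params.normalize else 1.0
    return _run_replicate(
        int(seed),
        int(config.generations),
        int(config.N),
        int(config.n_encounters),
        float(config.mu),
        float(config.jump_prob),
        int(params.allele_max),
        init,
        float(params.P_opt),
        float(params.B_max),
        float(params.s_w),
        float(params.x_w),
        float(params.s_p),
        float(params.x_p),
        float(params.si),
        float(params.xi),
        float(params.sd),
        float(params.xd),
        float(params.c0),
        float(params.D_opt),
        norm_div,
        int(decoy_mode),
    )
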