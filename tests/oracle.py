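"""Naive loop-based re-implementation of the simulator used as a test oracle.

Everything here is written with explicit Python loops and sets, independent
of the vectorized library code paths, but follows the same documented RNG
protocol (substream spawning and array-draw layout) so that a whole run can
be compared with the library bit for bit.
"""

from __future__ import annotations

import numpy as np


def naive_express(genome, target, P_e):
    """Set-union expression of one genome."""
    present = set()
    for locus, allele in enumerate(genome):
        present.add(int(target[locus, int(allele)]))
    return np.array([k in present for k in range(P_e)])


def naive_develop(elements, C):
    """Prefix scan: count leading all-present blocks of C elements."""
    f = len(elements) // C
    n = 0
    for j in range(f):
        if all(bool(e) for e in elements[j * C:(j + 1) * C]):
            n += 1
        else:
            break
    return n


def _naive_develop_and_learn(genomes, target, params, rng):
    N, P_e, C, f = params.N, params.P_e, params.C, params.f
    inherited = np.array([naive_express(genomes[i], target, P_e)
                          for i in range(N)])
    n_inh = np.array([naive_develop(inherited[i], C) for i in range(N)])
    plastic = np.zeros_like(inherited)
    n_tot = n_inh.copy()
    for _ in range(params.t):
        u = rng.random(N)
        for i in range(N):
            if n_tot[i] >= f:
                continue
            block = range(n_tot[i] * C, (n_tot[i] + 1) * C)
            missing = [k for k in block if not (inherited[i, k] or plastic[i, k])]
            if u[i] < params.p_e ** len(missing):
                for k in missing:
                    plastic[i, k] = True
                n_tot[i] = naive_develop(inherited[i] | plastic[i], C)
    return inherited, plastic, n_inh, n_tot


def naive_run_simulation(params, seed):
    """Full run with per-individual loops; mirrors the library RNG protocol.

    Returns (records, genomes) where records is a list of per-generation
    (generation, max_inherited, mean_inherited, max_total, mean_total)
    tuples and genomes the final genome matrix.
    """
    root = np.random.SeedSequence(seed)
    map_ss, init_ss, evo_ss = root.spawn(3)
    target = np.random.default_rng(map_ss).integers(
        0, params.P_e, size=(params.L, params.A))
    genomes = np.random.default_rng(init_ss).integers(
        0, params.A, size=(params.N, params.L))

    records = []

    def record(gen, n_inh, n_tot):
        records.append((gen, int(max(n_inh)), float(np.mean(n_inh)),
                        int(max(n_tot)), float(np.mean(n_tot))))

    rng = np.random.default_rng(evo_ss.spawn(1)[0])
    inherited, plastic, n_inh, n_tot = _naive_develop_and_learn(
        genomes, target, params, rng)
    record(0, n_inh, n_tot)

    N, L, A = params.N, params.L, params.A
    for gen in range(1, params.n_g + 1):
        rng = np.random.default_rng(evo_ss.spawn(1)[0])
        fitness = [int(v) for v in n_tot]
        maxf = max(fitness)
        parents = []
        for _ in range(N):
            if maxf == 0:
                parents.append(int(rng.integers(N)))
                continue
            while True:
                i = int(rng.integers(N))
                u = rng.random()
                if u * maxf < fitness[i]:
                    parents.append(i)
                    break
        new_genomes = np.array([genomes[p].copy() for p in parents])
        if params.mu > 0.0 and A > 1:
            mask = rng.random((N, L)) < params.mu
            shifts = rng.integers(1, A, size=int(mask.sum()))
            pos = 0
            for i in range(N):
                for locus in range(L):
                    if mask[i, locus]:
                        new_genomes[i, locus] = (new_genomes[i, locus]
                                                 + shifts[pos]) % A
                        pos += 1
        genomes = new_genomes
        inherited, plastic, n_inh, n_tot = _naive_develop_and_learn(
            genomes, target, params, rng)
        record(gen, n_inh, n_tot)
    return records, genomes
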