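"""Empirical fitness landscapes over binary genotypes.

A landscape maps binary genotype strings (one bit per mutated locus, the
all-zeros string being wild type) to relative fitness.  Neighbours differ at
a single locus (Hamming distance 1).  The module locates strict local and
global optima, enumerates selectively accessible mutational paths (fitness
strictly increasing at every step), and integrates deterministic
replicator-mutation dynamics — the infinite-population limit appropriate to
a chemostat population of ~2e9 cells, where drift is negligible for the
genotype frequencies of interest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitnessLandscape",
    "OptimaReport",
    "build_landscape",
    "local_optima",
    "accessible_paths",
    "selection_dynamics",
]

_MAX_LOCI = 20


@dataclass(frozen=True)
class FitnessLandscape:
    loci: tuple[str, ...]
    fitness: dict  # genotype string -> relative fitness
    missing: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return len(self.missing) == 0

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(sorted(self.fitness))

    def neighbors(self, genotype: str):
        for i in range(len(genotype)):
            flipped = genotype[:i] + ("1" if genotype[i] == "0" else "0") + genotype[i + 1 :]
            if flipped in self.fitness:
                yield flipped


@dataclass(frozen=True)
class OptimaReport:
    local_optima: frozenset
    global_optimum: str
    ties: tuple[tuple[str, str], ...]  # neighbour pairs with exactly equal fitness


def build_landscape(table) -> FitnessLandscape:
    """Validate a genotype->fitness table into a FitnessLandscape.

    ``table`` is a DataFrame with columns ``genotype`` and ``fitness`` (or
    any iterable of such pairs).  Genotype strings must share one length and
    be over {0,1}; duplicates with conflicting fitness are rejected; missing
    genotypes are allowed but flagged.  Locus labels may be given in a
    ``loci`` attribute column-wise; defaults are L0, L1, ...
    """
    if isinstance(table, pd.DataFrame):
        pairs = list(zip(table["genotype"].astype(str), table["fitness"].astype(float)))
    else:
        pairs = [(str(g), float(w)) for g, w in table]
    if not pairs:
        raise ValueError("empty genotype-fitness table")
    length = len(pairs[0][0])
    fitness: dict[str, float] = {}
    for g, w in pairs:
        if len(g) != length or set(g) - {"0", "1"}:
            raise ValueError(f"genotype {g!r}: expected a binary string of length {length}")
        if w <= 0:
            raise ValueError(f"genotype {g!r}: fitness must be positive, got {w}")
        if g in fitness and fitness[g] != w:
            raise ValueError(f"duplicate genotype {g!r} with conflicting fitness")
        fitness[g] = w
    if length > _MAX_LOCI:
        raise ValueError(f"more than {_MAX_LOCI} loci not supported")
    wild_type = "0" * length
    if wild_type not in fitness:
        raise ValueError("the wild-type (all-zeros) genotype must be present")
    all_genotypes = ("".join(bits) for bits in itertools.product("01", repeat=length))
    missing = tuple(g for g in all_genotypes if g not in fitness)
    loci = tuple(f"L{i}" for i in range(length))
    return FitnessLandscape(loci=loci, fitness=fitness, missing=missing)


def local_optima(ls: FitnessLandscape) -> OptimaReport:
    """Strict local optima, the global optimum, and any exact neighbour ties.

    A genotype is a local optimum iff it is strictly fitter than every
    Hamming-1 neighbour; a genotype exactly tied with a neighbour is not a
    strict optimum and the tie is reported rather than silently broken.
    """
    if not ls.complete:
        raise ValueError("local optima require a complete landscape")
    optima = set()
    ties = []
    for g in ls.genotypes:
        wg = ls.fitness[g]
        strict = True
        for h in ls.neighbors(g):
            if ls.fitness[h] == wg and g < h:
                ties.append((g, h))
            if ls.fitness[h] >= wg:
                strict = False
        if strict:
            optima.add(g)
    global_opt = max(ls.genotypes, key=lambda g: ls.fitness[g])
    return OptimaReport(
        local_optima=frozenset(optima), global_optimum=global_opt, ties=tuple(ties)
    )


def accessible_paths(
    ls: FitnessLandscape, start: str, end: str, geodesic: bool = True
) -> tuple[int, list[list[str]]]:
    """Count and list selectively accessible paths from ``start`` to ``end``.

    A path is accessible when fitness strictly increases at every mutational
    step.  With ``geodesic=True`` (default) only shortest paths are
    considered: each step flips one of the loci at which start and end
    differ, so path length equals the Hamming distance.  With
    ``geodesic=False`` any non-revisiting monotone walk through the
    landscape counts.  ``start == end`` yields the single empty path.
    """
    for g in (start, end):
        if g not in ls.fitness:
            raise ValueError(f"genotype {g!r} not in landscape")
    if start == end:
        return 1, [[start]]
    paths: list[list[str]] = []
    if geodesic:
        differing = [i for i, (a, b) in enumerate(zip(start, end)) if a != b]
        for order in itertools.permutations(differing):
            path = [start]
            current = start
            ok = True
            for i in order:
                nxt = current[:i] + end[i] + current[i + 1 :]
                if nxt not in ls.fitness or ls.fitness[nxt] <= ls.fitness[current]:
                    ok = False
                    break
                path.append(nxt)
                current = nxt
            if ok:
                paths.append(path)
    else:
        def walk(path: list[str]) -> None:
            current = path[-1]
            if current == end:
                paths.append(list(path))
                return
            for h in ls.neighbors(current):
                if h not in path and ls.fitness[h] > ls.fitness[current]:
                    path.append(h)
                    walk(path)
                    path.pop()

        walk([start])
    return len(paths), paths


def selection_dynamics(
    ls: FitnessLandscape,
    mu: float,
    init: dict | np.ndarray,
    n_generations: int,
) -> pd.DataFrame:
    """Deterministic replicator-mutation dynamics on the landscape.

    Per discrete generation each genotype frequency is weighted by its
    fitness and renormalised by the population mean fitness, then mutation
    moves probability mass ``mu`` per locus to each Hamming-1 neighbour.
    Returns a DataFrame indexed by generation (0..n_generations) with one
    column per genotype; frequencies sum to one at every step.
    """
    if not ls.complete:
        raise ValueError("dynamics require a complete landscape")
    genotypes = list(ls.genotypes)
    n_loci = len(ls.loci)
    if not (0.0 <= mu <= 0.5):
        raise ValueError("mu must be in [0, 0.5]")
    if mu * n_loci > 1.0:
        raise ValueError(f"mu too large: {n_loci} loci lose {mu * n_loci:.3g} > 1 mass")
    idx = {g: k for k, g in enumerate(genotypes)}
    w = np.array([ls.fitness[g] for g in genotypes])
    if isinstance(init, dict):
        f = np.zeros(len(genotypes))
        for g, v in init.items():
            f[idx[g]] = v
    else:
        f = np.asarray(init, dtype=float).copy()
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValueError("initial frequencies must be non-negative and sum to 1")
    f = f / f.sum()

    # sparse mutation structure: list of neighbour index arrays
    nbr = [np.array([idx[h] for h in ls.neighbors(g)]) for g in genotypes]

    out = np.empty((n_generations + 1, len(genotypes)))
    out[0] = f
    for t in range(1, n_generations + 1):
        sel = f * w
        sel /= sel.sum()
        g_next = sel * (1.0 - mu * n_loci)
        if mu > 0:
            for k, neighbours in enumerate(nbr):
                g_next[k] += mu * sel[neighbours].sum()
        assert np.all(g_next >= 0), "negative frequency: internal error"
        assert np.isclose(g_next.sum(), 1.0), "frequency mass not conserved"
        f = g_next / g_next.sum()
        out[t] = f
    return pd.DataFrame(out, columns=genotypes, index=pd.RangeIndex(n_generations + 1, name="generation"))
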