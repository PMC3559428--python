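"""Shared test utilities: independent oracles kept free of package internals.

The alignment oracle enumerates every global alignment explicitly; the tree
generator builds random additive distance matrices directly from random
topologies. Neither reuses the code paths they are meant to check.
"""

from __future__ import annotations

import numpy as np

from piezocomp.align import ScoringScheme
from piezocomp.alphabet import AA_INDEX, DEFAULT_AA_FREQS
from piezocomp.simulate import SimulationConfig


def brute_force_best_score(seq_a: str, seq_b: str, scoring: ScoringScheme) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    Recursively enumerates all alignment operation sequences (match/mismatch,
    gap in A, gap in B), scoring gap runs as open + extend * length, end gaps
    included. Exponential — only for sequences of length <= 8.
    """
    bio_mat = scoring.substitution_matrix()
    mat = {
        (x, y): float(bio_mat[x, y])
        for x in bio_mat.alphabet
        for y in bio_mat.alphabet
    }
    open_cost = scoring.gap_open + scoring.gap_extend
    ext_cost = scoring.gap_extend
    la, lb = len(seq_a), len(seq_b)
    best = [-np.inf]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == la and j == lb:
            if score > best[0]:
                best[0] = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, "M", score + mat[seq_a[i], seq_b[j]])
        if i < la:
            rec(i + 1, j, "D", score - (ext_cost if prev == "D" else open_cost))
        if j < lb:
            rec(i, j + 1, "I", score - (ext_cost if prev == "I" else open_cost))

    rec(0, 0, "", 0.0)
    return float(best[0])


def random_additive_tree(
    rng: np.random.Generator, n_taxa: int
) -> tuple[str, list[str], np.ndarray]:
    """Random binary tree with random branch lengths and its exact
    leaf-to-leaf path-length matrix.

    Returns (newick, labels, distance matrix). Distances are accumulated
    during random pairwise joining, independently of any tree class.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    index = {name: i for i, name in enumerate(labels)}
    d = np.zeros((n_taxa, n_taxa))
    # cluster: (newick fragment, {leaf: distance to cluster root})
    clusters: list[tuple[str, dict[str, float]]] = [
        (name, {name: 0.0}) for name in labels
    ]
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, da), (nb, db) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for x, vx in da.items():
            for y, vy in db.items():
                d[index[x], index[y]] = d[index[y], index[x]] = vx + la + vy + lb
        merged = {x: v + la for x, v in da.items()}
        merged.update({y: v + lb for y, v in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((f"({na}:{la:.10g},{nb}:{lb:.10g})", merged))
    (na, da), (nb, db) = clusters
    lab = rng.uniform(0.1, 1.0)
    for x, vx in da.items():
        for y, vy in db.items():
            d[index[x], index[y]] = d[index[y], index[x]] = vx + lab + vy
    newick = f"({na}:{lab:.10g},{nb}:0);"
    return newick, labels, d


def kr_power_config(
    seed: int,
    target_sum: float = 4000.0,
    ratio: float = 1.37,
    sub_rate: float = 0.2,
    length: float = 300.0,
) -> SimulationConfig:
    """Simulation sized so the K/R exchange has x+y ~ target_sum, x/y ~ ratio.

    Under the generator's equal-input exchange model with a K→R bias
    multiplier m, the expected directed counts over N sites are
    x = N c pi_K pi_R m (1 - pi_K) / D_K with
    D_K = (1 - pi_K) + (m - 1) pi_R, and y = N c pi_K pi_R, where
    c = sub_rate / (1 - sum(pi^2)) (the unbiased R row's normalisation
    cancels its leave probability exactly). Solving x/y = ratio for m and
    x + y = target_sum for N gives the configuration.
    """
    pi = DEFAULT_AA_FREQS
    f_k = pi[AA_INDEX["K"]]
    f_r = pi[AA_INDEX["R"]]
    mult = ratio * (1.0 - f_k - f_r) / (1.0 - f_k - ratio * f_r)
    c = sub_rate / (1.0 - float(np.sum(pi**2)))
    d_k = (1.0 - f_k) + (mult - 1.0) * f_r
    per_site = c * f_k * f_r * (mult * (1.0 - f_k) / d_k + 1.0)
    n_proteins = int(round(target_sum / per_site / length))
    return SimulationConfig(
        n_proteins=n_proteins,
        length_mean=length,
        length_sd=0.0,
        sub_rate=sub_rate,
        bias_pairs={("K", "R"): mult},
        seed=seed,
    )


def shifted_composition(factor_up: float = 1.15) -> np.ndarray:
    """A piezophile-like composition: A,R,H,T up, D,E,K,N down, renormalised."""
    comp = DEFAULT_AA_FREQS.copy()
    for aa in "ARHT":
        comp[AA_INDEX[aa]] *= factor_up
    for aa in "DEKN":
        comp[AA_INDEX[aa]] /= factor_up
    return comp / comp.sum()
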