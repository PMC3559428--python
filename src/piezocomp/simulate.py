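"""Synthetic data generators with recorded ground truth.

Three generators feed the downstream stages so the whole pipeline can be
exercised, and its parameter recovery measured, without external genomes:

* :func:`simulate_ortholog_proteomes` — a pair of proteomes diverged from a
  common ancestor under a single-hit, optionally direction-biased residue
  substitution process, with single-residue indels, diverged paralog copies
  and unpaired orphan genes.
* :func:`simulate_cds_set` — coding nucleotide sequences with a target GC3
  (third-codon-position G+C fraction).
* :func:`simulate_spot_table` — two-condition gel spot-volume tables with
  planted fold changes and multiplicative log-normal noise.

Every generator is driven by a single integer seed and is deterministic:
identical configuration and seed give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AA_ORDER, DEFAULT_AA_FREQS, UNIFORM_AA_FREQS, decode

Proteome = dict[str, str]
CdsSet = dict[str, str]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the ortholog-pair simulator.

    Parameters
    ----------
    n_proteins:
        Number of ancestral (hence orthologous) genes.
    length_mean, length_sd:
        Protein length distribution (residues, normal, floored at 10).
    sub_rate:
        Per-site substitution probability (single hit, no back substitution).
    bias_pairs:
        Map from ordered residue pair ``(a, b)`` to a directional weight
        multiplier >= 1 applied when a substituted site with state ``a``
        chooses target ``b``. The base exchange process is an equal-input
        model in detailed balance with the ancestral composition, so its
        expected directed counts are symmetric; bias multipliers break
        that symmetry for the listed ordered pairs only.
    indel_rate:
        Per-site probability of a single-residue indel in the descendant
        (split evenly between insertion and deletion).
    paralog_fraction:
        Fraction of genes duplicated in proteome B as diverged copies
        (three-fold substitution rate), to exercise best-hit tie handling.
    orphan_fraction:
        Fraction of additional unpaired genes added to each proteome.
    composition:
        Ancestral residue composition; ``"swissprot"`` (default, average
        frequencies of a large curated proteome collection) or ``"uniform"``.
    seed:
        Integer seed for all randomness.
    """

    n_proteins: int
    length_mean: float = 300.0
    length_sd: float = 60.0
    sub_rate: float = 0.2
    bias_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    indel_rate: float = 0.0
    paralog_fraction: float = 0.0
    orphan_fraction: float = 0.0
    composition: str = "swissprot"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("length_mean", "length_sd", "sub_rate", "indel_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate is a per-site probability in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate is a per-site probability in [0, 1]")
        for name in ("paralog_fraction", "orphan_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for (a, b), mult in self.bias_pairs.items():
            if a not in AA_INDEX or b not in AA_INDEX or a == b:
                raise ValueError(f"invalid bias pair ({a!r}, {b!r})")
            if not math.isfinite(mult) or mult < 1.0:
                raise ValueError(f"bias multiplier for ({a},{b}) must be finite and >= 1")
        if self.composition not in ("swissprot", "uniform"):
            raise ValueError("composition must be 'swissprot' or 'uniform'")

    @property
    def ancestral_frequencies(self) -> np.ndarray:
        if self.composition == "uniform":
            return UNIFORM_AA_FREQS.copy()
        return DEFAULT_AA_FREQS.copy()


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`simulate_ortholog_proteomes`.

    Substitution events are stored as parallel arrays (pair index, ancestor
    position, source residue index, target residue index); indel events as a
    list of ``(pair_id, kind, ancestor_position)`` with kind ``"ins"``/``"del"``.
    ``directed_counts[a, b]`` is the number of injected a→b substitutions in
    the A→B reading direction (A carries the ancestral state).
    """

    ortholog_map: list[tuple[str, str]]
    sub_pair_index: np.ndarray
    sub_position: np.ndarray
    sub_from: np.ndarray
    sub_to: np.ndarray
    directed_counts: np.ndarray
    indels: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return int(self.sub_position.size)

    def substitutions_frame(self) -> pd.DataFrame:
        """Event log as a tidy table (pair_id, residue_from, residue_to, position)."""
        pair_ids = np.array([a for a, _ in self.ortholog_map], dtype=object)
        return pd.DataFrame(
            {
                "pair_id": pair_ids[self.sub_pair_index],
                "residue_from": [AA_ORDER[i] for i in self.sub_from],
                "residue_to": [AA_ORDER[i] for i in self.sub_to],
                "position": self.sub_position,
            }
        )

    def directed_count(self, a: str, b: str) -> int:
        """Number of injected a→b substitutions (A-state a, B-state b)."""
        return int(self.directed_counts[AA_INDEX[a], AA_INDEX[b]])


def _sample_residues(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """Draw n residue indices from a composition via inverse-CDF sampling."""
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.int8)


def _target_matrix(
    bias_pairs: dict[tuple[str, str], float], freqs: np.ndarray
) -> np.ndarray:
    """Row-stochastic 20x20 target-choice matrix with zero diagonal.

    The base process is an equal-input (composition-driven) exchange: the
    target weight of b from source a is the equilibrium frequency pi_b,
    multiplied by the configured directional bias for listed pairs, then
    normalised per source row. Together with the state-dependent leave
    probabilities of :func:`_leave_probabilities` this satisfies detailed
    balance, so without bias the expected directed count matrix over
    ancestor-composition sites is symmetric.
    """
    w = np.tile(freqs, (20, 1))
    np.fill_diagonal(w, 0.0)
    for (a, b), mult in bias_pairs.items():
        w[AA_INDEX[a], AA_INDEX[b]] *= mult
    return w / w.sum(axis=1, keepdims=True)


def _leave_probabilities(sub_rate: float, freqs: np.ndarray) -> np.ndarray:
    """Per-state substitution probability p_a = c (1 - pi_a).

    The constant c is set so the composition-averaged per-site substitution
    probability equals ``sub_rate`` (probabilities are capped at 1, so
    rates near 1 saturate slightly below the nominal value).
    """
    c = sub_rate / (1.0 - float(np.sum(freqs**2)))
    return np.minimum(1.0, c * (1.0 - freqs))


def _mutate(
    rng: np.random.Generator,
    ancestor: np.ndarray,
    sub_rate: float,
    targets: np.ndarray,
    freqs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply single-hit substitutions; return (descendant, substituted mask)."""
    leave = _leave_probabilities(sub_rate, freqs)
    mask = rng.random(ancestor.size) < leave[ancestor.astype(np.intp)]
    desc = ancestor.copy()
    cdf = np.cumsum(targets, axis=1)
    cdf[:, -1] = 1.0
    idx = np.nonzero(mask)[0]
    if idx.size:
        u = rng.random(idx.size)
        rows = cdf[ancestor[idx].astype(np.intp)]
        desc[idx] = (rows < u[:, None]).sum(axis=1).astype(np.int8)
    return desc, mask


def simulate_ortholog_proteomes(
    config: SimulationConfig,
) -> tuple[Proteome, Proteome, SyntheticTruth]:
    """Simulate an orthologous proteome pair with recorded ground truth.

    Proteome A carries the ancestral sequences; proteome B is the diverged
    descendant. Substitutions are applied independently per site with a
    single hit, so the event log equals the site-wise differences between A
    and B at non-indel positions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    freqs = cfg.ancestral_frequencies
    targets = _target_matrix(cfg.bias_pairs, freqs)

    lengths = np.maximum(
        10, np.rint(rng.normal(cfg.length_mean, cfg.length_sd, cfg.n_proteins)).astype(int)
    )
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    ancestor = _sample_residues(rng, freqs, total)
    descendant, sub_mask = _mutate(rng, ancestor, cfg.sub_rate, targets, freqs)

    sub_idx = np.nonzero(sub_mask)[0]
    sub_pair = np.searchsorted(offsets, sub_idx, side="right") - 1
    sub_pos = sub_idx - offsets[sub_pair]
    sub_from = ancestor[sub_idx]
    sub_to = descendant[sub_idx]
    directed = np.zeros((20, 20), dtype=np.int64)
    if sub_idx.size:
        np.add.at(directed, (sub_from.astype(np.intp), sub_to.astype(np.intp)), 1)

    width = max(4, len(str(cfg.n_proteins)))
    ids_a = [f"A_{i:0{width}d}" for i in range(cfg.n_proteins)]
    ids_b = [f"B_{i:0{width}d}" for i in range(cfg.n_proteins)]

    proteome_a: Proteome = {}
    proteome_b: Proteome = {}
    indels: list[tuple[str, str, int]] = []
    for i in range(cfg.n_proteins):
        a_arr = ancestor[offsets[i] : offsets[i + 1]]
        b_arr = descendant[offsets[i] : offsets[i + 1]]
        proteome_a[ids_a[i]] = decode(a_arr)
        if cfg.indel_rate > 0.0:
            b_arr, events = _apply_indels(rng, b_arr, cfg.indel_rate, freqs)
            indels.extend((ids_a[i], kind, pos) for kind, pos in events)
        proteome_b[ids_b[i]] = decode(b_arr)

    truth = SyntheticTruth(
        ortholog_map=list(zip(ids_a, ids_b)),
        sub_pair_index=sub_pair.astype(np.int64),
        sub_position=sub_pos.astype(np.int64),
        sub_from=sub_from,
        sub_to=sub_to,
        directed_counts=directed,
        indels=indels,
    )

    n_par = int(round(cfg.paralog_fraction * cfg.n_proteins))
    if n_par:
        par_rate = min(1.0, 3.0 * cfg.sub_rate)
        sources = rng.choice(cfg.n_proteins, size=n_par, replace=False)
        for j, src in enumerate(sorted(int(s) for s in sources)):
            seq = ancestor[offsets[src] : offsets[src + 1]]
            dup, _ = _mutate(rng, seq, par_rate, targets, freqs)
            proteome_b[f"B_par_{j:0{width}d}"] = decode(dup)

    n_orph = int(round(cfg.orphan_fraction * cfg.n_proteins))
    for prefix, proteome in (("A", proteome_a), ("B", proteome_b)):
        for j in range(n_orph):
            length = max(10, int(round(rng.normal(cfg.length_mean, cfg.length_sd))))
            proteome[f"{prefix}_orphan_{j:0{width}d}"] = decode(
                _sample_residues(rng, freqs, length)
            )

    return proteome_a, proteome_b, truth


def random_proteome(
    n_proteins: int,
    length_mean: float,
    length_sd: float,
    frequencies: np.ndarray | None = None,
    seed: int = 0,
    prefix: str = "g",
) -> Proteome:
    """Draw an i.i.d. proteome from a stated residue composition.

    Used for composition-clustering experiments where each organism's
    proteome is a finite sample from its own amino-acid frequency vector.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    freqs = DEFAULT_AA_FREQS if frequencies is None else np.asarray(frequencies, float)
    if freqs.shape != (20,) or (freqs < 0).any():
        raise ValueError("frequencies must be 20 non-negative values")
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        10, np.rint(rng.normal(length_mean, length_sd, n_proteins)).astype(int)
    )
    width = max(4, len(str(n_proteins)))
    return {
        f"{prefix}_{i:0{width}d}": decode(_sample_residues(rng, freqs, int(lengths[i])))
        for i in range(n_proteins)
    }


def _apply_indels(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    freqs: np.ndarray,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Apply single-residue insertions/deletions; positions in ancestor coords."""
    u = rng.random(seq.size)
    dels = u < rate / 2.0
    ins = (u >= rate / 2.0) & (u < rate)
    events: list[tuple[str, int]] = []
    out: list[np.ndarray] = []
    for pos in range(seq.size):
        if dels[pos]:
            events.append(("del", pos))
            continue
        out.append(seq[pos : pos + 1])
        if ins[pos]:
            events.append(("ins", pos))
            out.append(_sample_residues(rng, freqs, 1))
    if not out:
        return seq.copy(), []
    return np.concatenate(out), events


def simulate_cds_set(
    n: int,
    length_codons: int,
    target_gc3: float,
    seed: int = 0,
) -> CdsSet:
    """Simulate coding sequences whose GC3 converges to ``target_gc3``.

    Every CDS starts with the fixed initiator ATG; the GC3 target governs the
    codons after it (each third position is drawn G/C with probability
    ``target_gc3``/100, A/T otherwise). The initiator's G pulls the realised
    whole-sequence GC3 toward 100 by at most 1/length_codons. Internal stop
    codons are excluded by resampling the first two positions.
    """
    if not 0.0 <= target_gc3 <= 100.0:
        raise ValueError("target_gc3 must be a percentage in [0, 100]")
    if length_codons < 2:
        raise ValueError("length_codons must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n_codons = n * (length_codons - 1)

    gc3_mask = rng.random(n_codons) < target_gc3 / 100.0
    third = np.where(
        gc3_mask,
        np.where(rng.random(n_codons) < 0.5, ord("G"), ord("C")),
        np.where(rng.random(n_codons) < 0.5, ord("A"), ord("T")),
    ).astype(np.uint8)
    first = _NT[rng.integers(0, 4, n_codons)]
    second = _NT[rng.integers(0, 4, n_codons)]

    # resample first two positions of any stop codon (TAA, TAG, TGA)
    while True:
        stop = (
            (first == ord("T"))
            & (
                ((second == ord("A")) & ((third == ord("A")) | (third == ord("G"))))
                | ((second == ord("G")) & (third == ord("A")))
            )
        )
        k = int(stop.sum())
        if not k:
            break
        first[stop] = _NT[rng.integers(0, 4, k)]
        second[stop] = _NT[rng.integers(0, 4, k)]

    codons = np.empty((n_codons, 3), dtype=np.uint8)
    codons[:, 0], codons[:, 1], codons[:, 2] = first, second, third
    flat = codons.reshape(n, -1)
    width = max(4, len(str(n)))
    return {
        f"cds_{i:0{width}d}": "ATG" + flat[i].tobytes().decode("ascii")
        for i in range(n)
    }


def simulate_spot_table(
    n_spots: int,
    planted: dict[str, float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    conditions: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """Simulate a two-condition gel spot-volume table in long format.

    Spot ids are ``s1..sN``. A planted fold change ``f`` multiplies the raw
    volume of that spot in the first condition, so the expected raw-volume
    ratio first/second is ``f`` and unplanted spots have expected ratio 1.
    Noise is multiplicative log-normal with unit mean and coefficient of
    variation ``noise_cv``, independent per measurement.

    Returns a DataFrame with columns ``spot_id, condition, replicate, volume``.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if noise_cv < 0 or not math.isfinite(noise_cv):
        raise ValueError("noise_cv must be finite and >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    planted = dict(planted or {})
    spot_ids = [f"s{i + 1}" for i in range(n_spots)]
    unknown = set(planted) - set(spot_ids)
    if unknown:
        raise ValueError(f"planted spot ids not in table: {sorted(unknown)}")
    for sid, fold in planted.items():
        if not math.isfinite(fold) or fold <= 0:
            raise ValueError(f"fold change for {sid} must be finite and > 0")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=math.log(1000.0), sigma=1.0, size=n_spots)
    folds = np.array([planted.get(sid, 1.0) for sid in spot_ids])

    if noise_cv > 0:
        sigma2 = math.log(1.0 + noise_cv**2)
        noise = lambda k: rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), k)  # noqa: E731
    else:
        noise = lambda k: np.ones(k)  # noqa: E731

    rows = []
    for cond_i, cond in enumerate(conditions):
        mult = folds if cond_i == 0 else np.ones(n_spots)
        for rep in range(1, n_replicates + 1):
            vols = base * mult * noise(n_spots)
            rows.append(
                pd.DataFrame(
                    {
                        "spot_id": spot_ids,
                        "condition": cond,
                        "replicate": rep,
                        "volume": vols,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
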