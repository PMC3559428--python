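"""Genome and proteome composition descriptors.

Amino-acid frequency vectors, Pearson-correlation distances between them,
GC/GC3 content of coding sequences, protein isoelectric points, the
COG-category outlier rule, and genomic signature vectors (tetranucleotide
frequencies and relative synonymous codon usage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .alphabet import AA_ORDER, encode
from .simulate import CdsSet, Proteome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionVector:
    """Amino-acid frequency vector of one organism (fixed residue order)."""

    label: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.shape != (20,):
            raise ValueError("composition vector must have 20 entries")
        if (freqs < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def aa_frequency(proteome: Proteome, label: str = "") -> CompositionVector:
    """Residue frequencies over all residues of all sequences of a proteome.

    Non-canonical letters (X, gaps) are ignored; a proteome without any
    canonical residue is rejected.
    """
    if not proteome:
        raise ValueError("empty proteome")
    counts = np.zeros(20, dtype=np.int64)
    for seq in proteome.values():
        idx = encode(seq)
        idx = idx[idx >= 0]
        counts += np.bincount(idx.astype(np.int64), minlength=20)
    total = counts.sum()
    if total == 0:
        raise ValueError("proteome contains no canonical residues")
    return CompositionVector(label, counts / total)


def pearson_correlation_distance(u, v) -> float:
    """Pearson correlation distance d = 1 - r between two vectors.

    d is 0 for perfectly (positively) correlated vectors — including any
    positive affine transform of one another — and at most 2. Constant
    vectors have undefined correlation and are rejected.
    """
    ua = u.frequencies if isinstance(u, CompositionVector) else np.asarray(u, float)
    va = v.frequencies if isinstance(v, CompositionVector) else np.asarray(v, float)
    if ua.shape != va.shape or ua.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(ua) == 0 or np.ptp(va) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.corrcoef(ua, va)[0, 1])
    return 1.0 - r


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def composition_distance_matrix(vectors: list[CompositionVector]) -> DistanceMatrix:
    """Pearson-correlation distance matrix over composition vectors."""
    n = len(vectors)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pearson_correlation_distance(vectors[i], vectors[j])
    return DistanceMatrix([v.label for v in vectors], d)


_STOPS = {"TAA", "TAG", "TGA"}


def gc_metrics(
    cds: CdsSet,
    strict: bool = False,
    exclude_stop: bool = True,
) -> tuple[float, float]:
    """Overall GC% and third-codon-position GC% pooled over a CDS set.

    GC is computed over all A/C/G/T of all sequences (N tolerated and
    excluded from denominators in lenient mode). GC3 pools every third codon
    position of every CDS; a terminal stop codon is excluded by default
    (stop codons encode no amino acid). Sequences whose length is not a
    multiple of 3 are skipped from GC3 with a warning, or rejected when
    ``strict``.
    """
    if not cds:
        raise ValueError("empty CDS set")
    gc = at = gc3 = n3 = 0
    for name, seq in cds.items():
        s = seq.upper()
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"{name}: non-nucleotide letters {sorted(bad)}")
        if "N" in s and strict:
            raise ValueError(f"{name}: ambiguous base N in strict mode")
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
        if len(s) % 3 != 0:
            if strict:
                raise ValueError(f"{name}: length {len(s)} not a multiple of 3")
            logger.warning("%s: length %d not a multiple of 3; skipped from GC3", name, len(s))
            continue
        codons = [s[i : i + 3] for i in range(0, len(s), 3)]
        if exclude_stop and codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        third = [c[2] for c in codons if c[2] != "N"]
        gc3 += sum(1 for b in third if b in "GC")
        n3 += len(third)
    if gc + at == 0:
        raise ValueError("no unambiguous bases in CDS set")
    gc_pct = 100.0 * gc / (gc + at)
    gc3_pct = 100.0 * gc3 / n3 if n3 else float("nan")
    return gc_pct, gc3_pct


# EMBOSS pKa set: termini plus the seven ionisable side chains.
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_ACIDIC = ("C", "D", "E", "Y")
_BASIC = ("H", "K", "R")


def net_charge(seq: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    pka = pka or EMBOSS_PKA
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        pos += seq.count(aa) / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        neg += seq.count(aa) / (1.0 + 10.0 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(
    seq: str,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point of a protein by bisection on the net-charge curve.

    The charge model sums Henderson–Hasselbalch terms over the two termini
    and the ionisable side chains (C, D, E, Y acidic; H, K, R basic) with
    the EMBOSS pKa set by default. Bisection on pH in [0, 14] stops when
    |net charge| < ``tol``.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AA_ORDER)
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)}")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    mid = (lo + hi) / 2.0
    if abs(net_charge(seq, mid, pka)) >= tol:
        raise ValueError("net-charge curve did not cross zero within tolerance")
    return mid


def mean_isoelectric_point(proteome: Proteome, pka: dict[str, float] | None = None) -> float:
    """Unweighted mean pI over the sequences of a proteome."""
    if not proteome:
        raise ValueError("empty proteome")
    return float(np.mean([isoelectric_point(s, pka) for s in proteome.values()]))


def cog_outliers(
    table: pd.DataFrame,
    focal: str,
    refs: list[str],
    n_sd: float = 2.0,
) -> pd.DataFrame:
    """Flag COG categories where the focal organism deviates from references.

    ``table`` holds raw category counts (organisms as rows). Counts are
    converted to within-organism proportions; for each category the focal
    proportion is compared to mean ± ``n_sd`` · SD (sample SD, n-1
    denominator) of the reference proportions. With zero reference variance
    any deviation of the focal proportion is flagged.

    Returns a per-category table with the focal proportion, reference mean
    and SD, and a ``flag`` column in {'high', 'low', ''}.
    """
    if focal in refs:
        raise ValueError("focal organism must not be among the references")
    if len(refs) < 2:
        raise ValueError("need at least 2 reference organisms")
    missing = {focal, *refs} - set(table.index)
    if missing:
        raise ValueError(f"organisms missing from table: {sorted(missing)}")
    props = table.div(table.sum(axis=1), axis=0)
    ref_block = props.loc[refs]
    mean = ref_block.mean(axis=0)
    sd = ref_block.std(axis=0, ddof=1)
    focal_p = props.loc[focal]
    flag = pd.Series("", index=table.columns, dtype=object)
    flag[focal_p > mean + n_sd * sd] = "high"
    flag[focal_p < mean - n_sd * sd] = "low"
    return pd.DataFrame(
        {"focal": focal_p, "ref_mean": mean, "ref_sd": sd, "flag": flag}
    )


_TETRA = ["".join(p) for p in product("ACGT", repeat=4)]
_COMP = str.maketrans("ACGT", "TGCA")


def tetranucleotide_frequencies(
    seqs: CdsSet,
    combine_revcomp: bool = False,
) -> pd.Series:
    """Frequencies of the 256 tetranucleotides over overlapping windows.

    Counts are single-strand by default; with ``combine_revcomp`` each
    window also contributes its reverse complement. Windows containing
    non-ACGT letters are skipped; sequences shorter than 4 contribute
    nothing (logged).
    """
    counts = dict.fromkeys(_TETRA, 0)
    for name, seq in seqs.items():
        s = seq.upper()
        if len(s) < 4:
            logger.warning("%s: shorter than 4 nt; contributes no tetranucleotides", name)
            continue
        for i in range(len(s) - 3):
            w = s[i : i + 4]
            if w in counts:
                counts[w] += 1
                if combine_revcomp:
                    counts[w.translate(_COMP)[::-1]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable tetranucleotide windows")
    return pd.Series({k: v / total for k, v in counts.items()}, name="frequency")


# Standard genetic code (translation table 1), stop codons excluded.
_CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA_BY_CODON = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(product(_BASES, _BASES, _BASES)):
    _aa = _AA_BY_CODON[_i]
    if _aa != "*":
        _CODON_TABLE[_b1 + _b2 + _b3] = _aa

_FAMILY: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _FAMILY.setdefault(_aa, []).append(_codon)


def rscu(cds: CdsSet) -> pd.DataFrame:
    """Relative synonymous codon usage over a CDS set.

    RSCU(c) = observed count of codon c × family size / total counts of its
    synonymous family. Uniform usage within a family gives RSCU 1 for every
    member; unobserved families get NaN. Stop codons are excluded.

    Returns a table indexed by codon with columns ``amino_acid``, ``count``,
    ``rscu``.
    """
    if not cds:
        raise ValueError("empty CDS set")
    counts = dict.fromkeys(_CODON_TABLE, 0)
    for name, seq in cds.items():
        s = seq.upper()
        if len(s) % 3 != 0:
            logger.warning("%s: length not a multiple of 3; truncated for codon counts", name)
        for i in range(0, len(s) - len(s) % 3, 3):
            c = s[i : i + 3]
            if c in counts:
                counts[c] += 1
    rows = []
    for aa, codons in sorted(_FAMILY.items()):
        fam_total = sum(counts[c] for c in codons)
        size = len(codons)
        for c in sorted(codons):
            value = counts[c] * size / fam_total if fam_total else math.nan
            rows.append((c, aa, counts[c], value))
    out = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "rscu"])
    return out.set_index("codon")


def genomic_signatures(cds: CdsSet) -> tuple[pd.Series, pd.DataFrame]:
    """Tetranucleotide frequency vector and RSCU table of a CDS set."""
    return tetranucleotide_frequencies(cds), rscu(cds)
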