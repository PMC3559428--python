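"""File formats: FASTA sequences, TSV tables, Newick trees, flat configs.

All tables are tab-delimited UTF-8 with a header row; sequence files are
standard multi-FASTA handled through Biopython. Writers are deterministic
(stable ordering, fixed float formatting) so a rerun with the same inputs
is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignedPair
from .alphabet import AA_ORDER
from .orthology import OrthologSet
from .substitution import DirectedSubstitutionMatrix


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-FASTA file into an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def write_alignments_fasta(orthologs: OrthologSet, path: str | Path) -> None:
    """Write ortholog alignments as aligned FASTA, two records per pair."""
    seqs: dict[str, str] = {}
    for pair in orthologs.pairs:
        seqs[pair.id_a] = pair.aligned_a
        seqs[pair.id_b] = pair.aligned_b
    write_fasta(seqs, path)


def read_alignments_fasta(path: str | Path) -> OrthologSet:
    records = read_fasta(path)
    items = list(records.items())
    if len(items) % 2 != 0:
        raise ValueError("aligned FASTA must contain an even number of records")
    out = OrthologSet()
    for (id_a, seq_a), (id_b, seq_b) in zip(items[::2], items[1::2]):
        out.pairs.append(AlignedPair(id_a, id_b, seq_a, seq_b))
    return out


def write_ortholog_table(orthologs: OrthologSet, path: str | Path) -> None:
    from .align import identity_coverage

    rows = []
    for pair in orthologs.pairs:
        identity, cov_a, cov_b = identity_coverage(pair)
        rows.append(
            {
                "id_a": pair.id_a,
                "id_b": pair.id_b,
                "n_ungapped": pair.n_ungapped_columns,
                "identity": round(identity, 4),
                "coverage_a": round(cov_a, 4),
                "coverage_b": round(cov_b, 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matrix(m: DirectedSubstitutionMatrix, path: str | Path) -> None:
    frame = m.to_frame()
    frame.index.name = "aa"
    frame.to_csv(path, sep="\t")


def read_matrix(
    path: str | Path, row_organism: str = "A", col_organism: str = "B"
) -> DirectedSubstitutionMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DirectedSubstitutionMatrix.from_frame(frame, row_organism, col_organism)


def write_truth(truth, path: str | Path) -> None:
    """Write a simulation's substitution event log as TSV."""
    truth.substitutions_frame().to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat key=value configuration file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def parse_bias_pairs(text: str) -> dict[tuple[str, str], float]:
    """Parse a bias specification like ``K:R:2.0,E:A:1.8``."""
    out: dict[tuple[str, str], float] = {}
    if not text:
        return out
    for chunk in text.split(","):
        parts = chunk.strip().split(":")
        if len(parts) != 3:
            raise ValueError(f"bad bias spec {chunk!r}; expected FROM:TO:MULT")
        a, b, mult = parts[0].strip().upper(), parts[1].strip().upper(), float(parts[2])
        if a not in AA_ORDER or b not in AA_ORDER:
            raise ValueError(f"bad residues in bias spec {chunk!r}")
        out[(a, b)] = mult
    return out
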