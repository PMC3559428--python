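"""Packaged reference tables with checksum-guarded loaders.

Two small TSV fixtures ship with the package:

* ``table1_aa_substitutions.tsv`` — the published 20x20 directed
  amino-acid substitution count table from the comparison of 1,911
  ortholog pairs between the reference (rows, the non-piezophilic marine
  relative) and the piezophilic organism (columns).
* ``differential_abundance.tsv`` — the published lists of gel spots with
  increased/decreased abundance at atmospheric (0.1 MPa) relative to high
  (10 MPa) hydrostatic pressure, with their DA ratios.

SHA-256 checksums guard against silent transcription drift.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .substitution import DirectedSubstitutionMatrix


class FixtureChecksumError(RuntimeError):
    """Raised when a packaged fixture does not match its recorded checksum."""


def _data_bytes(name: str) -> bytes:
    ref = resources.files("piezocomp.data").joinpath(name)
    return ref.read_bytes()


def _verify(name: str, payload: bytes) -> None:
    checks = dict(
        line.split("\t")
        for line in _data_bytes("checksums.tsv").decode().strip().split("\n")
    )
    expected = checks.get(name)
    actual = hashlib.sha256(payload).hexdigest()
    if expected is None or actual != expected:
        raise FixtureChecksumError(
            f"fixture {name}: checksum mismatch (expected {expected}, got {actual})"
        )


def load_table1_fixture() -> DirectedSubstitutionMatrix:
    """Load the packaged 20x20 directed substitution count table.

    Orientation: rows are the reference organism's residue states
    (D. salexigens), columns the piezophile's (D. piezophilus).
    """
    payload = _data_bytes("table1_aa_substitutions.tsv")
    _verify("table1_aa_substitutions.tsv", payload)
    import io

    frame = pd.read_csv(io.BytesIO(payload), sep="\t", index_col=0)
    return DirectedSubstitutionMatrix.from_frame(
        frame, row_organism="D. salexigens", col_organism="D. piezophilus"
    )


def load_da_fixture() -> pd.DataFrame:
    """Load the packaged published differential-abundance spot lists.

    Columns: ``spot`` (number), ``accession``, ``annotation``, ``cog``,
    ``da`` (ratio; NaN for the one spot reported only qualitatively),
    ``direction`` (``increased``/``decreased`` at 0.1 MPa relative to
    10 MPa), ``membrane_fraction``. The spot with missing DA counts as
    significant (presence/absence difference).
    """
    payload = _data_bytes("differential_abundance.tsv")
    _verify("differential_abundance.tsv", payload)
    import io

    frame = pd.read_csv(io.BytesIO(payload), sep="\t", dtype={"cog": "string"})
    expected = ["spot", "accession", "annotation", "cog", "da", "direction", "membrane_fraction"]
    if list(frame.columns) != expected:
        raise ValueError(f"malformed fixture: columns {list(frame.columns)} != {expected}")
    if not frame["direction"].isin(["increased", "decreased"]).all():
        raise ValueError("malformed fixture: unknown direction label")
    frame["significant"] = frame["da"].isna() | (frame["da"] >= 1.5)
    return frame
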