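"""End-to-end pipeline: orthology -> substitution asymmetry -> summaries,
with optional composition, GC, pI, signature, COG and spot-table stages.

Every run writes its outputs plus a JSON manifest (parameters, seed,
package version, SHA-256 of every written file) sufficient to reproduce the
run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import ScoringScheme
from .composition import (
    aa_frequency,
    cog_outliers,
    composition_distance_matrix,
    gc_metrics,
    genomic_signatures,
    mean_isoelectric_point,
)
from .io import (
    read_fasta,
    write_alignments_fasta,
    write_matrix,
    write_ortholog_table,
)
from .nj import neighbor_joining
from .orthology import reciprocal_best_hits
from .proteomics import differential_abundance
from .substitution import (
    DEFAULT_ALPHA,
    count_substitutions,
    replacement_summary,
    results_to_frame,
    test_all_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and scoring for one pipeline run."""

    proteome_a: str | Path | None = None
    proteome_b: str | Path | None = None
    cds_fasta: str | Path | None = None
    cog_table: str | Path | None = None
    cog_focal: str | None = None
    spot_table: str | Path | None = None
    composition_proteomes: list[str | Path] = field(default_factory=list)
    min_identity: float = 30.0
    min_coverage: float = 70.0
    alpha: float = DEFAULT_ALPHA
    da_threshold: float = 1.5
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    seed: int = 0
    out_dir: str | Path = "piezocomp_out"

    def __post_init__(self) -> None:
        for attr in ("proteome_a", "proteome_b", "cds_fasta", "cog_table", "spot_table"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr}: {value} does not exist")
        for p in self.composition_proteomes:
            if not Path(p).exists():
                raise FileNotFoundError(f"composition proteome {p} does not exist")


class StageError(RuntimeError):
    """A named pipeline stage failed."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for which inputs are available.

    Returns a manifest dict (also written as ``manifest.json``) recording
    parameters, stage timings, headline numbers and output checksums.
    Missing optional inputs skip their stage with a log message; a failure
    inside a stage aborts with a stage-named error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    summary: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)

        return wrap

    if config.proteome_a and config.proteome_b:

        @stage("orthology")
        def _orthology():
            pa = read_fasta(config.proteome_a)
            pb = read_fasta(config.proteome_b)
            orthologs = reciprocal_best_hits(
                pa,
                pb,
                scoring=config.scoring,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
            )
            write_ortholog_table(orthologs, out_dir / "orthologs.tsv")
            write_alignments_fasta(orthologs, out_dir / "alignments.faa")
            outputs.extend(["orthologs.tsv", "alignments.faa"])
            summary["n_ortholog_pairs"] = orthologs.n_pairs
            summary["total_aa_positions"] = orthologs.total_aa_positions

            matrix = count_substitutions(orthologs)
            write_matrix(matrix, out_dir / "substitution_matrix.tsv")
            outputs.append("substitution_matrix.tsv")

            results = test_all_pairs(matrix, alpha=config.alpha)
            results_to_frame(results).to_csv(
                out_dir / "asymmetry_tests.tsv", sep="\t", index=False
            )
            outputs.append("asymmetry_tests.tsv")
            summary["n_significant_pairs"] = sum(r.significant for r in results)

            summ = replacement_summary(matrix, results)
            summ.table.rename_axis("aa").to_csv(
                out_dir / "replacement_summary.tsv", sep="\t"
            )
            outputs.append("replacement_summary.tsv")
            summary["preferred_acceptors"] = summ.preferred_acceptors

    else:
        logger.info("orthology stage skipped: both proteomes required")

    if len(config.composition_proteomes) >= 3:

        @stage("composition_tree")
        def _composition():
            vectors = []
            for path in config.composition_proteomes:
                label = Path(path).stem
                vectors.append(aa_frequency(read_fasta(path), label=label))
            dm = composition_distance_matrix(vectors)
            dm.to_frame().rename_axis("organism").to_csv(
                out_dir / "composition_distances.tsv", sep="\t"
            )
            tree = neighbor_joining(dm)
            (out_dir / "composition_tree.nwk").write_text(tree.to_newick() + "\n")
            outputs.extend(["composition_distances.tsv", "composition_tree.nwk"])

    elif config.composition_proteomes:
        logger.info("composition stage skipped: need >= 3 proteomes")

    if config.cds_fasta:

        @stage("gc_signatures")
        def _gc():
            cds = read_fasta(config.cds_fasta)
            gc, gc3 = gc_metrics(cds)
            tetra, codon_usage = genomic_signatures(cds)
            tetra.rename_axis("tetranucleotide").to_csv(
                out_dir / "tetranucleotide_frequencies.tsv", sep="\t"
            )
            codon_usage.to_csv(out_dir / "codon_usage_rscu.tsv", sep="\t")
            outputs.extend(["tetranucleotide_frequencies.tsv", "codon_usage_rscu.tsv"])
            summary["gc_percent"] = round(gc, 4)
            summary["gc3_percent"] = round(gc3, 4)

    if config.proteome_a:

        @stage("isoelectric_point")
        def _pi():
            summary["mean_pi_proteome_a"] = round(
                mean_isoelectric_point(read_fasta(config.proteome_a)), 4
            )

    if config.cog_table and config.cog_focal:

        @stage("cog_outliers")
        def _cog():
            table = pd.read_csv(config.cog_table, sep="\t", index_col=0)
            refs = [org for org in table.index if org != config.cog_focal]
            flags = cog_outliers(table, config.cog_focal, refs)
            flags.rename_axis("category").to_csv(out_dir / "cog_outliers.tsv", sep="\t")
            outputs.append("cog_outliers.tsv")
            summary["n_cog_flags"] = int((flags["flag"] != "").sum())

    if config.spot_table:

        @stage("differential_abundance")
        def _da():
            table = pd.read_csv(config.spot_table, sep="\t")
            result = differential_abundance(table, threshold=config.da_threshold)
            result.to_csv(out_dir / "differential_abundance.tsv", sep="\t")
            outputs.append("differential_abundance.tsv")
            summary["n_significant_spots"] = int(result["significant"].sum())

    manifest = {
        "package": "piezocomp",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "min_identity": config.min_identity,
            "min_coverage": config.min_coverage,
            "alpha": config.alpha,
            "da_threshold": config.da_threshold,
            "scoring": {
                "matrix": config.scoring.matrix_name,
                "gap_open": config.scoring.gap_open,
                "gap_extend": config.scoring.gap_extend,
            },
        },
        "inputs": {
            k: str(v)
            for k, v in {
                "proteome_a": config.proteome_a,
                "proteome_b": config.proteome_b,
                "cds_fasta": config.cds_fasta,
                "cog_table": config.cog_table,
                "spot_table": config.spot_table,
            }.items()
            if v
        },
        "summary": summary,
        "timings_s": timings,
        "outputs": {
            name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
            for name in outputs
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
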