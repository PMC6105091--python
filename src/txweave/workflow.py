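"""End-to-end driver: prepare → evidence → pick, on files in a directory.

Thin composition of the stage modules so the CLI, the test-suite and the
reproduction script all run the identical pipeline.
"""

from __future__ import annotations

import os

from . import io as tio
from .evidence import build_store
from .pick import PickResult, pick_run, write_metrics_tsv, write_scores_tsv
from .prepare import prepare_run, write_decision_log
from .scoring import ScoringConfig, default_config


def run_pipeline(
    inputs: list[tuple[str, str, bool]],
    genome,
    workdir: str,
    junctions_path: str | None = None,
    orfs_path: str | None = None,
    homology_path: str | None = None,
    config: ScoringConfig | None = None,
) -> tuple[PickResult, dict[str, str]]:
    """Run the full integration pipeline; returns the pick result and
    the paths of every artifact written under ``workdir``.

    ``genome`` is a chrom→sequence mapping (a pyfaidx.Fasta or a dict);
    ``inputs`` are (path, source_label, strand_specific) triples.
    """
    config = config or default_config()
    os.makedirs(workdir, exist_ok=True)
    paths = {
        "prepared_gtf": os.path.join(workdir, "prepared.gtf"),
        "prepared_fasta": os.path.join(workdir, "prepared.fasta"),
        "prepare_log": os.path.join(workdir, "prepare_decisions.tsv"),
        "final_gff3": os.path.join(workdir, "final.gff3"),
        "metrics": os.path.join(workdir, "metrics.tsv"),
        "scores": os.path.join(workdir, "scores.tsv"),
        "pick_log": os.path.join(workdir, "pick.log"),
    }
    prep = prepare_run(
        inputs,
        genome,
        paths["prepared_gtf"],
        paths["prepared_fasta"],
        min_length=config.min_length,
    )
    write_decision_log(prep.decisions, paths["prepare_log"])
    prepared = tio.read_gtf(paths["prepared_gtf"])
    cdnas = tio.read_fasta(paths["prepared_fasta"])
    store = build_store(junctions_path, orfs_path, homology_path, cdnas)
    result = pick_run(prepared, store, config)
    tio.write_gff3(result.annotation, paths["final_gff3"])
    write_metrics_tsv(result.metrics, paths["metrics"])
    write_scores_tsv(result.scores, paths["scores"])
    with open(paths["pick_log"], "w") as fh:
        fh.write("\n".join(result.log) + ("\n" if result.log else ""))
    return result, paths
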