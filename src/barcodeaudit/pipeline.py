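"""End-to-end audit pipeline: inputs -> distance matrix -> tree -> reports.

``run_pipeline`` orchestrates every stage and writes a fixed bundle of
plain-text artifacts (TSV/Newick/JSON) with stable column orders so runs
diff cleanly.  Analysis outcomes — a low success rate, many deep splits —
are results, never errors; only validation failures raise.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .discrimination import (
    classify_species,
    condition_counts,
    success_rate,
)
from .distance import distance_matrix
from .divergence import deep_split_table, divergence_summary, flag_deep_splits
from .errors import ValidationError
from .records import qc_flags, read_dataset, write_dataset
from .regression import sampling_bias_regression
from .simulate import SimConfig, simulate_community
from .tree import build_nj, write_newick

logger = logging.getLogger(__name__)


def percent(value: float, decimals: int = 1) -> str:
    """Render a proportion-derived percentage at fixed precision."""
    return f"{value:.{decimals}f}"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (either real input or simulation)."""

    fasta: Path | None = None
    metadata: Path | None = None
    simulate: SimConfig | None = None
    outdir: Path = Path("audit_out")
    threshold_pct: float = 3.0
    min_len: int = 500
    haplotype_floor: int = 400
    bin_width: float = 1.0
    outgroup_species: str | None = None   # binomial used for rooting
    write_distances: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.simulate is None:
            if self.fasta is None or self.metadata is None:
                raise ValidationError("need fasta+metadata paths or a simulation config")
            for p in (self.fasta, self.metadata):
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")
        if self.threshold_pct <= 0:
            raise ValidationError("threshold must be > 0")


def _stage(name: str):
    logger.info("=== %s ===", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``cfg.outdir``.

    Returns a dict with the summary (also written as ``summary.json``) and
    the paths of all written artifacts.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t0 = _stage("load inputs")
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        if cfg.seed is not None:
            sim_cfg = SimConfig(**{**sim_cfg.__dict__, "seed": cfg.seed})
        dataset, truth = simulate_community(sim_cfg)
        paths["fasta"] = outdir / "simulated.fasta"
        paths["metadata"] = outdir / "simulated_metadata.tsv"
        write_dataset(dataset, paths["fasta"], paths["metadata"])
        paths["truth"] = outdir / "truth.json"
        truth.to_json(paths["truth"])
    else:
        dataset = read_dataset(cfg.fasta, cfg.metadata)
    logger.info("loaded %d records (%.1fs)", len(dataset), time.perf_counter() - t0)

    t0 = _stage("quality flags")
    qc = qc_flags(dataset, min_len=cfg.min_len)
    paths["qc"] = outdir / "qc_report.tsv"
    qc.to_csv(paths["qc"], sep="\t", index=False)

    t0 = _stage("K2P distances")
    m = distance_matrix(dataset)
    if cfg.write_distances:
        paths["distances"] = outdir / "distance_matrix.tsv"
        m.to_tsv(paths["distances"])
    logger.info("distance matrix %dx%d (%.1fs)", len(m), len(m), time.perf_counter() - t0)

    t0 = _stage("neighbour joining")
    tree = build_nj(m)
    paths["tree"] = outdir / "nj_tree.nwk"
    write_newick(tree, paths["tree"])
    logger.info("tree built (%.1fs)", time.perf_counter() - t0)

    outgroup_ids: set[str] | None = None
    if cfg.outgroup_species:
        og = dataset.species_members().get(cfg.outgroup_species)
        if not og:
            raise ValidationError(f"outgroup species not in dataset: {cfg.outgroup_species}")
        outgroup_ids = set(og)

    t0 = _stage("species diagnosability")
    assessments = classify_species(
        tree, dataset, outgroup_ids=outgroup_ids, haplotype_floor=cfg.haplotype_floor
    )
    n_ok, n_sp, prop = success_rate(assessments)
    table1 = pd.DataFrame(
        [
            (
                a.species,
                a.n_specimens,
                a.condition.value,
                ";".join(a.congeners_involved),
                a.n_specimens == 1 and a.success,
            )
            for a in sorted(assessments, key=lambda a: a.species)
        ],
        columns=["species", "n", "condition", "congeners_involved", "untested_by_replication"],
    )
    paths["assessments"] = outdir / "species_assessments.tsv"
    table1.to_csv(paths["assessments"], sep="\t", index=False)
    logger.info("classified %d species (%.1fs)", n_sp, time.perf_counter() - t0)

    t0 = _stage("divergence summaries")
    summary = divergence_summary(m, dataset, bin_width=cfg.bin_width)
    paths["histogram"] = outdir / "divergence_histogram.tsv"
    summary.gap_table().to_csv(paths["histogram"], sep="\t", index=False)
    reports = flag_deep_splits(m, dataset, threshold_pct=cfg.threshold_pct)
    paths["deep_splits"] = outdir / "deep_splits.tsv"
    deep_split_table(reports).to_csv(paths["deep_splits"], sep="\t", index=False)

    t0 = _stage("sampling regression")
    reg, scatter = sampling_bias_regression(summary)
    paths["regression"] = outdir / "regression.tsv"
    pd.DataFrame(
        [
            (
                reg.slope,
                reg.intercept,
                reg.r_squared,
                reg.p_value,
                reg.stderr,
                reg.n_points,
            )
        ],
        columns=["slope", "intercept", "r_squared", "p_value", "stderr", "n_points"],
    ).to_csv(paths["regression"], sep="\t", index=False)
    paths["scatter"] = outdir / "regression_scatter.tsv"
    scatter.to_csv(paths["scatter"], sep="\t", index=False)

    flagged = [r for r in reports if r.flagged]
    cluster_breakdown: dict[str, int] = {}
    for r in flagged:
        key = str(len(r.cluster_sizes))
        cluster_breakdown[key] = cluster_breakdown.get(key, 0) + 1

    summary_json = {
        "version": __version__,
        "seed": cfg.simulate.seed if cfg.simulate is not None else cfg.seed,
        "n_sequences": len(dataset),
        "n_species": n_sp,
        "n_genera": len({r.genus for r in dataset.records}),
        "alignment_length": dataset.alignment_length,
        "n_meets_standard": int(qc["meets_standard"].sum()),
        "success": {
            "n_success": n_ok,
            "n_total": n_sp,
            "proportion": prop,
            "percent": percent(prop * 100.0),
        },
        "condition_counts": condition_counts(assessments),
        "divergence": {
            "mean_intra_pct": summary.mean_intra_pct,
            "intra_range_pct": list(summary.intra_range_pct),
            "n_intra_pairs": summary.n_intra_pairs,
            "mean_congeneric_pct": summary.mean_congeneric_pct,
            "congeneric_range_pct": list(summary.congeneric_range_pct),
            "n_congeneric_pairs": summary.n_congeneric_pairs,
            "n_other_pairs": summary.n_other_pairs,
            "n_multispecimen_species": int(len(summary.per_species)),
        },
        "deep_splits": {
            "threshold_pct": cfg.threshold_pct,
            "n_flagged_species": len(flagged),
            "clusters_per_flagged_species": cluster_breakdown,
        },
        "regression": {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r_squared": reg.r_squared,
            "p_value": reg.p_value,
            "n_points": reg.n_points,
        },
        "parameters": {
            "min_len": cfg.min_len,
            "haplotype_floor": cfg.haplotype_floor,
            "bin_width": cfg.bin_width,
            "outgroup_species": cfg.outgroup_species,
            "rooting": "outgroup" if outgroup_ids else "midpoint",
        },
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary_json, indent=1, sort_keys=True))
    logger.info("success rate %s%% (%d/%d species)", summary_json["success"]["percent"], n_ok, n_sp)
    return {"summary": summary_json, "paths": paths, "assessments": assessments}
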