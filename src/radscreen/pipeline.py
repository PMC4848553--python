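"""Stage orchestration: one config in, a reproducible report bundle out.

Every output table carries a provenance header (# key: value lines)
recording the package version, the seed and a hash of the canonical
config, so any table can be regenerated from the config alone; two runs
with the same config are bitwise identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import cohort as cohort_stats
from . import scna, signatures, survival
from .errors import ConfigurationError, RadscreenError
from .io import (
    NamedMatrix,
    group_segments_by_sample,
    read_gene_intervals,
    read_gmt,
    read_matrix,
    read_mutations,
    read_seg,
    write_gmt,
    write_matrix,
    write_mutations,
    write_seg,
)
from .simulate import CohortConfig, SyntheticCohort, config_from_dict, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline run description: either simulate a cohort or point at inputs."""

    output_dir: str
    simulate: CohortConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # plates_dir/seg/expression/mutations/gmt/genes/lineages
    stages: tuple[str, ...] = (
        "scoring", "scna", "mutations", "association", "correlation",
        "ssgsea", "signature", "cohort_stats",
    )
    n_perm: int = 999
    seed: int = 0
    direction: str = "resistance"
    min_carriers: int = assoc.DEFAULT_MIN_CARRIERS

    def __post_init__(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ConfigurationError("config needs either a simulate block or inputs")
        if self.simulate is not None and self.inputs:
            raise ConfigurationError("simulate block and inputs are mutually exclusive")


def _canonical(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _canonical(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis parameters (the output location is excluded)."""
    canonical = _canonical(config)
    canonical.pop("output_dir", None)
    blob = json.dumps(canonical, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(path: Path, frame: pd.DataFrame, provenance: Mapping[str, Any]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages in order; returns the bundle directory.

    A stage failure halts the run with a stage-named error; tables
    written before the failure are kept next to a FAILED marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "radscreen_version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
    }
    stage = "setup"
    try:
        bundle = _load_or_simulate(config, out)
        scores: dict[str, float] = {}
        if "scoring" in config.stages:
            stage = "scoring"
            scores = _stage_scoring(config, bundle, out, provenance)
        amp = dele = None
        if "scna" in config.stages and bundle.segments:
            stage = "scna"
            amp, dele = _stage_scna(config, bundle, out, provenance)
        mut_matrix = None
        if "mutations" in config.stages and bundle.mutations:
            stage = "mutations"
            mut_matrix = assoc.mutation_matrix(bundle.mutations, bundle.sample_ids)
        if "association" in config.stages and scores:
            stage = "association"
            estimator = assoc.ICEstimator(min_carriers=config.min_carriers)
            for name, matrix in (("mutation", mut_matrix), ("amp", amp), ("del", dele)):
                if matrix is None:
                    continue
                results, excluded = assoc.rank_associations(
                    matrix, scores, direction=config.direction,
                    n_perm=config.n_perm, seed=config.seed, estimator=estimator,
                )
                table = assoc.associations_table(results)
                write_table(out / f"ic_{name}.tsv", table, provenance)
                if excluded:
                    logger.info("%s screen: %d features excluded", name, len(excluded))
        if "correlation" in config.stages and bundle.expression is not None and scores:
            stage = "correlation"
            table, dropped = assoc.correlation_rank(bundle.expression, scores, "spearman")
            write_table(out / "expression_correlation.tsv", table, provenance)
        ssgsea_scores = None
        if "ssgsea" in config.stages and bundle.expression is not None and bundle.gene_sets:
            stage = "ssgsea"
            ssgsea_scores, rejected = signatures.ssgsea_project(
                bundle.expression, bundle.gene_sets
            )
            write_table(
                out / "ssgsea.tsv",
                ssgsea_scores.to_frame().rename_axis("gene_set").reset_index(),
                provenance,
            )
        if "signature" in config.stages and bundle.expression is not None and bundle.gene_sets:
            stage = "signature"
            sigs = {gs.name: sorted(gs.members) for gs in bundle.gene_sets}
            summary = signatures.signature_summary(bundle.expression, sigs)
            write_table(
                out / "signature_scores.tsv",
                pd.DataFrame(
                    {"sample_id": summary.sample_ids, "summary_score": summary.scores}
                ),
                provenance,
            )
        if "cohort_stats" in config.stages and scores:
            stage = "cohort_stats"
            _stage_cohort_stats(bundle, scores, out, provenance)
    except RadscreenError as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise RadscreenError(f"stage {stage!r} failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# bundle loading / simulation
# ---------------------------------------------------------------------------

@dataclass
class _Bundle:
    sample_ids: list[str]
    lineage_of: dict[str, str]
    plates: dict[str, NamedMatrix]
    segments: list
    mutations: list
    expression: NamedMatrix | None
    gene_sets: list
    gene_intervals: list


def _load_or_simulate(config: RunConfig, out: Path) -> _Bundle:
    if config.simulate is not None:
        t0 = time.perf_counter()
        cohort = simulate_cohort(config.simulate)
        logger.info("simulated cohort in %.2fs", time.perf_counter() - t0)
        write_cohort(cohort, out / "inputs")
        return _Bundle(
            sample_ids=cohort.sample_ids,
            lineage_of=cohort.lineage_of,
            plates=cohort.plates,
            segments=cohort.segments,
            mutations=cohort.mutations,
            expression=cohort.expression,
            gene_sets=cohort.gene_sets,
            gene_intervals=list(cohort.config.genome.genes),
        )
    inputs = config.inputs
    plates: dict[str, NamedMatrix] = {}
    if "plates_dir" in inputs:
        for path in sorted(Path(inputs["plates_dir"]).glob("*.tsv")):
            plates[path.stem] = read_matrix(path, value_kind="luminescence")
    segments = read_seg(inputs["seg"]) if "seg" in inputs else []
    mutations = read_mutations(inputs["mutations"]) if "mutations" in inputs else []
    expression = (
        read_matrix(inputs["expression"], value_kind="expression")
        if "expression" in inputs else None
    )
    gene_sets = read_gmt(inputs["gmt"]) if "gmt" in inputs else []
    gene_intervals = (
        read_gene_intervals(inputs["genes"]) if "genes" in inputs else []
    )
    lineage_of: dict[str, str] = {}
    if "lineages" in inputs:
        for line in Path(inputs["lineages"]).read_text(encoding="utf-8").splitlines()[1:]:
            if line.strip():
                sid, lin = line.split("\t")[:2]
                lineage_of[sid] = lin
    sample_ids = sorted(
        set(plates)
        | {s.sample_id for s in segments}
        | {m.sample_id for m in mutations}
        | set(expression.column_ids if expression else [])
    )
    return _Bundle(
        sample_ids=sample_ids, lineage_of=lineage_of, plates=plates,
        segments=segments, mutations=mutations, expression=expression,
        gene_sets=gene_sets, gene_intervals=gene_intervals,
    )


def write_cohort(cohort: SyntheticCohort, directory: Path | str) -> Path:
    """Write every cohort component in the package's on-disk dialects."""
    directory = Path(directory)
    (directory / "plates").mkdir(parents=True, exist_ok=True)
    for sid, plate in cohort.plates.items():
        write_matrix(directory / "plates" / f"{sid}.tsv", plate, id_header="well")
    write_seg(directory / "segments.seg", cohort.segments)
    write_mutations(directory / "mutations.tsv", cohort.mutations)
    write_matrix(directory / "expression.tsv", cohort.expression, id_header="gene")
    write_gmt(directory / "gene_sets.gmt", cohort.gene_sets)
    with open(directory / "lineages.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tlineage\n")
        for sid in cohort.sample_ids:
            fh.write(f"{sid}\t{cohort.lineage_of[sid]}\n")
    with open(directory / "truth_scores.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\ttrue_integral_survival\n")
        for sid in cohort.sample_ids:
            fh.write(f"{sid}\t{cohort.truth.true_scores[sid]!r}\n")
    return directory


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_scoring(
    config: RunConfig, bundle: _Bundle, out: Path, provenance: Mapping[str, Any]
) -> dict[str, float]:
    densities = (
        config.simulate.cell_densities if config.simulate is not None else (25, 75, 225)
    )
    scores: dict[str, float] = {}
    for sid in bundle.sample_ids:
        if sid not in bundle.plates:
            continue
        result = survival.score_plate(bundle.plates[sid], densities, sample_id=sid)
        scores[sid] = result.score
    if scores:
        write_table(
            out / "integral_survival.tsv",
            pd.DataFrame(
                {
                    "sample_id": list(scores),
                    "score": list(scores.values()),
                    "n": [1] * len(scores),
                }
            ),
            provenance,
        )
    return scores


def _stage_scna(
    config: RunConfig, bundle: _Bundle, out: Path, provenance: Mapping[str, Any]
):
    write_table(out / "fscna.tsv", scna.fscna_table(bundle.segments), provenance)
    amp = dele = None
    if bundle.gene_intervals:
        gene_cna = scna.gene_level_cna_matrix(bundle.segments, bundle.gene_intervals)
        write_table(
            out / "gene_cna.tsv",
            gene_cna.to_frame().rename_axis("gene").reset_index(),
            provenance,
        )
        amp, dele, n_missing = scna.binarize_cna(gene_cna)
        if n_missing:
            logger.info("binarize_cna: %d missing gene values set to 0", n_missing)
    return amp, dele


def _stage_cohort_stats(
    bundle: _Bundle, scores: dict[str, float], out: Path, provenance: Mapping[str, Any]
) -> None:
    summaries, normality = cohort_stats.lineage_summaries(scores, bundle.lineage_of)
    write_table(out / "lineage_summary.tsv", cohort_stats.lineage_table(summaries), provenance)
    if normality:
        write_table(
            out / "lineage_normality.tsv",
            pd.DataFrame(
                {
                    "lineage": [r.group for r in normality],
                    "n": [r.n for r in normality],
                    "k2": [r.k2 for r in normality],
                    "p": [r.p for r in normality],
                    "gaussian_flag": [r.gaussian_flag for r in normality],
                }
            ),
            provenance,
        )
    report = cohort_stats.distribution_report(list(scores.values()))
    for name, frame in report.items():
        write_table(out / f"distribution_{name}.tsv", frame, provenance)
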