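"""Synthetic radiogenomic cohorts with known ground truth.

Every downstream stage of the pipeline — plate scoring, fSCNA and
gene-level copy number, mutation matrices, IC screens, ssGSEA and
cohort statistics — can be exercised end-to-end on a cohort generated
here, and its output checked against the planted truth.

The generative model mirrors the structure of the real screen:

* per-lineage true integral survival ~ Normal(mean, sd) truncated to
  the 0-7 scale;
* planted binary features (mutations, amplifications, deletions) whose
  carriers are shifted by a configurable multiple of the cohort SD;
* expression programs whose linked genes shift with carrier status;
* null binary features with carriers drawn independently of survival;
* raw luminescence plates at three cell densities with mock wells and
  replicate dose wells, built by *inverting* the integral-survival
  formula: a monotone survival curve A*exp(-b*log2(dose/dmin)) is
  solved so its rescaled trapezoid score equals the line's true score,
  then multiplied into density-proportional baselines with
  multiplicative log-normal noise;
* segmented copy-number profiles tiling a toy genome whose fraction of
  altered bases hits a per-line target exactly (to coordinate rounding).

A single global seed expands into per-component child generators by
fixed stream offsets, so an identical seed yields a bitwise-identical
cohort while each component remains individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, ValidationError
from .io import GeneInterval, GeneSet, MutationRecord, NamedMatrix, SegmentRecord
from .survival import MOCK_LABEL, RESCALE, STANDARD_DOSES

# fixed stream offsets expanding the global seed into child generators
_STREAMS = {
    "truth": 1, "carriers": 2, "plates": 3, "segments": 4,
    "expression": 5, "gene_sets": 6, "nulls": 7,
}


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSpec:
    """One lineage's size and survival/instability distribution."""

    name: str
    n: int
    mean_integral_survival: float
    sd: float
    fscna_mean: float = 0.2
    fscna_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"lineage {self.name}: n must be positive")
        if self.sd <= 0 or self.fscna_sd < 0:
            raise ConfigurationError(f"lineage {self.name}: sds must be positive")


@dataclass(frozen=True)
class PlantedEffect:
    """A binary feature (or expression program) with a known survival effect.

    effect_size is the carrier shift of true integral survival in units
    of the cohort SD; linked_genes, when given, have their expression
    shifted by effect_size per-gene SDs in carriers. target_gene anchors
    amplification/deletion effects to a genome gene (defaults to the
    first linked gene, or a catalogue gene assigned by the generator).
    """

    feature_id: str
    kind: str
    prevalence: float
    effect_size: float
    linked_genes: tuple[str, ...] = ()
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"mutation", "amplification", "deletion", "expression_program"}:
            raise ConfigurationError(f"unknown planted-effect kind {self.kind!r}")
        if not 0 < self.prevalence < 1:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: named chromosomes with lengths, and a gene catalogue."""

    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneInterval, ...]

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @classmethod
    def default(
        cls,
        n_chromosomes: int = 10,
        chromosome_length: int = 1_000_000,
        genes_per_chromosome: int = 20,
        gene_length: int = 5_000,
    ) -> "GenomeModel":
        chroms = tuple((str(i + 1), chromosome_length) for i in range(n_chromosomes))
        genes: list[GeneInterval] = []
        gid = 0
        for name, length in chroms:
            spacing = length // genes_per_chromosome
            for k in range(genes_per_chromosome):
                gid += 1
                start = k * spacing + spacing // 4
                genes.append(GeneInterval(name, start, start + gene_length, f"G{gid:04d}"))
        return cls(chromosomes=chroms, genes=tuple(genes))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the real screen's assay design: the standard
    1-10 Gy dose panel, quadruplicate wells, three cell densities in
    the 25-225 cells/well range, and a 10% multiplicative luminescence
    CV as a plausible plate-noise level.
    """

    lineages: tuple[LineageSpec, ...]
    planted_features: tuple[PlantedEffect, ...] = ()
    n_null_features: int = 0
    doses: tuple[float, ...] = STANDARD_DOSES
    replicates: int = 4
    cell_densities: tuple[int, ...] = (25, 75, 225)
    noise_cv: float = 0.1
    seed: int = 0
    genome: GenomeModel = field(default_factory=GenomeModel.default)
    luminescence_per_cell: float = 1_000.0

    def __post_init__(self) -> None:
        if not self.lineages:
            raise ConfigurationError("at least one lineage required")
        if self.replicates < 1 or self.n_null_features < 0:
            raise ConfigurationError("counts must be positive")
        d = np.asarray(self.doses)
        if np.any(np.diff(d) <= 0) or np.any(d < 1):
            raise ConfigurationError("doses must be strictly increasing and >= 1 Gy")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        for eff in self.planted_features:
            if round(eff.prevalence * self.n_lines) < 1:
                raise ConfigurationError(
                    f"planted feature {eff.feature_id}: prevalence "
                    f"{eff.prevalence} x {self.n_lines} lines yields no carriers"
                )

    @property
    def n_lines(self) -> int:
        return sum(lin.n for lin in self.lineages)


def config_from_dict(raw: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML-loaded) mapping."""
    raw = dict(raw)
    lineages = tuple(LineageSpec(**lin) for lin in raw.pop("lineages"))
    planted = tuple(
        PlantedEffect(**{**p, "linked_genes": tuple(p.get("linked_genes", ()))})
        for p in raw.pop("planted_features", [])
    )
    raw.pop("genome", None)  # genome model is code-defined
    for key in ("doses", "cell_densities"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortConfig(lineages=lineages, planted_features=planted, **raw)


# ---------------------------------------------------------------------------
# dose-response inversion
# ---------------------------------------------------------------------------

def survival_curve_for_score(
    true_score: float, doses: Sequence[float] = STANDARD_DOSES
) -> np.ndarray:
    """Survival fractions at the panel doses whose trapezoid score is true_score.

    The curve family is A * exp(-b * (log2 d - log2 dmin)), monotone
    decreasing in dose with A in [0, 1]. A pure exponential (A=1) is
    pinned to 1 at the lowest dose, so its score cannot fall below half
    the first trapezoid; below that regime the amplitude A scales a
    steep exponential instead. The recomputed trapezoid score matches
    the target to root-solver precision (<1e-9).
    """
    x = np.log2(np.asarray(doses, dtype=float))
    x = x - x[0]
    max_score = RESCALE * float(np.trapezoid(np.ones_like(x), x))
    if not 0 <= true_score <= max_score + 1e-9:
        raise ValidationError(f"true_score {true_score} outside [0, {max_score:.4f}]")
    if true_score <= 0:
        return np.zeros_like(x)
    if true_score >= max_score - 1e-12:
        return np.ones_like(x)

    def score_of(b: float) -> float:
        return RESCALE * float(np.trapezoid(np.exp(-b * x), x))

    b_cap = 60.0
    floor = score_of(b_cap)
    if true_score > floor:
        b = optimize.brentq(lambda b: score_of(b) - true_score, 0.0, b_cap, xtol=1e-14)
        return np.exp(-b * x)
    amplitude = true_score / floor
    return amplitude * np.exp(-b_cap * x)


def simulate_dose_response(
    true_score: float,
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "",
) -> NamedMatrix:
    """Raw luminescence plate for one cell line.

    Rows are 'mock' plus 'd<dose>'; columns '<density>_r<rep>'. Signal =
    density-proportional baseline x survival fraction x multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` (mean 1).
    """
    fractions = survival_curve_for_score(true_score, config.doses)
    row_ids = [MOCK_LABEL] + [f"d{d:g}" for d in config.doses]
    col_ids = [
        f"{density}_r{r + 1}"
        for density in config.cell_densities
        for r in range(config.replicates)
    ]
    signal_per_row = np.concatenate([[1.0], fractions])
    baselines = np.repeat(
        [d * config.luminescence_per_cell for d in config.cell_densities],
        config.replicates,
    )
    values = signal_per_row[:, None] * baselines[None, :]
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=values.shape)
        values = values * noise
    return NamedMatrix(
        row_ids=row_ids, column_ids=col_ids, values=values, value_kind="luminescence"
    )


# ---------------------------------------------------------------------------
# segment simulation
# ---------------------------------------------------------------------------

def simulate_segments(
    lineage_fscna_target: float,
    genome: GenomeModel,
    rng: np.random.Generator,
    sample_id: str = "S",
    threshold: float = 0.2,
) -> list[SegmentRecord]:
    """Segment profile tiling the genome with fSCNA equal to the target.

    Each chromosome is cut into random tiles; altered status is assigned
    to shuffled tiles until exactly round(target * genome) bases are
    altered, splitting one tile at the boundary. Altered tiles draw
    |log2 ratio| from U(0.3, 1.2) with random sign; neutral tiles draw
    from N(0, 0.05) clipped strictly inside the threshold. The resulting
    fSCNA differs from the target only by coordinate rounding.
    """
    if not 0 <= lineage_fscna_target <= 1:
        raise ValidationError("fSCNA target must be in [0, 1]")
    tiles: list[tuple[str, int, int]] = []
    for chrom, length in genome.chromosomes:
        k = int(rng.integers(3, 9))
        cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            tiles.append((chrom, int(a), int(b)))
    total = genome.total_bp
    needed = int(round(lineage_fscna_target * total))
    order = rng.permutation(len(tiles))
    altered_flags: dict[int, bool] = {}
    extra: list[tuple[str, int, int, bool]] = []
    acc = 0
    for idx in order:
        chrom, a, b = tiles[idx]
        length = b - a
        if acc + length <= needed:
            altered_flags[idx] = True
            acc += length
        elif acc < needed:
            split = a + (needed - acc)
            altered_flags[idx] = False  # replaced by the two split parts
            extra.append((chrom, a, split, True))
            extra.append((chrom, split, b, False))
            tiles[idx] = (chrom, a, a)  # sentinel: dropped below
            acc = needed
        else:
            altered_flags[idx] = False

    records: list[SegmentRecord] = []

    def _ratio(altered: bool) -> float:
        if altered:
            return float(rng.choice([-1, 1]) * rng.uniform(threshold + 0.1, 1.2))
        return float(np.clip(rng.normal(0.0, 0.05), -(threshold - 0.01), threshold - 0.01))

    pieces = [
        (chrom, a, b, altered_flags[idx])
        for idx, (chrom, a, b) in enumerate(tiles)
        if b > a
    ] + extra
    for chrom, a, b, altered in pieces:
        records.append(
            SegmentRecord(
                sample_id=sample_id, chromosome=chrom, start=a, end=b,
                log2_ratio=_ratio(altered),
            )
        )
    chrom_order = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    records.sort(key=lambda r: (chrom_order[r.chromosome], r.start))
    return records


def impose_segment(
    segments: list[SegmentRecord],
    chromosome: str,
    start: int,
    end: int,
    log2_ratio: float,
) -> list[SegmentRecord]:
    """Overwrite [start, end) on one chromosome with a fixed ratio.

    Existing tiles are split at the interval's boundaries so the profile
    still tiles the genome without gaps or overlaps.
    """
    out: list[SegmentRecord] = []
    sample_id = segments[0].sample_id if segments else "S"
    for seg in segments:
        if seg.chromosome != chromosome or seg.end <= start or seg.start >= end:
            out.append(seg)
            continue
        if seg.start < start:
            out.append(
                SegmentRecord(seg.sample_id, seg.chromosome, seg.start, start, seg.log2_ratio)
            )
        if seg.end > end:
            out.append(
                SegmentRecord(seg.sample_id, seg.chromosome, end, seg.end, seg.log2_ratio)
            )
    out.append(SegmentRecord(sample_id, chromosome, start, end, log2_ratio))
    out.sort(key=lambda r: (r.chromosome, r.start))
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Planted ground truth: what a correct pipeline should recover."""

    true_scores: dict[str, float]
    carriers: dict[str, frozenset[str]]
    cohort_sd: float
    fscna_targets: dict[str, float]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    sample_ids: list[str]
    lineage_of: dict[str, str]
    plates: dict[str, NamedMatrix]
    segments: list[SegmentRecord]
    mutations: list[MutationRecord]
    expression: NamedMatrix
    gene_sets: list[GeneSet]
    truth: CohortTruth


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort (plates, segments, mutations, expression, sets).

    Identical configs (including seed) produce bitwise-identical cohorts.
    """
    seed = config.seed
    rng_truth = _child_rng(seed, "truth")
    rng_carriers = _child_rng(seed, "carriers")
    rng_plates = _child_rng(seed, "plates")
    rng_segments = _child_rng(seed, "segments")
    rng_expr = _child_rng(seed, "expression")
    rng_sets = _child_rng(seed, "gene_sets")
    rng_nulls = _child_rng(seed, "nulls")

    # --- sample universe and lineage-level true survival -------------------
    sample_ids: list[str] = []
    lineage_of: dict[str, str] = {}
    truths: list[float] = []
    fscna_targets: dict[str, float] = {}
    for lin in config.lineages:
        a = (0.0 - lin.mean_integral_survival) / lin.sd
        b = (7.0 - lin.mean_integral_survival) / lin.sd
        draws = stats.truncnorm.rvs(
            a, b, loc=lin.mean_integral_survival, scale=lin.sd,
            size=lin.n, random_state=rng_truth,
        )
        fscna_draws = np.clip(
            rng_truth.normal(lin.fscna_mean, lin.fscna_sd, size=lin.n), 0.0, 0.95
        )
        for i in range(lin.n):
            sid = f"{lin.name}_{len(sample_ids):04d}"
            sample_ids.append(sid)
            lineage_of[sid] = lin.name
            truths.append(float(draws[i]))
            fscna_targets[sid] = float(fscna_draws[i])
    truth_arr = np.asarray(truths)
    cohort_sd = float(truth_arr.std(ddof=1)) if len(truths) > 1 else 1.0

    # --- planted carriers shift survival -----------------------------------
    n = len(sample_ids)
    carriers: dict[str, frozenset[str]] = {}
    for eff in config.planted_features:
        n_carriers = int(round(eff.prevalence * n))
        chosen = rng_carriers.choice(n, size=n_carriers, replace=False)
        carriers[eff.feature_id] = frozenset(sample_ids[i] for i in chosen)
        truth_arr[chosen] += eff.effect_size * cohort_sd
    truth_arr = np.clip(truth_arr, 0.0, 7.0)
    true_scores = dict(zip(sample_ids, map(float, truth_arr)))

    # --- mutations ----------------------------------------------------------
    mutations: list[MutationRecord] = []
    for eff in config.planted_features:
        if eff.kind != "mutation":
            continue
        for sid in sorted(carriers[eff.feature_id]):
            pos = int(rng_carriers.integers(1, 500))
            mutations.append(
                MutationRecord(
                    gene=eff.feature_id, sample_id=sid,
                    protein_position=pos, variant_label=f"p.A{pos}V",
                )
            )
    for k in range(config.n_null_features):
        gene = f"NULL{k:04d}"
        prevalence = float(rng_nulls.uniform(0.1, 0.4))
        n_car = max(2, int(round(prevalence * n)))
        chosen = rng_nulls.choice(n, size=n_car, replace=False)
        carriers[gene] = frozenset(sample_ids[i] for i in chosen)
        for i in sorted(chosen):
            pos = int(rng_nulls.integers(1, 500))
            mutations.append(
                MutationRecord(
                    gene=gene, sample_id=sample_ids[i],
                    protein_position=pos, variant_label=f"p.A{pos}V",
                )
            )

    # --- segments, with planted amp/del imposed on carriers ----------------
    genome = config.genome
    gene_by_name = {g.gene: g for g in genome.genes}
    cna_targets: dict[str, tuple[GeneInterval, float]] = {}
    spare_genes = iter(g for g in genome.genes)
    for eff in config.planted_features:
        if eff.kind not in ("amplification", "deletion"):
            continue
        gene_name = eff.target_gene or (eff.linked_genes[0] if eff.linked_genes else None)
        if gene_name is None:
            gene_name = next(spare_genes).gene
        if gene_name not in gene_by_name:
            raise ConfigurationError(
                f"planted {eff.kind} {eff.feature_id}: gene {gene_name!r} "
                "not in the genome catalogue"
            )
        ratio = 1.0 if eff.kind == "amplification" else -1.0
        cna_targets[eff.feature_id] = (gene_by_name[gene_name], ratio)

    segments: list[SegmentRecord] = []
    for sid in sample_ids:
        profile = simulate_segments(
            fscna_targets[sid], genome, rng_segments, sample_id=sid
        )
        for eff in config.planted_features:
            if eff.feature_id not in cna_targets or sid not in carriers[eff.feature_id]:
                continue
            gene, ratio = cna_targets[eff.feature_id]
            profile = impose_segment(profile, gene.chromosome, gene.start, gene.end, ratio)
        segments.extend(profile)

    # --- expression ---------------------------------------------------------
    gene_names = [g.gene for g in genome.genes]
    base_means = rng_expr.uniform(4.0, 10.0, size=len(gene_names))
    expr = base_means[:, None] + rng_expr.normal(0.0, 1.0, size=(len(gene_names), n))
    gene_row = {g: i for i, g in enumerate(gene_names)}
    carrier_mask = {
        fid: np.array([sid in members for sid in sample_ids])
        for fid, members in carriers.items()
    }
    for eff in config.planted_features:
        if not eff.linked_genes:
            continue
        mask = carrier_mask[eff.feature_id]
        for gname in eff.linked_genes:
            if gname not in gene_row:
                raise ConfigurationError(
                    f"linked gene {gname!r} not in the genome catalogue"
                )
            expr[gene_row[gname], mask] += eff.effect_size
    expression = NamedMatrix(
        row_ids=gene_names, column_ids=list(sample_ids), values=expr,
        value_kind="expression",
    )

    # --- gene sets ----------------------------------------------------------
    gene_sets: list[GeneSet] = []
    for eff in config.planted_features:
        if eff.linked_genes:
            gene_sets.append(
                GeneSet(
                    name=f"{eff.feature_id}_program",
                    description=f"genes co-regulated with {eff.feature_id}",
                    members=frozenset(eff.linked_genes),
                )
            )
    # background sets sized to leave a non-trivial complement on small genomes
    set_size = min(20, max(5, len(gene_names) // 4), max(2, len(gene_names) - 5))
    for k in range(5):
        members = rng_sets.choice(gene_names, size=set_size, replace=False)
        gene_sets.append(
            GeneSet(
                name=f"RANDOM_SET_{k + 1}",
                description="random background set",
                members=frozenset(members.tolist()),
            )
        )

    # --- plates -------------------------------------------------------------
    plates = {
        sid: simulate_dose_response(true_scores[sid], config, rng_plates, sample_id=sid)
        for sid in sample_ids
    }

    return SyntheticCohort(
        config=config,
        sample_ids=sample_ids,
        lineage_of=lineage_of,
        plates=plates,
        segments=segments,
        mutations=mutations,
        expression=expression,
        gene_sets=gene_sets,
        truth=CohortTruth(
            true_scores=true_scores,
            carriers=carriers,
            cohort_sd=cohort_sd,
            fscna_targets=fscna_targets,
        ),
    )
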