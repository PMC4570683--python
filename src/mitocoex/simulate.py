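"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design this pipeline targets: a factorial
RNA-seq experiment (cell lines × treatments × replicates, default
4 × 4 × 2 = 32 samples) measured as an RPKM matrix, plus a conserved-TFBS
promoter annotation for enrichment analysis.

Expression model: for gene g in sample s,

    log-expression(g, s) = baseline(g) + loading(m) · factor(m, s) + ε,
    ε ~ Normal(0, noise_sd²),  RPKM = exp(log-expression)

where genes of a planted module m share a latent per-sample factor, so the
expected within-module Pearson correlation is loading² / (loading² +
noise_sd²).  Modules emulate co-regulated gene groups (a tightly coupled
subunit-like module, optionally a weakly coupled assembly-factor-like one).

TFBS model: each gene gets one transcription start site on a synthetic
contig; each (TF, gene) target relationship is Bernoulli — probability p1
for the planted TF on its enriched gene set, p0 otherwise — and every
target relationship is realized as at least one motif interval inside the
gene's promoter window.  Ground truth (module membership, TF target table)
is returned alongside every dataset so recovery can be scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .containers import MITOCHONDRIAL, NUCLEAR, ExpressionMatrix, GeneSetCatalog, SampleDesign
from .tfbs import TfbsTargetMap

DEFAULT_TREATMENTS = ("DMSO", "chloramphenicol", "AICAR", "resveratrol")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``loading`` scales the shared latent factor (log-expression units per
    factor SD); ``treatment_shifts`` optionally adds a per-treatment offset
    to the factor, mimicking a treatment-driven response.
    """

    size: int
    loading: float
    label: str
    treatment_shifts: dict[str, float] | None = None


@dataclass
class SimulationConfig:
    """Parameters of the expression simulation.

    Defaults reproduce the factorial design the pipeline was built around:
    4 cell lines (first half control, rest patient) × 4 treatments × 2
    replicates.  ``baseline_log_mean``/``baseline_log_sd`` are on the
    natural-log scale (median RPKM ≈ exp(baseline_log_mean)).
    """

    n_genes: int = 2000
    n_cell_lines: int = 4
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_replicates: int = 2
    module_specs: tuple[ModuleSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 1.5
    n_mito: int = 0
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cell_lines <= 0 or self.n_replicates < 1:
            raise ConfigError("counts must be positive and replicates ≥ 1")
        if len(self.treatments) == 0:
            raise ConfigError("at least one treatment is required")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigError("dropout_prob must be in [0, 1)")
        if sum(m.size for m in self.module_specs) > self.n_genes - self.n_mito:
            raise ConfigError("module sizes exceed the number of nuclear genes")
        if self.n_mito < 0 or self.n_mito > self.n_genes:
            raise ConfigError("n_mito must lie in [0, n_genes]")


def generate_design(config: SimulationConfig) -> SampleDesign:
    """Enumerate the full factorial design.

    Produces ``n_cell_lines × len(treatments) × n_replicates`` samples; the
    first half of the cell lines are labeled ``control``, the rest
    ``patient``.
    """
    n_control = config.n_cell_lines // 2
    rows = []
    for (ci, treatment, rep) in itertools.product(
        range(config.n_cell_lines), config.treatments, range(1, config.n_replicates + 1)
    ):
        cell_line = f"CL{ci + 1}"
        genotype = "control" if ci < n_control else "patient"
        rows.append(
            {
                "sample_id": f"{cell_line}_{treatment}_r{rep}",
                "cell_line": cell_line,
                "genotype": genotype,
                "treatment": treatment,
                "replicate": rep,
            }
        )
    return SampleDesign(pd.DataFrame(rows))


@dataclass
class ExpressionSimResult:
    """Simulated matrix plus the ground truth needed to score recovery."""

    matrix: ExpressionMatrix
    design: SampleDesign
    membership: pd.Series  # gene id → module label ("" for background)
    factors: pd.DataFrame  # module label × sample latent factor values
    config: SimulationConfig

    def module_genes(self, label: str) -> list[str]:
        return list(self.membership.index[self.membership == label])


def generate_expression(design: SampleDesign, config: SimulationConfig) -> ExpressionSimResult:
    """Draw an RPKM matrix under the latent-factor model.

    Module genes occupy consecutive blocks at the top of the gene list;
    mitochondrial genes (if any) come last and never belong to a module.
    """
    if len(design) == 0:
        raise ConfigError("design has no samples")
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = config.n_genes, len(design)

    n_nuclear = n_genes - config.n_mito
    gene_ids = [f"G{i + 1:05d}" for i in range(n_nuclear)]
    gene_ids += [f"MT-G{i + 1:02d}" for i in range(config.n_mito)]
    origin = pd.Series(
        [NUCLEAR] * n_nuclear + [MITOCHONDRIAL] * config.n_mito, index=gene_ids
    )

    membership = pd.Series("", index=gene_ids, dtype=object)
    loading = np.zeros(n_genes)
    module_of = np.full(n_genes, -1)
    start = 0
    for mi, spec in enumerate(config.module_specs):
        sl = slice(start, start + spec.size)
        membership.iloc[sl] = spec.label
        loading[sl] = spec.loading
        module_of[sl] = mi
        start += spec.size

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_genes)
    factors = rng.standard_normal((max(len(config.module_specs), 1), n_samples))
    factors = factors[: len(config.module_specs)]
    for mi, spec in enumerate(config.module_specs):
        if spec.treatment_shifts:
            shift = np.array(
                [spec.treatment_shifts.get(t, 0.0) for t in design.table["treatment"]]
            )
            factors[mi] += shift

    log_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    in_module = module_of >= 0
    if in_module.any():
        log_expr[in_module] += loading[in_module, None] * factors[module_of[in_module]]

    rpkm = np.exp(log_expr)
    if config.dropout_prob > 0:
        rpkm[rng.random(rpkm.shape) < config.dropout_prob] = 0.0

    data = pd.DataFrame(rpkm, index=gene_ids, columns=design.sample_ids)
    matrix = ExpressionMatrix(data, state="raw", origin=origin)
    factor_df = pd.DataFrame(
        factors, index=[m.label for m in config.module_specs], columns=design.sample_ids
    )
    return ExpressionSimResult(matrix, design, membership, factor_df, config)


# ------------------------------------------------------------------ TFBS sim

@dataclass
class TfbsSimConfig:
    """Parameters of the promoter/TFBS simulation.

    ``p0`` is the background probability that any TF targets any gene;
    ``p1`` the elevated probability for the planted TF on the enriched gene
    set.  Defaults emulate a motif resource in which most TFs have a
    handful of similar binding motifs.
    """

    n_tfs: int = 50
    p0: float = 0.1
    enriched_tf_label: str = "TF_PLANTED"
    p1: float = 0.5
    enriched_genes: tuple[str, ...] = ()
    motifs_per_tf: int = 2
    promoter_halfwidth: int = 2000
    gene_spacing: int = 10_000
    contig: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= self.p1 <= 1.0):
            raise ConfigError("require 0 ≤ p0 ≤ p1 ≤ 1")
        if self.motifs_per_tf < 1:
            raise ConfigError("motifs_per_tf must be ≥ 1")
        if self.n_tfs < 1:
            raise ConfigError("n_tfs must be ≥ 1")
        if self.promoter_halfwidth <= 0:
            raise ConfigError("promoter_halfwidth must be > 0")


@dataclass
class TfbsSimResult:
    """TSS/TFBS annotation plus the ground-truth target table."""

    tss: list[mio.BedRecord]
    sites: list[mio.BedRecord]
    motif_map: dict[str, str]
    truth: pd.DataFrame  # genes × TFs, bool
    config: TfbsSimConfig

    def target_map(self) -> TfbsTargetMap:
        """Collapse the ground-truth table to a per-gene TF set map."""
        return target_map_from_truth(self.truth)


def target_map_from_truth(truth: pd.DataFrame) -> TfbsTargetMap:
    """Ground-truth gene × TF boolean table → TfbsTargetMap."""
    tfs = np.asarray(truth.columns)
    values = truth.to_numpy(dtype=bool)
    targets = {
        gene: set(tfs[row]) for gene, row in zip(truth.index, values)
    }
    counts = {(g, tf): 1 for g, s in targets.items() for tf in s}
    return TfbsTargetMap(targets=targets, provenance=counts)


def _tf_names(config: TfbsSimConfig) -> list[str]:
    names = [f"TF{i + 1:03d}" for i in range(config.n_tfs - 1)]
    return [config.enriched_tf_label] + names


def simulate_target_truth(genes: list[str], config: TfbsSimConfig) -> pd.DataFrame:
    """Draw the Bernoulli target table only (no interval realization).

    Used where the genomic realization adds nothing, e.g. large null
    calibrations of the enrichment statistics.
    """
    genes = list(genes)
    missing = set(config.enriched_genes) - set(genes)
    if missing:
        raise ConfigError(f"enriched genes not in gene list: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed)
    tfs = _tf_names(config)
    probs = np.full((len(genes), len(tfs)), config.p0)
    enriched_rows = [i for i, g in enumerate(genes) if g in set(config.enriched_genes)]
    probs[enriched_rows, 0] = config.p1  # column 0 is the planted TF
    draws = rng.random((len(genes), len(tfs))) < probs
    return pd.DataFrame(draws, index=genes, columns=tfs)


def generate_tfbs_annotation(genes: list[str], config: TfbsSimConfig) -> TfbsSimResult:
    """Generate TSS BED, TFBS BED, motif→TF map and the ground-truth table.

    Each gene gets one TSS, spaced so promoter windows of different genes
    never overlap; each target relationship is realized as 1–2 motif
    intervals drawn uniformly inside the promoter window.
    """
    truth = simulate_target_truth(genes, config)
    rng = np.random.default_rng(config.seed + 1)
    genes = list(genes)
    tfs = list(truth.columns)
    hw = config.promoter_halfwidth

    motif_map: dict[str, str] = {}
    for tf in tfs:
        for j in range(config.motifs_per_tf):
            motif_map[f"{tf}_m{j + 1}"] = tf

    tss_records = []
    tss_pos: dict[str, int] = {}
    for i, gene in enumerate(genes):
        pos = config.gene_spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        tss_pos[gene] = pos
        tss_records.append(mio.BedRecord(config.contig, pos, pos + 1, gene, 0.0, strand))

    site_records = []
    truth_np = truth.to_numpy()
    for gi, gene in enumerate(genes):
        win_start, win_end = tss_pos[gene] - hw, tss_pos[gene] + hw
        for ti in np.flatnonzero(truth_np[gi]):
            tf = tfs[ti]
            for _ in range(int(rng.integers(1, 3))):
                length = int(rng.integers(8, 15))
                start = int(rng.integers(win_start, win_end - length))
                motif = f"{tf}_m{int(rng.integers(1, config.motifs_per_tf + 1))}"
                site_records.append(
                    mio.BedRecord(config.contig, start, start + length, motif)
                )
    return TfbsSimResult(tss_records, site_records, motif_map, truth, config)


# ------------------------------------------------------------------- dataset

def write_dataset(
    outdir,
    expr: ExpressionSimResult,
    tfbs: TfbsSimResult | None = None,
    bait_label: str | None = None,
    bait_genes: list[str] | None = None,
) -> None:
    """Write a complete observable dataset plus ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_expression(expr.matrix, outdir / "expression.tsv")
    mio.write_sample_sheet(expr.design, outdir / "samples.tsv")
    mio.write_origin(expr.matrix.origin, outdir / "gene_origin.tsv")
    sets = {
        spec.label: expr.module_genes(spec.label) for spec in expr.config.module_specs
    }
    if bait_label and bait_genes:
        sets[bait_label] = list(bait_genes)
    if sets:
        mio.write_gmt(GeneSetCatalog(sets), outdir / "genesets.gmt")
    expr.membership.rename("module").to_csv(
        outdir / "truth_modules.tsv", sep="\t", index_label="gene_id"
    )
    if tfbs is not None:
        mio.write_bed(tfbs.tss, outdir / "tss.bed", fields=6)
        mio.write_bed(tfbs.sites, outdir / "tfbs.bed", fields=4)
        mio.write_motif_map(tfbs.motif_map, outdir / "motif_map.tsv")
        tfbs.truth.to_csv(outdir / "truth_tf_targets.tsv", sep="\t", index_label="gene_id")
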