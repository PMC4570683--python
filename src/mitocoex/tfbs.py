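"""Promoter-window TFBS mapping and per-TF over-representation tests.

Promoters are symmetric windows centered on every annotated transcription
start site (default 2 kb up- and downstream, i.e. a 4 kb window); a gene is
a target of a TF if any conserved binding-site interval of any of the TF's
motifs overlaps any promoter window of the gene by at least one base
(0-based half-open semantics throughout).  Over-representation of each TF
in a test gene set against a background is assessed with a one-sided
Fisher's exact test, corrected across TFs by Bonferroni and
Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BedRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterWindow:
    chrom: str
    start: int
    end: int
    gene: str
    truncated: bool = False


@dataclass
class PromoterMap:
    """Gene id → promoter windows (a gene may have several TSSs)."""

    windows: dict[str, list[PromoterWindow]]
    half_width: int

    @property
    def genes(self) -> set[str]:
        return set(self.windows)

    def all_windows(self) -> list[PromoterWindow]:
        return [w for ws in self.windows.values() for w in ws]


@dataclass
class TfbsTargetMap:
    """Gene id → set of TFs with ≥1 conserved site in a promoter window.

    Genes without promoter annotation are absent from the map (not present
    with an empty set); ``provenance`` counts motif instances per
    (gene, TF) pair.
    """

    targets: dict[str, set[str]]
    provenance: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.targets)

    @property
    def tfs(self) -> set[str]:
        return {tf for s in self.targets.values() for tf in s}

    def targets_of(self, tf: str) -> set[str]:
        return {g for g, s in self.targets.items() if tf in s}


def build_promoters(tss: list[BedRecord], half_width: int = 2000) -> PromoterMap:
    """Expand TSS records to symmetric promoter windows.

    The TSS coordinate is the strand-appropriate end of the input feature
    (``start`` on +, ``end − 1`` on −); windows truncated at the contig
    start (coordinate 0) are flagged.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    windows: dict[str, list[PromoterWindow]] = {}
    for rec in tss:
        pos = rec.start if rec.strand != "-" else rec.end - 1
        start = pos - half_width
        truncated = start < 0
        start = max(start, 0)
        win = PromoterWindow(rec.chrom, start, pos + half_width, rec.name, truncated)
        windows.setdefault(rec.name, []).append(win)
    return PromoterMap(windows, half_width)


def map_tfbs(
    sites: list[BedRecord],
    motif_map: dict[str, str],
    promoters: PromoterMap,
) -> TfbsTargetMap:
    """Overlay conserved binding sites on promoter windows.

    Collapses motifs to their TF: gene g is a target of TF t iff at least
    one interval of any motif of t overlaps (≥1 bp) at least one promoter
    window of g.  Every gene with promoter annotation appears in the map,
    with an empty TF set if nothing overlaps.  Unresolvable motif ids and
    contigs absent from the promoter annotation are skipped with a log
    message.
    """
    trees: dict[str, IntervalTree] = {}
    for win in promoters.all_windows():
        if win.end > win.start:
            trees.setdefault(win.chrom, IntervalTree()).addi(win.start, win.end, win.gene)

    targets: dict[str, set[str]] = {g: set() for g in promoters.windows}
    provenance: dict[tuple[str, str], int] = {}
    unresolved: set[str] = set()
    skipped_contigs: set[str] = set()
    for rec in sites:
        tf = motif_map.get(rec.name)
        if tf is None:
            unresolved.add(rec.name)
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            skipped_contigs.add(rec.chrom)
            continue
        if rec.end <= rec.start:
            continue
        for hit in tree.overlap(rec.start, rec.end):
            gene = hit.data
            targets[gene].add(tf)
            provenance[(gene, tf)] = provenance.get((gene, tf), 0) + 1
    if unresolved:
        logger.warning("unresolvable motif ids skipped: %s", sorted(unresolved)[:10])
    if skipped_contigs:
        logger.warning("sites on contigs without promoters skipped: %s",
                       sorted(skipped_contigs))
    return TfbsTargetMap(targets, provenance)


def tf_enrichment(
    test_set: set[str],
    background: set[str],
    targets: TfbsTargetMap,
    alternative: str = "greater",
    annotated_only: bool = True,
) -> pd.DataFrame:
    """Per-TF Fisher's exact over-representation of the test set.

    Both sets are intersected with the annotated universe (genes carrying
    ≥1 promoter annotation) before counting, unless ``annotated_only`` is
    False, in which case unannotated background genes count as universal
    non-targets.  Returns one row per TF seen in the universe, with the
    2×2 counts, fold enrichment, raw p and Bonferroni/BH-adjusted p.
    """
    test_set, background = set(test_set), set(background)
    if not test_set <= background:
        raise ValueError("test set must be a subset of the background")
    universe = background & targets.genes if annotated_only else background
    test = test_set & universe
    if not test:
        raise ValueError("no test-set genes in the annotated universe")
    n_bg = len(universe)
    n_test = len(test)

    tf_to_genes: dict[str, set[str]] = {tf: set() for tf in targets.tfs}
    for g in universe:
        for tf in targets.targets.get(g, ()):
            tf_to_genes[tf].add(g)

    rows = []
    for tf in sorted(tf_to_genes):
        tf_targets = tf_to_genes[tf]
        a = len(tf_targets & test)
        b = n_test - a
        c = len(tf_targets) - a
        d = n_bg - n_test - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        expected = (a + c) / n_bg
        fold = (a / n_test) / expected if expected > 0 else math.nan
        rows.append({"tf": tf, "a": a, "b": b, "c": c, "d": d, "fold": fold, "p_raw": p})
    table = pd.DataFrame(rows).set_index("tf")
    table["p_bonferroni"] = adjust_pvalues(table["p_raw"].tolist(), "bonferroni")
    table["p_bh"] = adjust_pvalues(table["p_raw"].tolist(), "bh")
    table["rank"] = table["p_raw"].rank(method="first").astype(int)
    return table


def adjust_pvalues(p: list[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (min(1, m·p)) or ``bh``
    (Benjamini-Hochberg step-up, monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def rank_tfs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sort by raw p ascending and flag individually/BH-significant TFs."""
    out = table.sort_index().sort_values("p_raw", kind="stable").copy()
    out["significant_raw"] = out["p_raw"] < alpha
    out["significant_bh"] = out["p_bh"] < alpha
    out["rank"] = np.arange(1, len(out) + 1)
    return out
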