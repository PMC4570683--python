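"""Bait-set co-expression scoring and top-fraction candidate selection.

For a bait set S (here: the nuclear-encoded complex I subunits plus the
assembly factors NDUFAF1-4, TMEM126B and ACAD9) the co-expression score of
gene g is

    c(g, S) = avg { ρ(e[g], e[g']) : g' ∈ S, ρ(e[g], e[g']) ≥ 0 }

— the arithmetic mean of the *non-negative* standard Pearson correlations
between g's normalized expression profile and each bait member's.
Discarding negative correlations makes the score sensitive to genes that
follow the transcriptional program of any positively co-regulated subset
of the baits without being penalized for anti-correlation with another
subset.  Candidates are the top fraction (default 5 %) of the score
ranking over the nuclear-gene universe.

Conventions (stated because the score definition leaves them open):
scoring a gene that is itself a bait excludes the self-pair by default
(ρ = 1 identically would inflate bait scores); a gene with no non-negative
bait correlation scores 0 so every gene stays rankable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NUCLEAR, ExpressionMatrix, GeneSetCatalog

logger = logging.getLogger(__name__)


@dataclass
class BaitSet:
    """Named reference gene set; members are resolved against the matrix
    (missing members are logged and skipped, an empty resolution raises)."""

    label: str
    members: list[str]

    def __post_init__(self) -> None:
        self.members = list(dict.fromkeys(self.members))
        if not self.members:
            raise ValueError("bait set is empty")

    def resolve(self, matrix: ExpressionMatrix) -> list[str]:
        present = [g for g in self.members if g in matrix.data.index]
        missing = sorted(set(self.members) - set(present))
        if missing:
            logger.warning("bait set %r: %d member(s) absent from the matrix: %s",
                           self.label, len(missing), missing[:5])
        if not present:
            raise ValueError(f"no bait members of {self.label!r} present in the matrix")
        return present


def pairwise_pearson(profile: np.ndarray, baits: np.ndarray) -> np.ndarray:
    """Standard (centered) Pearson ρ of one profile against each bait row.

    A constant profile on either side yields NaN for that pair (undefined
    correlation, excluded downstream).
    """
    profile = np.asarray(profile, dtype=float)
    baits = np.atleast_2d(np.asarray(baits, dtype=float))
    if profile.size < 3 or baits.shape[1] != profile.size:
        raise ValueError("profiles must have equal length ≥ 3")
    x = profile - profile.mean()
    b = baits - baits.mean(axis=1, keepdims=True)
    sx = np.sqrt((x ** 2).sum())
    sb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (b @ x) / (sb * sx)
    rho[(sb == 0) | np.isnan(rho)] = np.nan
    if sx == 0:
        rho[:] = np.nan
    return np.clip(rho, -1.0, 1.0)


def bait_coexpression_score(
    gene: str,
    baits: BaitSet,
    matrix: ExpressionMatrix,
    include_self: bool = False,
) -> tuple[float, int]:
    """c(g, S) for a single gene: (score, count of baits with ρ ≥ 0)."""
    if gene not in matrix.data.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    members = baits.resolve(matrix)
    if not include_self:
        members = [m for m in members if m != gene]
    if not members:
        return 0.0, 0
    rho = pairwise_pearson(
        matrix.data.loc[gene].to_numpy(),
        matrix.data.loc[members].to_numpy(),
    )
    pos = rho[np.isfinite(rho) & (rho >= 0)]
    if pos.size == 0:
        return 0.0, 0
    return float(pos.mean()), int(pos.size)


def score_all(
    matrix: ExpressionMatrix,
    baits: BaitSet,
    universe: str = "nuclear",
    include_self: bool = False,
) -> pd.DataFrame:
    """Score every gene of the universe against the bait set.

    ``universe``: ``nuclear`` (default — candidates are ranked among
    nuclear genes only, though baits may correlate with anything in the
    matrix) or ``all``.  Returns a DataFrame indexed by gene with columns
    score, n_pos, rank (dense, 1 = best) and the selection flag column
    initialized to False (filled by :func:`rank_and_cutoff`).
    """
    if matrix.state != "centered":
        raise ValueError("co-expression expects the median-centered state")
    if universe == "nuclear":
        scored = matrix.nuclear()
    elif universe == "all":
        scored = matrix
    else:
        raise ValueError(f"unknown universe {universe!r}")
    if scored.n_genes == 0:
        raise ValueError("empty scoring universe")

    members = baits.resolve(matrix)
    bait_values = matrix.data.loc[members].to_numpy(dtype=float)
    values = scored.values()

    # centered Pearson of every universe gene against every bait, vectorized
    x = values - values.mean(axis=1, keepdims=True)
    b = bait_values - bait_values.mean(axis=1, keepdims=True)
    sx = np.sqrt((x ** 2).sum(axis=1))
    sb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (x @ b.T) / np.outer(sx, sb)
    rho = np.clip(rho, -1.0, 1.0)
    if (sx == 0).any():
        logger.warning("%d constant profile(s) in the scoring universe", int((sx == 0).sum()))

    if not include_self:
        gene_pos = {g: i for i, g in enumerate(scored.gene_ids)}
        for j, m in enumerate(members):
            if m in gene_pos:
                rho[gene_pos[m], j] = np.nan

    mask = np.isfinite(rho) & (rho >= 0)
    n_pos = mask.sum(axis=1)
    sums = np.where(mask, rho, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.where(n_pos > 0, sums / np.maximum(n_pos, 1), 0.0)

    table = pd.DataFrame(
        {"score": scores, "n_pos": n_pos.astype(int)}, index=scored.gene_ids
    )
    table.index.name = "gene_id"
    table["rank"] = table["score"].rank(method="dense", ascending=False).astype(int)
    table["selected"] = False
    return table


def rank_and_cutoff(table: pd.DataFrame, fraction: float = 0.05) -> tuple[pd.DataFrame, float]:
    """Select the top ``fraction`` of genes by score.

    Exactly ``floor(fraction × n)`` genes are selected, ties at the
    boundary broken by ascending gene id (stable, documented).  Returns
    the table with the ``selected`` flag filled and the cutoff score (the
    minimum selected score).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_selected = math.floor(fraction * len(table))
    if n_selected == 0:
        raise ValueError(f"fraction {fraction} of {len(table)} genes selects nothing")
    # stable sort: descending score, ties broken by ascending gene id
    order = table.sort_index(kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )
    chosen = order.index[:n_selected]
    out = table.copy()
    out["selected"] = out.index.isin(chosen)
    cutoff = float(table.loc[chosen, "score"].min())
    return out, cutoff


def group_score_distributions(
    table: pd.DataFrame,
    catalog: GeneSetCatalog,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group five-number summaries of the co-expression scores.

    Groups must be mutually exclusive.  Genes absent from the score table
    are ignored.  Returns a DataFrame indexed by group with n, min, q1,
    median, q3, max; raw per-group score lists are attached as the
    ``scores`` column for downstream tests.
    """
    groups = list(groups) if groups is not None else catalog.names
    catalog.validate_exclusive(groups)
    rows = []
    for name in groups:
        present = [g for g in catalog[name] if g in table.index]
        vals = table.loc[present, "score"].to_numpy()
        if vals.size:
            q = np.percentile(vals, [0, 25, 50, 75, 100])
        else:
            q = [np.nan] * 5
        rows.append(
            {"group": name, "n": len(vals), "min": q[0], "q1": q[1],
             "median": q[2], "q3": q[3], "max": q[4], "scores": vals.tolist()}
        )
    return pd.DataFrame(rows).set_index("group")
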