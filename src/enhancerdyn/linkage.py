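"""Regulated-gene calling, site-gene association, expression kinetics, stats.

Expression tables are pandas DataFrames with gene ids as index and condition
labels (time points or cell types) as columns; all values are non-negative.
Fold changes are computed after adding a small floor to numerator and
denominator, which keeps background-level ratios tame and all-zero genes
"unchanged".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneAnnotation, PeakSet, ValidationError

EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    fold: float
    label: str  # up | down | unchanged


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if (expr.values < 0).any():
        raise ValidationError("expression values must be >= 0")
    if expr.index.has_duplicates:
        raise ValidationError("duplicate gene ids in expression table")
    return expr


def read_expression(path) -> pd.DataFrame:
    """Expression TSV: first column gene_id, header row of condition labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    return validate_expression(df)


def call_regulated(
    expr: pd.DataFrame,
    baseline: str,
    terminal: str,
    fold_threshold: float = 2.0,
    floor: float = 1.0,
) -> list[RegulationCall]:
    """Call genes up/down/unchanged by floored terminal/baseline fold.

    fold = (terminal + floor) / (baseline + floor); up iff fold > threshold,
    down iff fold < 1/threshold, unchanged otherwise.
    """
    validate_expression(expr)
    if floor <= 0:
        raise ValidationError("floor must be > 0")
    folds = (expr[terminal] + floor) / (expr[baseline] + floor)
    calls = []
    for gene, fold in folds.items():
        if fold > fold_threshold:
            label = "up"
        elif fold < 1.0 / fold_threshold:
            label = "down"
        else:
            label = "unchanged"
        calls.append(RegulationCall(str(gene), float(fold), label))
    return calls


def window_fraction_curve(
    genes: Sequence[str],
    annotation: GeneAnnotation,
    sites: PeakSet,
    windows: Sequence[int],
) -> list[tuple[int, float]]:
    """Fraction of genes whose TSS lies within each window of a site center.

    Distance is |TSS - nearest site midpoint| (unsigned); genes on
    chromosomes without sites count as farther than any window.  The curve
    is monotone non-decreasing in the window size.
    """
    if list(windows) != sorted(windows):
        raise ValidationError("windows must be sorted ascending")
    if not genes:
        raise ValidationError("no genes to associate")
    tss_lookup = {gid: (iv.chrom, GeneAnnotation.tss_of(iv)) for gid, iv in annotation.genes}
    centers: dict[str, np.ndarray] = {}
    for iv in sites.intervals:
        centers.setdefault(iv.chrom, [])
    tmp: dict[str, list[int]] = {}
    for iv in sites.intervals:
        tmp.setdefault(iv.chrom, []).append(iv.midpoint)
    centers = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in tmp.items()}

    dists = np.full(len(genes), np.inf)
    for i, gid in enumerate(genes):
        if gid not in tss_lookup:
            raise ValidationError(f"gene {gid!r} missing from annotation")
        chrom, tss = tss_lookup[gid]
        mids = centers.get(chrom)
        if mids is None or mids.size == 0:
            continue
        j = int(np.searchsorted(mids, tss))
        best = np.inf
        for k in (j - 1, j):
            if 0 <= k < mids.size:
                best = min(best, abs(tss - int(mids[k])))
        dists[i] = best
    return [(int(w), float(np.mean(dists <= w))) for w in windows]


def class_expression_kinetics(
    records,
    expr: pd.DataFrame,
    baseline: str,
    time_points: Sequence[str] | None = None,
    label_filter: str = "up",
    fold_threshold: float = 2.0,
    floor: float = 1.0,
    classes: tuple[str, ...] = ("pre_existing", "de_novo"),
    by: str = "final_class",
) -> dict[str, dict[str, float]]:
    """Per final class, median fold over baseline of upregulated nearest genes.

    For each class, the gene set is the (deduplicated) nearest genes of its
    enhancers restricted to genes called ``label_filter``; per time point,
    the median of floored per-gene folds is reported.
    """
    if time_points is None:
        time_points = list(expr.columns)
    terminal = time_points[-1]
    calls = {
        c.gene_id: c.label
        for c in call_regulated(expr, baseline, terminal, fold_threshold, floor)
    }
    out: dict[str, dict[str, float]] = {}
    for cls in classes:
        genes = sorted(
            {
                r.nearest_gene
                for r in records
                if getattr(r, by) == cls
                and r.nearest_gene is not None
                and calls.get(r.nearest_gene) == label_filter
            }
        )
        per_time: dict[str, float] = {}
        for t in time_points:
            if genes:
                folds = (expr.loc[genes, t] + floor) / (expr.loc[genes, baseline] + floor)
                per_time[str(t)] = float(np.median(folds))
            else:
                per_time[str(t)] = float("nan")
        out[cls] = per_time
    return out


def normalize_celltypes(expr: pd.DataFrame) -> pd.DataFrame:
    """Divide each condition column by its own mean (column means become 1)."""
    validate_expression(expr)
    means = expr.mean(axis=0)
    if (means == 0).any():
        raise ValidationError("cannot normalize a zero-mean condition column")
    return expr / means


# ---------------------------------------------------------------------------
# Group-comparison statistics


def _ranksum_exact_p(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Two-tailed exact p for the rank-sum of the first group.

    Enumerates all C(n, n_a) assignments of the pooled ranks to group a;
    handles ties exactly because tied values share mid-ranks in every
    assignment.  The two-sided p is twice the smaller one-sided tail,
    capped at 1 (the standard exact convention).  Returns (rank sum, p).
    """
    n = ranks.size
    observed = float(ranks[:n_a].sum())
    total = comb(n, n_a)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        s = float(ranks[list(idx)].sum())
        if s <= observed + 1e-12:
            le += 1
        if s >= observed - 1e-12:
            ge += 1
    return observed, min(1.0, 2.0 * min(le, ge) / total)


def _ranksum_normal_p(ranks: np.ndarray, n_a: int, alternative: str) -> tuple[float, float]:
    """Tie-corrected normal approximation to the rank-sum null."""
    n = ranks.size
    n_b = n - n_a
    observed = float(ranks[:n_a].sum())
    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return observed, 1.0
    z = (observed - mean) / np.sqrt(var)
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = stats.norm.sf(z)
    return observed, float(np.clip(p, np.finfo(float).tiny, 1.0))


def compare_groups(
    a: Sequence[float], b: Sequence[float], test: str = "wilcoxon_two_tailed"
) -> tuple[float, float]:
    """Group comparison used for coverage/expression contrasts.

    test="wilcoxon_two_tailed": Wilcoxon rank-sum, two-tailed; the null is
    evaluated by full enumeration for combined n <= 20 and by the
    tie-corrected normal approximation otherwise.  Returns (rank sum of a, p).

    test="t_one_tailed": one-tailed Student's t (alternative: mean(a) >
    mean(b)).  Returns (t statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if test == "t_one_tailed":
        res = stats.ttest_ind(a, b, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    if test != "wilcoxon_two_tailed":
        raise ValidationError(f"unknown test {test!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    if pooled.size <= EXACT_RANKSUM_MAX_N:
        return _ranksum_exact_p(ranks, a.size)
    return _ranksum_normal_p(ranks, a.size, "two-sided")
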