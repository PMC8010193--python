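"""Gene-set scoring and in/out-of-region differential expression.

Single-sample GSEA (ssGSEA) summarizes, for one sample at a time, how
coordinately up- or down-regulated the genes of a set are: genes are ranked
by expression within the sample and the enrichment score is the integrated
difference between the weighted in-set rank ECDF and the uniform out-of-set
ECDF. Being rank-based, the score is invariant to any strictly increasing
transform of a sample's expression values.

With rank positions r_1 < ... < r_N (1 = highest expression), in-set
indicator s_i and weight w_i = r_i**alpha for in-set genes:

    ES = sum_k [ P_in(k) - P_out(k) ]
    P_in(k)  = sum_{i<=k} s_i * w_i / sum_i s_i * w_i
    P_out(k) = sum_{i<=k} (1-s_i) / (N - |S|)

Downstream, enrichment scores and single genes are compared between samples
in and outside the reference region with a pooled-variance two-sample
t-test; a purity proxy combines immune and stromal signature scores (high
immune/stromal content implies low tumor-cell fraction).

Expression matrices are pandas DataFrames (genes x samples) assumed to be
on a log-like, monotone-comparable scale; a log2(x+1) pre-transform flag is
available for raw intensities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "ScoringConfig",
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "purity_proxy",
    "celltype_scores",
    "diff_by_group",
    "differential_expression",
    "rank_diff_genes",
    "significance_stars",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class ScoringConfig:
    """ssGSEA settings.

    weight_exponent: rank-weight exponent alpha (0 = unweighted Kolmogorov-
        Smirnov-like running sum; 0.25 is the conventional single-sample
        choice and the default).
    tie_policy: "average" uses average rank positions as weights for tied
        values; "first" breaks ties by gene order.
    normalize: optional min-max rescaling of scores across samples.
    log2_transform: apply log2(x+1) to the matrix before ranking.
    """

    weight_exponent: float = 0.25
    tie_policy: Literal["average", "first"] = "average"
    normalize: Literal["none", "minmax"] = "none"
    log2_transform: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight_exponent) or self.weight_exponent < 0:
            raise ValueError("weight_exponent must be finite and >= 0")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = GeneSet(parts[0], frozenset(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> Path:
    lines = [
        "\t".join([s.name, "na", *sorted(s.genes)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _prep_matrix(expr: pd.DataFrame, config: ScoringConfig) -> pd.DataFrame:
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    if config.log2_transform:
        expr = np.log2(expr + 1.0)
    return expr


def ssgsea_score(
    expr: pd.DataFrame, gene_set: GeneSet, config: ScoringConfig | None = None
) -> pd.Series:
    """Per-sample ssGSEA enrichment score for one gene set.

    ``expr`` is genes x samples. Genes of the set absent from the matrix are
    ignored; it is an error when none remain or when the set swallows the
    whole matrix (the out-of-set ECDF would be empty).
    """
    config = config or ScoringConfig()
    expr = _prep_matrix(expr, config)
    in_set = expr.index.isin(gene_set.genes)
    n_in = int(in_set.sum())
    N = expr.shape[0]
    if n_in == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the matrix")
    if n_in >= N:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole matrix")
    if N < 2:
        raise ValueError("matrix needs at least 2 genes")

    alpha = config.weight_exponent
    values = expr.to_numpy(dtype=float)
    scores = np.empty(expr.shape[1])
    gene_idx = np.arange(N)
    for j in range(expr.shape[1]):
        x = values[:, j]
        # descending order; ties broken by gene position for a fixed path
        order = np.lexsort((gene_idx, -x))
        if config.tie_policy == "average":
            rank_pos = stats.rankdata(-x, method="average")[order]
        else:
            rank_pos = np.arange(1, N + 1, dtype=float)
        s = in_set[order]
        w = np.where(s, rank_pos**alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~s) / (N - n_in)
        scores[j] = np.sum(p_in - p_out)
    out = pd.Series(scores, index=expr.columns, name=gene_set.name)
    if config.normalize == "minmax":
        rng = out.max() - out.min()
        out = (out - out.min()) / rng if rng > 0 else out * 0.0
    return out


def purity_proxy(
    expr: pd.DataFrame,
    immune_set: GeneSet,
    stromal_set: GeneSet,
    config: ScoringConfig | None = None,
) -> pd.Series:
    """Signature-based tumor-purity proxy (higher = purer).

    purity = -(z(immune ES) + z(stromal ES)) / 2 across samples: samples
    rich in immune or stromal transcripts contain fewer tumor cells. This is
    a signature-combination score, not the published ESTIMATE polynomial.
    """
    if expr.shape[1] < 2:
        raise ValueError("purity proxy needs at least 2 samples (z-score across samples)")
    immune = ssgsea_score(expr, immune_set, config)
    stromal = ssgsea_score(expr, stromal_set, config)

    def z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"constant {v.name} scores; z-scores set to 0")
            return v * 0.0
        return (v - v.mean()) / sd

    out = -(z(immune) + z(stromal)) / 2.0
    out.name = "purity"
    return out


def celltype_scores(
    expr: pd.DataFrame,
    marker_sets: Sequence[GeneSet],
    config: ScoringConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """ssGSEA score per marker set (e.g. 22 immune cell types).

    Returns (samples x sets score frame, per-set error messages). A set that
    cannot be scored is recorded and skipped rather than aborting the rest.
    """
    scores: dict[str, pd.Series] = {}
    errors: dict[str, str] = {}
    for gs in marker_sets:
        try:
            scores[gs.name] = ssgsea_score(expr, gs, config)
        except ValueError as exc:
            errors[gs.name] = str(exc)
    frame = pd.DataFrame(scores) if scores else pd.DataFrame(index=expr.columns)
    return frame, errors


@dataclass
class GroupComparison:
    t: float
    p: float
    mean_a: float
    mean_b: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def diff_by_group(
    values: pd.Series, in_area: Mapping[str, bool] | pd.Series
) -> GroupComparison:
    """Pooled-variance two-sample t-test of a per-sample quantity,
    in-area group first (df = n1 + n2 - 2)."""
    in_area = pd.Series(in_area).reindex(values.index)
    if in_area.isna().any():
        raise ValueError("membership missing for some samples")
    mask = in_area.astype(bool).to_numpy()
    a = values.to_numpy(dtype=float)[mask]
    b = values.to_numpy(dtype=float)[~mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = _pooled_t(a, b)
    return GroupComparison(t, p, float(a.mean()), float(b.mean()))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("both groups constant with different means; p -> 0")
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Report annotation: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def differential_expression(
    expr: pd.DataFrame,
    in_area: Mapping[str, bool] | pd.Series,
    genes: Iterable[str] | None = None,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene pooled t-test between out-of-area and in-area samples.

    Returns a frame indexed by gene with columns ``t``, ``p``, ``log2_fc``
    and ``stars``. The fold change is the out-area minus in-area difference
    of group means on the (log-scale) values, so genes up-regulated outside
    the region carry a positive log2_fc; ``t`` follows the same orientation.
    """
    if log2_transform:
        expr = np.log2(expr + 1.0)
    if genes is not None:
        genes = [g for g in genes if g in expr.index]
        expr = expr.loc[genes]
    if expr.shape[0] == 0:
        raise ValueError("no genes to test")
    in_area = pd.Series(in_area).reindex(expr.columns)
    if in_area.isna().any():
        raise ValueError("membership missing for some samples")
    mask = in_area.astype(bool).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    vals = expr.to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(expr.index):
        t, p = _pooled_t(vals[i, ~mask], vals[i, mask])  # out vs in
        lfc = float(vals[i, ~mask].mean() - vals[i, mask].mean())
        rows.append((gene, t, p, lfc, significance_stars(p)))
    return pd.DataFrame(
        rows, columns=["gene", "t", "p", "log2_fc", "stars"]
    ).set_index("gene")


def rank_diff_genes(diff: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k significant genes by absolute log2 fold change.

    Filters p < 0.05, sorts by |log2_fc| descending with ties broken by
    smaller p then gene id; returns all significant genes when fewer than k.
    """
    if len(diff) == 0:
        raise ValueError("empty differential-expression result")
    sig = diff[diff["p"] < 0.05].reset_index()
    sig["abs_lfc"] = sig["log2_fc"].abs()
    sig = sig.sort_values(["abs_lfc", "p", "gene"], ascending=[False, True, True])
    return sig.drop(columns="abs_lfc").set_index("gene").head(k)
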