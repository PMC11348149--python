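"""Expression study I/O, exposed-vs-control contrasts and seed-gene selection.

The contrast is an ordinary per-gene two-condition linear model (pooled
variance t statistic) with Benjamini-Hochberg correction; downstream steps
consume only the log fold changes, p-values and the ranks derived from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import TINY_P, bh_adjust
from .errors import FormatError, InsufficientReplicationError, ParameterError

CONDITIONS = ("control", "exposed")
META_COLUMNS = ("sample_id", "condition", "exposure", "dose", "time")


@dataclass
class ExpressionStudy:
    """Log2 expression matrix (genes x samples) with per-sample metadata."""

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    study_id: str = ""

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            raise FormatError("duplicate gene ids in expression matrix")
        if set(self.matrix.columns) != set(self.sample_meta.index):
            raise FormatError("matrix samples and metadata samples differ")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown conditions: {sorted(bad)}")
        # align metadata to matrix column order; never reorder samples silently
        self.sample_meta = self.sample_meta.loc[list(self.matrix.columns)]

    def samples(self, condition: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["condition"] == condition])

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


@dataclass
class DEGSelection:
    """An ordered, de-duplicated list of selected genes plus its provenance."""

    genes: list[str]
    direction: str = "both"
    criterion: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("duplicate genes in selection")


def read_expression_study(matrix_path, meta_path, study_id: str = "") -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    meta = meta.set_index("sample_id")
    return ExpressionStudy(matrix=matrix, sample_meta=meta, study_id=study_id)


def write_expression_study(study: ExpressionStudy, matrix_path, meta_path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    study.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def differential_expression(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene exposed-vs-control contrast.

    Returns a frame with columns ``gene, logFC, p, p_adj, zero_variance``;
    logFC is mean(exposed) - mean(control) on the log2 scale and p comes from
    the pooled-variance two-sample t statistic.
    """
    ctrl = study.samples("control")
    expo = study.samples("exposed")
    for name, cols in (("control", ctrl), ("exposed", expo)):
        if len(cols) < 2:
            raise InsufficientReplicationError(
                f"condition {name!r} has {len(cols)} samples; >= 2 required"
            )
    xc = study.matrix[ctrl].to_numpy(dtype=float)
    xe = study.matrix[expo].to_numpy(dtype=float)
    n1, n2 = xc.shape[1], xe.shape[1]
    logfc = xe.mean(axis=1) - xc.mean(axis=1)
    sp2 = ((n1 - 1) * xc.var(axis=1, ddof=1) + (n2 - 1) * xe.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    # degenerate genes: no residual variance -> no valid t; flag them
    p = np.where(zero_var, np.where(logfc == 0.0, 1.0, TINY_P), p)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} gene(s) with zero residual variance")
    out = pd.DataFrame(
        {
            "gene": study.genes,
            "logFC": logfc,
            "p": np.clip(p, TINY_P, 1.0),
            "zero_variance": zero_var,
        }
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out[["gene", "logFC", "p", "p_adj", "zero_variance"]].reset_index(drop=True)


def filter_degs(
    rows: pd.DataFrame,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.58,
    use_adjusted: bool = False,
) -> DEGSelection:
    """Keep genes with p < ``p_thresh`` and \\|logFC\\| > ``lfc_thresh`` (strict)."""
    if p_thresh <= 0 or lfc_thresh < 0:
        raise ParameterError("thresholds must be positive")
    pcol = "p_adj" if use_adjusted else "p"
    keep = rows[(rows[pcol] < p_thresh) & (rows["logFC"].abs() > lfc_thresh)]
    return DEGSelection(
        genes=list(keep["gene"]),
        direction="both",
        criterion={"p_column": pcol, "p_thresh": p_thresh, "lfc_thresh": lfc_thresh},
    )


def select_top_bottom(rows: pd.DataFrame, k: int = 100) -> DEGSelection:
    """Rank genes by the mean of rank(|logFC| desc) and rank(p asc) and take
    the ``k`` best-ranked up-regulated plus ``k`` best-ranked down-regulated.

    Genes with logFC exactly 0 belong to neither side.  Ties are broken by
    gene id so the output is stable across runs.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    df = rows.copy()
    df["_rank_fc"] = stats.rankdata(-df["logFC"].abs())
    df["_rank_p"] = stats.rankdata(df["p"])
    df["_composite"] = (df["_rank_fc"] + df["_rank_p"]) / 2.0

    selected: list[str] = []
    for side, mask in (("up", df["logFC"] > 0), ("down", df["logFC"] < 0)):
        pool = df[mask].sort_values(["_composite", "gene"], kind="mergesort")
        if len(pool) < k:
            warnings.warn(f"only {len(pool)} {side}-regulated genes available for k={k}")
        selected.extend(pool["gene"].head(k))
    # union, preserving order of first occurrence
    seen: dict[str, None] = dict.fromkeys(selected)
    return DEGSelection(genes=list(seen), direction="both", criterion={"k": k, "rule": "top_bottom"})


def write_contrast(rows: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        rows.to_csv(fh, sep="\t", index=False)


def read_contrast(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
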