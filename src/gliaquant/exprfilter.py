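"""Single-nucleus count-matrix QC filtering and DEG significance calls.

Cells are retained when they satisfy all four rules: 500–5,000 detected
genes, 1,000–30,000 UMIs, < 2.5% mitochondrial reads, and a library
complexity score log10(detected genes) / log10(UMIs) > 0.8. (The
complexity score is the standard per-cell genes-per-UMI metric on the
log10 scale; a raw genes/UMI ratio is always at most 1, so its log10 can
never exceed 0.8 — the log-log form is the quantity this QC recipe
measures.) Genes are called differentially expressed when
|log2 fold change| ≥ log2(1.2) and the Benjamini-Hochberg adjusted
p-value is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

FC_THRESHOLD = float(np.log2(1.2))


@dataclass
class QcThresholds:
    """Per-cell retention thresholds.

    Range endpoints (genes, UMIs) are inclusive; the mitochondrial ceiling
    and complexity floor are strict, as printed.
    """

    gene_floor: int = 500
    gene_ceiling: int = 5000
    umi_floor: int = 1000
    umi_ceiling: int = 30000
    mito_ceiling_pct: float = 2.5
    complexity_floor: float = 0.8

    def __post_init__(self) -> None:
        if not (self.gene_floor < self.gene_ceiling
                and self.umi_floor < self.umi_ceiling):
            raise ValueError("floors must be below ceilings")


@dataclass
class CountMatrix:
    """Genes × cells non-negative integer counts with gene/cell metadata."""

    counts: np.ndarray | sparse.spmatrix
    gene_names: list[str]
    cell_names: list[str] | None = None
    cell_groups: np.ndarray | None = None
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_names):
            raise ValueError("gene_names length must match counts rows")
        if self.cell_names is None:
            self.cell_names = [f"cell{j}" for j in range(n_cells)]
        if len(self.cell_names) != n_cells:
            raise ValueError("cell_names length must match counts columns")
        if self.cell_groups is not None and len(self.cell_groups) != n_cells:
            raise ValueError("cell_groups length must match counts columns")
        dense = self.counts.toarray() if sparse.issparse(self.counts) else self.counts
        if np.any(dense < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_mask(self) -> np.ndarray:
        return np.array(
            [g.lower().startswith(self.mito_prefix.lower())
             for g in self.gene_names]
        )

    def to_anndata(self):
        """Cells × genes AnnData view of the matrix (scanpy convention)."""
        import anndata as ad

        X = self.counts.T.copy() if not sparse.issparse(self.counts) else (
            sparse.csr_matrix(self.counts.T)
        )
        adata = ad.AnnData(X=X)
        adata.var_names = list(self.gene_names)
        adata.obs_names = list(self.cell_names)
        adata.var["mito"] = self.mito_mask
        if self.cell_groups is not None:
            adata.obs["group"] = np.asarray(self.cell_groups)
        return adata

    @classmethod
    def from_anndata(cls, adata, mito_prefix: str = "mt-",
                     group_key: str | None = "group") -> "CountMatrix":
        X = adata.X
        counts = (sparse.csr_matrix(X).T if sparse.issparse(X)
                  else np.asarray(X).T)
        groups = None
        if group_key is not None and group_key in adata.obs:
            groups = adata.obs[group_key].to_numpy()
        return cls(
            counts=counts,
            gene_names=list(adata.var_names),
            cell_names=list(adata.obs_names),
            cell_groups=groups,
            mito_prefix=mito_prefix,
        )


def qc_metrics(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell detected genes, UMIs, mito %, and complexity score."""
    c = matrix.counts
    if sparse.issparse(c):
        c = sparse.csc_matrix(c)
        detected = np.asarray((c > 0).sum(axis=0)).ravel()
        umi = np.asarray(c.sum(axis=0)).ravel()
        mito = np.asarray(c[matrix.mito_mask].sum(axis=0)).ravel()
    else:
        detected = (c > 0).sum(axis=0)
        umi = c.sum(axis=0)
        mito = c[matrix.mito_mask].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_pct = np.where(umi > 0, 100.0 * mito / np.maximum(umi, 1), np.nan)
        complexity = np.where(
            (umi > 1) & (detected > 0),
            np.log10(np.maximum(detected, 1)) / np.log10(np.maximum(umi, 2)),
            np.nan,
        )
    return pd.DataFrame(
        {
            "cell": matrix.cell_names,
            "detected_genes": detected.astype(int),
            "umi": umi.astype(int),
            "mito_pct": mito_pct,
            "complexity": complexity,
        }
    )


def qc_filter(
    matrix: CountMatrix,
    thresholds: QcThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the four retention rules; returns (filtered matrix, report).

    The report carries per-cell metrics, a ``retained`` flag, and the
    semicolon-joined failure reasons. A zero-UMI cell fails explicitly
    (its complexity is undefined).
    """
    thr = thresholds or QcThresholds()
    report = qc_metrics(matrix)
    reasons: list[str] = []
    retained = np.ones(matrix.n_cells, dtype=bool)
    for j, row in report.iterrows():
        why = []
        if row["umi"] == 0:
            why.append("zero UMIs (complexity undefined)")
        else:
            if not thr.gene_floor <= row["detected_genes"] <= thr.gene_ceiling:
                why.append(
                    f"detected genes {row['detected_genes']} outside "
                    f"[{thr.gene_floor}, {thr.gene_ceiling}]"
                )
            if not thr.umi_floor <= row["umi"] <= thr.umi_ceiling:
                why.append(
                    f"UMIs {row['umi']} outside "
                    f"[{thr.umi_floor}, {thr.umi_ceiling}]"
                )
            if not row["mito_pct"] < thr.mito_ceiling_pct:
                why.append(
                    f"mito {row['mito_pct']:.2f}% >= {thr.mito_ceiling_pct}%"
                )
            if not row["complexity"] > thr.complexity_floor:
                why.append(
                    f"complexity {row['complexity']:.3f} <= "
                    f"{thr.complexity_floor}"
                )
        retained[j] = not why
        reasons.append("; ".join(why))
    report["retained"] = retained
    report["fail_reason"] = reasons

    keep = np.flatnonzero(retained)
    filt = CountMatrix(
        counts=matrix.counts[:, keep],
        gene_names=list(matrix.gene_names),
        cell_names=[matrix.cell_names[j] for j in keep],
        cell_groups=(
            np.asarray(matrix.cell_groups)[keep]
            if matrix.cell_groups is not None else None
        ),
        mito_prefix=matrix.mito_prefix,
    )
    return filt, report


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    stats: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    fdr: float = 0.05,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Flag differentially expressed genes from per-gene log2FC and p-values.

    ``stats`` needs columns ``log2fc`` and ``pvalue`` (raw by default;
    pass ``adjusted=True`` if already FDR-adjusted). A gene is DE iff
    |log2fc| ≥ ``fc_threshold`` and adjusted p < ``fdr``; direction is the
    sign of log2fc. Up/down totals are stored in ``result.attrs``.
    """
    for col in ("log2fc", "pvalue"):
        if col not in stats.columns:
            raise ValueError(f"stats is missing required column {col!r}")
    out = stats.copy()
    out["padj"] = (
        out["pvalue"].to_numpy() if adjusted else bh_adjust(out["pvalue"])
    )
    out["de"] = (np.abs(out["log2fc"]) >= fc_threshold) & (out["padj"] < fdr)
    out["direction"] = np.where(
        ~out["de"], "ns", np.where(out["log2fc"] > 0, "up", "down")
    )
    out.attrs["n_up"] = int((out["direction"] == "up").sum())
    out.attrs["n_down"] = int((out["direction"] == "down").sum())
    return out
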