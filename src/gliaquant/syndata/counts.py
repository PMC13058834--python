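"""Synthetic gene-by-cell count matrices with planted QC violations and DE.

Compliant cells are constructed to sit comfortably inside the QC retention
box (detected genes, UMIs, mitochondrial fraction, library complexity);
each planted violator breaks exactly one rule. Two groups of cells are
generated with a stated set of truly differentially expressed genes at a
given log2 fold change, injected by Poisson thickening (up) or binomial
thinning (down) so counts stay integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exprfilter import CountMatrix
from .base import GroundTruth, object_rng


@dataclass
class CountsSpec:
    """Parameters of a synthetic count matrix.

    ``violations`` maps a rule name — ``low_genes``, ``high_genes``,
    ``low_umi``, ``high_umi``, ``high_mito``, ``low_complexity``,
    ``zero_umi`` — to the number of cells planted to break exactly that
    rule. ``n_de_genes`` non-mitochondrial genes receive a true log2 fold
    change of ``de_log2fc`` (alternating up/down) in the second group.
    """

    n_genes: int = 6000
    n_cells: int = 100
    n_mito: int = 13
    mito_prefix: str = "mt-"
    violations: dict[str, int] = field(default_factory=dict)
    groups: tuple[str, str] = ("WT", "KO")
    n_de_genes: int = 0
    de_log2fc: float = 1.0
    detected_range: tuple[int, int] = (3000, 4500)
    complexity_range: tuple[float, float] = (0.86, 0.93)
    mito_pct_range: tuple[float, float] = (0.3, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes - self.n_mito:
            raise ValueError(
                f"requested {self.n_de_genes} DE genes but only "
                f"{self.n_genes - self.n_mito} non-mitochondrial genes exist"
            )
        if self.n_mito >= self.n_genes:
            raise ValueError("n_mito must be < n_genes")
        for k, v in self.violations.items():
            if v < 0:
                raise ValueError(f"violation count for {k!r} must be >= 0")


def _make_cell(rng, n_genes, mito_idx, detected, umi, mito_pct) -> np.ndarray:
    """A count column with the exact detected-gene, UMI and mito% targets."""
    counts = np.zeros(n_genes, dtype=np.int64)
    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)
    mito_umi = int(round(umi * mito_pct / 100.0))
    body_umi = umi - mito_umi
    n_mito_detected = min(len(mito_idx), mito_umi)
    n_body = detected - n_mito_detected
    n_body = int(np.clip(n_body, 1, min(len(non_mito), body_umi)))
    chosen = rng.choice(non_mito, size=n_body, replace=False)
    counts[chosen] = 1
    extra = body_umi - n_body
    if extra > 0:
        share = rng.multinomial(extra, np.full(n_body, 1.0 / n_body))
        counts[chosen] += share
    if mito_umi > 0:
        m = rng.choice(mito_idx, size=n_mito_detected, replace=False)
        counts[m] = 1
        extra_m = mito_umi - n_mito_detected
        if extra_m > 0:
            counts[m] += rng.multinomial(
                extra_m, np.full(n_mito_detected, 1.0 / n_mito_detected)
            )
    return counts


def _violator_targets(rule: str, rng, spec: CountsSpec):
    """(detected, umi, mito_pct) breaking exactly one retention rule."""
    if rule == "low_genes":
        return 400, 1500, 0.0
    if rule == "high_genes":
        det = min(5500, spec.n_genes - spec.n_mito)
        if det <= 5000:
            raise ValueError(
                "n_genes too small to plant a high_genes violation "
                "(need > 5000 detectable non-mito genes)"
            )
        return det, 9500, 0.0
    if rule == "low_umi":
        return 700, 800, 0.0
    if rule == "high_umi":
        return 4400, 32000, 0.0
    if rule == "high_mito":
        return 3500, 8000, 5.0
    if rule == "low_complexity":
        return 600, 9000, 0.0
    if rule == "zero_umi":
        return 0, 0, 0.0
    raise ValueError(f"unknown QC violation rule {rule!r}")


def gen_counts(spec: CountsSpec) -> tuple[CountMatrix, GroundTruth]:
    """Generate a count matrix plus intended pass/fail flags and true log2FC."""
    rng = object_rng(spec.seed, 0)
    gene_names = [f"{spec.mito_prefix}{i}" for i in range(spec.n_mito)] + [
        f"gene{i}" for i in range(spec.n_genes - spec.n_mito)
    ]
    mito_idx = np.arange(spec.n_mito)

    plan: list[tuple[str, bool]] = []  # (rule or "pass", intended pass flag)
    for rule, count in sorted(spec.violations.items()):
        plan.extend([(rule, False)] * count)
    n_fail = len(plan)
    if n_fail > spec.n_cells:
        raise ValueError(
            f"{n_fail} planted violators exceed n_cells={spec.n_cells}"
        )
    plan.extend([("pass", True)] * (spec.n_cells - n_fail))
    order = rng.permutation(spec.n_cells)
    plan = [plan[i] for i in order]

    counts = np.zeros((spec.n_genes, spec.n_cells), dtype=np.int64)
    for j, (rule, ok) in enumerate(plan):
        cell_rng = object_rng(spec.seed, 1, j)
        if ok:
            det = int(cell_rng.integers(*spec.detected_range))
            det = min(det, spec.n_genes - spec.n_mito - 1)
            c = cell_rng.uniform(*spec.complexity_range)
            umi = int(round(10 ** (np.log10(det) / c)))
            mito_pct = cell_rng.uniform(*spec.mito_pct_range)
        else:
            det, umi, mito_pct = _violator_targets(rule, cell_rng, spec)
        if umi > 0:
            counts[:, j] = _make_cell(
                cell_rng, spec.n_genes, mito_idx, det, umi, mito_pct
            )

    # group labels: first half group 0, second half group 1 (pre-shuffle order
    # is irrelevant downstream; DE is injected per label)
    cell_groups = np.array(
        [spec.groups[0]] * (spec.n_cells // 2)
        + [spec.groups[1]] * (spec.n_cells - spec.n_cells // 2)
    )

    true_lfc = np.zeros(spec.n_genes)
    if spec.n_de_genes > 0:
        de_rng = object_rng(spec.seed, 2)
        candidates = np.arange(spec.n_mito, spec.n_genes)
        de_idx = de_rng.choice(candidates, size=spec.n_de_genes, replace=False)
        signs = np.where(np.arange(spec.n_de_genes) % 2 == 0, 1.0, -1.0)
        true_lfc[de_idx] = signs * spec.de_log2fc
        ko = cell_groups == spec.groups[1]
        for g, lfc in zip(de_idx, true_lfc[de_idx]):
            base = counts[g, ko]
            if lfc > 0:
                counts[g, ko] = base + de_rng.poisson(
                    base * (2.0**lfc - 1.0)
                )
            else:
                counts[g, ko] = de_rng.binomial(base, 2.0**lfc)

    matrix = CountMatrix(
        counts=counts,
        gene_names=gene_names,
        cell_groups=cell_groups,
        mito_prefix=spec.mito_prefix,
    )
    truth = GroundTruth(
        modality="counts",
        values={
            "qc_pass": np.array([ok for _, ok in plan]),
            "violated_rule": [rule for rule, _ in plan],
            "true_log2fc": true_lfc,
            "de_genes": [gene_names[i] for i in np.flatnonzero(true_lfc)],
        },
    )
    return matrix, truth
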