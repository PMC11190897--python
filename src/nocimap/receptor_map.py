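"""Mediator -> receptor prioritization against single-neuron expression.

Given (a) bulk fold changes of secreted mediators between patient groups,
(b) a mediator -> receptor mapping, and (c) a gene x cell TPM matrix of
colonic sensory neurons, this module computes receptor coverage (fraction
of neurons expressing ANY listed receptor), coexpression with nociceptor
markers (Scn10a, Trpv1), and a prioritization table: a mediator is carried
forward when it is significantly upregulated and its receptor coverage
reaches the minimum (default 10% of neurons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MediatorReceptorMap",
    "group_fold_change",
    "receptor_coverage",
    "coexpress_fraction",
    "prioritize_mediators",
    "read_mediator_map_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class MediatorReceptorMap:
    """Mediator gene -> receptor gene list (ANY of the list counts)."""

    pairs: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty mediator -> receptor map")
        for m, rs in self.pairs.items():
            if not rs:
                raise ValueError(f"mediator {m} has no receptors")


def read_mediator_map_tsv(path) -> MediatorReceptorMap:
    df = pd.read_csv(path, sep="\t")
    pairs: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        pairs.setdefault(str(row["mediator"]), []).append(str(row["receptor"]))
    return MediatorReceptorMap(pairs)


def group_fold_change(
    expr: pd.DataFrame, groups: pd.Series, gene: str, case: str, control: str
) -> float:
    """Ratio of group mean expression for one gene, case over control.

    ``expr`` is gene x sample on any linear expression scale (RPKM/CPM).
    A zero control mean yields +inf (flagged by the caller via isinf).
    """
    groups = pd.Series(groups).reindex(expr.columns)
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = expr.loc[gene]
    m_case = row[groups == case].mean()
    m_ctrl = row[groups == control].mean()
    if m_ctrl == 0:
        logger.warning("control mean is 0 for %s: fold change reported as +inf", gene)
        return float("inf")
    return float(m_case / m_ctrl)


def _positive(cells: pd.DataFrame, genes: list[str], tpm_threshold: float) -> pd.Series:
    """Boolean per cell: ANY listed gene above the TPM threshold."""
    missing = [g for g in genes if g not in cells.index]
    if missing:
        raise KeyError(f"genes missing from matrix: {missing}")
    return (cells.loc[genes] > tpm_threshold).any(axis=0)


def receptor_coverage(
    cells: pd.DataFrame, receptors: list[str], tpm_threshold: float = 0.0
) -> tuple[int, float]:
    """(count, fraction) of cells expressing ANY listed receptor."""
    if cells.shape[1] == 0:
        raise ValueError("empty cell matrix")
    pos = _positive(cells, receptors, tpm_threshold)
    return int(pos.sum()), float(pos.mean())


def coexpress_fraction(
    cells: pd.DataFrame,
    base_genes: list[str],
    marker_gene: str,
    tpm_threshold: float = 0.0,
) -> float:
    """Among cells positive for ANY base gene, fraction positive for marker."""
    base = _positive(cells, base_genes, tpm_threshold)
    if base.sum() == 0:
        raise ValueError("no base-positive cells: coexpression undefined")
    marker = _positive(cells, [marker_gene], tpm_threshold)
    return float(marker[base].mean())


def prioritize_mediators(
    de: pd.DataFrame,
    mr_map: MediatorReceptorMap,
    cells: pd.DataFrame,
    tpm_threshold: float = 0.0,
    min_coverage: float = 0.10,
    markers: tuple[str, ...] = ("Scn10a", "Trpv1"),
    alpha: float = 1e-4,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Per-mediator fold change, receptor coverage, marker coexpression.

    selected = significantly upregulated (adjusted p <= alpha by default,
    raw p if use_fdr=False) AND coverage >= min_coverage. Coverage exactly
    at the minimum keeps the mediator (the exclusion rule drops receptors
    found on fewer than 10% of neurons). Sorted by coverage then fold
    change, both descending. Mediators absent from the DE table are logged
    and skipped.
    """
    rows = []
    for mediator, receptors in mr_map.pairs.items():
        if mediator not in de.index:
            logger.warning("mediator %s not in DE table; skipped", mediator)
            continue
        rec = de.loc[mediator]
        count, cov = receptor_coverage(cells, receptors, tpm_threshold)
        p = rec["fdr"] if use_fdr else rec["pvalue"]
        upregulated = bool(rec["log2fc"] > 0 and p <= alpha)
        row = {
            "mediator": mediator,
            "fold_change": float(2.0 ** rec["log2fc"]),
            "log2fc": float(rec["log2fc"]),
            "receptor_coverage": cov,
            "receptor_count": count,
            "selected": upregulated and cov >= min_coverage,
        }
        for mk in markers:
            try:
                row[f"coexpr_{mk}"] = coexpress_fraction(cells, receptors, mk, tpm_threshold)
            except (KeyError, ValueError):
                row[f"coexpr_{mk}"] = float("nan")
        rows.append(row)
    if not rows:
        raise ValueError("no mediator of the map is present in the DE table")
    out = pd.DataFrame(rows).sort_values(
        ["receptor_coverage", "fold_change"], ascending=False
    )
    return out.set_index("mediator", drop=False).rename_axis(None)


def coverage_sensitivity(
    cells: pd.DataFrame, receptors: list[str], thresholds=(0.0, 1.0, 5.0)
) -> pd.Series:
    """Coverage at several TPM thresholds (diagnostic for the unstated
    'expressing' cutoff)."""
    return pd.Series(
        {t: receptor_coverage(cells, receptors, t)[1] for t in thresholds}, name="coverage"
    )
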