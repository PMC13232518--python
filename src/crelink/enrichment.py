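"""Condition-specific motif enrichment and gene-set enrichment.

CREs from all conditions' networks are merged into maximal >=1 bp overlap
regions; a merged region seen in exactly one condition is condition-
specific, otherwise condition-agnostic. Per transcription factor, a 2x2
table of motif-present vs motif-absent by specific vs agnostic is tested
with a one-sided Fisher exact test (enrichment of presence among the
condition-specific set), effect sizes are 0.5-continuity-corrected log2
odds ratios, and Benjamini-Hochberg FDR is applied across TFs within each
condition. Gene-set enrichment uses the hypergeometric survival function
sf(x - 1; M, n, k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, MergedRegion, merge_overlapping

logger = logging.getLogger(__name__)

__all__ = [
    "Contingency2x2",
    "EnrichmentRecord",
    "build_merged_regions",
    "tf_presence",
    "fisher_one_sided",
    "log2_or_cc",
    "bh_fdr",
    "hypergeom_gene_enrichment",
    "tf_enrichment_table",
    "FIMO_P_THRESHOLD",
]

FIMO_P_THRESHOLD = 1e-5


@dataclass(frozen=True)
class Contingency2x2:
    """a = present & specific, b = present & agnostic,
    c = absent & specific,  d = absent & agnostic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentRecord:
    tf_name: str
    table: Contingency2x2
    odds_ratio: float
    log2_or_cc: float
    p_one_sided: float
    fdr: float | None = None


def build_merged_regions(
    cre_sets: Mapping[str, Sequence[GenomicInterval]],
) -> list[MergedRegion]:
    """Merge all conditions' CREs; a region's labels are the contributing
    conditions and it is condition-specific iff exactly one contributed."""
    if not cre_sets:
        raise ValueError("need at least one condition")
    labeled = [
        (iv, condition) for condition, ivs in cre_sets.items() for iv in ivs
    ]
    return merge_overlapping(labeled)


def is_specific(region: MergedRegion) -> bool:
    return len(region.labels) == 1


def tf_presence(
    merged_regions: Sequence[MergedRegion],
    hits: pd.DataFrame,
    condition: str,
    cre_lookup: Mapping[str, GenomicInterval] | None = None,
    condition_cres: set[str] | None = None,
) -> pd.DataFrame:
    """Boolean (region x TF) presence table for one condition.

    ``hits`` is a motif-hit table with columns tf_name, sequence_name and
    1-based start/stop. sequence_name either keys into ``cre_lookup``
    (CRE-id mode: the hit is placed at the CRE's coordinates offset by
    start) or encodes coordinates directly as chrom:start-stop. Hits whose
    CRE is not in ``condition_cres`` (the condition's network) are ignored;
    a hit referencing an unknown CRE id raises.
    """
    points: dict[str, list[int]] = {}
    tf_of: dict[str, list[str]] = {}
    unknown = []
    for row in hits.itertuples(index=False):
        name = str(row.sequence_name)
        if cre_lookup is not None and name in cre_lookup:
            if condition_cres is not None and name not in condition_cres:
                continue
            iv = cre_lookup[name]
            chrom = iv.chrom
            pos = iv.start + int(row.start) - 1  # 1-based within-CRE offset
        elif ":" in name and "-" in name:
            chrom, span = name.split(":")
            pos = int(span.split("-")[0]) - 1 + int(row.start) - 1
        elif cre_lookup is not None:
            unknown.append(name)
            continue
        else:
            raise ValueError(f"cannot resolve sequence_name {name!r}")
        points.setdefault(chrom, []).append(pos)
        tf_of.setdefault(chrom, []).append(str(row.tf_name))
    if unknown:
        raise ValueError(f"motif hits reference unknown CREs: {sorted(set(unknown))[:10]}")

    tfs = sorted(hits["tf_name"].astype(str).unique())
    table = pd.DataFrame(
        False, index=range(len(merged_regions)), columns=tfs, dtype=bool
    )
    regions_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, reg in enumerate(merged_regions):
        regions_by_chrom.setdefault(reg.interval.chrom, []).append(
            (reg.interval.start, reg.interval.end, i)
        )
    for chrom, pos_list in points.items():
        regs = regions_by_chrom.get(chrom, [])
        if not regs:
            continue
        starts = np.array([r[0] for r in regs])
        ends = np.array([r[1] for r in regs])
        ridx = np.array([r[2] for r in regs])
        for pos, tf in zip(pos_list, tf_of[chrom]):
            inside = (starts <= pos) & (pos < ends)
            for i in ridx[np.flatnonzero(inside)]:
                table.loc[i, tf] = True
    return table


def fisher_one_sided(table: Contingency2x2) -> float:
    """One-sided (greater) Fisher exact p for enrichment of motif presence
    among condition-specific regions. Empty tables return 1.0 (logged)."""
    if table.total == 0:
        logger.info("degenerate empty contingency table; p = 1.0")
        return 1.0
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="greater"
    )
    return float(p)


def log2_or_cc(table: Contingency2x2, cc: float = 0.5) -> float:
    """Continuity-corrected log2 odds ratio; cc > 0 guarantees finiteness."""
    if cc <= 0:
        raise ValueError("continuity correction must be > 0")
    return float(
        np.log2(((table.a + cc) * (table.d + cc)) / ((table.b + cc) * (table.c + cc)))
    )


def odds_ratio(table: Contingency2x2) -> float:
    """Raw odds ratio ad/bc; +inf when bc = 0 and ad > 0, nan for 0/0."""
    num, den = table.a * table.d, table.b * table.c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def hypergeom_gene_enrichment(M: int, n: int, k: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeom(M population, n successes, k draws)."""
    if not (0 <= n <= M and 0 <= k <= M):
        raise ValueError("require n, k <= M")
    if x > min(n, k):
        raise ValueError("overlap x cannot exceed min(n, k)")
    return float(stats.hypergeom.sf(x - 1, M, n, k))


def tf_enrichment_table(
    presence: pd.DataFrame, specific_mask: Sequence[bool]
) -> pd.DataFrame:
    """Per-TF enrichment across merged regions of one condition.

    ``presence`` is the (region x TF) boolean table, ``specific_mask``
    marks condition-specific regions. Returns a DataFrame with counts,
    odds ratios, one-sided p and BH FDR (corrected across TFs within this
    condition only), sorted by FDR then p.
    """
    spec = np.asarray(specific_mask, dtype=bool)
    records = []
    for tf in presence.columns:
        pres = presence[tf].to_numpy()
        t = Contingency2x2(
            a=int(np.sum(pres & spec)),
            b=int(np.sum(pres & ~spec)),
            c=int(np.sum(~pres & spec)),
            d=int(np.sum(~pres & ~spec)),
        )
        records.append(
            {
                "tf_name": tf,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "odds_ratio": odds_ratio(t),
                "log2_or_cc": log2_or_cc(t),
                "p_one_sided": fisher_one_sided(t),
            }
        )
    df = pd.DataFrame(records)
    df["fdr"] = bh_fdr(df["p_one_sided"])
    return df.sort_values(["fdr", "p_one_sided"], ignore_index=True)
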