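"""Candidate CRE selection, E-G pair enumeration, ABC scoring, and
assembly of the per-pair feature matrix.

Candidate cis-regulatory elements come from accessibility peaks resized to
a fixed 500 bp scoring width plus one promoter element per gene. Candidate
pairs are every (CRE, gene) combination on the same chromosome whose
CRE-midpoint-to-TSS distance is at most a 5 Mb window. The activity-by-
contact (ABC) score for a pair is the CRE's activity times its 3D contact
with the gene, normalized by the sum of that product over every candidate
element in the gene's window, so per-gene scores sum to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CREClass,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    classify_cre,
    resize_center,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateCRE",
    "FeatureMatrix",
    "CRE_SCORING_WIDTH",
    "PAIRING_WINDOW",
    "N_TOP_PEAKS",
    "CONTACT_PSEUDOCOUNT",
    "select_candidates",
    "enumerate_pairs",
    "abc_score",
    "average_orientations",
    "ensemble_mean",
    "collapse_duplicate_columns",
    "assemble",
]

CRE_SCORING_WIDTH = 500          # bp width of candidate elements for scoring
PAIRING_WINDOW = 5_000_000       # bp, CRE midpoint to TSS, inclusive
N_TOP_PEAKS = 150_000            # peaks kept, ranked by total read count
CONTACT_PSEUDOCOUNT = 1e-6       # added to zero contact values


@dataclass(frozen=True)
class CandidateCRE:
    cre_id: str
    interval: GenomicInterval            # fixed scoring width (500 bp)
    source: str                          # "dnase_peak" | "promoter"
    summit: int
    read_count: float
    gene_id: str | None = None           # owning gene for promoter elements
    peak_interval: GenomicInterval | None = None  # original peak coordinates

    @property
    def region(self) -> GenomicInterval:
        """Native-width region: the original peak for peak-derived elements,
        the promoter window otherwise (used for overlap-based analyses)."""
        return self.peak_interval or self.interval


@dataclass
class FeatureMatrix:
    """Per-pair feature table plus a column-provenance manifest.

    ``data`` is indexed by rows in a canonical (cre_id, gene_id) sort;
    ``manifest`` maps each feature column to its provenance tag
    (``re2g``, ``mpralegnet``, ``sei`` or ``abc``).
    """

    data: pd.DataFrame
    manifest: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        feat = self.feature_columns
        if self.data[feat].isna().any().any() or not np.isfinite(
            self.data[feat].to_numpy(dtype=float)
        ).all():
            raise ValueError("feature matrix contains non-finite values")
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValueError("duplicate column names")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("cre_id", "gene_id")]


def select_candidates(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    sizes: Mapping[str, int],
    n_top: int = N_TOP_PEAKS,
) -> list[CandidateCRE]:
    """Resize peaks to the scoring width, keep the top ``n_top`` by read
    count, and append one promoter element per gene.

    Read-count ties break by (chrom, start) ascending so selection is
    deterministic; candidates with identical coordinates are collapsed
    (first occurrence wins).
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    resized = [
        (resize_center(p.interval, CRE_SCORING_WIDTH, sizes), p) for p in peaks
    ]
    resized.sort(key=lambda t: (-t[1].read_count, t[0].chrom, t[0].start))
    out: list[CandidateCRE] = []
    seen: set[tuple[str, int, int]] = set()
    for iv, p in resized[: min(n_top, len(resized))]:
        key = (iv.chrom, iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            CandidateCRE(
                cre_id=f"cre_{iv.chrom}_{iv.start}_{iv.end}",
                interval=iv,
                source="dnase_peak",
                summit=p.summit,
                read_count=p.read_count,
                peak_interval=p.interval,
            )
        )
    for g in genes:
        iv = g.promoter
        key = (iv.chrom, iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            CandidateCRE(
                cre_id=f"pr_{g.gene_id}",
                interval=iv,
                source="promoter",
                summit=g.tss,
                read_count=0.0,
                gene_id=g.gene_id,
            )
        )
    return out


def enumerate_pairs(
    cres: Sequence[CandidateCRE],
    genes: Sequence[GeneAnnotation],
    window: int = PAIRING_WINDOW,
) -> pd.DataFrame:
    """All (CRE, gene) pairs on the same chromosome with midpoint-to-TSS
    distance <= ``window`` (boundary inclusive).

    Returns a DataFrame with columns cre_id, gene_id, distance, sorted
    canonically by (cre_id, gene_id).
    """
    rows = []
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for cre in cres:
        mid = cre.interval.midpoint
        for g in by_chrom.get(cre.interval.chrom, ()):
            d = abs(mid - g.tss)
            if d <= window:
                rows.append((cre.cre_id, g.gene_id, d))
    df = pd.DataFrame(rows, columns=["cre_id", "gene_id", "distance"])
    df = df.drop_duplicates(["cre_id", "gene_id"])
    return df.sort_values(["cre_id", "gene_id"], ignore_index=True)


def abc_score(
    pairs: pd.DataFrame,
    activity: pd.DataFrame,
    contact: Mapping[tuple[str, str], float],
    pseudocount: float = CONTACT_PSEUDOCOUNT,
) -> pd.Series:
    """Activity-by-contact score per pair, normalized within each gene.

    Activity A = sqrt(dnase * h3k27ac) (geometric mean of the two signals);
    contact values of zero receive ``pseudocount``. For pair (e, g):
    score = A_e * C_eg / sum over the gene's candidate elements. Genes whose
    total A*C is zero get all-zero scores (logged).
    """
    act = activity.set_index("cre_id")
    a = np.sqrt(
        act.loc[pairs["cre_id"], "dnase"].to_numpy(dtype=float)
        * act.loc[pairs["cre_id"], "h3k27ac"].to_numpy(dtype=float)
    )
    c = np.array(
        [
            max(contact.get((e, g), 0.0), 0.0) or pseudocount
            for e, g in zip(pairs["cre_id"], pairs["gene_id"])
        ]
    )
    prod = a * c
    totals = pd.Series(prod).groupby(pairs["gene_id"].to_numpy()).transform("sum")
    score = np.zeros(len(pairs))
    nonzero = totals.to_numpy() > 0
    score[nonzero] = prod[nonzero] / totals.to_numpy()[nonzero]
    n_dead = pairs.loc[~nonzero, "gene_id"].nunique()
    if n_dead:
        logger.warning("%d gene(s) with zero total activity*contact; scores set to 0", n_dead)
    return pd.Series(score, index=pairs.index, name="abc_score")


def average_orientations(fwd, rev):
    """Mean of forward- and reverse-orientation activity predictions."""
    fwd = np.asarray(fwd, dtype=float)
    rev = np.asarray(rev, dtype=float)
    if not (np.isfinite(fwd).all() and np.isfinite(rev).all()):
        raise ValueError("non-finite orientation score")
    return (fwd + rev) / 2.0


def ensemble_mean(predictions: Sequence[float], expected: int = 10) -> float:
    """Mean over an ensemble of model predictions (10 expected)."""
    preds = np.asarray(list(predictions), dtype=float)
    if preds.size == 0:
        raise ValueError("empty prediction ensemble")
    if preds.size != expected:
        logger.warning("ensemble has %d predictions, expected %d", preds.size, expected)
    return float(preds.mean())


def collapse_duplicate_columns(
    table: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Average columns mapping to the same chromatin feature.

    ``groups`` maps output feature name -> list of raw column names; output
    has one column per feature, the row-wise arithmetic mean of its group.
    """
    out = {}
    for feature, cols in groups.items():
        if not cols:
            raise ValueError(f"empty column group for {feature!r}")
        out[feature] = table[list(cols)].mean(axis=1)
    return pd.DataFrame(out, index=table.index)


def assemble(
    pairs: pd.DataFrame,
    re2g_features: pd.DataFrame | None = None,
    mpra_activity: pd.DataFrame | None = None,
    sei_features: pd.DataFrame | None = None,
    abc: pd.Series | None = None,
) -> FeatureMatrix:
    """Join per-pair and per-CRE feature sources into one matrix.

    Pair-keyed tables join on (cre_id, gene_id); CRE-keyed tables on
    cre_id. Feature tables referencing unknown ids raise. Missing values
    are imputed with the column median and flagged with a companion
    ``<col>_missing`` indicator column. Output rows are canonically sorted
    by (cre_id, gene_id) regardless of input order.
    """
    df = pairs[["cre_id", "gene_id", "distance"]].copy()
    manifest = {"distance": "re2g"}
    if abc is not None:
        df["abc_score"] = np.asarray(abc, dtype=float)
        manifest["abc_score"] = "abc"

    known_cres = set(df["cre_id"])
    known_pairs = set(zip(df["cre_id"], df["gene_id"]))

    def _check_ids(tab: pd.DataFrame, what: str, pair_keyed: bool) -> None:
        if pair_keyed:
            bad = sorted(
                set(zip(tab["cre_id"], tab["gene_id"])) - known_pairs
            )
        else:
            bad = sorted(set(tab["cre_id"]) - known_cres)
        if bad:
            raise ValueError(f"{what} references unknown ids: {bad[:10]}")

    if re2g_features is not None:
        _check_ids(re2g_features, "re2g feature table", pair_keyed=True)
        df = df.merge(re2g_features, on=["cre_id", "gene_id"], how="left")
        for c in re2g_features.columns:
            if c not in ("cre_id", "gene_id"):
                manifest[c] = "re2g"
    if mpra_activity is not None:
        _check_ids(mpra_activity, "MPRA activity table", pair_keyed=False)
        df = df.merge(mpra_activity, on="cre_id", how="left")
        for c in mpra_activity.columns:
            if c != "cre_id":
                manifest[c] = "mpralegnet"
    if sei_features is not None:
        _check_ids(sei_features, "chromatin-probability table", pair_keyed=False)
        df = df.merge(sei_features, on="cre_id", how="left")
        for c in sei_features.columns:
            if c != "cre_id":
                manifest[c] = "sei"

    feat_cols = [c for c in df.columns if c not in ("cre_id", "gene_id")]
    for c in feat_cols:
        vals = df[c].astype(float)
        if vals.isna().any():
            med = float(vals.median())
            if math.isnan(med):
                med = 0.0
            flag = vals.isna().astype(float)
            df[c] = vals.fillna(med)
            df[c + "_missing"] = flag
            manifest[c + "_missing"] = manifest[c]
        else:
            df[c] = vals

    df = df.sort_values(["cre_id", "gene_id"], ignore_index=True)
    return FeatureMatrix(data=df, manifest=manifest)
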