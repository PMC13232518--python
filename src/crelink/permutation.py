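"""Matched-background permutation tests.

Two related procedures share the machinery here:

1. Variant-in-CRE enrichment. The observed statistic is the number of
   unique variants falling inside at least one network CRE. The null
   preserves each CRE's chromosome and resamples, with replacement, whole
   candidate peaks from the same (length, distance-to-nearest-TSS) bin;
   empty bins trigger hierarchical relaxation to adjacent bins (increasing
   Chebyshev rings in bin space) until candidates exist.

2. eQTL variant-gene concordance. The observed statistic is the number of
   unique (variant, gene) pairs where the variant sits in a network CRE
   that the model links to that gene. The null additionally matches on CRE
   class and predicted-target count, and each sampled peak carries its own
   model-predicted edges, rebuilt with the network's threshold and
   promoter-self rule.

Empirical p-values carry a +1 correction in numerator and denominator
(floor 1/(n_perm+1)); fold enrichment is observed / mean(null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CREClass, GeneAnnotation, GenomicInterval, Peak, distance_to_nearest_tss
from .network import EGNetwork, build_network

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "MatchIndex",
    "observed_variant_overlap",
    "build_match_index",
    "sample_matched",
    "permutation_test_variants",
    "observed_eqtl_concordance",
    "permutation_test_eqtl",
    "decile_edges",
]

N_PERMUTATIONS = 1000


@dataclass
class PermutationResult:
    observed: int
    null_values: np.ndarray
    p_empirical: float
    fold_enrichment: float
    n_perm: int
    seed: int
    relaxation_events: int = 0
    metadata: dict = field(default_factory=dict)


def _finish(observed: int, null: np.ndarray, seed: int, relaxed: int, **meta) -> PermutationResult:
    n_perm = len(null)
    p = (int(np.sum(null >= observed)) + 1) / (n_perm + 1)
    mean_null = float(null.mean()) if n_perm else 0.0
    fe = observed / mean_null if mean_null > 0 else float("nan")
    return PermutationResult(
        observed=int(observed),
        null_values=null,
        p_empirical=p,
        fold_enrichment=fe,
        n_perm=n_perm,
        seed=seed,
        relaxation_events=relaxed,
        metadata=meta,
    )


# ---------------------------------------------------------------- overlap

def _dedup_variants(variants: pd.DataFrame) -> pd.DataFrame:
    keys = [k for k in ("chrom", "pos", "id") if k in variants.columns]
    return variants.drop_duplicates(keys)


def _interval_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays for fast stabbing."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(sorted(pairs))
        starts, ends = arr[:, 0], arr[:, 1]
        run_end = np.maximum.accumulate(ends)
        # merged runs: a new run starts where start > running max of prior ends
        new_run = np.r_[True, starts[1:] > run_end[:-1]]
        m_starts = starts[new_run]
        m_ends = np.maximum.reduceat(ends, np.flatnonzero(new_run))
        out[chrom] = (m_starts, m_ends)
    return out


def _count_covered(positions: Mapping[str, np.ndarray],
                   merged: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> int:
    total = 0
    for chrom, pos in positions.items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        total += int(np.sum(ok & (pos < ends[np.clip(idx, 0, None)])))
    return total


def observed_variant_overlap(
    variants: pd.DataFrame, cres: Sequence[GenomicInterval]
) -> int:
    """Unique variants (0-based ``pos``) inside >= 1 CRE; a variant hit by
    several CREs counts once."""
    v = _dedup_variants(variants)
    positions = {
        chrom: np.sort(grp["pos"].to_numpy(dtype=int))
        for chrom, grp in v.groupby("chrom")
    }
    return _count_covered(positions, _interval_arrays(cres))


# ---------------------------------------------------------------- matching

def decile_edges(values: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Interior quantile cut points giving ``n_bins`` equal-frequency bins
    (deciles by default; the default edges when none are supplied)."""
    qs = np.linspace(1 / n_bins, 1 - 1 / n_bins, n_bins - 1)
    return np.unique(np.quantile(np.asarray(values, dtype=float), qs))


def _bin(value: float, edges: np.ndarray) -> int:
    # half-open [e_{i-1}, e_i): a value on an edge falls in the right bin;
    # values outside the outermost edges land in the boundary bins
    return int(np.digitize(value, edges, right=False))


@dataclass
class MatchIndex:
    """Peaks indexed by matching key for null-set sampling.

    Keys are (chrom, len_bin, dist_bin) in variant mode and
    (chrom, class, len_bin, dist_bin, n_targets) in eQTL mode.
    """

    mode: str
    peaks: list[Peak]
    len_edges: np.ndarray
    dist_edges: np.ndarray
    bins: dict[tuple, np.ndarray]
    lengths: np.ndarray
    dists: np.ndarray
    chroms: list[str]
    classes: list[CREClass] | None = None
    n_targets: np.ndarray | None = None

    def key_for(
        self,
        chrom: str,
        length: int,
        dist: int,
        cre_class: CREClass | None = None,
        n_targets: int | None = None,
    ) -> tuple:
        lb, db = _bin(length, self.len_edges), _bin(dist, self.dist_edges)
        if self.mode == "eqtl":
            return (chrom, cre_class, lb, db, int(n_targets))
        return (chrom, lb, db)

    def candidates(self, key: tuple) -> tuple[np.ndarray, int]:
        """Candidate peak indices for a key, relaxing hierarchically.

        Relaxation level r admits (len, dist) bins within Chebyshev
        distance r and, in eQTL mode, target counts within +/- r; the
        chromosome (and class) never relax. Returns (indices, r used).
        """
        if self.mode == "eqtl":
            chrom, cls, lb, db, nt = key
        else:
            chrom, lb, db = key
        max_r = max(len(self.len_edges), len(self.dist_edges)) + 1
        if self.mode == "eqtl" and self.n_targets is not None and self.n_targets.size:
            max_r = max(max_r, int(self.n_targets.max()) + 1)
        for r in range(max_r + 1):
            found: list[np.ndarray] = []
            for k, idx in self.bins.items():
                if self.mode == "eqtl":
                    kc, kcls, klb, kdb, knt = k
                    if kc != chrom or kcls != cls:
                        continue
                    if max(abs(klb - lb), abs(kdb - db)) > r or abs(knt - nt) > r:
                        continue
                else:
                    kc, klb, kdb = k
                    if kc != chrom or max(abs(klb - lb), abs(kdb - db)) > r:
                        continue
                found.append(idx)
            if found:
                return np.concatenate(found), r
        raise ValueError(f"no candidate peak matches chromosome/class of key {key}")


def build_match_index(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    len_edges: np.ndarray | None = None,
    dist_edges: np.ndarray | None = None,
    mode: str = "variant",
    classes: Sequence[CREClass] | None = None,
    n_targets: Sequence[int] | None = None,
) -> MatchIndex:
    """Index candidate peaks by chromosome, length bin and TSS-distance bin
    (plus class and predicted-target count in eQTL mode). Default edges are
    deciles of the candidate-peak distributions."""
    if not peaks:
        raise ValueError("no candidate peaks")
    if mode not in ("variant", "eqtl"):
        raise ValueError(f"unknown mode {mode!r}")
    lengths = np.array([p.interval.length for p in peaks])
    dists = np.array(
        [
            distance_to_nearest_tss(p.interval.midpoint, p.interval.chrom, genes)
            for p in peaks
        ]
    )
    chroms = [p.interval.chrom for p in peaks]
    if len_edges is None:
        len_edges = decile_edges(lengths)
    if dist_edges is None:
        dist_edges = decile_edges(dists)
    len_edges = np.asarray(len_edges, dtype=float)
    dist_edges = np.asarray(dist_edges, dtype=float)
    if np.any(np.diff(len_edges) <= 0) or np.any(np.diff(dist_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    nt = np.asarray(n_targets, dtype=int) if n_targets is not None else None
    bins: dict[tuple, list[int]] = {}
    for i, p in enumerate(peaks):
        lb, db = _bin(lengths[i], len_edges), _bin(dists[i], dist_edges)
        if mode == "eqtl":
            key = (chroms[i], classes[i], lb, db, int(nt[i]))
        else:
            key = (chroms[i], lb, db)
        bins.setdefault(key, []).append(i)
    return MatchIndex(
        mode=mode,
        peaks=list(peaks),
        len_edges=len_edges,
        dist_edges=dist_edges,
        bins={k: np.array(v) for k, v in bins.items()},
        lengths=lengths,
        dists=dists,
        chroms=chroms,
        classes=list(classes) if classes is not None else None,
        n_targets=nt,
    )


def sample_matched(
    index: MatchIndex,
    chrom: str,
    length: int,
    dist: int,
    rng: np.random.Generator,
    cre_class: CREClass | None = None,
    n_targets: int | None = None,
) -> tuple[Peak, int]:
    """Uniformly sample one matched peak; returns (peak, relaxation level)."""
    key = index.key_for(chrom, length, dist, cre_class, n_targets)
    cands, r = index.candidates(key)
    return index.peaks[int(rng.choice(cands))], r


# ------------------------------------------------- variant permutation test

def permutation_test_variants(
    variants: pd.DataFrame,
    network_cres: Mapping[str, GenomicInterval],
    all_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    len_edges: np.ndarray | None = None,
    dist_edges: np.ndarray | None = None,
) -> PermutationResult:
    """Chromosome-stratified permutation test of variant-in-CRE overlap.

    Each permutation replaces every network CRE by a matched candidate peak
    (sampling with replacement; repeats allowed; overlap counted on the
    union of sampled intervals) and recounts unique overlapping variants.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    index = build_match_index(all_peaks, genes, len_edges, dist_edges, mode="variant")
    observed = observed_variant_overlap(variants, list(network_cres.values()))

    v = _dedup_variants(variants)
    positions = {
        chrom: np.sort(grp["pos"].to_numpy(dtype=int))
        for chrom, grp in v.groupby("chrom")
    }

    # resolve each CRE's candidate list once (relaxation is deterministic)
    groups: dict[tuple, int] = {}
    relaxed = 0
    cand_lists: dict[tuple, np.ndarray] = {}
    for iv in network_cres.values():
        d = distance_to_nearest_tss(iv.midpoint, iv.chrom, genes)
        key = index.key_for(iv.chrom, iv.length, d)
        if key not in cand_lists:
            cands, r = index.candidates(key)
            cand_lists[key] = cands
            if r > 0:
                logger.info("relaxation level %d for bin key %s", r, key)
        groups[key] = groups.get(key, 0) + 1
        if len(index.bins.get(key, ())) == 0:
            relaxed += 1

    rng = np.random.default_rng(seed)
    peak_ivs = [p.interval for p in index.peaks]
    starts = np.array([iv.start for iv in peak_ivs])
    ends = np.array([iv.end for iv in peak_ivs])
    chrom_codes = pd.Categorical([iv.chrom for iv in peak_ivs])

    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        sampled = np.concatenate(
            [rng.choice(cand_lists[key], size=cnt) for key, cnt in groups.items()]
        )
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        codes = chrom_codes.codes[sampled]
        for code in np.unique(codes):
            chrom = chrom_codes.categories[code]
            sel = sampled[codes == code]
            order = np.argsort(starts[sel], kind="stable")
            s, e = starts[sel][order], ends[sel][order]
            run_end = np.maximum.accumulate(e)
            new_run = np.r_[True, s[1:] > run_end[:-1]]
            rid = np.cumsum(new_run) - 1
            m_starts = s[new_run]
            m_ends = np.maximum.reduceat(e, np.flatnonzero(new_run))
            merged[chrom] = (m_starts, m_ends)
        null[i] = _count_covered(positions, merged)
    return _finish(observed, null, seed, relaxed, test="variant_overlap")


# ---------------------------------------------------- eQTL concordance test

def _concordant_pairs(
    eqtls: pd.DataFrame, network: EGNetwork, cre_intervals: Mapping[str, GenomicInterval]
) -> int:
    edges = set(zip(network.edges["cre_id"], network.edges["gene_id"]))
    net_cres = [c for c in network.cres if c in cre_intervals]
    by_chrom: dict[str, list[str]] = {}
    for c in net_cres:
        by_chrom.setdefault(cre_intervals[c].chrom, []).append(c)
    found: set[tuple] = set()
    e = eqtls.drop_duplicates(
        [k for k in ("chrom", "pos", "id", "gene_id") if k in eqtls.columns]
    )
    for chrom, grp in e.groupby("chrom"):
        cres = by_chrom.get(chrom, [])
        if not cres:
            continue
        s = np.array([cre_intervals[c].start for c in cres])
        t = np.array([cre_intervals[c].end for c in cres])
        ids = np.array(cres)
        for row in grp.itertuples(index=False):
            hit = ids[(s <= row.pos) & (row.pos < t)]
            for c in hit:
                if (c, row.gene_id) in edges:
                    found.add((chrom, row.pos, getattr(row, "id", ""), row.gene_id))
                    break
    return len(found)


def observed_eqtl_concordance(
    eqtls: pd.DataFrame,
    network: EGNetwork,
    cre_intervals: Mapping[str, GenomicInterval],
) -> int:
    """Unique (variant, gene) pairs whose variant lies in a network CRE
    predicted to regulate that gene."""
    return _concordant_pairs(eqtls, network, cre_intervals)


def permutation_test_eqtl(
    eqtls: pd.DataFrame,
    network: EGNetwork,
    all_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    peak_edges: pd.DataFrame,
    peak_classes: Sequence[CREClass],
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    len_edges: np.ndarray | None = None,
    dist_edges: np.ndarray | None = None,
    cre_intervals: Mapping[str, GenomicInterval] | None = None,
    peak_ids: Sequence[str] | None = None,
    promoter_owner: Mapping[str, str] | None = None,
) -> PermutationResult:
    """Permutation test of eQTL variant-gene concordance.

    ``peak_edges`` holds every candidate peak's model-scored links
    (peak_id, gene_id, score); each sampled peak keeps its own links,
    thresholded with the network's threshold and the promoter-self rule.
    Matching is on chromosome, class, length bin, TSS-distance bin, and
    predicted-target count (exact first, then jointly relaxed).
    """
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(len(all_peaks))]
    peak_ids = list(peak_ids)
    if cre_intervals is None:
        raise ValueError("cre_intervals required (network CRE coordinates)")

    # above-threshold target count per candidate peak, with promoter-self rule
    sub_net = build_network(
        peak_edges.rename(columns={"peak_id": "cre_id"}),
        threshold=network.threshold,
        cre_classes=dict(zip(peak_ids, peak_classes)),
        promoter_owner=promoter_owner,
    )
    targets_by_peak: dict[str, list[str]] = {
        c: g["gene_id"].tolist() for c, g in sub_net.edges.groupby("cre_id")
    }
    n_targets = [len(targets_by_peak.get(pid, ())) for pid in peak_ids]

    index = build_match_index(
        all_peaks, genes, len_edges, dist_edges, mode="eqtl",
        classes=peak_classes, n_targets=n_targets,
    )
    observed = observed_eqtl_concordance(eqtls, network, cre_intervals)

    # per network CRE: matching attributes
    id_by_coord = {
        (p.interval.chrom, p.interval.start, p.interval.end): i
        for i, p in enumerate(all_peaks)
    }
    net_cre_ids = network.cres
    queries = []
    relaxed = 0
    cand_cache: dict[tuple, np.ndarray] = {}
    deg = network.edges.groupby("cre_id").size()
    for cid in net_cre_ids:
        iv = cre_intervals[cid]
        d = distance_to_nearest_tss(iv.midpoint, iv.chrom, genes)
        pi = id_by_coord.get((iv.chrom, iv.start, iv.end))
        cls = (
            index.classes[pi]
            if pi is not None
            else network.cre_classes.get(cid, CREClass.INTERGENIC_ENHANCER)
        )
        key = index.key_for(iv.chrom, iv.length, d, cls, int(deg.get(cid, 0)))
        if key not in cand_cache:
            cands, r = index.candidates(key)
            cand_cache[key] = cands
            if r > 0:
                relaxed += 1
        queries.append(key)

    rng = np.random.default_rng(seed)
    eqtl_u = eqtls.drop_duplicates(
        [k for k in ("chrom", "pos", "id", "gene_id") if k in eqtls.columns]
    )
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        sampled = [int(rng.choice(cand_cache[k])) for k in queries]
        count = 0
        seen: set[tuple] = set()
        # group sampled peaks per chromosome for stabbing
        by_chrom: dict[str, list[int]] = {}
        for pi in sampled:
            by_chrom.setdefault(index.peaks[pi].interval.chrom, []).append(pi)
        for chrom, grp in eqtl_u.groupby("chrom"):
            pis = by_chrom.get(chrom, [])
            if not pis:
                continue
            s = np.array([index.peaks[p].interval.start for p in pis])
            t = np.array([index.peaks[p].interval.end for p in pis])
            for row in grp.itertuples(index=False):
                key2 = (chrom, row.pos, getattr(row, "id", ""), row.gene_id)
                if key2 in seen:
                    continue
                for j in np.flatnonzero((s <= row.pos) & (row.pos < t)):
                    if row.gene_id in targets_by_peak.get(peak_ids[pis[j]], ()):
                        seen.add(key2)
                        count += 1
                        break
        null[i] = count
    return _finish(observed, null, seed, relaxed, test="eqtl_concordance")
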