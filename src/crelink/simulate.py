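"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate a small two-chromosome genome with accessibility
peaks, genes, activity and 3D-contact signals, per-element reporter-assay
and chromatin-probability scores, CRISPRi-style labels, trait variants,
eQTLs, and motif-scanner hits. Regulatory structure is *planted*: true
links follow a logistic model over the assembled features, variants are
enriched in network CREs at a configurable fold, eQTL target genes agree
with planted links at a configurable rate, and designated motifs occur in
condition-specific regions at a configurable odds ratio. Every generator
is a pure function of (config, seed): randomness flows from one top-level
seed through named `numpy` child streams so modules can be exercised
independently yet reproducibly.

These fixtures do not attempt genome-realistic sequence content or real
chromatin covariance; they exist so parameter recovery, benchmark
behavior, permutation calibration, and enrichment recovery are testable
without any downloads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .intervals import GeneAnnotation, GenomicInterval, MergedRegion, Peak

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureConfig",
    "World",
    "PairData",
    "gen_world",
    "gen_pair_data",
    "gen_variants",
    "gen_eqtls",
    "gen_motif_hits",
]


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic genome and planted structure."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 100
    n_peaks: int = 2500
    n_top: int = 300
    # peak geometry: log-normal lengths around ~500 bp, gamma read counts
    peak_len_log_mean: float = np.log(500.0)
    peak_len_log_sd: float = 0.35
    read_count_shape: float = 2.0
    read_count_scale: float = 50.0
    # 3D contact decay C(d) = (d + d0)^-gamma with log-normal noise
    contact_gamma: float = 1.0
    contact_d0: float = 5_000.0
    contact_noise_sd: float = 0.5
    # planted logistic link model over assembled (z-scored) feature columns
    link_intercept: float = -3.0
    link_beta: dict[str, float] = field(
        default_factory=lambda: {"mpra": 1.2, "log_contact": 0.8, "nuis1": 0.6}
    )
    label_noise: float = 0.05
    # variant / eQTL planting
    n_variants: int = 500
    planted_fe: float = 1.0
    n_eqtls: int = 2000
    eqtl_concordance_rate: float = 0.7
    # motif planting
    motif_background_rate: float = 0.2
    motif_planted_or: float = 1.0

    @classmethod
    def network_scale(cls, seed: int = 0, **overrides) -> "FixtureConfig":
        """Sparse-genome conditions for network-architecture analyses.

        A larger genome with sharply distance-local links, approximating the
        sparseness of genome-wide regulatory networks (hundreds of small
        communities, a substantial non-redundant fraction). The default
        conditions instead maximize labeled-pair volume for classifier
        experiments; the two scales serve different analyses.
        """
        params = dict(
            seed=seed,
            chrom_length=50_000_000,
            n_genes=200,
            link_intercept=-6.5,
            link_beta={"mpra": 1.2, "log_contact": 3.0, "nuis1": 0.6},
            n_variants=6_000,   # genome is 10x larger; keep overlap counts informative
            n_eqtls=8_000,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        for name, v in (("label_noise", self.label_noise),
                        ("eqtl_concordance_rate", self.eqtl_concordance_rate),
                        ("motif_background_rate", self.motif_background_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.contact_gamma < 0:
            raise ValueError("contact_gamma must be >= 0")

def _rng(seed: int, name: str) -> np.random.Generator:
    """Named child stream: platform-stable split of the top-level seed."""
    tag = sum(ord(ch) * 131**i for i, ch in enumerate(name)) % 2**31
    return np.random.default_rng([int(seed), tag])


@dataclass
class World:
    sizes: dict[str, int]
    genes: list[GeneAnnotation]
    peaks: list[Peak]


@dataclass
class PairData:
    candidates: list
    pairs: pd.DataFrame
    activity: pd.DataFrame
    contact: dict
    mpra_raw: pd.DataFrame
    sei_raw: pd.DataFrame
    re2g: pd.DataFrame
    matrix: feat.FeatureMatrix
    labels: pd.DataFrame           # cre_id, gene_id, label, effect_size
    truth: dict


def gen_world(config: FixtureConfig) -> World:
    """Random genome: uniform TSS positions, log-normal peak lengths,
    gamma-distributed read counts. Deterministic given the config seed."""
    rng = _rng(config.seed, "world")
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chroms = list(sizes)

    genes = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        tss = int(rng.integers(1_000, config.chrom_length - 1_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gene_id=f"g{i:04d}", chrom=chrom, tss=tss, strand=strand))

    peaks = []
    for i in range(config.n_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(np.clip(
            rng.lognormal(config.peak_len_log_mean, config.peak_len_log_sd), 100, 5_000
        ))
        if length >= config.chrom_length:
            raise ValueError("peak longer than chromosome: infeasible geometry")
        start = int(rng.integers(0, config.chrom_length - length))
        summit = int(rng.integers(start, start + length))
        rc = float(rng.gamma(config.read_count_shape, config.read_count_scale))
        peaks.append(Peak(GenomicInterval(chrom, start, start + length), summit, rc))
    return World(sizes=sizes, genes=genes, peaks=peaks)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gen_pair_data(world: World, config: FixtureConfig) -> PairData:
    """Candidate pairs plus all feature sources with a planted logistic
    link model.

    True-link log-odds are ``intercept + beta . z`` where z are the
    z-scored realized values of the named assembled feature columns, so a
    correctly specified logistic fit recovers ``beta`` on its standardized
    scale. Labels flip at ``label_noise``; effect sizes (percent expression
    change) are strongly negative for true links and near zero otherwise.
    """
    rng = _rng(config.seed, "pairs")
    cands = feat.select_candidates(world.peaks, world.genes, world.sizes, n_top=config.n_top)
    pairs = feat.enumerate_pairs(cands, world.genes)
    cre_ids = [c.cre_id for c in cands]

    activity = pd.DataFrame({
        "cre_id": cre_ids,
        "dnase": rng.gamma(2.0, 50.0, size=len(cands)),
        "h3k27ac": rng.gamma(2.0, 50.0, size=len(cands)),
    })

    d = pairs["distance"].to_numpy(dtype=float)
    base = (d + config.contact_d0) ** (-config.contact_gamma)
    noise = rng.lognormal(0.0, config.contact_noise_sd, size=len(pairs))
    contact = {
        (e, g): float(c)
        for e, g, c in zip(pairs["cre_id"], pairs["gene_id"], base * noise)
    }

    # reporter-assay scores: 10 models x 2 orientations around a latent truth
    latent_mpra = rng.normal(0.0, 1.0, size=len(cands))
    mpra_rows = []
    for cre, m in zip(cre_ids, latent_mpra):
        for k in range(10):
            mpra_rows.append((cre, m + rng.normal(0, 0.2), m + rng.normal(0, 0.2), k))
    mpra_raw = pd.DataFrame(mpra_rows, columns=["cre_id", "fwd", "rev", "model_index"])
    per_model = feat.average_orientations(mpra_raw["fwd"], mpra_raw["rev"])
    mpra_feature = (
        pd.DataFrame({"cre_id": mpra_raw["cre_id"], "v": per_model})
        .groupby("cre_id", sort=False)["v"].apply(lambda s: feat.ensemble_mean(s.to_numpy()))
        .rename("mpra").reset_index()
    )

    # chromatin probabilities: duplicate outputs per feature, later averaged
    sei_rows = []
    for cre in cre_ids:
        for feature in ("sei_dnase", "sei_h3k27ac"):
            latent = rng.normal(0.0, 1.0)
            for rep in range(2):
                sei_rows.append(
                    (cre, f"{feature}|{rep}", float(_sigmoid(latent + rng.normal(0, 0.3))))
                )
    sei_raw = pd.DataFrame(sei_rows, columns=["cre_id", "sei_output_name", "probability"])
    wide = sei_raw.pivot(index="cre_id", columns="sei_output_name", values="probability")
    groups = {}
    for col in wide.columns:
        groups.setdefault(col.split("|")[0], []).append(col)
    sei_features = feat.collapse_duplicate_columns(wide, groups).reset_index()

    re2g = pairs[["cre_id", "gene_id"]].copy()
    re2g["log_contact"] = np.log(
        [contact[(e, g)] for e, g in zip(pairs["cre_id"], pairs["gene_id"])]
    )
    re2g["nuis1"] = rng.normal(0, 1, size=len(pairs))
    re2g["nuis2"] = rng.normal(0, 1, size=len(pairs))

    abc = feat.abc_score(pairs, activity, contact)
    matrix = feat.assemble(pairs, re2g_features=re2g, mpra_activity=mpra_feature,
                           sei_features=sei_features, abc=abc)

    df = matrix.data
    eta = np.full(len(df), config.link_intercept)
    for col, b in config.link_beta.items():
        v = df[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        eta += b * (v - v.mean()) / (sd if sd > 0 else 1.0)
    p_link = _sigmoid(eta)
    true_link = rng.random(len(df)) < p_link
    flip = rng.random(len(df)) < config.label_noise
    label = np.where(flip, ~true_link, true_link).astype(int)

    effect = np.where(
        true_link,
        -(10.0 + 40.0 * p_link) + rng.normal(0, 5, size=len(df)),
        rng.normal(0, 3, size=len(df)),
    )
    labels = pd.DataFrame({
        "cre_id": df["cre_id"],
        "gene_id": df["gene_id"],
        "label": label,
        "effect_size": effect,
        "true_link": true_link.astype(int),
        "p_link": p_link,
    })
    truth = {
        "link_intercept": config.link_intercept,
        "link_beta": dict(config.link_beta),
        "prevalence": float(true_link.mean()),
        "n_pairs": int(len(df)),
    }
    return PairData(
        candidates=cands, pairs=pairs, activity=activity, contact=contact,
        mpra_raw=mpra_raw, sei_raw=sei_raw, re2g=re2g, matrix=matrix,
        labels=labels, truth=truth,
    )


def _coverage(intervals: Sequence[GenomicInterval], sizes: Mapping[str, int]) -> float:
    from .permutation import _interval_arrays

    merged = _interval_arrays(list(intervals))
    covered = sum(int(np.sum(e - s)) for s, e in merged.values())
    return covered / sum(sizes.values())


def _self_sampling_rate(
    network_cres: Sequence[GenomicInterval],
    match_peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
) -> float:
    """Expected probability that a position inside a network CRE is covered
    by a resampled copy of that same CRE under the matched null.

    The matched null samples, per network CRE, a peak from the CRE's own
    (chromosome, length, TSS-distance) bin — which contains the CRE itself
    when the network is a subset of the catalog. With m queries mapping to
    a bin of s candidates, a specific member is drawn ~m/s times.
    """
    from .intervals import distance_to_nearest_tss
    from .permutation import build_match_index

    index = build_match_index(match_peaks, genes)
    m_per_key: dict[tuple, int] = {}
    keys = []
    for iv in network_cres:
        d = distance_to_nearest_tss(iv.midpoint, iv.chrom, genes)
        key = index.key_for(iv.chrom, iv.length, d)
        keys.append(key)
        m_per_key[key] = m_per_key.get(key, 0) + 1
    rates = []
    for key in keys:
        cands, _ = index.candidates(key)
        rates.append(min(1.0, m_per_key[key] / len(cands)))
    return float(np.mean(rates)) if rates else 0.0


def gen_variants(
    world: World,
    network_cres: Sequence[GenomicInterval],
    planted_fe: float = 1.0,
    n_variants: int = 500,
    seed: int = 0,
    match_peaks: Sequence[Peak] | None = None,
) -> pd.DataFrame:
    """Variant table (0-based ``pos``) with enrichment planted at
    ``planted_fe`` relative to the matched-background expectation.

    ``n_variants`` background variants land uniformly on the genome; extra
    variants land inside network CREs so that observed/null-mean ~ f under
    the matched permutation null: E = N*c*(f-1)/(1-f*(c+q)), where c is the
    network-CRE genome coverage and q the null's self-resampling rate
    (estimated from ``match_peaks`` when given, else 0). Errors when f is
    infeasible for the coverage.
    """
    if planted_fe < 1:
        raise ValueError("planted_fe must be >= 1")
    rng = _rng(seed, "variants")
    sizes = world.sizes
    chroms = list(sizes)
    lens = np.array([sizes[c] for c in chroms], dtype=float)
    c_cov = _coverage(network_cres, sizes) if len(network_cres) else 0.0
    q = (
        _self_sampling_rate(network_cres, match_peaks, world.genes)
        if (match_peaks is not None and planted_fe > 1 and network_cres)
        else 0.0
    )
    if planted_fe > 1 and planted_fe * (c_cov + q) >= 1:
        raise ValueError(
            f"planted_fe={planted_fe} unachievable; maximum feasible is "
            f"{1 / (c_cov + q):.2f}"
        )
    n_extra = (
        int(round(
            n_variants * c_cov * (planted_fe - 1)
            / (1 - planted_fe * (c_cov + q))
        ))
        if planted_fe > 1
        else 0
    )
    rows = []
    which = rng.choice(len(chroms), size=n_variants, p=lens / lens.sum())
    for i, ci in enumerate(which):
        rows.append((chroms[ci], int(rng.integers(0, lens[ci])), f"v{i:05d}"))
    cre_list = list(network_cres)
    for j in range(n_extra):
        iv = cre_list[int(rng.integers(len(cre_list)))]
        rows.append((iv.chrom, int(rng.integers(iv.start, iv.end)), f"ve{j:05d}"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    df["p_value"] = rng.uniform(0, 0.01, size=len(df))  # pre-filtered SNV set
    return df


def gen_eqtls(
    world: World,
    network_edges: pd.DataFrame,
    cre_intervals: Mapping[str, GenomicInterval],
    concordance_rate: float = 0.7,
    n_eqtls: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """eQTL variant-gene table: variants uniform over the genome; a variant
    landing inside a network CRE takes one of that CRE's predicted target
    genes with probability ``concordance_rate``, otherwise (and always for
    variants outside CREs) a random gene. When the edge table carries a
    ``score`` column, targets are drawn proportionally to it (eQTLs
    corroborate strong links more often than marginal ones)."""
    rng = _rng(seed, "eqtls")
    sizes = world.sizes
    chroms = list(sizes)
    lens = np.array([sizes[c] for c in chroms], dtype=float)
    targets: dict[str, tuple[list[str], np.ndarray]] = {}
    for c, g in network_edges.groupby("cre_id"):
        wts = (g["score"].to_numpy(dtype=float)
               if "score" in g.columns else np.ones(len(g)))
        targets[c] = (g["gene_id"].tolist(), wts / wts.sum())
    by_chrom: dict[str, list[str]] = {}
    for cid, iv in cre_intervals.items():
        by_chrom.setdefault(iv.chrom, []).append(cid)
    gene_ids = [g.gene_id for g in world.genes]
    rows = []
    for i in range(n_eqtls):
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        chrom = chroms[ci]
        pos = int(rng.integers(0, lens[ci]))
        hit = [
            c for c in by_chrom.get(chrom, ())
            if cre_intervals[c].start <= pos < cre_intervals[c].end
        ]
        gene = None
        if hit and rng.random() < concordance_rate:
            cands, wts = targets.get(hit[int(rng.integers(len(hit)))], ([], None))
            if cands:
                gene = cands[int(rng.choice(len(cands), p=wts))]
        if gene is None:
            gene = gene_ids[int(rng.integers(len(gene_ids)))]
        rows.append((chrom, pos, f"e{i:05d}", gene))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "gene_id"])


def gen_motif_hits(
    merged_regions: Sequence[MergedRegion],
    tf_list: Sequence[str],
    planted_or: Mapping[str, float] | float = 1.0,
    background_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif-scanner-style hit table with planted condition-specific
    enrichment.

    Presence probability is ``background_rate`` in condition-agnostic
    regions; in condition-specific regions the presence *odds* are
    multiplied by the TF's planted odds ratio, so the population 2x2 odds
    ratio equals the planted value. Output columns follow the scanner's
    TSV dialect with coordinate-encoded sequence names.
    """
    if isinstance(planted_or, (int, float)):
        planted = {tf: float(planted_or) for tf in tf_list}
    else:
        planted = {tf: float(planted_or.get(tf, 1.0)) for tf in tf_list}
    if min(planted.values()) <= 0:
        raise ValueError("planted odds ratios must be > 0")
    rng = _rng(seed, "motifs")
    b = background_rate
    odds_b = b / (1 - b) if b < 1 else np.inf
    rows = []
    for reg in merged_regions:
        specific = len(reg.labels) == 1
        iv = reg.interval
        name = f"{iv.chrom}:{iv.start + 1}-{iv.end}"
        for tf in tf_list:
            if specific:
                o = odds_b * planted[tf]
                p = o / (1 + o)
            else:
                p = b
            if rng.random() < p:
                off = int(rng.integers(1, max(2, iv.length - 8)))
                rows.append((
                    tf, tf, name, off, off + 8, "+",
                    float(rng.uniform(10, 20)),
                    float(rng.uniform(1e-8, 1e-5)), float("nan"), "N" * 9,
                ))
    return pd.DataFrame(rows, columns=[
        "motif_id", "motif_alt_id", "sequence_name", "start", "stop",
        "strand", "score", "p-value", "q-value", "matched_sequence",
    ])
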