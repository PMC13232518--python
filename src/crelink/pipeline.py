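"""End-to-end orchestration: simulate a fixture directory, then run the
feature-assembly -> classifier -> benchmark -> network -> enrichment
stages over it.

The run is deterministic for a fixed config: every artifact is stamped
with the config hash, seed and package version, and re-runs on identical
inputs produce identical outputs. Training uses pairs on the first
chromosome; benchmarking uses the held-out remainder so reported
performance is out-of-sample.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import benchmark as bench
from . import enrichment as enr
from . import features as feat
from . import io
from . import model as mdl
from . import network as net
from . import permutation as perm
from . import simulate as sim
from .intervals import CREClass, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate_fixture", "run_pipeline"]


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    edge_threshold: float = net.SCORE_THRESHOLD_STANDARD
    recall_target: float = 0.70
    n_boot: int = 10_000
    n_perm: int = 1000
    reg_strength: float = 1.0
    fimo_p: float = enr.FIMO_P_THRESHOLD
    variant_p: float = io.VARIANT_P_FILTER
    len_edges: list[float] | None = None
    dist_edges: list[float] | None = None
    n_top: int | None = None  # candidate-peak cap; falls back to the input
                              # directory's params.json, then the 150k default

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded so identical
        analyses in different directories stamp identically)."""
        payload = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in ("input_dir", "output_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def simulate_fixture(config: sim.FixtureConfig, outdir: str | Path) -> dict:
    """Write a complete fixture directory and return the planted truth.

    Emits peaks.narrowPeak, genes.tsv, activity.tsv, contact.tsv, mpra.tsv,
    sei.tsv, re2g.tsv, labels.tsv, variants.tsv, eqtls.tsv, fimo.tsv and
    truth.json. Variant/eQTL positions are written 1-based (the readers
    convert back).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = sim.gen_world(config)
    data = sim.gen_pair_data(world, config)

    io.write_narrowpeak(outdir / "peaks.narrowPeak", world.peaks)
    io.write_genes_tsv(outdir / "genes.tsv", world.genes)
    data.activity.to_csv(outdir / "activity.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(e, g, c) for (e, g), c in data.contact.items()],
        columns=["cre_id", "gene_id", "contact"],
    ).to_csv(outdir / "contact.tsv", sep="\t", index=False)
    data.mpra_raw.to_csv(outdir / "mpra.tsv", sep="\t", index=False)
    data.sei_raw.to_csv(outdir / "sei.tsv", sep="\t", index=False)
    data.re2g.to_csv(outdir / "re2g.tsv", sep="\t", index=False)
    data.labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)

    # planted "true" network: realized true links, scored by link probability
    true_edges = data.labels[data.labels["true_link"] == 1][["cre_id", "gene_id"]]
    cre_regions = {c.cre_id: c.region for c in data.candidates}
    enhancer_ids = {c.cre_id for c in data.candidates if c.source == "dnase_peak"}
    # variant enrichment is planted over peak-derived network elements: the
    # matched null resamples whole catalog peaks, for which promoter windows
    # have no counterpart
    true_enh = [
        cre_regions[cid]
        for cid in true_edges["cre_id"].unique()
        if cid in enhancer_ids
    ]

    variants = sim.gen_variants(
        world, true_enh, planted_fe=config.planted_fe,
        n_variants=config.n_variants, seed=config.seed,
        match_peaks=world.peaks,
    )
    v_out = variants.copy()
    v_out["pos"] = v_out["pos"] + 1
    v_out.to_csv(outdir / "variants.tsv", sep="\t", index=False)

    true_scored = data.labels.loc[
        data.labels["true_link"] == 1, ["cre_id", "gene_id", "p_link"]
    ].rename(columns={"p_link": "score"})
    eqtls = sim.gen_eqtls(
        world, true_scored, cre_regions,
        concordance_rate=config.eqtl_concordance_rate,
        n_eqtls=config.n_eqtls, seed=config.seed,
    )
    e_out = eqtls.copy()
    e_out["pos"] = e_out["pos"] + 1
    e_out.to_csv(outdir / "eqtls.tsv", sep="\t", index=False)

    # two synthetic conditions over the candidate CREs for motif enrichment
    rng = sim._rng(config.seed, "conditions")
    cre_sets: dict[str, list[GenomicInterval]] = {"condA": [], "condB": []}
    for c in data.candidates:
        u = rng.random()
        if u < 0.4:
            cre_sets["condA"].append(c.interval)
        elif u < 0.8:
            cre_sets["condB"].append(c.interval)
        else:
            cre_sets["condA"].append(c.interval)
            cre_sets["condB"].append(c.interval)
    merged = enr.build_merged_regions(cre_sets)
    tfs = [f"TF{i:02d}" for i in range(20)]
    fimo = sim.gen_motif_hits(
        merged, tfs, planted_or={"TF00": config.motif_planted_or},
        background_rate=config.motif_background_rate, seed=config.seed,
    )
    fimo.to_csv(outdir / "fimo.tsv", sep="\t", index=False)

    truth = dict(
        data.truth,
        planted_fe=config.planted_fe,
        eqtl_concordance_rate=config.eqtl_concordance_rate,
        motif_planted_or=config.motif_planted_or,
        planted_tf="TF00",
        true_edges=[list(t) for t in true_edges.itertuples(index=False)],
    )
    io.write_json(outdir / "truth.json", truth)
    io.write_json(outdir / "params.json", {"n_top": config.n_top, "seed": config.seed})
    return truth


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages over a fixture-format input directory."""
    ind = Path(cfg.input_dir)
    outd = Path(cfg.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    for required in ("peaks.narrowPeak", "genes.tsv", "activity.tsv",
                     "contact.tsv", "labels.tsv"):
        if not (ind / required).exists():
            raise FileNotFoundError(f"missing input: {ind / required}")
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
             "version": __version__}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("features")
        peaks = io.read_narrowpeak(ind / "peaks.narrowPeak")
        genes = io.read_genes_tsv(ind / "genes.tsv")
        sizes = {}
        for p in peaks:
            sizes[p.interval.chrom] = max(
                sizes.get(p.interval.chrom, 0), p.interval.end + 10_000
            )
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.tss + 10_000)
        n_top = cfg.n_top
        if n_top is None and (ind / "params.json").exists():
            n_top = io.read_json(ind / "params.json").get("n_top")
        cands = feat.select_candidates(peaks, genes, sizes,
                                       n_top=n_top or feat.N_TOP_PEAKS)
        pairs = feat.enumerate_pairs(cands, genes)
        activity = io.read_activity(ind / "activity.tsv")
        contact = io.read_contact(ind / "contact.tsv")
        abc = feat.abc_score(pairs, activity, contact)

        mpra_feature = None
        if (ind / "mpra.tsv").exists():
            raw = io.read_cre_table(ind / "mpra.tsv")
            per_model = feat.average_orientations(raw["fwd"], raw["rev"])
            mpra_feature = (
                pd.DataFrame({"cre_id": raw["cre_id"], "v": per_model})
                .groupby("cre_id", sort=False)["v"]
                .apply(lambda s: feat.ensemble_mean(s.to_numpy()))
                .rename("mpra").reset_index()
            )
        sei_feature = None
        if (ind / "sei.tsv").exists():
            raw = io.read_cre_table(ind / "sei.tsv")
            wide = raw.pivot(index="cre_id", columns="sei_output_name", values="probability")
            groups: dict[str, list[str]] = {}
            for col in wide.columns:
                groups.setdefault(str(col).split("|")[0], []).append(col)
            sei_feature = feat.collapse_duplicate_columns(wide, groups).reset_index()
        re2g = io.read_pair_table(ind / "re2g.tsv") if (ind / "re2g.tsv").exists() else None

        matrix = feat.assemble(pairs, re2g_features=re2g, mpra_activity=mpra_feature,
                               sei_features=sei_feature, abc=abc)
        io.write_feature_matrix(outd / "features", matrix)

        _stage("train")
        labels = io.read_labels(ind / "labels.tsv")
        df = matrix.data.merge(labels, on=["cre_id", "gene_id"], how="inner")
        cre_chrom = {c.cre_id: c.interval.chrom for c in cands}
        chroms = sorted({c.interval.chrom for c in cands})
        train_mask = df["cre_id"].map(cre_chrom) == chroms[0]
        feat_cols = matrix.feature_columns
        model = mdl.train(df.loc[train_mask, feat_cols], df.loc[train_mask, "label"],
                          reg_strength=cfg.reg_strength, seed=cfg.seed)
        model.metadata.update(stamp)
        model.to_json(outd / "model.json")

        _stage("benchmark")
        test = df.loc[~train_mask] if (~train_mask).any() else df
        scores = mdl.score(model, test[feat_cols])
        effects = test["effect_size"].to_numpy() if "effect_size" in test else None
        result = bench.evaluate(scores, test["label"].to_numpy(), effects=effects,
                                n_boot=cfg.n_boot, target_recall=cfg.recall_target,
                                seed=cfg.seed)
        io.write_json(outd / "benchmark.json", {**stamp, **dataclasses.asdict(result)})

        _stage("network")
        all_scores = mdl.score(model, matrix)
        scored = matrix.data[["cre_id", "gene_id"]].assign(score=all_scores)
        cre_classes = {
            c.cre_id: (CREClass.PROMOTER if c.source == "promoter"
                       else CREClass.INTERGENIC_ENHANCER)
            for c in cands
        }
        owner = {c.cre_id: c.gene_id for c in cands if c.source == "promoter"}
        network = net.build_network(scored, threshold=cfg.edge_threshold,
                                    cre_classes=cre_classes, promoter_owner=owner)
        cre_intervals = {c.cre_id: c.interval for c in cands}
        io.write_network_tsv(outd / "network.tsv", network, cre_intervals)
        partition, modularity = net.detect_communities(network, seed=cfg.seed)
        subs = net.classify_substructures(network, partition)
        pd.DataFrame(
            [(s.community_id, s.type, s.n_cres, s.n_genes,
              ";".join(s.cres + s.genes)) for s in subs],
            columns=["community_id", "type", "n_cres", "n_genes", "members"],
        ).to_csv(outd / "substructures.tsv", sep="\t", index=False)
        summary = net.summarize(network, subs, modularity=modularity)
        io.write_json(outd / "summary.json", {**stamp, **dataclasses.asdict(summary)})

        artifacts = {"summary": summary, "benchmark": result, "network": network,
                     "model": model, "matrix": matrix}

        cre_regions = {c.cre_id: c.region for c in cands}
        if (ind / "variants.tsv").exists():
            _stage("enrich-variants")
            variants = io.read_variants(ind / "variants.tsv", p_filter=cfg.variant_p)
            # peak-derived elements only: promoter windows have no matched
            # counterpart in the peak catalog
            net_cres = {
                c.cre_id: c.region for c in cands
                if c.source == "dnase_peak" and c.cre_id in set(network.cres)
            }
            pr = perm.permutation_test_variants(
                variants, net_cres, peaks, genes, n_perm=cfg.n_perm, seed=cfg.seed,
                len_edges=cfg.len_edges, dist_edges=cfg.dist_edges,
            )
            io.write_json(outd / "variant_enrichment.json", {
                **stamp, "observed": pr.observed, "p_empirical": pr.p_empirical,
                "fold_enrichment": pr.fold_enrichment, "n_perm": pr.n_perm,
                "relaxation_events": pr.relaxation_events,
            })
            artifacts["variant_enrichment"] = pr

        if (ind / "eqtls.tsv").exists():
            _stage("enrich-eqtl")
            eqtls = io.read_eqtls(ind / "eqtls.tsv")
            from .intervals import Peak as _Peak

            universe = [
                _Peak(c.region, min(max(c.summit, c.region.start), c.region.end - 1),
                      c.read_count)
                for c in cands
            ]
            classes = [cre_classes[c.cre_id] for c in cands]
            pe = perm.permutation_test_eqtl(
                eqtls, network, universe, genes,
                peak_edges=scored.rename(columns={"cre_id": "peak_id"}),
                peak_classes=classes,
                n_perm=cfg.n_perm, seed=cfg.seed,
                # coarser bins than variant mode: the extra class and
                # target-count keys already subdivide the small universe
                len_edges=cfg.len_edges or perm.decile_edges(
                    [p.interval.length for p in universe], n_bins=4),
                dist_edges=cfg.dist_edges or perm.decile_edges(
                    [perm.distance_to_nearest_tss(p.interval.midpoint,
                                                  p.interval.chrom, genes)
                     for p in universe], n_bins=4),
                cre_intervals=cre_regions,
                peak_ids=[c.cre_id for c in cands],
                promoter_owner=owner,
            )
            io.write_json(outd / "eqtl_enrichment.json", {
                **stamp, "observed": pe.observed, "p_empirical": pe.p_empirical,
                "fold_enrichment": pe.fold_enrichment, "n_perm": pe.n_perm,
                "relaxation_events": pe.relaxation_events,
            })
            artifacts["eqtl_enrichment"] = pe

        if (ind / "fimo.tsv").exists():
            _stage("enrich-motifs")
            fimo = io.read_fimo(ind / "fimo.tsv", p_threshold=cfg.fimo_p)
            # condition sets: reuse the simulated split when truth is present,
            # else treat the network vs non-network CREs as two conditions
            rng = sim._rng(cfg.seed, "conditions")
            cre_sets: dict[str, list[GenomicInterval]] = {"condA": [], "condB": []}
            for c in cands:
                u = rng.random()
                if u < 0.4:
                    cre_sets["condA"].append(c.interval)
                elif u < 0.8:
                    cre_sets["condB"].append(c.interval)
                else:
                    cre_sets["condA"].append(c.interval)
                    cre_sets["condB"].append(c.interval)
            merged = enr.build_merged_regions(cre_sets)
            presence = enr.tf_presence(merged, fimo, condition="condA")
            specific = [enr.is_specific(r) for r in merged]
            table = enr.tf_enrichment_table(presence, specific)
            table.to_csv(outd / "motif_enrichment.tsv", sep="\t", index=False)
            artifacts["motif_enrichment"] = table

        io.write_json(outd / "run.json", stamp)
        return artifacts
    except Exception as exc:  # annotate failing stage for the operator
        raise RuntimeError(f"pipeline failed: {exc}") from exc
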