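"""Readers and writers for the pipeline's tabular formats.

All on-disk coordinates follow each format's native convention (BED /
narrowPeak half-open 0-based; VCF, variant TSV and motif-scanner start/stop
1-based). Conversion to the package's internal 0-based half-open
convention happens exactly once, here. Writers emit canonical
tab-separated output so write(read(x)) is byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .intervals import GeneAnnotation, GenomicInterval, Peak
from .network import EGNetwork
from .intervals import CREClass

__all__ = [
    "read_narrowpeak", "write_narrowpeak",
    "read_bed", "write_bed",
    "read_genes_tsv", "write_genes_tsv", "read_gtf_genes",
    "read_activity", "read_contact", "read_pair_table", "read_cre_table",
    "read_labels",
    "read_variants", "read_eqtls", "read_fimo",
    "read_network_tsv", "write_network_tsv",
    "write_feature_matrix", "read_feature_matrix",
    "write_json", "read_json",
]

VARIANT_P_FILTER = 0.01  # SNVs with p below this are retained when p present


def _err(path, lineno, fieldinfo):
    raise ValueError(f"{path}:{lineno}: malformed row ({fieldinfo})")


def read_narrowpeak(path, read_count_col: int = 6) -> list[Peak]:
    """MACS2 narrowPeak (10 columns). Summit = start + column-10 offset;
    read count from ``read_count_col`` (0-based; default 6 = signalValue)."""
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 10:
            _err(path, lineno, f"expected 10 columns, got {len(f)}")
        try:
            start, end, offset = int(f[1]), int(f[2]), int(f[9])
            rc = float(f[read_count_col])
        except ValueError as exc:
            _err(path, lineno, str(exc))
        peaks.append(Peak(GenomicInterval(f[0], start, end), start + offset, rc))
    return peaks


def write_narrowpeak(path, peaks: Sequence[Peak], read_count_col: int = 6) -> None:
    lines = []
    for i, p in enumerate(peaks):
        f = [p.interval.chrom, str(p.interval.start), str(p.interval.end),
             f"peak_{i}", "0", ".", "0", "-1", "-1", str(p.summit - p.interval.start)]
        f[read_count_col] = repr(p.read_count)
        lines.append("\t".join(f))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6; extra columns ignored."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            _err(path, lineno, "fewer than 3 BED columns")
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    Path(path).write_text(
        "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in intervals)
    )


def read_genes_tsv(path) -> list[GeneAnnotation]:
    """Gene table: gene_id, chrom, strand, tss (+ optional promoter_start,
    promoter_end, gene_start, gene_end)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = []
    for row in df.itertuples(index=False):
        promoter = None
        if "promoter_start" in df.columns and not pd.isna(row.promoter_start):
            promoter = GenomicInterval(row.chrom, int(row.promoter_start), int(row.promoter_end))
        genes.append(GeneAnnotation(
            gene_id=str(row.gene_id), chrom=str(row.chrom),
            tss=int(row.tss), strand=str(row.strand), promoter=promoter,
        ))
    return genes


def write_genes_tsv(path, genes: Sequence[GeneAnnotation]) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.tss, g.promoter.start, g.promoter.end)
        for g in genes
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "promoter_start", "promoter_end"]
    ).to_csv(path, sep="\t", index=False)


def read_gtf_genes(path) -> list[GeneAnnotation]:
    """Minimal GTF subset: 'gene' features only; TSS from strand-aware end."""
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            _err(path, lineno, "fewer than 9 GTF columns")
        if f[2] != "gene":
            continue
        chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
        gene_id = None
        for part in attrs.split(";"):
            part = part.strip()
            if part.startswith("gene_id"):
                gene_id = part.split()[1].strip('"')
        if gene_id is None:
            _err(path, lineno, "missing gene_id attribute")
        tss = start - 1 if strand == "+" else end - 1  # GTF is 1-based closed
        genes.append(GeneAnnotation(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    return genes


def read_activity(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"cre_id", "dnase", "h3k27ac"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: activity table needs columns {sorted(need)}")
    return df


def read_contact(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        (str(r.cre_id), str(r.gene_id)): float(r.contact)
        for r in df.itertuples(index=False)
    }


def read_pair_table(path) -> pd.DataFrame:
    """Generic pair-keyed feature table (cre_id, gene_id, ...)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_cre_table(path) -> pd.DataFrame:
    """Generic CRE-keyed table (cre_id, ...)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"cre_id", "gene_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: labels need cre_id, gene_id, label")
    return df


def read_variants(path, p_filter: float | None = VARIANT_P_FILTER) -> pd.DataFrame:
    """Variant table, TSV (chrom, pos, id[, p_value]) or sites-only VCF.

    Positions convert 1-based -> 0-based here. When a p-value column is
    present, variants with p >= ``p_filter`` are dropped.
    """
    text = Path(path).read_text()
    first = next((l for l in text.splitlines() if l.strip()), "")
    if first.startswith("##") or first.startswith("#CHROM"):
        rows = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]) - 1, f[2]))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        df["pos"] = df["pos"].astype(int) - 1
    if p_filter is not None and "p_value" in df.columns:
        df = df[df["p_value"] < p_filter]
    return df.drop_duplicates(
        [k for k in ("chrom", "pos", "id") if k in df.columns]
    ).reset_index(drop=True)


def read_eqtls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: eQTL table needs a gene_id column")
    df["pos"] = df["pos"].astype(int) - 1
    keys = [k for k in ("chrom", "pos", "id", "gene_id") if k in df.columns]
    return df.drop_duplicates(keys).reset_index(drop=True)


def read_fimo(path, p_threshold: float = 1e-5) -> pd.DataFrame:
    """FIMO TSV dialect; comment lines tolerated; hits above the scan
    p-value threshold are dropped. start/stop stay 1-based (within-sequence
    offsets, converted downstream)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns={"motif_id": "tf_name"})
    if "p-value" in df.columns:
        df = df[df["p-value"] <= p_threshold]
    return df.reset_index(drop=True)


def read_network_tsv(path) -> EGNetwork:
    df = pd.read_csv(path, sep="\t", comment="#")
    classes = {}
    if "cre_class" in df.columns:
        classes = {
            str(r.cre_id): CREClass(r.cre_class) for r in df.itertuples(index=False)
        }
    return EGNetwork(
        edges=df[["cre_id", "gene_id", "score"]].drop_duplicates(["cre_id", "gene_id"]),
        cre_classes=classes,
    )


def write_network_tsv(path, network: EGNetwork,
                      cre_intervals: Mapping[str, GenomicInterval] | None = None) -> None:
    df = network.edges.copy()
    if cre_intervals:
        df["cre_chrom"] = [cre_intervals[c].chrom for c in df["cre_id"]]
        df["cre_start"] = [cre_intervals[c].start for c in df["cre_id"]]
        df["cre_end"] = [cre_intervals[c].end for c in df["cre_id"]]
    if network.cre_classes:
        df["cre_class"] = [network.cre_classes.get(c, "").value
                           if network.cre_classes.get(c) else ""
                           for c in df["cre_id"]]
    df.to_csv(path, sep="\t", index=False)


def write_feature_matrix(prefix, matrix: FeatureMatrix) -> None:
    """TSV + JSON manifest at <prefix>.tsv / <prefix>.manifest.json."""
    matrix.data.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    Path(f"{prefix}.manifest.json").write_text(json.dumps(matrix.manifest, indent=2))


def read_feature_matrix(prefix) -> FeatureMatrix:
    data = pd.read_csv(f"{prefix}.tsv", sep="\t")
    manifest = json.loads(Path(f"{prefix}.manifest.json").read_text())
    return FeatureMatrix(data=data, manifest=manifest)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
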