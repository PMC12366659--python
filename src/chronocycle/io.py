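"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: expression TSV is genes x samples with a header row of sample
ids and the gene id as the first (index) column; sample metadata TSV has
columns sample, bin, batch (plus any extras); phase TSV has cell,
condition, phase; BED6 is 0-based half-open; Repli-seq signal is a
window x fraction TSV with chrom/start/end leading columns and fraction
columns S1..Sf ordered early to late, or one bedGraph per fraction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chronogram import ChronogramMatrix
from .repliseq import RepliseqMatrix

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_expression_tsv(values: pd.DataFrame, path):
    values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_meta_tsv(meta: pd.DataFrame, path):
    meta.to_csv(path, sep="\t", index=False)


def read_chronogram(expr_path, meta_path) -> ChronogramMatrix:
    values = read_expression_tsv(expr_path)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
    meta = meta.loc[values.columns]
    return ChronogramMatrix(values, meta["bin"].astype(int), meta["batch"])


def write_chronogram(chron: ChronogramMatrix, expr_path, meta_path):
    write_expression_tsv(chron.values, expr_path)
    meta = pd.DataFrame(
        {
            "sample": chron.values.columns,
            "bin": chron.sample_bin.to_numpy(),
            "batch": chron.sample_batch.to_numpy(),
        }
    )
    write_meta_tsv(meta, meta_path)


def write_phase_tsv(phases: pd.DataFrame, path):
    phases[["cell", "condition", "phase"]].to_csv(path, sep="\t", index=False)


def read_phase_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: pd.DataFrame, path):
    """Write BED6; missing name/score/strand columns are filled (., 0, .)."""
    df = intervals.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_repliseq_tsv(mat: RepliseqMatrix, path, what: str = "counts"):
    values = mat.counts if what == "counts" else mat.percentages
    if values is None:
        raise ValueError("matrix has no percentages; run smooth_normalize first")
    body = pd.DataFrame(
        values, columns=[f"S{j + 1}" for j in range(values.shape[1])]
    )
    pd.concat([mat.windows.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_repliseq_tsv(path) -> RepliseqMatrix:
    df = pd.read_csv(path, sep="\t")
    frac_cols = [c for c in df.columns if c.startswith("S") and c[1:].isdigit()]
    frac_cols = sorted(frac_cols, key=lambda c: int(c[1:]))
    return RepliseqMatrix(df[["chrom", "start", "end"]], df[frac_cols].to_numpy())


def write_bedgraph(windows: pd.DataFrame, values, path):
    out = windows[["chrom", "start", "end"]].copy()
    out["value"] = np.asarray(values)
    out.to_csv(path, sep="\t", index=False, header=False)


def write_repliseq_bedgraphs(mat: RepliseqMatrix, out_dir, prefix="fraction"):
    """One bedGraph per fraction (counts), fraction order early to late."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for j in range(mat.f):
        write_bedgraph(mat.windows, mat.counts[:, j], out_dir / f"{prefix}_S{j + 1}.bedGraph")


def read_peak_manifest(manifest_path) -> dict:
    """Peak sets from a manifest TSV with columns dbp, path (BED files)."""
    man = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    return {
        row["dbp"]: read_bed(base / row["path"]) for _, row in man.iterrows()
    }


def read_peak_dir(directory) -> dict:
    """Peak sets from a directory of <dbp>.bed files."""
    return {p.stem: read_bed(p) for p in sorted(Path(directory).glob("*.bed"))}


def write_dms_tsv(dms: pd.DataFrame, path):
    dms.to_csv(path, sep="\t", index=False)


def read_dms_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_aligned_fasta(path) -> dict:
    """Aligned FASTA (A2M-style) -> {record id: aligned sequence}."""
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
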