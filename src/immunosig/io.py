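"""Readers and writers for the pipeline's on-disk formats.

Expression matrices travel as MTX triplets (matrix.mtx + genes.tsv +
barcodes.tsv, observations as columns of the MTX per the 10x convention) or
dense TSV (genes x observations); clinical tables and score matrices as TSV;
ground truth and run summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth


def write_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write genes x observations MTX with genes.tsv / barcodes.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x obs
    spio.mmwrite(str(outdir / "matrix.mtx"), mat)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "obs_meta.tsv", sep="\t")


def read_mtx(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    mat = spio.mmread(str(indir / "matrix.mtx")).tocsr().T  # obs x genes
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=np.asarray(mat.todense(), dtype=np.float64),
                       obs=pd.DataFrame(index=obs.values),
                       var=pd.DataFrame(index=genes.values))
    meta = indir / "obs_meta.tsv"
    if meta.exists():
        adata.obs = pd.read_csv(meta, sep="\t", index_col=0).loc[adata.obs_names]
    return adata


def write_dense_tsv(adata: ad.AnnData, path: str | Path) -> None:
    """Dense genes x observations TSV."""
    pd.DataFrame(np.asarray(adata.X).T, index=adata.var_names,
                 columns=adata.obs_names).to_csv(path, sep="\t")


def read_dense_tsv(path: str | Path) -> ad.AnnData:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ad.AnnData(X=df.values.T.astype(np.float64),
                      obs=pd.DataFrame(index=df.columns.astype(str)),
                      var=pd.DataFrame(index=df.index.astype(str)))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="obs_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="obs_id")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "gene_ids": truth.gene_ids,
        "program_loadings": truth.program_loadings.tolist(),
        "immuno_program_index": truth.immuno_program_index,
        "immuno_genes": truth.immuno_genes,
        "celltype_log_baseline": truth.celltype_log_baseline.tolist(),
        "true_or": truth.true_or,
        "true_hr": truth.true_hr,
        "patient_signature_scores": (
            None if truth.patient_signature_scores is None
            else truth.patient_signature_scores.tolist()),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        gene_ids=d["gene_ids"],
        program_loadings=np.asarray(d["program_loadings"]),
        immuno_program_index=d["immuno_program_index"],
        immuno_genes=d["immuno_genes"],
        cell_program_activities=np.zeros((0, np.asarray(d["program_loadings"]).shape[1])),
        celltype_log_baseline=np.asarray(d["celltype_log_baseline"]),
        true_or=d["true_or"],
        true_hr=d["true_hr"],
        patient_signature_scores=(
            None if d["patient_signature_scores"] is None
            else np.asarray(d["patient_signature_scores"])),
    )


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")
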