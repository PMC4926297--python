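"""Readers, writers and harmonisation for cohort-level tabular data.

All on-disk formats are plain tab-separated text:

* expression / copy-number matrices -- first column ``gene_id``, one column
  per sample, floats written with 6 significant digits;
* segmented copy number -- SEG-style table with columns ``sample``,
  ``chromosome``, ``start``, ``end``, ``log2ratio``; coordinates are 1-based
  and inclusive on both ends (the common SEG dialect);
* mutations -- minimal MAF-like table ``gene_id``, ``sample_id``,
  ``variant_class``;
* clinical -- ``sample_id``, ``time_years``, ``event``, ``age``, ``stage``,
  ``subtype`` (stage/subtype may be missing);
* gene annotation -- BED-like table ``gene_id``, ``chromosome``, ``start``,
  ``end`` plus ``cytoband`` and ``is_metabolic`` columns;
* gene lists (e.g. a hypoxia signature) -- one gene id per line.

In memory, matrices are :class:`pandas.DataFrame` objects with gene ids as
the index (named ``gene_id``) and sample ids as columns.  Expression input
may not contain missing values; copy-number matrices may (segment gaps),
and downstream correlation code deletes missing entries pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "log2ratio"]
MUTATION_COLUMNS = ["gene_id", "sample_id", "variant_class"]
CLINICAL_COLUMNS = ["sample_id", "time_years", "event", "age", "stage", "subtype"]
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "cytoband", "is_metabolic"]

FLOAT_FORMAT = "%.6g"


@dataclass
class CohortBundle:
    """One cancer cohort's aligned data layers.

    After :func:`harmonise`, ``tumour_expr``, ``cn_log2`` and (if present)
    ``scna_calls`` share identical gene and sample orderings, and clinical
    sample ids are a subset of the tumour expression samples.
    """

    name: str
    tumour_expr: pd.DataFrame
    cn_log2: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame
    hypoxia_signature: list[str]
    normal_expr: pd.DataFrame | None = None
    scna_calls: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# matrices


def _check_matrix(df: pd.DataFrame, path, allow_missing: bool) -> pd.DataFrame:
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id {dup[0]!r} in {path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample id in {path}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy()][0]
                raise ValueError(
                    f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r},"
                    f" sample {col!r} in {path}"
                )
            df[col] = coerced
    df = df.astype(float)
    if not allow_missing and df.isna().to_numpy().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[loc[0]]!r},"
            f" sample {df.columns[loc[1]]!r} in {path}"
        )
    return df


def read_expression(path, log2_transform: bool = False, allow_missing: bool = False) -> pd.DataFrame:
    """Read a gene x sample matrix; optionally apply ``log2(x + 1)``.

    The pseudocount of 1 maps zero-read genes to 0, so the zero-read filter
    behaves identically before and after the transform.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = "gene_id"
    df.index = df.index.astype(str)
    df = _check_matrix(df, path, allow_missing)
    if log2_transform:
        df = np.log2(df + 1.0)
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr = expr.copy()
    expr.index.name = "gene_id"
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def filter_zero_heavy_genes(expr: pd.DataFrame, max_zero_fraction: float = 0.75) -> pd.DataFrame:
    """Drop genes whose fraction of exactly-zero values exceeds the cutoff.

    The inequality is strict: a gene with zeros in exactly
    ``max_zero_fraction`` of samples is retained.
    """
    zero_frac = (expr.to_numpy() == 0).mean(axis=1)
    return expr.loc[zero_frac <= max_zero_fraction]


def collapse_probes(probe_expr: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    For each gene the probe with the largest sample standard deviation is
    kept; ties break to the lexicographically smallest probe id.  Probes
    without a gene mapping are dropped.
    """
    sd = probe_expr.std(axis=1, ddof=1)
    best: dict[str, str] = {}
    for probe in sorted(probe_expr.index):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best or sd[probe] > sd[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = probe_expr.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return out


# ---------------------------------------------------------------------------
# segments


def read_segments(path) -> pd.DataFrame:
    segs = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    missing = set(SEG_COLUMNS) - set(segs.columns)
    if missing:
        raise ValueError(f"segment file {path} missing columns {sorted(missing)}")
    validate_segments(segs)
    return segs[SEG_COLUMNS]


def write_segments(segs: pd.DataFrame, path) -> None:
    segs[SEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def validate_segments(segs: pd.DataFrame) -> None:
    if (segs["start"] > segs["end"]).any():
        raise ValueError("segment with start > end")
    for (sample, chrom), grp in segs.groupby(["sample", "chromosome"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments for sample {sample!r} on {chrom!r}")


def segments_to_gene_matrix(segs: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Map segmented log2 ratios onto genes.

    Each gene's value per sample is the length-weighted mean log2 ratio of
    the overlapping segments (1-based inclusive coordinates on both sides);
    genes with no overlapping segment get a missing value.
    """
    validate_segments(segs)
    validate_annotation(ann)
    genes = ann["gene_id"].to_numpy()
    samples = list(dict.fromkeys(segs["sample"]))
    gene_pos = {g: i for i, g in enumerate(genes)}
    weight = np.zeros((len(genes), len(samples)))
    accum = np.zeros((len(genes), len(samples)))
    by_chrom = {chrom: grp for chrom, grp in ann.groupby("chromosome", sort=False)}
    for j, sample in enumerate(samples):
        ssegs = segs[segs["sample"] == sample]
        for _, seg in ssegs.iterrows():
            grp = by_chrom.get(seg["chromosome"])
            if grp is None:
                continue
            ov = np.minimum(grp["end"].to_numpy(), seg["end"]) - np.maximum(
                grp["start"].to_numpy(), seg["start"]
            ) + 1
            hit = ov > 0
            for g, w in zip(grp["gene_id"].to_numpy()[hit], ov[hit]):
                i = gene_pos[g]
                weight[i, j] += w
                accum[i, j] += w * seg["log2ratio"]
    with np.errstate(invalid="ignore"):
        values = np.where(weight > 0, accum / np.where(weight > 0, weight, 1.0), np.nan)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


# ---------------------------------------------------------------------------
# other tables


def read_mutations(path) -> pd.DataFrame:
    mut = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MUTATION_COLUMNS) - set(mut.columns)
    if missing:
        raise ValueError(f"mutation file {path} missing columns {sorted(missing)}")
    if mut.duplicated(MUTATION_COLUMNS).any():
        raise ValueError("duplicated (gene, sample, variant_class) mutation record")
    return mut[MUTATION_COLUMNS]


def write_mutations(mut: pd.DataFrame, path) -> None:
    mut[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subtype": str})
    missing = set(CLINICAL_COLUMNS) - set(clin.columns)
    if missing:
        raise ValueError(f"clinical file {path} missing columns {sorted(missing)}")
    if (clin["time_years"] < 0).any():
        raise ValueError("negative survival time")
    clin["event"] = clin["event"].astype(int).astype(bool)
    return clin[CLINICAL_COLUMNS]


def write_clinical(clin: pd.DataFrame, path) -> None:
    out = clin[CLINICAL_COLUMNS].copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str, "cytoband": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file {path} missing columns {sorted(missing)}")
    ann["is_metabolic"] = ann["is_metabolic"].astype(int).astype(bool)
    validate_annotation(ann)
    return ann[ANNOTATION_COLUMNS]


def validate_annotation(ann: pd.DataFrame) -> None:
    if ann["gene_id"].duplicated().any():
        dup = ann["gene_id"][ann["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation")
    if (ann["start"] > ann["end"]).any():
        raise ValueError("annotation with start > end")
    if (ann["chromosome"].astype(str).str.len() == 0).any():
        raise ValueError("empty chromosome name in annotation")


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann[ANNOTATION_COLUMNS].copy()
    out["is_metabolic"] = out["is_metabolic"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# cohort assembly


def harmonise(bundle: CohortBundle) -> CohortBundle:
    """Align genes and samples across the bundle's data layers.

    Gene and sample sets are intersected across tumour expression and copy
    number (and SCNA calls if present); the intersection keeps the tumour
    expression matrix's ordering.  Clinical rows are restricted to retained
    samples; mutations to retained genes and samples.
    """
    genes = [g for g in bundle.tumour_expr.index if g in set(bundle.cn_log2.index)]
    samples = [s for s in bundle.tumour_expr.columns if s in set(bundle.cn_log2.columns)]
    if bundle.scna_calls is not None:
        call_genes = set(bundle.scna_calls.index)
        call_samples = set(bundle.scna_calls.columns)
        genes = [g for g in genes if g in call_genes]
        samples = [s for s in samples if s in call_samples]
    ann_genes = set(bundle.annotation["gene_id"])
    genes = [g for g in genes if g in ann_genes]
    tumour = bundle.tumour_expr.loc[genes, samples]
    cn = bundle.cn_log2.loc[genes, samples]
    calls = bundle.scna_calls.loc[genes, samples] if bundle.scna_calls is not None else None
    normal = None
    if bundle.normal_expr is not None:
        norm_genes = [g for g in genes if g in set(bundle.normal_expr.index)]
        tumour = tumour.loc[norm_genes]
        cn = cn.loc[norm_genes]
        if calls is not None:
            calls = calls.loc[norm_genes]
        genes = norm_genes
        normal = bundle.normal_expr.loc[genes]
    clinical = bundle.clinical[bundle.clinical["sample_id"].isin(samples)].reset_index(drop=True)
    mutations = bundle.mutations[
        bundle.mutations["gene_id"].isin(genes) & bundle.mutations["sample_id"].isin(samples)
    ].reset_index(drop=True)
    annotation = bundle.annotation[bundle.annotation["gene_id"].isin(genes)].reset_index(drop=True)
    return CohortBundle(
        name=bundle.name,
        tumour_expr=tumour,
        normal_expr=normal,
        cn_log2=cn,
        scna_calls=calls,
        mutations=mutations,
        clinical=clinical,
        annotation=annotation,
        hypoxia_signature=list(bundle.hypoxia_signature),
    )


_COHORT_FILES = {
    "tumour_expr": "tumour_expression.tsv",
    "normal_expr": "normal_expression.tsv",
    "cn_log2": "cn_log2.tsv",
    "scna_calls": "scna_calls.tsv",
    "mutations": "mutations.tsv",
    "clinical": "clinical.tsv",
    "annotation": "annotation.tsv",
    "hypoxia_signature": "hypoxia_signature.txt",
}


def write_cohort(bundle: CohortBundle, outdir) -> None:
    """Write every layer of a cohort into a directory, one file per layer."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.tumour_expr, outdir / _COHORT_FILES["tumour_expr"])
    if bundle.normal_expr is not None:
        write_expression(bundle.normal_expr, outdir / _COHORT_FILES["normal_expr"])
    write_expression(bundle.cn_log2, outdir / _COHORT_FILES["cn_log2"])
    if bundle.scna_calls is not None:
        calls = bundle.scna_calls.copy()
        write_expression(calls, outdir / _COHORT_FILES["scna_calls"])
    write_mutations(bundle.mutations, outdir / _COHORT_FILES["mutations"])
    write_clinical(bundle.clinical, outdir / _COHORT_FILES["clinical"])
    write_annotation(bundle.annotation, outdir / _COHORT_FILES["annotation"])
    write_gene_list(bundle.hypoxia_signature, outdir / _COHORT_FILES["hypoxia_signature"])


def read_cohort(indir, name: str | None = None) -> CohortBundle:
    """Load a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    normal_path = indir / _COHORT_FILES["normal_expr"]
    calls_path = indir / _COHORT_FILES["scna_calls"]
    return CohortBundle(
        name=name or indir.name,
        tumour_expr=read_expression(indir / _COHORT_FILES["tumour_expr"]),
        normal_expr=read_expression(normal_path) if normal_path.exists() else None,
        cn_log2=read_expression(indir / _COHORT_FILES["cn_log2"], allow_missing=True),
        scna_calls=read_expression(calls_path, allow_missing=True) if calls_path.exists() else None,
        mutations=read_mutations(indir / _COHORT_FILES["mutations"]),
        clinical=read_clinical(indir / _COHORT_FILES["clinical"]),
        annotation=read_annotation(indir / _COHORT_FILES["annotation"]),
        hypoxia_signature=read_gene_list(indir / _COHORT_FILES["hypoxia_signature"]),
    )
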