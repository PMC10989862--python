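"""Reading and writing genotype / phenotype tables.

Genotypes travel either as VCF (biallelic SNPs, GT field; read through
cyvcf2, written as plain uncompressed VCF 4.2 text) or as a dosage TSV
(rows = individuals, columns = markers, values 0/1/2/fractional/NA) with two
side tables for the marker map and the individual metadata. Phenotypes are a
long-format TSV with the columns
``genotype, cross, set, year, row, col, trait, value``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genomat import INDIVIDUAL_COLUMNS, MARKER_COLUMNS, GenotypeMatrix

PHENOTYPE_COLUMNS = ["genotype", "cross", "set", "year", "row", "col", "trait", "value"]

#: fixed float formatting so repeated runs emit byte-identical tables
FLOAT_FORMAT = "%.10g"


def write_dosage_tsv(G: GenotypeMatrix, prefix: str) -> None:
    """Write ``<prefix>.dosage.tsv``, ``<prefix>.markers.tsv``, ``<prefix>.individuals.tsv``."""
    dos = pd.DataFrame(G.dosages, index=G.individual_ids, columns=G.marker_ids)
    dos.index.name = "individual"
    dos.to_csv(prefix + ".dosage.tsv", sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")
    mk = G.markers.copy()
    mk.index.name = "marker"
    mk.to_csv(prefix + ".markers.tsv", sep="\t", float_format=FLOAT_FORMAT)
    ind = G.individuals.copy()
    ind.index.name = "individual"
    ind.to_csv(prefix + ".individuals.tsv", sep="\t")


def read_dosage_tsv(prefix: str) -> GenotypeMatrix:
    dos = pd.read_csv(prefix + ".dosage.tsv", sep="\t", index_col=0, na_values="NA")
    mk = pd.read_csv(prefix + ".markers.tsv", sep="\t", index_col=0, dtype={"chrom": str})
    ind = pd.read_csv(prefix + ".individuals.tsv", sep="\t", index_col=0,
                      keep_default_na=False)
    missing = [c for c in MARKER_COLUMNS if c not in mk.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    for c in INDIVIDUAL_COLUMNS:
        if c not in ind.columns:
            ind[c] = ""
    return GenotypeMatrix(dos.to_numpy(dtype=float), mk, ind)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write biallelic SNP genotypes as uncompressed VCF 4.2 (GT only).

    Dosages are rounded to the nearest integer genotype; fractional imputed
    dosages therefore lose information on this route (use the TSV route to
    preserve them).
    """
    ids = list(G.individual_ids)
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=vinegp\n")
        for chrom in pd.unique(G.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in ids) + "\n")
        D = G.dosages
        for j, (mid, row) in enumerate(G.markers.iterrows()):
            gts = []
            for d in D[:, j]:
                gts.append("./." if np.isnan(d) else code[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{mid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str, individuals: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix` via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            continue
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((mid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        gt = np.array(var.genotypes, dtype=object)
        col = np.full(len(samples), np.nan)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                col[i] = a + b
        dosage_cols.append(col)
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    mk = pd.DataFrame(rows, columns=["marker"] + MARKER_COLUMNS).set_index("marker")
    D = np.column_stack(dosage_cols)
    if individuals is None:
        individuals = pd.DataFrame(
            {c: [""] * len(samples) for c in INDIVIDUAL_COLUMNS},
            index=pd.Index(samples, name="individual"),
        )
    else:
        individuals = individuals.loc[samples]
    return GenotypeMatrix(D, mk, individuals)


def write_phenotypes(records: pd.DataFrame, path: str) -> None:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    records[PHENOTYPE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA"
    )


def read_phenotypes(path: str) -> pd.DataFrame:
    rec = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    return rec


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    """Deterministic TSV writer used for every report artifact."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, na_rep="NA")
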