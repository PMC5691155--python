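"""Readers and writers for the plain-text interchange formats.

Genotypes travel as uncompressed VCF 4.2 (DS dosage field, plus GT when the
dosages are integral); phenotypes/covariates and summary statistics as TSV;
pathway membership as GMT. Summary-statistic tables use the fixed column set
SNP, CHR, BP, A1, A2, BETA, SE, P, N (+ optional COHORT).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SNP_META_COLUMNS, GenotypePanel

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N"]


# ---------------------------------------------------------------- VCF

def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    """Write the panel as an uncompressed VCF 4.2 with DS (and, when the
    dosages are all integral, GT) per sample. REF = other allele, ALT =
    effect allele, so DS counts ALT copies as usual."""
    path = Path(path)
    integral = np.allclose(panel.dosages, np.round(panel.dosages), atol=1e-9)
    fmt = "GT:DS" if integral else "DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(i) for i in panel.iids) + "\n")
        meta = panel.snp_meta
        for j in range(panel.n_snps):
            row = meta.iloc[j]
            fields = [str(row["chr"]), str(int(row["pos"])), str(row["snp"]),
                      str(row["a2"]), str(row["a1"]), ".", "PASS", ".", fmt]
            ds = panel.dosages[:, j]
            if integral:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}
                cells = [f"{gt[int(round(d))]}:{d:g}" for d in ds]
            else:
                cells = [f"{d:.10g}" for d in ds]
            fh.write("\t".join(fields + cells) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF written by :func:`write_vcf` (or any VCF carrying DS or GT)
    back into a :class:`GenotypePanel`."""
    from cyvcf2 import VCF  # deferred: import cost only when reading

    vcf = VCF(str(path))
    iids = np.array(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        try:
            ds = np.asarray(var.format("DS"), dtype=float)[:, 0]
        except (TypeError, KeyError):
            gts = np.asarray(var.genotypes)[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        dosage_cols.append(ds)
        rows.append(
            {
                "snp": var.ID,
                "chr": var.CHROM,
                "pos": var.POS,
                "a1": var.ALT[0],
                "a2": var.REF,
                "maf": np.nan,
            }
        )
    meta = pd.DataFrame(rows, columns=SNP_META_COLUMNS)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(iids), 0))
    p = dosages.mean(axis=0) / 2.0 if dosages.size else np.empty(0)
    meta["maf"] = np.minimum(p, 1 - p)
    sex = np.ones(len(iids), dtype=int)
    return GenotypePanel(dosages=dosages, snp_meta=meta, sex=sex, iids=iids)


# ---------------------------------------------------------------- GMT

def write_gmt(pathways: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    """Write pathway membership as GMT (name, description, members...)."""
    path = Path(path)
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in pathways.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + [str(m) for m in members]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        out[parts[0]] = parts[2:]
    return out


# ---------------------------------------------------------------- TSV tables

def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in SUMSTAT_COLUMNS + ["COHORT"] if c in stats.columns]
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    stats.to_csv(path, sep="\t", index=False, columns=cols)
    return Path(path)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> Path:
    pheno.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- GRM

def write_grm_tsv(grm: np.ndarray, iids, path: str | Path) -> Path:
    df = pd.DataFrame(grm, index=iids, columns=iids)
    df.to_csv(path, sep="\t")
    return Path(path)


def write_grm_binary(grm: np.ndarray, iids, prefix: str | Path) -> tuple[Path, Path]:
    """Lower-triangle float32 stream (row-major, diagonal included) plus an
    id file, the binary-triplet convention of the usual GREML tooling."""
    prefix = Path(prefix)
    n = grm.shape[0]
    bin_path = prefix.with_suffix(".grm.bin")
    id_path = prefix.with_suffix(".grm.id")
    with open(bin_path, "wb") as fh:
        for i in range(n):
            fh.write(struct.pack(f"<{i + 1}f", *grm[i, : i + 1]))
    with open(id_path, "w") as fh:
        for iid in iids:
            fh.write(f"{iid}\t{iid}\n")
    return bin_path, id_path


def read_grm_binary(prefix: str | Path) -> tuple[np.ndarray, list[str]]:
    prefix = Path(prefix)
    ids = [line.split("\t")[0] for line in prefix.with_suffix(".grm.id").read_text().splitlines()]
    n = len(ids)
    flat = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f4")
    grm = np.zeros((n, n))
    k = 0
    for i in range(n):
        grm[i, : i + 1] = flat[k : k + i + 1]
        k += i + 1
    grm = grm + np.tril(grm, -1).T
    return grm, ids


# ---------------------------------------------------------------- fixtures

def emit_fixtures(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    pathways: dict[str, list[str]],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the simulated study as plain-text files (VCF + TSV + GMT) that
    round-trip losslessly through this module's readers."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": write_vcf(panel, out / "genotypes.vcf"),
            "phenotypes": write_phenotypes(phenotypes, out / "phenotypes.tsv"),
            "gmt": write_gmt(pathways, out / "pathways.gmt"),
        }
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {out}: {exc}") from exc
    return paths
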