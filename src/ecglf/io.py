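"""File formats: HDF5 beat containers, VCF / dosage-matrix genotypes,
latent CSVs and summary-statistic TSVs."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd

from ecglf.containers import (
    LEAD_NAMES,
    GenotypeMatrix,
    LatentRepresentation,
    MedianBeatSet,
    RawECGSet,
)

__all__ = [
    "write_beats_hdf5", "read_beats_hdf5",
    "write_raw_hdf5", "read_raw_hdf5",
    "write_vcf", "read_vcf",
    "write_dosage_matrix", "read_dosage_matrix",
    "write_sumstats", "read_sumstats",
    "write_latents_csv", "read_latents_csv",
]


def write_beats_hdf5(path, beats: MedianBeatSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("beats", data=beats.beats)
        f.create_dataset("subject_ids", data=np.asarray(beats.subject_ids, dtype="S"))
        f.attrs["fs"] = beats.sampling_rate
        f.attrs["lead_names"] = list(beats.lead_names)


def read_beats_hdf5(path) -> MedianBeatSet:
    with h5py.File(path, "r") as f:
        return MedianBeatSet(
            f["beats"][...],
            f["subject_ids"][...].astype(str),
            int(f.attrs.get("fs", 500)),
            tuple(f.attrs.get("lead_names", LEAD_NAMES)),
        )


def write_raw_hdf5(path, raw: RawECGSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=raw.signals)
        f.create_dataset("subject_ids", data=np.asarray(raw.subject_ids, dtype="S"))
        f.attrs["fs"] = raw.sampling_rate


def read_raw_hdf5(path) -> RawECGSet:
    with h5py.File(path, "r") as f:
        return RawECGSet(f["signals"][...], f["subject_ids"][...].astype(str),
                         int(f.attrs.get("fs", 500)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=GENE,Number=1,Type=String,Description="Assigned gene">
##INFO=<ID=LOF,Number=0,Type=Flag,Description="Loss of function">
##INFO=<ID=DEL5,Number=0,Type=Flag,Description="Deleterious by all five predictors">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, genotypes: GenotypeMatrix) -> None:
    """Write hard-call genotypes as a plain-text VCF 4.2 with GT fields."""
    var = genotypes.variants
    with open(path, "w") as f:
        f.write(_VCF_HEADER)
        f.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, genotypes.subject_ids)) + "\n")
        for j in range(genotypes.n_variants):
            row = var.iloc[j]
            info = [f"AF={row['af']:.6g}"]
            if "gene" in var.columns and pd.notna(row.get("gene")):
                info.append(f"GENE={row['gene']}")
            if bool(row.get("is_lof", False)):
                info.append("LOF")
            if bool(row.get("deleterious_all5", False)):
                info.append("DEL5")
            gts = "\t".join(_GT_CODE[int(d)] for d in genotypes.dosages[:, j])
            vid = row.get("variant_id", f"{row['chrom']}:{row['pos']}")
            f.write(f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                    f"\t.\tPASS\t{';'.join(info)}\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (alt-allele dosage from GT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    dosages, rows = [], []
    for v in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=0)
        dosages.append(dos)
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "af": float(v.INFO.get("AF", dos.mean() / 2.0)),
                "is_lof": bool(v.INFO.get("LOF", False)),
                "deleterious_all5": bool(v.INFO.get("DEL5", False)),
                "gene": v.INFO.get("GENE", None),
            }
        )
    return GenotypeMatrix(np.stack(dosages, axis=1), pd.DataFrame(rows), subjects)


def write_dosage_matrix(prefix, genotypes: GenotypeMatrix) -> None:
    """Tab-delimited dosage matrix (variants x subjects) plus a sidecar
    variant-metadata TSV at ``<prefix>.dosage.tsv`` / ``<prefix>.variants.tsv``."""
    prefix = pathlib.Path(prefix)
    ids = genotypes.variants.get(
        "variant_id",
        pd.Series([f"{c}:{p}" for c, p in
                   zip(genotypes.variants["chrom"], genotypes.variants["pos"])]),
    )
    pd.DataFrame(genotypes.dosages.T, index=ids,
                 columns=genotypes.subject_ids).to_csv(
        f"{prefix}.dosage.tsv", sep="\t", index_label="variant_id")
    meta = genotypes.variants.rename(columns={
        "chrom": "CHROM", "pos": "POS", "ref": "REF", "alt": "ALT", "af": "AF",
        "is_lof": "IS_LOF", "deleterious_all5": "DEL_ALL5", "gene": "GENE"})
    meta.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)


def read_dosage_matrix(prefix) -> GenotypeMatrix:
    dos = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", index_col="variant_id")
    meta = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    variants = meta.rename(columns={
        "CHROM": "chrom", "POS": "pos", "REF": "ref", "ALT": "alt", "AF": "af",
        "IS_LOF": "is_lof", "DEL_ALL5": "deleterious_all5", "GENE": "gene"})
    if "variant_id" not in variants:
        variants["variant_id"] = dos.index.to_numpy()
    return GenotypeMatrix(dos.to_numpy().T, variants, dos.columns.to_numpy())


def write_sumstats(path, assoc) -> None:
    """Summary statistics TSV: CHR POS ID A1 A2 AF BETA SE P N."""
    t = assoc.table
    out = pd.DataFrame(
        {
            "CHR": t["chrom"],
            "POS": t["pos"],
            "ID": t.get("variant_id", t["chrom"].astype(str) + ":" + t["pos"].astype(str)),
            "A1": t.get("alt", "."),
            "A2": t.get("ref", "."),
            "AF": t["af"],
            "BETA": t["beta"],
            "SE": t["se"],
            "P": t["p"],
            "N": t["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"CHR": "chrom", "POS": "pos", "ID": "variant_id",
                              "BETA": "beta", "SE": "se", "P": "p", "AF": "af", "N": "n"})


def write_latents_csv(path, latents: LatentRepresentation) -> None:
    latents.to_frame().to_csv(path, index=False)


def read_latents_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
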