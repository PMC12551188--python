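"""Readers and writers: TSV tables, PLINK .raw dosages, JSON fits, YAML config.

The canonical on-disk format is tab-separated text with a header and an
animal_id column; genotype files may alternatively use the PLINK .raw
dialect (FID IID PAT MAT SEX PHENOTYPE followed by per-SNP dosage columns).
All readers align animals by identifier, never by row order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeData, TranscriptData, PhenotypeData

logger = logging.getLogger(__name__)

_PLINK_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(path) -> GenotypeData:
    """Read a dosage matrix from TSV (animal_id + SNP columns) or PLINK .raw.

    Dosages must be integers in {0, 1, 2}; missing values are imputed to
    the column mean (rounded) with the count logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+" if path.suffix == ".raw" else "\t")
    if list(df.columns[:6]) == _PLINK_LEAD:
        ids = df["IID"].astype(str).tolist()
        snps = df.columns[6:].tolist()
        mat = df[snps]
    else:
        if "animal_id" not in df.columns:
            raise ValueError(f"{path}: expected an 'animal_id' column or PLINK .raw header")
        if df["animal_id"].duplicated().any():
            dup = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
            raise ValueError(f"{path}: duplicated animal_id {dup}")
        ids = df["animal_id"].astype(str).tolist()
        snps = [c for c in df.columns if c != "animal_id"]
        mat = df[snps]
    vals = mat.to_numpy(dtype=float)
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("%s: imputing %d missing dosages to column means", path, n_missing)
        col_mean = np.nanmean(vals, axis=0)
        idx = np.where(np.isnan(vals))
        vals[idx] = np.round(col_mean[idx[1]])
    bad = ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{path}: invalid dosage {vals[i, j]!r} at animal "
                         f"{ids[i]!r}, SNP {snps[j]!r}")
    return GenotypeData(vals.astype(np.int64), ids, snps)


def read_table(path, required=("animal_id",), align_to=None) -> pd.DataFrame:
    """Header-checked TSV keyed by animal_id; optionally align/validate
    against a reference id list, reporting mismatches explicitly."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "animal_id" in df.columns:
        df["animal_id"] = df["animal_id"].astype(str)
        if df["animal_id"].duplicated().any():
            dup = sorted(df.loc[df["animal_id"].duplicated(), "animal_id"])
            raise ValueError(f"{path}: duplicated animal_id {dup}")
        if align_to is not None:
            want, have = list(map(str, align_to)), set(df["animal_id"])
            extra = sorted(have - set(want))
            absent = sorted(set(want) - have)
            if extra or absent:
                raise ValueError(f"{path}: animal_id mismatch; extra={extra[:10]} "
                                 f"missing={absent[:10]}")
            df = df.set_index("animal_id").loc[want].reset_index()
    return df


def write_genotypes_tsv(geno: GenotypeData, path):
    df = geno.to_dataframe()
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t")


def write_genotypes_raw(geno: GenotypeData, path, pedigree=None):
    """PLINK .raw dialect (space separated, 6 leading columns)."""
    lead = pd.DataFrame({
        "FID": 1, "IID": geno.animal_ids, "PAT": 0, "MAT": 0,
        "SEX": 0, "PHENOTYPE": -9,
    })
    if pedigree is not None:
        tab = pedigree.table.set_index("animal_id")
        lead["PAT"] = [tab.sire_id.get(a, 0) or 0 for a in geno.animal_ids]
        lead["MAT"] = [tab.dam_id.get(a, 0) or 0 for a in geno.animal_ids]
    out = pd.concat([lead, pd.DataFrame(geno.dosages, columns=[f"{s}_A" for s in geno.snp_ids])],
                    axis=1)
    out.to_csv(path, sep=" ", index=False)


def write_matrix_tsv(values, row_ids, col_ids, path, index_name="animal_id"):
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_phenotypes_tsv(phen: PhenotypeData, path):
    df = pd.DataFrame({"animal_id": phen.animal_ids, phen.trait: phen.y})
    if phen.testday is not None:
        df["testday"] = phen.testday
    df.to_csv(path, sep="\t", index=False)


def write_transcripts_tsv(tdata: TranscriptData, path, which="W"):
    mat = tdata.W if which == "W" else tdata.raw
    write_matrix_tsv(mat, tdata.animal_ids, tdata.transcript_ids, path)


def write_truth_json(truth, path):
    payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in vars(truth).items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def write_fit_json(results, path, extra=None):
    payload = results.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed, inputs=()):
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "input_hashes": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
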