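"""Reading and writing genotype matrices and tabular data.

Two genotype dialects are supported and round-trip bit-exactly for hard
calls:

* ``plink-bed`` — the PLINK 1 binary triplet ``.bed/.bim/.fam``.  The .bed
  file is SNP-major (v1.00 magic bytes ``0x6c 0x1b 0x01``), four samples per
  byte, two bits per call.  In this package dosages count the ``.bim`` A1
  allele: bit pair 00 = two copies of A1, 10 = heterozygote, 11 = zero
  copies, 01 = missing.
* ``tsv-dosage`` — a single plain-text file for small fixtures, one row per
  SNP: ``#CHROM POS ID A1 A2 <IID...>`` with dosages in {0,1,2} or ``NA``.

Phenotype and covariate tables are TSV with an ``IID`` sample-id column.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_plink",
    "write_plink",
    "read_tsv_dosage",
    "write_tsv_dosage",
    "read_table",
    "write_table",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix: Path, suffix: str) -> Path:
    # Path.with_suffix mangles prefixes containing dots
    return prefix.parent / (prefix.name + suffix)

# bit-pair value (little-endian within byte) -> dosage of A1
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """Malformed genotype file (bad magic bytes, header or cell value)."""


def read_genotypes(path: str | os.PathLike, dialect: str = "plink-bed") -> GenotypeMatrix:
    """Read a genotype matrix; ``dialect`` is ``plink-bed`` or ``tsv-dosage``.

    For ``plink-bed``, ``path`` is the file-set prefix (no extension).
    """
    if dialect == "plink-bed":
        return read_plink(path)
    if dialect == "tsv-dosage":
        return read_tsv_dosage(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'plink-bed' or 'tsv-dosage'")


def write_genotypes(
    gm: GenotypeMatrix, path: str | os.PathLike, dialect: str = "plink-bed"
) -> None:
    if dialect == "plink-bed":
        write_plink(gm, path)
    elif dialect == "tsv-dosage":
        write_tsv_dosage(gm, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'plink-bed' or 'tsv-dosage'")


# ---------------------------------------------------------------------------
# PLINK 1 binary


def write_plink(gm: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write ``<prefix>.bed/.bim/.fam`` (SNP-major v1.00)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    bim = pd.DataFrame(
        {
            "chrom": gm.snps["chrom"],
            "id": gm.snps["id"],
            "cm": 0,
            "pos": gm.snps["pos"],
            "a1": gm.snps["a1"],
            "a2": gm.snps["a2"],
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": gm.samples,
            "iid": gm.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)

    n = gm.n_samples
    n_pad = -n % 4
    # dosage of A1 -> 2-bit code
    codes = np.full((gm.n_snps, n + n_pad), 1, dtype=np.uint8)  # pad = missing
    dos = gm.dosages.T
    with np.errstate(invalid="ignore"):
        codes[:, :n] = np.select(
            [np.isnan(dos), dos == 2.0, dos == 1.0, dos == 0.0],
            [1, 0, 2, 3],
        ).astype(np.uint8)
    codes = codes.reshape(gm.n_snps, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read ``<prefix>.bed/.bim/.fam`` into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    dup = bim["id"][bim["id"].duplicated()]
    if len(dup):
        raise FormatError(
            f"{_ext(prefix, '.bim')}: duplicated SNP ids {sorted(set(dup))}"
        )
    fam = pd.read_csv(_ext(prefix, ".fam"), sep=r"\s+", header=None, dtype=str)
    samples = fam.iloc[:, 1].to_numpy(dtype=object)

    n, m = len(samples), len(bim)
    bytes_per_snp = (n + 3) // 4
    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{_ext(prefix, '.bed')}: bad magic bytes {raw[:3]!r} at offset 0 "
            f"(expected {_BED_MAGIC!r}: SNP-major v1.00)"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"{_ext(prefix, '.bed')}: expected {m * bytes_per_snp} data bytes "
            f"after offset 3, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T

    snps = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(samples, snps, dosages)


# ---------------------------------------------------------------------------
# TSV dosage dialect


def write_tsv_dosage(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        header = ["#CHROM", "POS", "ID", "A1", "A2"] + [str(s) for s in gm.samples]
        fh.write("\t".join(header) + "\n")
        for j in range(gm.n_snps):
            row = gm.snps.iloc[j]
            cells = [
                "NA" if np.isnan(d) else str(int(d)) for d in gm.dosages[:, j]
            ]
            fh.write(
                "\t".join(
                    [str(row["chrom"]), str(row["pos"]), str(row["id"]),
                     str(row["a1"]), str(row["a2"])] + cells
                )
                + "\n"
            )


def read_tsv_dosage(path: str | os.PathLike) -> GenotypeMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["#CHROM", "POS", "ID", "A1", "A2"]:
            raise FormatError(
                f"{path}: bad header {header[:5]} (expected #CHROM POS ID A1 A2 <IID...>)"
            )
        samples = np.array(header[5:], dtype=object)
        ids, chroms, poss, a1s, a2s, rows = [], [], [], [], [], []
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(samples):
                raise FormatError(
                    f"{path}: line {line_no} has {len(parts)} fields, "
                    f"expected {5 + len(samples)}"
                )
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            ids.append(parts[2])
            a1s.append(parts[3])
            a2s.append(parts[4])
            row = np.empty(len(samples))
            for k, cell in enumerate(parts[5:]):
                if cell == "NA":
                    row[k] = np.nan
                elif cell in ("0", "1", "2"):
                    row[k] = float(cell)
                else:
                    raise FormatError(
                        f"{path}: line {line_no}, sample {samples[k]}: "
                        f"invalid dosage {cell!r} (expected 0/1/2/NA)"
                    )
            rows.append(row)
    snps = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    dosages = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, snps, dosages)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a phenotype/covariate table; the index becomes the IID column."""
    out = df.copy()
    out.insert(0, "IID", out.index)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"IID": str})
    if "IID" not in df.columns:
        raise FormatError(f"{path}: missing IID column")
    return df.set_index("IID")
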