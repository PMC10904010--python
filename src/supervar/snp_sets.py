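"""SNP-set definition: 1-Mbp genomic windows and user-named sets.

A SNP set is the unit over which a supervariant is constructed.  The
systematic partition slices each chromosome into nonoverlapping windows of
``window_bp`` base pairs; window *k* on chromosome *c* is named ``Chr{c}_{k}``
with ``k = floor(pos / window_bp) + 1``, so positions 1..999,999 fall in set
1 and 1,000,000..1,999,999 in set 2 of the default 1-Mbp grid.  Named sets
(e.g. all SNPs in the genes of one Gene Ontology term) may span chromosomes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["SnpSet", "partition_genome", "define_named_set",
           "write_sets_tsv", "read_sets_tsv"]


@dataclass(frozen=True)
class SnpSet:
    set_id: str
    snp_ids: tuple[str, ...]
    provenance: str  # "window" | "named"

    def __post_init__(self) -> None:
        if not self.snp_ids:
            raise ValueError(f"SNP set {self.set_id!r} is empty")
        if self.provenance not in ("window", "named"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.snp_ids)


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def partition_genome(snps: pd.DataFrame, window_bp: int = 1_000_000) -> list[SnpSet]:
    """Partition SNPs into nonoverlapping physical windows.

    Parameters
    ----------
    snps
        DataFrame with columns ``id chrom pos`` (1-based positions).
    window_bp
        Window length in base pairs (default 1 Mbp).

    Returns
    -------
    Nonempty window sets ordered by (chromosome, window index); SNPs within
    a set ordered by position.  Every input SNP lands in exactly one set and
    the result is invariant to input row order.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be positive")
    if len(snps) == 0:
        return []
    if (snps["pos"] < 1).any():
        bad = snps.loc[snps["pos"] < 1, "id"].tolist()
        raise ValueError(f"positions must be >= 1; offending SNPs: {bad}")
    df = snps[["id", "chrom", "pos"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["k"] = df["pos"] // window_bp + 1
    sets = []
    for (chrom, k), grp in df.groupby(["chrom", "k"], sort=False):
        grp = grp.sort_values(["pos", "id"], kind="mergesort")
        sets.append(
            SnpSet(f"Chr{chrom}_{k}", tuple(grp["id"]), "window")
        )
    sets.sort(key=lambda s: (_chrom_sort_key(s.set_id.split("_")[0][3:]),
                             int(s.set_id.split("_")[1])))
    return sets


def define_named_set(
    name: str,
    members: Sequence[str] | Mapping[str, Sequence[str]],
    known_snp_ids: Iterable[str],
) -> SnpSet:
    """Build a user-named SNP set from explicit ids or a gene -> SNPs mapping.

    Duplicate ids are removed preserving first occurrence.  Ids absent from
    ``known_snp_ids`` are dropped; if *all* resolve unknown (or the input is
    empty) an error lists them.  Members may span chromosomes.
    """
    if isinstance(members, Mapping):
        flat: list[str] = [s for gene in members for s in members[gene]]
    else:
        flat = list(members)
    seen: dict[str, None] = {}
    for s in flat:
        seen.setdefault(s, None)
    known = set(known_snp_ids)
    resolved = [s for s in seen if s in known]
    unknown = [s for s in seen if s not in known]
    if not resolved:
        raise ValueError(
            f"named set {name!r} resolved to no known SNPs; unknown ids: {unknown}"
        )
    if unknown:
        warnings.warn(
            f"named set {name!r}: {len(unknown)} unknown SNP ids dropped: {unknown}",
            stacklevel=2,
        )
    return SnpSet(name, tuple(resolved), "named")


def write_sets_tsv(sets: Iterable[SnpSet], path: str | os.PathLike) -> None:
    """Two-column TSV ``set_name snp_id``, one row per membership."""
    rows = [(s.set_id, snp) for s in sets for snp in s.snp_ids]
    pd.DataFrame(rows, columns=["set_name", "snp_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_sets_tsv(path: str | os.PathLike, known_snp_ids: Iterable[str]) -> list[SnpSet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        define_named_set(name, grp["snp_id"].tolist(), known_snp_ids)
        for name, grp in df.groupby("set_name", sort=False)
    ]
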