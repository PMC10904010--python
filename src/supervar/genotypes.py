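"""Genotype container and allele-orientation utilities.

The central in-memory object is :class:`GenotypeMatrix`: a samples x SNPs
matrix of hard-call minor-allele dosages (0/1/2, ``NaN`` for missing) plus a
per-SNP metadata table.  All association scans, burden-score aggregation and
cross-cohort harmonization operate on this container.

Orientation conventions
-----------------------
``a1`` is the *counted* allele of each SNP: a dosage of 2 means two copies of
``a1``.  :func:`orient_to_minor` re-orients a matrix so that ``a1`` is the
minor allele as estimated on that matrix (ties at frequency 0.5 broken by the
lexicographically smaller allele label, so orientation is deterministic across
cohorts).  :func:`harmonize_to_reference` re-orients a second cohort to a
reference orientation table, flipping dosages ``g -> 2 - g`` where the counted
allele disagrees — the step that makes external validation cohorts comparable
to the discovery cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNP_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (unique strings).
    snps
        DataFrame with columns ``id, chrom, pos, a1, a2`` where ``a1`` is the
        counted allele and ``pos`` is a 1-based base-pair position.
    dosages
        ``(n_samples, n_snps)`` float array with values in {0, 1, 2} or NaN
        for missing hard calls.
    """

    samples: np.ndarray
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        dup = self.snps["id"][self.snps["id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate SNP ids: {sorted(set(dup))}")
        if len(np.unique(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        same = self.snps["a1"].astype(str) == self.snps["a2"].astype(str)
        if same.any():
            bad = self.snps.loc[same, "id"].tolist()
            raise ValueError(f"SNPs with identical allele labels: {bad}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be hard calls in {0,1,2} or NaN")

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["id"].to_numpy()

    def snp_indexer(self, snp_ids) -> np.ndarray:
        """Column indices of ``snp_ids``; raises naming absent SNPs."""
        lookup = pd.Index(self.snps["id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            absent = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs absent from genotype matrix: {absent}")
        return idx

    # -- summaries --------------------------------------------------------

    def allele1_frequency(self) -> np.ndarray:
        """Frequency of the counted allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele1_frequency()
        return np.minimum(f, 1.0 - f)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def imputed(self, columns: np.ndarray | None = None) -> np.ndarray:
        """Dosages with missing calls filled by the per-SNP mean.

        Mean imputation happens only at aggregation/regression time; the
        stored matrix keeps its hard calls and NaNs.
        """
        g = self.dosages if columns is None else self.dosages[:, columns]
        g = g.copy()
        nan = np.isnan(g)
        if nan.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(g, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            g[nan] = np.broadcast_to(col_mean, g.shape)[nan]
        return g

    # -- subsetting -------------------------------------------------------

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples[index], self.snps.copy(), self.dosages[index])

    def select_samples(self, sample_ids) -> "GenotypeMatrix":
        lookup = pd.Index(self.samples)
        idx = lookup.get_indexer(list(sample_ids))
        if (idx < 0).any():
            raise KeyError("sample ids absent from genotype matrix")
        return self.take_samples(idx)

    def take_snps(self, columns: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.copy(),
            self.snps.iloc[columns].reset_index(drop=True),
            self.dosages[:, columns],
        )


@dataclass
class OrientationTable:
    """Reference minor-allele orientation: SNP id -> (minor, major) labels."""

    table: pd.DataFrame  # columns: id, minor_allele, major_allele

    def __post_init__(self) -> None:
        need = {"id", "minor_allele", "major_allele"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"orientation table needs columns {sorted(need)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()


def orient_to_minor(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, OrientationTable]:
    """Re-orient a matrix so each SNP's dosage counts its minor allele.

    The minor allele is determined on *this* matrix; a frequency of exactly
    0.5 is broken by the lexicographically smaller allele label so that two
    cohorts seeing 0.5 agree.  Returns the oriented matrix and an
    :class:`OrientationTable` recording the decision for reuse on other
    cohorts.  Idempotent.
    """
    f1 = gm.allele1_frequency()
    a1 = gm.snps["a1"].astype(str).to_numpy()
    a2 = gm.snps["a2"].astype(str).to_numpy()
    tie = np.isclose(f1, 0.5)
    # flip when counted allele is the major one, or on a tie when a2 sorts first
    flip = (f1 > 0.5) & ~tie
    flip |= tie & (a2 < a1)
    # monomorphic-NaN frequency: leave as-is
    flip &= np.isfinite(f1)

    dos = gm.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    snps = gm.snps.copy()
    snps.loc[flip, ["a1", "a2"]] = snps.loc[flip, ["a2", "a1"]].to_numpy()
    oriented = GenotypeMatrix(gm.samples.copy(), snps, dos)
    orientation = OrientationTable(
        pd.DataFrame(
            {
                "id": snps["id"].to_numpy(),
                "minor_allele": snps["a1"].astype(str).to_numpy(),
                "major_allele": snps["a2"].astype(str).to_numpy(),
            }
        )
    )
    return oriented, orientation


def harmonize_to_reference(
    gm: GenotypeMatrix, orientation: OrientationTable
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Align a cohort's dosage coding to a reference minor-allele orientation.

    For each SNP shared with the reference: if the cohort counts the
    reference minor allele already, it is kept as-is; if it counts the
    reference *major* allele, the dosage is complemented (``g -> 2 - g``) and
    the allele labels swapped.  SNPs absent from the cohort and SNPs whose
    allele labels match neither reference allele are excluded, not fatal.

    Returns
    -------
    (harmonized matrix restricted to usable shared SNPs, report DataFrame
    with columns ``snp_id action`` where action is one of
    ``kept | flipped | missing | allele_mismatch``).
    """
    ref = orientation.table.set_index("id")
    cohort_idx = pd.Index(gm.snps["id"])
    actions: list[tuple[str, str]] = []
    keep_cols: list[int] = []
    flip_cols: list[int] = []
    for snp_id, minor, major in ref[["minor_allele", "major_allele"]].itertuples():
        j = cohort_idx.get_indexer([snp_id])[0]
        if j < 0:
            actions.append((snp_id, "missing"))
            continue
        a1 = str(gm.snps.at[j, "a1"])
        a2 = str(gm.snps.at[j, "a2"])
        if a1 == minor and a2 == major:
            actions.append((snp_id, "kept"))
            keep_cols.append(j)
        elif a1 == major and a2 == minor:
            actions.append((snp_id, "flipped"))
            keep_cols.append(j)
            flip_cols.append(j)
        else:
            actions.append((snp_id, "allele_mismatch"))
    report = pd.DataFrame(actions, columns=["snp_id", "action"])

    keep = np.array(keep_cols, dtype=int)
    sub = gm.take_snps(keep) if len(keep) else gm.take_snps(np.array([], dtype=int))
    if flip_cols:
        flip_ids = set(gm.snps.loc[flip_cols, "id"])
        mask = sub.snps["id"].isin(flip_ids).to_numpy()
        sub.dosages[:, mask] = 2.0 - sub.dosages[:, mask]
        sub.snps.loc[mask, ["a1", "a2"]] = sub.snps.loc[mask, ["a2", "a1"]].to_numpy()
    return sub, report
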