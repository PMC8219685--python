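"""Core in-memory containers shared by every module.

Genotypes are held as an individuals x SNPs dosage matrix coded 0/1/2
(count of the minor allele), with ``numpy.nan`` for missing calls.
Phenotypes are a quantitative trait vector aligned to the same
individuals.  Alignment between the two is always by individual id,
never silently positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhenotypeVector", "align"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n individuals x m SNPs) with SNP metadata.

    Parameters
    ----------
    dosages
        Float array of minor-allele counts in {0, 1, 2}; ``nan`` marks a
        missing call.
    snp_ids, chrom, pos
        Per-SNP metadata arrays of length m.  Positions are 1-based.
    individual_ids
        Length-n identifiers; used for joins against phenotypes.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        self.individual_ids = np.asarray(self.individual_ids)
        for name, arr, want in (
            ("snp_ids", self.snp_ids, m),
            ("chrom", self.chrom, m),
            ("pos", self.pos, m),
            ("individual_ids", self.individual_ids, n),
        ):
            if arr.shape != (want,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({want},)")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, f = mean(dosage)/2."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency, min(f, 1-f) in [0, 0.5]."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    # ------------------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order of ``index``."""
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_ids[index],
            self.chrom[index],
            self.pos[index],
            self.individual_ids,
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[index, :],
            self.snp_ids,
            self.chrom,
            self.pos,
            self.individual_ids[index],
        )

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chr": self.chrom, "pos": self.pos,
             "maf": self.maf(), "call_rate": self.call_rate()}
        )


@dataclass
class PhenotypeVector:
    """Quantitative trait values aligned to individuals by id."""

    individual_ids: np.ndarray
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.individual_ids.shape:
            raise ValueError("values and individual_ids must have equal length")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "PhenotypeVector":
        return replace(self, values=np.asarray(values, dtype=float),
                       missing=self.missing.copy())

    def drop_missing(self) -> "PhenotypeVector":
        keep = ~self.missing
        return PhenotypeVector(self.individual_ids[keep], self.values[keep])


def align(genotypes: GenotypeMatrix, phenotype: PhenotypeVector
          ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Inner-join genotypes and phenotype on individual id.

    Individuals with a missing phenotype are dropped.  Raises if the two
    share no individuals; never joins positionally.
    """
    pheno = phenotype.drop_missing()
    g_index = pd.Index(genotypes.individual_ids)
    p_index = pd.Index(pheno.individual_ids)
    common = g_index.intersection(p_index)
    if len(common) == 0:
        raise ValueError("genotypes and phenotype share no individual ids")
    g_pos = g_index.get_indexer(common)
    p_pos = p_index.get_indexer(common)
    return genotypes.take_individuals(g_pos), PhenotypeVector(
        np.asarray(common), pheno.values[p_pos])
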