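"""Core in-memory containers shared across the pipeline.

All genotypes are fully homozygous doubled-haploid (DH) or inbred lines,
coded 0/2 on a fixed reference strand. Haplotype presence/absence markers
use the same 0/2 coding (2 = carrier), so downstream mixed-model code is
agnostic to whether a column is a SNP or a window haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACROSS_ENV = "ACROSS"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class MarkerMap:
    """Per-marker chromosome, physical (bp, 1-based) and optional genetic (cM) position.

    Rows are kept strictly sorted by (chromosome, bp); positions are unique
    within a chromosome and cM, when present, is non-decreasing with bp.
    """

    table: pd.DataFrame  # columns: marker, chrom, pos_bp, [pos_cM]

    def __post_init__(self) -> None:
        req = {"marker", "chrom", "pos_bp"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"marker map missing columns: {sorted(missing)}")
        t = self.table.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in t.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if len(np.unique(pos)) != len(pos):
                dup = pos[np.where(np.diff(np.sort(pos)) == 0)[0][0]]
                raise ValidationError(f"duplicate bp position {dup} on chromosome {chrom}")
            if "pos_cM" in grp.columns and grp["pos_cM"].notna().all():
                cm = grp["pos_cM"].to_numpy(float)
                if np.any(np.diff(cm) < 0):
                    raise ValidationError(f"cM positions decrease with bp on chromosome {chrom}")
        self.table = t

    @property
    def has_cm(self) -> bool:
        return "pos_cM" in self.table.columns and self.table["pos_cM"].notna().all()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypePanel:
    """Lines x markers allele matrix (values in {0, 2}) with population labels."""

    lines: list[str]
    populations: list[str]  # per line: landrace name or "breeding"
    geno: np.ndarray  # (n_lines, n_markers) int8, values in {0, 2}
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        n, m = self.geno.shape
        if len(self.lines) != n or len(self.populations) != n:
            raise ValidationError("line labels do not match genotype matrix rows")
        if m != self.marker_map.n_markers:
            raise ValidationError(
                f"{m} genotype columns but {self.marker_map.n_markers} map rows"
            )
        bad = ~np.isin(self.geno, (0, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype value {self.geno[i, j]} for line {self.lines[i]}, "
                f"marker {self.marker_map.table['marker'].iloc[j]}; DH panels must be coded 0/2"
            )

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def subset_lines(self, keep: np.ndarray | list[str]) -> "GenotypePanel":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif isinstance(keep, np.ndarray) and np.issubdtype(keep.dtype, np.integer):
            idx = keep
        else:
            pos = {l: i for i, l in enumerate(self.lines)}
            idx = np.array([pos[l] for l in keep])
        return GenotypePanel(
            [self.lines[i] for i in idx],
            [self.populations[i] for i in idx],
            self.geno[idx],
            self.marker_map,
        )

    def subset_population(self, *names: str) -> "GenotypePanel":
        mask = np.array([p in names for p in self.populations])
        return self.subset_lines(mask)


@dataclass
class WindowSet:
    """Nonoverlapping consecutive SNP windows exhausting each chromosome."""

    table: pd.DataFrame  # window_id, chrom, start_idx, end_idx, start_bp, end_bp, n_snps, partial, [cm_length]
    window_size: int = 10

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def snp_indices(self, window_id: int) -> np.ndarray:
        row = self.table.loc[self.table["window_id"] == window_id].iloc[0]
        return np.arange(row["start_idx"], row["end_idx"] + 1)


@dataclass
class HaplotypeCatalog:
    """Per-(window, allele string) haplotype with counts/frequencies per population.

    Catalog ids are assigned by (window, lexicographic allele string) so they
    are stable across panels and run order: the same ten-SNP allele string
    observed in the landrace and breeding panels maps to the same hap_id.
    """

    table: pd.DataFrame  # window_id, hap_id, allele_string + count_<pop>, freq_<pop>
    populations: list[str] = field(default_factory=list)

    def counts(self, population: str) -> pd.Series:
        return self.table[f"count_{population}"]

    def freqs(self, population: str) -> pd.Series:
        return self.table[f"freq_{population}"]


@dataclass
class HaplotypeMatrix:
    """Lines x haplotype-markers presence/absence scores in {0, 2}."""

    lines: list[str]
    scores: np.ndarray  # (n_lines, n_haps) int8
    info: pd.DataFrame  # per column: window_id, hap_id, chrom, start_bp, end_bp

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        if self.scores.shape != (len(self.lines), len(self.info)):
            raise ValidationError("haplotype score matrix shape mismatch")

    @property
    def n_lines(self) -> int:
        return self.scores.shape[0]

    @property
    def n_haps(self) -> int:
        return self.scores.shape[1]

    def subset_lines(self, keep_idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            [self.lines[i] for i in keep_idx], self.scores[keep_idx], self.info
        )

    def subset_columns(self, keep: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.lines, self.scores[:, keep], self.info.iloc[keep].reset_index(drop=True)
        )


@dataclass
class PhenotypeTable:
    """Long-format BLUEs: one value per (line, environment, trait).

    Environment label ``ACROSS`` marks the across-environment BLUE.
    """

    table: pd.DataFrame  # line, environment, trait, value

    def __post_init__(self) -> None:
        req = {"line", "environment", "trait", "value"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        dup = self.table.duplicated(["line", "environment", "trait"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValidationError(
                f"duplicate phenotype record for line={row['line']} "
                f"environment={row['environment']} trait={row['trait']}"
            )
        self.table = self.table.reset_index(drop=True)

    def environments(self, trait: str, include_across: bool = False) -> list[str]:
        envs = self.table.loc[self.table["trait"] == trait, "environment"].unique().tolist()
        if not include_across:
            envs = [e for e in envs if e != ACROSS_ENV]
        return sorted(envs)

    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique().tolist())

    def values_for(self, trait: str, environment: str) -> pd.Series:
        sub = self.table[
            (self.table["trait"] == trait) & (self.table["environment"] == environment)
        ]
        return pd.Series(sub["value"].to_numpy(), index=sub["line"].to_numpy())
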