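"""Core in-memory containers shared by every stage of the pipeline.

All coordinates held in these containers are 0-based half-open; conversion
from the 1-based inclusive conventions of VCF and GFF3 happens exactly once,
at the I/O boundary.  Genotypes are stored as alt-allele dosages in
{0, 1, 2} with ``-1`` marking a missing call; phase is discarded because no
statistic in this package uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEX_LABELS = ("male", "hermaphrodite")


class FormatError(ValueError):
    """A file violates the format contract (bad header, unsorted records...)."""


class ValidationError(ValueError):
    """Inputs are well-formed but violate a semantic invariant."""


@dataclass
class VariantTable:
    """Biallelic SNP sites by samples, with per-sample alt-allele dosages.

    Attributes
    ----------
    contig : np.ndarray of str, one entry per site
    pos : np.ndarray of int, 0-based site position
    ref, alt : np.ndarray of single-character alleles
    dosages : int8 array of shape (n_sites, n_samples); -1 = missing call
    samples : list of sample identifiers (column order of ``dosages``)
    """

    contig: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != self.pos.shape[0]:
            raise ValidationError("dosage matrix must be (n_sites, n_samples)")
        if self.dosages.shape[1] != len(self.samples):
            raise ValidationError("dosage columns must match sample list")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosages must be in {0,1,2} or -1 (missing)")
        # positions strictly increasing within each contig
        for ctg in pd.unique(self.contig):
            p = self.pos[self.contig == ctg]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise FormatError(
                    f"positions not strictly increasing on contig {ctg!r}"
                )

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValidationError(f"samples not in variant table: {missing}")
        return np.array([lookup[n] for n in names], dtype=np.intp)

    def subset_contig(self, contig: str) -> "VariantTable":
        keep = self.contig == contig
        return VariantTable(
            self.contig[keep], self.pos[keep], self.ref[keep],
            self.alt[keep], self.dosages[keep], self.samples,
        )


@dataclass
class SexManifest:
    """Sample -> sex / population assignment defining the two scan groups."""

    table: pd.DataFrame  # columns: sample_id, sex, population

    def __post_init__(self) -> None:
        required = {"sample_id", "sex", "population"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"manifest must have columns {sorted(required)}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = self.table.loc[~self.table["sex"].isin(SEX_LABELS)]
        if len(bad):
            rows = bad.index.tolist()
            raise ValidationError(
                f"unknown sex labels {sorted(set(bad['sex']))} in rows {rows}; "
                f"allowed: {list(SEX_LABELS)}"
            )

    @property
    def samples(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group(self, sex: str) -> list[str]:
        if sex not in SEX_LABELS:
            raise ValidationError(f"unknown sex label {sex!r}")
        return self.table.loc[self.table["sex"] == sex, "sample_id"].tolist()

    @property
    def males(self) -> list[str]:
        return self.group("male")

    @property
    def hermaphrodites(self) -> list[str]:
        return self.group("hermaphrodite")

    def require_scan_groups(self, min_per_sex: int = 2) -> None:
        for sex in SEX_LABELS:
            if len(self.group(sex)) < min_per_sex:
                raise ValidationError(
                    f"need at least {min_per_sex} {sex} samples for a scan"
                )


@dataclass
class DepthTable:
    """Per-sample mean read depth over tiled windows (0-based half-open)."""

    contig: np.ndarray
    start: np.ndarray
    end: np.ndarray
    depth: np.ndarray  # (n_windows, n_samples), float, >= 0
    samples: list[str]

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.end <= self.start).any():
            raise ValidationError("depth windows must have end > start")
        if (self.depth < 0).any():
            raise ValidationError("depths must be non-negative")
        if self.depth.shape != (len(self.start), len(self.samples)):
            raise ValidationError("depth matrix must be (n_windows, n_samples)")
        for ctg in pd.unique(self.contig):
            m = self.contig == ctg
            s, e = self.start[m], self.end[m]
            if len(s) > 1 and not ((s[1:] >= e[:-1]).all() and (np.diff(s) > 0).all()):
                raise FormatError(f"windows overlap or unsorted on contig {ctg!r}")

    @property
    def n_windows(self) -> int:
        return int(self.start.shape[0])

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValidationError(f"samples not in depth table: {missing}")
        return np.array([lookup[n] for n in names], dtype=np.intp)


@dataclass
class GeneAnnotation:
    """Gene models as a DataFrame: gene_id, contig, start, end, strand.

    ``start``/``end`` are 0-based half-open (converted from GFF3 at read
    time); ``strand`` is one of '+', '-', '.'.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"gene_id", "contig", "start", "end", "strand"}
        if len(self.table) == 0:
            self.table = pd.DataFrame(columns=sorted(required))
        if not required.issubset(self.table.columns):
            raise FormatError(f"annotation must have columns {sorted(required)}")
        if (self.table["end"] <= self.table["start"]).any():
            bad = self.table.loc[self.table["end"] <= self.table["start"], "gene_id"]
            raise ValidationError(f"gene end <= start for: {bad.tolist()}")
        dup = self.table["gene_id"][self.table["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene ids: {sorted(set(dup))}")

    def __len__(self) -> int:
        return len(self.table)


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """True iff two 0-based half-open intervals share at least one base."""
    return a_start < b_end and b_start < a_end
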