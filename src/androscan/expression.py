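"""RPKM normalization and group-contrast screening of candidate genes.

Expression is compared between tissue groups (male flowers, hermaphroditic
flowers, fruits) after RPKM normalization.  The screen classifies each
gene by the log2 fold change of group-mean RPKM (with a pseudocount of
1 RPKM) combined with a label-permutation test; it is a deliberately
simple, assumption-light contrast with the same interface a
negative-binomial differential-expression model would have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with gene lengths and sample group labels."""

    counts: pd.DataFrame          # genes x samples, non-negative ints
    gene_lengths: pd.Series       # bp, indexed by gene_id
    sample_groups: pd.Series      # tissue/sex label, indexed by sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValidationError("every gene needs a positive length")
        self.sample_groups = self.sample_groups.reindex(self.counts.columns)
        if self.sample_groups.isna().any():
            missing = self.counts.columns[self.sample_groups.isna()].tolist()
            raise ValidationError(f"unlabeled samples: {missing}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def rpkm(counts, gene_length, library_size):
    """Reads per kilobase of transcript per million mapped reads.

    counts * 1e9 / (gene_length * library_size); linear in counts,
    inversely proportional to gene length and library size.
    """
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (library_size <= 0).any():
        raise ValidationError("library size must be positive")
    if (gene_length <= 0).any():
        raise ValidationError("gene length must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (gene_length * library_size)


def rpkm_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    lib = matrix.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = matrix.counts.columns[lib <= 0].tolist()
        raise ValidationError(f"zero library size for samples: {bad}")
    vals = rpkm(
        matrix.counts.to_numpy(dtype=float),
        matrix.gene_lengths.to_numpy(dtype=float)[:, None],
        lib[None, :],
    )
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)


def group_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean RPKM per gene within each sample group."""
    r = rpkm_matrix(matrix)
    groups = matrix.sample_groups
    if (groups.value_counts() == 0).any():
        raise ValidationError("every group must be non-empty")
    return r.T.groupby(groups).mean().T


def contrast_screen(matrix: ExpressionMatrix, group_a: str, group_b: str,
                    min_abs_log2fc: float = 1.0, permutations: int = 1000,
                    alpha: float = 0.05, pseudocount: float = 1.0,
                    seed: int = 0) -> pd.DataFrame:
    """Classify genes as a-high / b-high / ns between two sample groups.

    The statistic is log2((mean_a + pc) / (mean_b + pc)) of group-mean
    RPKM.  Significance combines |log2FC| >= ``min_abs_log2fc`` with a
    two-sided label-permutation p-value <= ``alpha`` (p includes the
    observed labeling: p = (1 + #{|perm| >= |obs|}) / (1 + permutations)).
    """
    if permutations < 19:
        raise ValidationError("need at least 19 permutations")
    labels = matrix.sample_groups
    for g in (group_a, group_b):
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} needs >= 2 samples")
    keep = labels.isin([group_a, group_b])
    r = rpkm_matrix(matrix).loc[:, keep.index[keep]].to_numpy()
    lab = labels[keep].to_numpy()
    is_a = lab == group_a

    def log2fc(a_mask: np.ndarray) -> np.ndarray:
        ma = r[:, a_mask].mean(axis=1)
        mb = r[:, ~a_mask].mean(axis=1)
        return np.log2((ma + pseudocount) / (mb + pseudocount))

    obs = log2fc(is_a)
    rng = np.random.default_rng(seed)
    n_a = int(is_a.sum())
    n = len(lab)
    exceed = np.zeros(r.shape[0], dtype=np.int64)
    for _ in range(permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_a, replace=False)] = True
        exceed += np.abs(log2fc(perm)) >= np.abs(obs)
    p = (1.0 + exceed) / (1.0 + permutations)

    cls = np.full(r.shape[0], "ns", dtype=object)
    sig = (np.abs(obs) >= min_abs_log2fc) & (p <= alpha)
    cls[sig & (obs > 0)] = "a-high"
    cls[sig & (obs < 0)] = "b-high"
    return pd.DataFrame(
        {"log2fc": obs, "perm_p": p, "class": cls}, index=matrix.counts.index
    )
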