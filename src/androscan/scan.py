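"""Genome-wide window scan for sex-linked regions.

The scan tiles each contig into windows (10 kb non-overlapping by default;
20 kb and sliding windows are supported), computes per-window nucleotide
diversity for males and hermaphrodites, windowed F_ST between the sexes,
and the reduction-of-diversity statistic ROD = 1 - pi_male/pi_herm, then
ranks windows by F_ST.

Significance is deliberately explicit about an ambiguity in common
practice: a printed "cutoff" of 1e-5 can mean an absolute F_ST (uselessly
permissive), an empirical top fraction, or a permutation p-value.  All
three are implemented as ``threshold_mode``; the default is ``quantile``,
reading the value as a top fraction of windows with a floor of one window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popgen
from .types import GeneAnnotation, SexManifest, ValidationError, VariantTable

THRESHOLD_MODES = ("quantile", "permutation", "absolute")


@dataclass
class ScanConfig:
    """Tunable parameters of the window scan (defaults mirror the study)."""

    window_size: int = 10_000
    window_step: int | None = None  # None -> non-overlapping (= size)
    estimator: str = "hudson"
    threshold_mode: str = "quantile"
    threshold_value: float = 1e-5
    min_sites: int = 5
    gene_fst_cutoff: float = 0.2
    merge_gap: int = 0
    permutations: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_step is None:
            self.window_step = self.window_size
        if self.window_size <= 0 or self.window_step <= 0:
            raise ValidationError("window size and step must be positive")
        if self.window_step > self.window_size:
            raise ValidationError("window_step must be <= window_size")
        if self.estimator not in popgen.ESTIMATORS:
            raise ValidationError(f"estimator must be one of {popgen.ESTIMATORS}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValidationError(f"threshold_mode must be one of {THRESHOLD_MODES}")
        if self.threshold_mode == "permutation" and self.permutations < 1:
            raise ValidationError("permutation mode needs permutations >= 1")


def make_windows(contig_lengths: dict[str, int], size: int, step: int | None = None
                 ) -> pd.DataFrame:
    """Tile contigs into 0-based half-open windows.

    The terminal partial window is retained and flagged (``partial``).
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValidationError("size and step must be positive")
    rows = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValidationError(f"contig {contig!r} has non-positive length")
        for start in range(0, length, step):
            end = min(start + size, length)
            rows.append((contig, start, end, end - start < size))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "partial"])


def infer_contig_lengths(variants: VariantTable, window_size: int) -> dict[str, int]:
    """Contig lengths implied by the last variant, rounded up to whole windows."""
    lengths: dict[str, int] = {}
    for contig in pd.unique(variants.contig):
        last = int(variants.pos[variants.contig == contig].max()) + 1
        n_win = -(-last // window_size)
        lengths[contig] = n_win * window_size
    return lengths


def _window_index(variants: VariantTable, windows: pd.DataFrame) -> list[np.ndarray]:
    """Per-window site index arrays (sliding windows may share sites)."""
    out = []
    for contig, start, end in windows[["contig", "start", "end"]].itertuples(index=False):
        mask = (variants.contig == contig) & (variants.pos >= start) & (variants.pos < end)
        out.append(np.flatnonzero(mask))
    return out


def _rank_p(fst: np.ndarray) -> np.ndarray:
    """Empirical tail probability: fraction of defined windows with F_ST >= own."""
    out = np.full(fst.shape, np.nan)
    defined = ~np.isnan(fst)
    vals = fst[defined]
    if vals.size:
        # fraction >= each value, via sorted search
        order = np.sort(vals)
        ge = vals.size - np.searchsorted(order, vals, side="left")
        out[defined] = ge / vals.size
    return out


def scan(variants: VariantTable, manifest: SexManifest,
         config: ScanConfig | None = None,
         contig_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Run the window scan; one row per window.

    Columns: contig, start, end, n_sites, pi_male, pi_herm, fst, rod,
    rank_p.  ``rank_p`` is the empirical tail probability of the window's
    F_ST among all defined windows.  Output is deterministic and invariant
    to site/sample ordering of the inputs.
    """
    config = config or ScanConfig()
    manifest.require_scan_groups()
    if contig_lengths is None:
        if variants.n_sites == 0:
            raise ValidationError("empty variant table and no contig lengths given")
        contig_lengths = infer_contig_lengths(variants, config.window_size)
    windows = make_windows(contig_lengths, config.window_size, config.window_step)
    cols_m = variants.sample_indices(sorted(manifest.males))
    cols_h = variants.sample_indices(sorted(manifest.hermaphrodites))

    nc_m, na_m = popgen.group_site_counts(variants.dosages, cols_m)
    nc_h, na_h = popgen.group_site_counts(variants.dosages, cols_h)
    pi_m_site = popgen._site_pi_arr(na_m, nc_m)
    pi_h_site = popgen._site_pi_arr(na_h, nc_h)
    num, den = popgen.fst_site_components(
        variants.dosages, cols_m, cols_h, config.estimator
    )

    idx = _window_index(variants, windows)
    n_win = len(windows)
    n_sites = np.zeros(n_win, dtype=np.int64)
    pi_m = np.zeros(n_win)
    pi_h = np.zeros(n_win)
    fst = np.full(n_win, np.nan)
    for w, sites in enumerate(idx):
        length = windows["end"].iat[w] - windows["start"].iat[w]
        n_sites[w] = sites.size
        pi_m[w] = np.nansum(pi_m_site[sites]) / length
        pi_h[w] = np.nansum(pi_h_site[sites]) / length
        fst[w] = popgen.combine_fst(num[sites], den[sites], config.min_sites)

    if np.isnan(fst).all():
        raise ValidationError(
            "no window has a defined F_ST; lower min_sites or enlarge windows"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rod_vals = np.where(pi_h > 0, 1.0 - pi_m / pi_h, np.nan)
    out = windows[["contig", "start", "end"]].copy()
    out["n_sites"] = n_sites
    out["pi_male"] = pi_m
    out["pi_herm"] = pi_h
    out["fst"] = fst
    out["rod"] = rod_vals
    out["rank_p"] = _rank_p(fst)
    return out


def permutation_null(variants: VariantTable, manifest: SexManifest,
                     config: ScanConfig | None = None,
                     contig_lengths: dict[str, int] | None = None,
                     permutations: int | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Family-wise permutation p-values from the genome-wide max-F_ST null.

    Sex labels are permuted across samples; each window's p-value is
    (1 + #{permutation max F_ST >= observed F_ST}) / (1 + permutations).
    Using the maximum over windows as the null statistic controls the
    family-wise error rate across the whole scan.
    """
    config = config or ScanConfig()
    permutations = config.permutations if permutations is None else permutations
    seed = config.seed if seed is None else seed
    if permutations < 19:
        raise ValidationError("need at least 19 permutations")
    if len(manifest.samples) < 4:
        raise ValidationError("need at least 4 samples to permute")
    observed = scan(variants, manifest, config, contig_lengths)
    obs_fst = observed["fst"].to_numpy()

    rng = np.random.default_rng(seed)
    sexes = manifest.table["sex"].to_numpy().copy()
    exceed = np.zeros(len(observed), dtype=np.int64)
    for _ in range(permutations):
        rng.shuffle(sexes)
        perm = SexManifest(
            manifest.table.assign(sex=sexes)[["sample_id", "sex", "population"]]
        )
        perm_fst = scan(variants, perm, config, contig_lengths)["fst"].to_numpy()
        max_null = np.nanmax(perm_fst)
        exceed += (max_null >= obs_fst) & ~np.isnan(obs_fst)

    out = observed.copy()
    p = np.full(len(observed), np.nan)
    defined = ~np.isnan(obs_fst)
    p[defined] = (1.0 + exceed[defined]) / (1.0 + permutations)
    out["perm_p"] = p
    return out


def _significant_mask(stats: pd.DataFrame, config: ScanConfig,
                      perm_p: np.ndarray | None = None) -> np.ndarray:
    fst = stats["fst"].to_numpy()
    defined = ~np.isnan(fst)
    if config.threshold_mode == "absolute":
        return defined & (fst >= config.threshold_value)
    if config.threshold_mode == "permutation":
        if perm_p is None:
            if "perm_p" not in stats.columns:
                raise ValidationError(
                    "permutation mode needs a 'perm_p' column (run permutation_null)"
                )
            perm_p = stats["perm_p"].to_numpy()
        return defined & (perm_p <= config.threshold_value)
    # quantile: top fraction of defined windows, floor of one window;
    # ties broken by higher F_ST then by coordinate
    n_defined = int(defined.sum())
    n_keep = max(1, int(np.floor(config.threshold_value * n_defined)))
    order = stats.assign(_fst=fst).sort_values(
        ["_fst", "contig", "start"], ascending=[False, True, True]
    ).index[:n_keep]
    mask = np.zeros(len(stats), dtype=bool)
    mask[stats.index.get_indexer(order)] = True
    return mask & defined


def candidate_regions(stats: pd.DataFrame, config: ScanConfig | None = None
                      ) -> pd.DataFrame:
    """Merge significant windows into candidate regions.

    Windows passing the configured threshold are merged when separated by
    at most ``merge_gap`` bp on the same contig.  Each region carries the
    best (highest) window F_ST, the best rank_p and the number of windows.
    """
    config = config or ScanConfig()
    sig = stats.loc[_significant_mask(stats, config)]
    if sig.empty:
        return pd.DataFrame(
            columns=["contig", "start", "end", "n_windows", "best_fst", "best_rank_p"]
        )
    sig = sig.sort_values(["contig", "start"])
    rows = []
    cur = None
    for r in sig.itertuples(index=False):
        if cur is not None and r.contig == cur["contig"] and r.start - cur["end"] <= config.merge_gap:
            cur["end"] = max(cur["end"], r.end)
            cur["n_windows"] += 1
            cur["best_fst"] = max(cur["best_fst"], r.fst)
            cur["best_rank_p"] = min(cur["best_rank_p"], r.rank_p)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "contig": r.contig, "start": int(r.start), "end": int(r.end),
                "n_windows": 1, "best_fst": float(r.fst),
                "best_rank_p": float(r.rank_p),
            }
    rows.append(cur)
    return pd.DataFrame(rows)


def candidate_genes(regions: pd.DataFrame, annotation: GeneAnnotation,
                    stats: pd.DataFrame, gene_fst_cutoff: float | None = None,
                    hemizygous_regions: pd.DataFrame | None = None,
                    expression_classes: dict[str, str] | None = None
                    ) -> pd.DataFrame:
    """Genes overlapping candidate regions, annotated with window statistics.

    A gene qualifies on >= 1 bp overlap with any candidate region.  Each
    row carries the maximum F_ST and best rank_p over windows overlapping
    the gene, the mean ROD over those windows, a hemizygosity flag (overlap
    with any supplied absence region) and an expression class looked up by
    gene id ('ns' when absent).  When ``gene_fst_cutoff`` is given, rows
    with max F_ST <= cutoff are dropped.
    """
    if regions.empty or len(annotation) == 0:
        return pd.DataFrame(
            columns=["gene_id", "contig", "max_window_fst", "best_rank_p",
                     "mean_rod", "hemizygous_flag", "expression_class"]
        )
    scan_contigs = set(stats["contig"])
    ann_contigs = set(annotation.table["contig"])
    if ann_contigs.isdisjoint(scan_contigs):
        raise ValidationError(
            f"no shared contigs between annotation {sorted(ann_contigs)} "
            f"and scan {sorted(scan_contigs)}"
        )
    rows = []
    for g in annotation.table.itertuples(index=False):
        hit = regions[
            (regions["contig"] == g.contig)
            & (regions["start"] < g.end)
            & (regions["end"] > g.start)
        ]
        if hit.empty:
            continue
        over = stats[
            (stats["contig"] == g.contig)
            & (stats["start"] < g.end)
            & (stats["end"] > g.start)
        ]
        hemi = False
        if hemizygous_regions is not None and not hemizygous_regions.empty:
            hemi = bool(
                (
                    (hemizygous_regions["contig"] == g.contig)
                    & (hemizygous_regions["start"] < g.end)
                    & (hemizygous_regions["end"] > g.start)
                ).any()
            )
        expr = "ns"
        if expression_classes is not None:
            expr = expression_classes.get(g.gene_id, "ns")
        rows.append(
            {
                "gene_id": g.gene_id,
                "contig": g.contig,
                "max_window_fst": float(np.nanmax(over["fst"])) if len(over) else np.nan,
                "best_rank_p": float(np.nanmin(over["rank_p"])) if len(over) else np.nan,
                "mean_rod": float(np.nanmean(over["rod"])) if len(over) and not over["rod"].isna().all() else np.nan,
                "hemizygous_flag": hemi,
                "expression_class": expr,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "contig", "max_window_fst", "best_rank_p",
                 "mean_rod", "hemizygous_flag", "expression_class"],
    )
    if gene_fst_cutoff is not None:
        out = out[out["max_window_fst"] > gene_fst_cutoff].reset_index(drop=True)
    return out
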