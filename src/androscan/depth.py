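"""Depth-based detection of sex-restricted (hemizygous) regions.

A region present in males but deleted in hermaphrodites leaves a simple
footprint in windowed read depth: after per-sample normalization,
hermaphrodites drop to ~0 while hemizygous males sit near 0.5 (one copy
instead of two).  This module normalizes each sample's windowed depth by
its own genome-wide median (making calls invariant to library size),
summarizes each sex group by its median across samples (robust to
single-sample dropouts), and calls maximal runs of windows where one group
is absent and the other clearly present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DepthTable, SexManifest, ValidationError

ABSENCE_COLUMNS = [
    "contig", "start", "end", "n_windows",
    "median_depth_male", "median_depth_herm", "classification",
]


def normalize_depth(table: DepthTable, min_nonzero_windows: int = 20) -> DepthTable:
    """Scale each sample's depth track by its genome-wide median window depth.

    After normalization a diploid-typical window sits near 1.0 for every
    sample regardless of sequencing effort; zero-depth windows stay 0.
    """
    depth = table.depth
    nonzero = (depth > 0).sum(axis=0)
    bad = [s for s, n in zip(table.samples, nonzero) if n < min_nonzero_windows]
    if bad:
        raise ValidationError(
            f"samples with fewer than {min_nonzero_windows} non-zero windows: {bad}"
        )
    medians = np.median(depth, axis=0)
    zero_med = [s for s, m in zip(table.samples, medians) if m <= 0]
    if zero_med:
        raise ValidationError(f"zero median depth for samples: {zero_med}")
    return DepthTable(
        table.contig, table.start, table.end, depth / medians, list(table.samples)
    )


def call_absent_regions(normalized: DepthTable, manifest: SexManifest,
                        herm_max: float = 0.1, male_min: float = 0.3,
                        min_region_length: int = 5_000,
                        merge_gap_windows: int = 1) -> pd.DataFrame:
    """Call regions absent in one sex from normalized group-median depth.

    A window is hermaphrodite-absent when the hermaphrodite median
    normalized depth is <= ``herm_max`` while the male median is
    >= ``male_min`` (and symmetrically for male-absent).  Adjacent flagged
    windows are merged across gaps of at most ``merge_gap_windows``
    windows; runs shorter than ``min_region_length`` bp are dropped.
    """
    if not herm_max < male_min:
        raise ValidationError("need herm_max < male_min")
    cols_m = normalized.sample_indices(manifest.males)
    cols_h = normalized.sample_indices(manifest.hermaphrodites)
    med_m = np.median(normalized.depth[:, cols_m], axis=1)
    med_h = np.median(normalized.depth[:, cols_h], axis=1)

    herm_absent = (med_h <= herm_max) & (med_m >= male_min)
    male_absent = (med_m <= herm_max) & (med_h >= male_min)

    rows = []
    for mask, label in ((herm_absent, "herm-absent"), (male_absent, "male-absent")):
        rows.extend(
            _merge_runs(normalized, mask, med_m, med_h, label,
                        min_region_length, merge_gap_windows)
        )
    out = pd.DataFrame(rows, columns=ABSENCE_COLUMNS)
    return out.sort_values(["contig", "start"]).reset_index(drop=True)


def _merge_runs(table: DepthTable, mask, med_m, med_h, label,
                min_region_length, merge_gap_windows):
    rows = []
    for contig in pd.unique(table.contig):
        on_ctg = np.flatnonzero(table.contig == contig)
        flagged = on_ctg[mask[on_ctg]]
        if flagged.size == 0:
            continue
        runs: list[list[int]] = [[flagged[0]]]
        for i in flagged[1:]:
            # gap counted in windows between consecutive flagged windows
            if i - runs[-1][-1] - 1 <= merge_gap_windows:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            first, last = run[0], run[-1]
            start = int(table.start[first])
            end = int(table.end[last])
            if end - start < min_region_length:
                continue
            span = np.arange(first, last + 1)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_windows": int(last - first + 1),
                    "median_depth_male": float(np.median(med_m[span])),
                    "median_depth_herm": float(np.median(med_h[span])),
                    "classification": label,
                }
            )
    return rows


def deletion_total_length(intervals) -> int:
    """Total length of deletions given lengths or (start, end) intervals.

    Scalar inputs are summed directly; interval inputs are unioned first so
    overlaps are not double-counted.
    """
    items = list(intervals)
    if not items:
        return 0
    if all(np.isscalar(x) for x in items):
        if any(x <= 0 for x in items):
            raise ValidationError("deletion lengths must be positive")
        return int(sum(items))
    spans = sorted((int(s), int(e)) for s, e in items)
    if any(e - s <= 0 for s, e in spans):
        raise ValidationError("intervals must have positive length")
    total = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total
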