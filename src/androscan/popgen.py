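"""Diversity and divergence estimators for the male/hermaphrodite contrast.

Per-site building blocks (``site_pi``, ``hudson_fst_site``, ``wc_fst_site``)
and their windowed forms.  Windowed F_ST uses ratio-of-sums aggregation
(sum of per-site numerators over sum of denominators), which is robust to
rare variants; nucleotide diversity is reported per base pair of window so
that the ROD ratio is comparable across windows.

Two F_ST estimators are available:

* ``hudson`` — Hudson's estimator in the two-population form
  num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
  den = p1(1-p2) + p2(1-p1), with n the called haplotype counts;
* ``weir-cockerham`` — the Weir & Cockerham (1984) variance components
  (a, b, c) for two populations, windowed as sum(a)/sum(a+b+c).

Missing genotypes reduce the called-allele count at a site; they are never
imputed.  Sites with fewer than two called haplotypes in a group are
excluded from that statistic and counted.
"""

from __future__ import annotations

import numpy as np

from .types import MISSING, ValidationError

ESTIMATORS = ("hudson", "weir-cockerham")


# ---------------------------------------------------------------------------
# per-site scalar forms
# ---------------------------------------------------------------------------

def site_pi(n_alt: int, n_called: int) -> float:
    """Mean pairwise difference at one site: 2*j*(n-j) / (n*(n-1)).

    ``n_called`` counts haplotypes (2 per fully called diploid).  Undefined
    (NaN) when fewer than two haplotypes are called.
    """
    if n_called < 2:
        return float("nan")
    if not 0 <= n_alt <= n_called:
        raise ValidationError("need 0 <= n_alt <= n_called")
    return 2.0 * n_alt * (n_called - n_alt) / (n_called * (n_called - 1.0))


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int):
    """Hudson per-site F_ST components (numerator, denominator).

    Returned separately so windows can aggregate ratio-of-sums.  Requires at
    least two called haplotypes per group; returns (nan, nan) otherwise.
    """
    if n1 < 2 or n2 < 2:
        return float("nan"), float("nan")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def wc_fst_site(dosages1, dosages2):
    """Weir & Cockerham (1984) components for one biallelic site, two groups.

    Parameters are per-group diploid dosage vectors (missing calls removed
    or coded -1, which is dropped here).  Returns ``(a, a + b + c)`` so the
    window value is sum(a) / sum(a+b+c).  Monomorphic sites give (0, 0);
    fewer than two called diploids in either group gives (nan, nan).
    """
    d1 = np.asarray(dosages1)
    d2 = np.asarray(dosages2)
    d1 = d1[d1 != MISSING]
    d2 = d2[d2 != MISSING]
    if d1.size < 2 or d2.size < 2:
        return float("nan"), float("nan")
    r = 2.0
    n_i = np.array([d1.size, d2.size], dtype=float)
    p_i = np.array([d1.mean() / 2.0, d2.mean() / 2.0])
    h_i = np.array([(d1 == 1).mean(), (d2 == 1).mean()])
    if p_i[0] in (0.0, 1.0) and p_i[1] == p_i[0]:
        return 0.0, 0.0
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1.0)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1.0) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return a, a + b + c


def rod(pi_male: float, pi_herm: float) -> float:
    """Reduction of diversity, 1 - pi_male / pi_hermaphroditic.

    Positive when male diversity is reduced relative to hermaphrodites;
    undefined (NaN) when hermaphrodite diversity is zero.
    """
    if pi_herm <= 0 or np.isnan(pi_herm) or np.isnan(pi_male):
        return float("nan")
    return 1.0 - pi_male / pi_herm


# ---------------------------------------------------------------------------
# vectorized group counts
# ---------------------------------------------------------------------------

def group_site_counts(dosages: np.ndarray, cols: np.ndarray):
    """Called-haplotype and alt-allele counts per site for one sample group.

    Returns (n_called, n_alt) as int arrays over sites.  A missing genotype
    removes both haplotypes of that diploid from the site.
    """
    sub = dosages[:, cols]
    called = sub != MISSING
    n_called = 2 * called.sum(axis=1)
    n_alt = np.where(called, sub, 0).sum(axis=1)
    return n_called.astype(np.int64), n_alt.astype(np.int64)


def _site_pi_arr(n_alt, n_called):
    out = np.full(n_alt.shape, np.nan)
    ok = n_called >= 2
    na, nc = n_alt[ok].astype(float), n_called[ok].astype(float)
    out[ok] = 2.0 * na * (nc - na) / (nc * (nc - 1.0))
    return out


def _hudson_arr(n_alt1, n_called1, n_alt2, n_called2):
    ok = (n_called1 >= 2) & (n_called2 >= 2)
    p1 = np.divide(n_alt1, n_called1, where=n_called1 > 0, out=np.zeros_like(n_alt1, dtype=float))
    p2 = np.divide(n_alt2, n_called2, where=n_called2 > 0, out=np.zeros_like(n_alt2, dtype=float))
    num = np.full(p1.shape, np.nan)
    den = np.full(p1.shape, np.nan)
    n1 = n_called1.astype(float)
    n2 = n_called2.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num_all = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den_all = p1 * (1 - p2) + p2 * (1 - p1)
    num[ok] = num_all[ok]
    den[ok] = den_all[ok]
    return num, den


def _wc_arr(dosages, cols1, cols2):
    num = np.empty(dosages.shape[0])
    den = np.empty(dosages.shape[0])
    for i in range(dosages.shape[0]):
        num[i], den[i] = wc_fst_site(dosages[i, cols1], dosages[i, cols2])
    return num, den


# ---------------------------------------------------------------------------
# windowed forms
# ---------------------------------------------------------------------------

def window_pi(variants, sample_names, window, contig=None) -> float:
    """Nucleotide diversity per bp of one window for one sample group.

    ``window`` is (start, end), 0-based half-open; monomorphic positions
    contribute zero implicitly (the denominator is the window length in bp).
    Sites with fewer than two called haplotypes are skipped.
    """
    start, end = window
    if end <= start:
        raise ValidationError("zero-length window")
    cols = variants.sample_indices(sample_names)
    in_win = (variants.pos >= start) & (variants.pos < end)
    if contig is not None:
        in_win &= variants.contig == contig
    n_called, n_alt = group_site_counts(variants.dosages[in_win], cols)
    pis = _site_pi_arr(n_alt, n_called)
    return float(np.nansum(pis) / (end - start))


def window_fst(variants, manifest, window, estimator: str = "hudson",
               contig=None, min_sites: int = 5) -> float:
    """Windowed two-group F_ST (ratio-of-sums); NaN when undefined.

    Undefined when the number of informative sites is below ``min_sites``
    or the summed denominator is zero.
    """
    if estimator not in ESTIMATORS:
        raise ValidationError(f"estimator must be one of {ESTIMATORS}")
    start, end = window
    if end <= start:
        raise ValidationError("zero-length window")
    in_win = (variants.pos >= start) & (variants.pos < end)
    if contig is not None:
        in_win &= variants.contig == contig
    cols_m = variants.sample_indices(manifest.males)
    cols_h = variants.sample_indices(manifest.hermaphrodites)
    dos = variants.dosages[in_win]
    num, den = fst_site_components(dos, cols_m, cols_h, estimator)
    return combine_fst(num, den, min_sites)


def fst_site_components(dosages, cols1, cols2, estimator: str = "hudson"):
    """Per-site F_ST (numerator, denominator) arrays for two sample groups."""
    if estimator == "hudson":
        nc1, na1 = group_site_counts(dosages, cols1)
        nc2, na2 = group_site_counts(dosages, cols2)
        return _hudson_arr(na1, nc1, na2, nc2)
    if estimator == "weir-cockerham":
        return _wc_arr(dosages, cols1, cols2)
    raise ValidationError(f"estimator must be one of {ESTIMATORS}")


def combine_fst(num, den, min_sites: int = 5) -> float:
    """Ratio-of-sums window F_ST from per-site components; NaN if undefined."""
    ok = ~(np.isnan(num) | np.isnan(den))
    informative = ok & (den != 0)
    if informative.sum() < min_sites:
        return float("nan")
    dsum = den[ok].sum()
    if dsum == 0:
        return float("nan")
    return float(num[ok].sum() / dsum)
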