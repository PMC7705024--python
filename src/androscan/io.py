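"""Readers and writers for the formats the pipeline touches.

VCF (via cyvcf2, GT subfield only), GFF3 (via gffutils), and the package's
own tab-separated tables: the sample manifest, the per-window statistics
table, the candidate-gene table and the BED-like depth table.  External
files use the conventions of their formats (VCF/GFF3 1-based inclusive);
everything returned by this module is 0-based half-open.

Floating-point columns in tables written here are serialized at six
significant digits, stated in the file header, so a write/read round trip
is exact for values already at that precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    DepthTable,
    FormatError,
    GeneAnnotation,
    SexManifest,
    ValidationError,
    VariantTable,
)

FLOAT_FMT = "%.6g"
_PRECISION_NOTE = "## float_precision=6 significant digits; NA = undefined"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, min_call_fraction: float = 0.8):
    """Load biallelic SNPs from a VCF into a :class:`VariantTable`.

    Multiallelic sites, indels and symbolic alleles are dropped and counted;
    sites whose fraction of called genotypes falls below ``min_call_fraction``
    are dropped as well.  Genotypes are reduced to alt-allele dosage.

    Returns
    -------
    (VariantTable, dict)
        The retained sites and a filter log with keys ``multiallelic``,
        ``indel``, ``symbolic`` and ``low_call``.
    """
    from cyvcf2 import VCF

    if not 0.0 <= min_call_fraction <= 1.0:
        raise ValidationError("min_call_fraction must be in [0, 1]")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises plain Exception on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc

    samples = list(vcf.samples)
    header_lines = vcf.raw_header.count("\n")
    log = {"multiallelic": 0, "indel": 0, "symbolic": 0, "low_call": 0}
    contigs, pos, ref, alt, dosages = [], [], [], [], []
    last_pos: dict[str, int] = {}

    for i, v in enumerate(vcf):
        line_no = header_lines + i + 1
        if v.CHROM in last_pos and v.POS <= last_pos[v.CHROM]:
            raise FormatError(
                f"unsorted VCF: {v.CHROM}:{v.POS} at line {line_no} "
                f"not after position {last_pos[v.CHROM]}"
            )
        last_pos[v.CHROM] = v.POS
        if len(v.ALT) != 1:
            log["multiallelic"] += 1
            continue
        a = v.ALT[0]
        if a.startswith("<") or "[" in a or "]" in a:
            log["symbolic"] += 1
            continue
        if len(v.REF) != 1 or len(a) != 1 or not v.is_snp:
            log["indel"] += 1
            continue
        gt = np.asarray(v.gt_types)  # gts012: 0/1/2 dosage, 3 = missing
        dos = np.where(gt == 3, MISSING, gt).astype(np.int8)
        called = float((dos != MISSING).mean()) if dos.size else 0.0
        if called < min_call_fraction:
            log["low_call"] += 1
            continue
        contigs.append(v.CHROM)
        pos.append(v.POS - 1)  # to 0-based
        ref.append(v.REF)
        alt.append(a)
        dosages.append(dos)

    vcf.close()
    n = len(pos)
    table = VariantTable(
        np.array(contigs, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        np.array(dosages, dtype=np.int8).reshape(n, len(samples)),
        samples,
    )
    return table, log


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> GeneAnnotation:
    """Read gene features (type ``gene``) from a GFF3 file.

    Only gene-type features are kept; each must carry an ``ID`` attribute.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    import gffutils

    # pre-scan so errors can name the offending line
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{line_no}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: non-integer coordinates") from exc
            if end < start:
                raise ValidationError(f"{path}:{line_no}: gene end < start")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise FormatError(f"{path}:{line_no}: gene feature without ID attribute")

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for f in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": f.attributes["ID"][0],
                "contig": f.seqid,
                "start": f.start - 1,  # to 0-based half-open
                "end": f.end,
                "strand": f.strand if f.strand in "+-" else ".",
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    """Read a '#'-headed TSV; the last comment line is the column header."""
    header = None
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line[1:].rstrip("\n").split("\t")
                continue
            if line.strip():
                body.append(line)
    if header is None:
        raise FormatError(f"{path}: missing '#'-prefixed header line")
    if not body:
        return pd.DataFrame(columns=header)
    df = pd.read_csv(
        _io.StringIO("".join(body)), sep="\t", names=header, na_values=["NA"]
    )
    return df


def _write_tsv(df: pd.DataFrame, path, float_cols) -> None:
    with open(path, "w") as fh:
        fh.write(_PRECISION_NOTE + "\n")
        fh.write("#" + "\t".join(df.columns) + "\n")
        out = df.copy()
        for c in float_cols:
            out[c] = [
                "NA" if pd.isna(v) else FLOAT_FMT % v for v in out[c]
            ]
        out.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")


def read_manifest(path) -> SexManifest:
    """Read a sample manifest TSV (sample_id, sex, population)."""
    df = _read_tsv(path)
    return SexManifest(df[["sample_id", "sex", "population"]])


def write_manifest(manifest: SexManifest, path) -> None:
    _write_tsv(manifest.table, path, float_cols=())


WINDOW_STAT_COLUMNS = [
    "contig", "start", "end", "n_sites",
    "pi_male", "pi_herm", "fst", "rod", "rank_p",
]
_WINDOW_FLOATS = ["pi_male", "pi_herm", "fst", "rod", "rank_p"]


def write_window_stats(table: pd.DataFrame, path) -> None:
    """Write a WindowStatTable TSV (0-based half-open coordinates)."""
    missing = set(WINDOW_STAT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"window table missing columns {sorted(missing)}")
    _write_tsv(table[WINDOW_STAT_COLUMNS], path, _WINDOW_FLOATS)


def read_window_stats(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(WINDOW_STAT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for c in ("start", "end", "n_sites"):
        df[c] = df[c].astype(np.int64)
    for c in _WINDOW_FLOATS:
        df[c] = df[c].astype(float)
    return df[WINDOW_STAT_COLUMNS]


CANDIDATE_COLUMNS = [
    "gene_id", "contig", "max_window_fst", "best_rank_p",
    "mean_rod", "hemizygous_flag", "expression_class",
]
_CANDIDATE_FLOATS = ["max_window_fst", "best_rank_p", "mean_rod"]


def write_candidates(table: pd.DataFrame, path) -> None:
    missing = set(CANDIDATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"candidate table missing columns {sorted(missing)}")
    _write_tsv(table[CANDIDATE_COLUMNS], path, _CANDIDATE_FLOATS)


def read_candidates(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(CANDIDATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for c in _CANDIDATE_FLOATS:
        df[c] = df[c].astype(float)
    df["hemizygous_flag"] = df["hemizygous_flag"].astype(bool)
    return df[CANDIDATE_COLUMNS]


def read_depth_table(path) -> DepthTable:
    """Read a BED-like depth TSV: contig, start, end, one column per sample."""
    df = _read_tsv(path)
    fixed = ["contig", "start", "end"]
    if df.columns[:3].tolist() != fixed:
        raise FormatError(f"{path}: first columns must be {fixed}")
    samples = df.columns[3:].tolist()
    if not samples:
        raise FormatError(f"{path}: no sample columns")
    return DepthTable(
        df["contig"].to_numpy(dtype=object),
        df["start"].to_numpy(dtype=np.int64),
        df["end"].to_numpy(dtype=np.int64),
        df[samples].to_numpy(dtype=float),
        samples,
    )


def write_depth_table(table: DepthTable, path) -> None:
    df = pd.DataFrame(
        {"contig": table.contig, "start": table.start, "end": table.end}
    )
    for j, s in enumerate(table.samples):
        df[s] = table.depth[:, j]
    _write_tsv(df, path, float_cols=table.samples)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write candidate regions as 3+ column BED (0-based half-open)."""
    cols = [c for c in ("contig", "start", "end") if c in regions.columns]
    if len(cols) != 3:
        raise ValidationError("regions need contig/start/end columns")
    extra = [c for c in regions.columns if c not in cols]
    regions[cols + extra].to_csv(path, sep="\t", header=False, index=False)
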