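"""Synthetic cohorts with the statistical structure the scan assumes.

The genotype generator draws neutral allele frequencies under the
Balding–Nichols island model: each deme's frequency is Beta-distributed
around an ancestral frequency with variance set by the target F_ST, and
diploid dosages are binomial draws from the deme frequency.  A planted
sex-linked region carries, with probability ``sex_divergence`` per site, a
fixed male/hermaphrodite difference; male genotypes there are encoded as
homozygous dosage 2, the way a diploid caller represents a hemizygous
single-copy allele.  Depth, expression, offspring and read simulators
emulate the remaining pipeline inputs.

Defaults mirror the study cohort: 55 diploid samples in 5 demes
(29 males, 26 hermaphrodites), a 24-kb sex region on scaffold 25, ~20
SNPs/kb, ~25x depth, and an 18-sample expression design (4 male flowers,
6 hermaphroditic flowers, 8 fruits).  All generators are reproducible
given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .types import DepthTable, GeneAnnotation, SexManifest, ValidationError, VariantTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort (defaults = study conditions)."""

    n_demes: int = 5
    samples_per_deme: tuple[int, ...] = (11, 11, 11, 11, 11)
    n_male: int = 29
    n_herm: int = 26
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"scaffold_25": 300_000, "scaffold_7": 200_000}
    )
    target_fst: float = 0.2
    snp_per_kb: float = 20.0
    sex_region_contig: str = "scaffold_25"
    sex_region_start: int = 120_000
    sex_region_length: int = 24_000
    sex_divergence: float = 0.8      # per-site probability of a fixed difference
    depth_mean: float = 25.0
    depth_cv2: float = 0.04          # squared coefficient of variation per window
    depth_window: int = 1_000
    n_genes: int = 2_000
    expression_groups: dict[str, int] = field(
        default_factory=lambda: {"male_flower": 4, "herm_flower": 6, "fruit": 8}
    )
    n_planted_genes: int = 5
    planted_fold: float = 10.0
    planted_group: str = "male_flower"
    expression_dispersion: float = 0.1
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.samples_per_deme) != self.n_demes:
            raise ValidationError("samples_per_deme must have n_demes entries")
        if sum(self.samples_per_deme) != self.n_male + self.n_herm:
            raise ValidationError("deme sizes must sum to n_male + n_herm")
        if not 0.0 < self.target_fst < 1.0:
            raise ValidationError("target_fst must be in (0, 1)")
        if not 0.0 <= self.sex_divergence <= 1.0:
            raise ValidationError("sex_divergence must be in [0, 1]")
        if self.sex_region_contig not in self.contig_lengths:
            raise ValidationError("sex region contig not among contigs")
        end = self.sex_region_start + self.sex_region_length
        if end > self.contig_lengths[self.sex_region_contig]:
            raise ValidationError("sex region extends past its contig")

    @property
    def n_samples(self) -> int:
        return self.n_male + self.n_herm

    @property
    def sex_region(self) -> tuple[str, int, int]:
        return (
            self.sex_region_contig,
            self.sex_region_start,
            self.sex_region_start + self.sex_region_length,
        )


def _manifest(config: SimConfig) -> SexManifest:
    """Deterministic sample sheet: sexes interleaved so demes stay mixed."""
    n = config.n_samples
    sexes = ["male" if i % 2 == 0 else "hermaphrodite" for i in range(n)]
    n_m = sexes.count("male")
    i = n - 1
    while n_m != config.n_male:  # patch the tail to hit the exact split
        want = "male" if n_m < config.n_male else "hermaphrodite"
        if sexes[i] != want:
            n_m += 1 if want == "male" else -1
            sexes[i] = want
        i -= 1
    demes = np.repeat(
        [f"pop{k + 1}" for k in range(config.n_demes)], config.samples_per_deme
    )
    return SexManifest(
        pd.DataFrame(
            {
                "sample_id": [f"T{i + 1:03d}" for i in range(n)],
                "sex": sexes,
                "population": demes,
            }
        )
    )


def balding_nichols_freqs(rng, n_sites: int, n_demes: int, fst: float):
    """Ancestral and per-deme allele frequencies under the island model."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    shape = (1.0 - fst) / fst
    a = p * shape
    b = (1.0 - p) * shape
    deme_p = rng.beta(a[:, None], b[:, None], size=(n_sites, n_demes))
    return p, deme_p


def simulate_genotypes(config: SimConfig | None = None, seed: int | None = None):
    """Draw the cohort's VariantTable and SexManifest.

    Returns (variants, manifest).  Neutral sites follow Balding–Nichols
    deme frequencies; inside the sex region each site is, with probability
    ``sex_divergence``, fixed different between the sexes (males dosage 2,
    hermaphrodites dosage 0).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    manifest = _manifest(config)
    deme_of = np.repeat(np.arange(config.n_demes), config.samples_per_deme)
    is_male = (manifest.table["sex"] == "male").to_numpy()

    all_contig, all_pos, all_ref, all_alt, all_dos = [], [], [], [], []
    region_contig, region_start, region_end = config.sex_region
    for contig, length in config.contig_lengths.items():
        n_sites = int(round(length / 1000.0 * config.snp_per_kb))
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        _, deme_p = balding_nichols_freqs(rng, n_sites, config.n_demes, config.target_fst)
        probs = deme_p[:, deme_of]  # n_sites x n_samples
        dos = rng.binomial(2, probs).astype(np.int8)
        if contig == region_contig:
            in_region = (pos >= region_start) & (pos < region_end)
            divergent = in_region & (rng.random(n_sites) < config.sex_divergence)
            dos[np.ix_(divergent, is_male)] = 2   # hemizygous called as hom-alt
            dos[np.ix_(divergent, ~is_male)] = 0
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        all_contig.append(np.full(n_sites, contig, dtype=object))
        all_pos.append(pos)
        all_ref.append(_BASES[ref_idx].astype(object))
        all_alt.append(_BASES[alt_idx].astype(object))
        all_dos.append(dos)

    variants = VariantTable(
        np.concatenate(all_contig),
        np.concatenate(all_pos),
        np.concatenate(all_ref),
        np.concatenate(all_alt),
        np.concatenate(all_dos, axis=0),
        manifest.samples,
    )
    return variants, manifest


def simulate_depth(config: SimConfig | None = None,
                   manifest: SexManifest | None = None,
                   seed: int | None = None) -> DepthTable:
    """Windowed per-sample read depth with the planted hemizygous region.

    Depth per window is gamma-distributed around a per-sample mean
    (squared CV = ``depth_cv2``; the zero-overdispersion limit is exactly
    the mean).  Inside the sex region hermaphrodite depth is scaled to 0
    and male depth to 0.5 (single copy).
    """
    config = config or SimConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1_000_003)
    manifest = manifest or _manifest(config)
    n = config.n_samples
    sample_mean = config.depth_mean * rng.uniform(0.7, 1.3, size=n)

    contigs, starts, ends = [], [], []
    for contig, length in config.contig_lengths.items():
        s = np.arange(0, length, config.depth_window)
        e = np.minimum(s + config.depth_window, length)
        contigs.append(np.full(len(s), contig, dtype=object))
        starts.append(s)
        ends.append(e)
    contig_arr = np.concatenate(contigs)
    start_arr = np.concatenate(starts)
    end_arr = np.concatenate(ends)
    n_win = len(start_arr)

    if config.depth_cv2 > 0:
        noise = rng.gamma(1.0 / config.depth_cv2, config.depth_cv2, size=(n_win, n))
    else:
        noise = np.ones((n_win, n))
    depth = sample_mean[None, :] * noise

    region_contig, region_start, region_end = config.sex_region
    in_region = (
        (contig_arr == region_contig)
        & (start_arr < region_end)
        & (end_arr > region_start)
    )
    is_male = (manifest.table["sex"] == "male").to_numpy()
    depth[np.ix_(in_region, is_male)] *= 0.5
    depth[np.ix_(in_region, ~is_male)] = 0.0
    return DepthTable(contig_arr, start_arr, end_arr, depth, manifest.samples)


def simulate_annotation(config: SimConfig | None = None,
                        gene_length: int = 2_000,
                        gene_spacing: int = 3_000) -> GeneAnnotation:
    """Deterministic gene models tiling every contig (for candidate calling)."""
    config = config or SimConfig()
    rows = []
    i = 0
    for contig, length in config.contig_lengths.items():
        for start in range(500, length - gene_length, gene_spacing):
            i += 1
            rows.append(
                {
                    "gene_id": f"Tsin{i:05d}",
                    "contig": contig,
                    "start": start,
                    "end": start + gene_length,
                    "strand": "+" if i % 2 else "-",
                }
            )
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_expression(config: SimConfig | None = None, seed: int | None = None):
    """Counts matrix + tissue design (4 MF / 6 HF / 8 fruit by default).

    Gene baselines are log-normal; counts are gamma-Poisson (negative
    binomial) around baseline x library factor; the first
    ``n_planted_genes`` genes are multiplied by ``planted_fold`` in
    ``planted_group``.  Returns (ExpressionMatrix, planted gene ids).
    """
    config = config or SimConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2_000_003)
    genes = [f"Tsin{i + 1:05d}" for i in range(config.n_genes)]
    samples, labels = [], []
    for group, count in config.expression_groups.items():
        for j in range(count):
            samples.append(f"{group}_{j + 1}")
            labels.append(group)
    lengths = pd.Series(
        rng.integers(500, 5_000, size=config.n_genes), index=genes, name="length"
    )
    baseline = rng.lognormal(mean=4.0, sigma=1.2, size=config.n_genes)
    size_factor = rng.uniform(0.8, 1.2, size=len(samples))
    mean = baseline[:, None] * size_factor[None, :] * (lengths.to_numpy()[:, None] / 1_000.0)

    planted = genes[: config.n_planted_genes]
    group_mask = np.array([lab == config.planted_group for lab in labels])
    mean[: config.n_planted_genes, group_mask] *= config.planted_fold

    disp = config.expression_dispersion
    if disp > 0:
        lam = rng.gamma(1.0 / disp, disp * mean)
    else:
        lam = mean
    counts = rng.poisson(lam)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        lengths,
        pd.Series(labels, index=samples, name="group"),
    )
    return matrix, planted


def simulate_offspring(n: int, true_ratio: float = 0.5, seed: int = 0):
    """Offspring sex counts (n_male, n_herm) from binomial sex draws."""
    if not 0.0 <= true_ratio <= 1.0:
        raise ValidationError("true_ratio must be a probability")
    if n < 0:
        raise ValidationError("n must be non-negative")
    rng = np.random.default_rng(seed)
    n_male = int(rng.binomial(n, true_ratio))
    return n_male, n - n_male


def simulate_reads(genome_length: int, coverage: float, error_rate: float = 0.0,
                   read_length: int = 100, seed: int = 0):
    """Uniform shotgun reads from a random genome; returns (genome, reads)."""
    if genome_length <= 0 or read_length <= 0:
        raise ValidationError("lengths must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValidationError("error_rate must be in [0, 1)")
    if coverage < 0:
        raise ValidationError("coverage must be non-negative")
    rng = np.random.default_rng(seed)
    genome_arr = rng.integers(0, 4, size=genome_length)
    genome = "".join(_BASES[genome_arr])
    n_reads = int(round(coverage * genome_length / read_length))
    reads = []
    for start in rng.integers(0, genome_length - read_length + 1, size=n_reads):
        read = genome_arr[start:start + read_length].copy()
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            read[err] = (read[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        reads.append("".join(_BASES[read]))
    return genome, reads


# ---------------------------------------------------------------------------
# file export
# ---------------------------------------------------------------------------

def _write_vcf(variants: VariantTable, path) -> None:
    """Minimal VCF 4.2 serialization of a simulated variant table."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(variants.contig):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.samples) + "\n"
        )
        gt_of = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(variants.n_sites):
            gts = "\t".join(gt_of[int(d)] for d in variants.dosages[i])
            fh.write(
                f"{variants.contig[i]}\t{variants.pos[i] + 1}\t.\t"
                f"{variants.ref[i]}\t{variants.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dataset(outdir, config: SimConfig | None = None, seed: int | None = None
                  ) -> dict[str, str]:
    """Simulate and export a full input set (VCF, manifest, depth, counts,
    annotation, reads) plus a JSON metadata sidecar recording config + seed."""
    from . import io as _aio

    config = config or SimConfig()
    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    variants, manifest = simulate_genotypes(config, seed)
    depth = simulate_depth(config, manifest, seed)
    annotation = simulate_annotation(config)
    matrix, planted = simulate_expression(config, seed)
    _, reads = simulate_reads(100_000, 5.0, 0.0, 100, seed)

    paths = {
        "vcf": str(outdir / "variants.vcf"),
        "manifest": str(outdir / "samples.tsv"),
        "depth": str(outdir / "depth.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "gff3": str(outdir / "genes.gff3"),
        "reads": str(outdir / "reads.fastq"),
        "metadata": str(outdir / "metadata.json"),
    }
    _write_vcf(variants, paths["vcf"])
    _aio.write_manifest(manifest, paths["manifest"])
    _aio.write_depth_table(depth, paths["depth"])

    counts = matrix.counts.copy()
    counts.insert(0, "length", matrix.gene_lengths)
    counts.index.name = "gene_id"
    counts.to_csv(paths["counts"], sep="\t")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.table.itertuples(index=False):
            fh.write(
                f"{g.contig}\tandroscan_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    with open(paths["reads"], "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
    with open(paths["metadata"], "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(config), "seed": seed,
             "planted_genes": planted},
            fh, indent=2, default=str,
        )
    return paths
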