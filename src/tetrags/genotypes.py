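"""Allele-depth and allele-frequency genotype matrices and marker filters.

Genotypes are never called: the per-sample alternative-read fraction at a
locus (a value in [0, 1]) is used directly as a continuous dosage proxy, so
tetraploid allele dosage is captured without deep sequencing.  A cell is
missing exactly when its total read depth is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlleleDepthMatrix",
    "AlleleFrequencyMatrix",
    "FilterConfig",
    "FilterReport",
    "read_vcf_allele_depths",
    "write_vcf_allele_depths",
    "compute_allele_frequencies",
    "allele_frequencies_from_dosages",
    "filter_markers",
    "stringent_marker_set",
    "random_marker_set",
    "random_marker_sets",
    "subsample_individuals",
]


@dataclass
class AlleleDepthMatrix:
    """Per sample x locus reference/alternative read counts (raw GBS signal)."""

    sample_ids: list[str]
    locus_ids: list[str]          # "chrom:pos:ref:alt"
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self):
        shape = (len(self.sample_ids), len(self.locus_ids))
        if self.ref_depth.shape != shape or self.alt_depth.shape != shape:
            raise ValueError("depth matrices must be samples x loci")
        if self.ref_depth.min() < 0 or self.alt_depth.min() < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx, cols = self.sample_ids, self.locus_ids
        return (pd.DataFrame(self.ref_depth, index=idx, columns=cols),
                pd.DataFrame(self.alt_depth, index=idx, columns=cols))


@dataclass
class AlleleFrequencyMatrix:
    """Per-cell alternative-allele read fraction; NaN marks missing cells.

    The per-cell total depth is retained so coverage-based marker filters can
    be applied after the frequencies are computed.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    af: np.ndarray                # float, NaN = missing
    depth: np.ndarray             # total read depth per cell

    def __post_init__(self):
        shape = (len(self.sample_ids), len(self.locus_ids))
        if self.af.shape != shape or self.depth.shape != shape:
            raise ValueError("matrices must be samples x loci")
        finite = self.af[~np.isnan(self.af)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.af)

    def take_loci(self, idx) -> "AlleleFrequencyMatrix":
        idx = np.asarray(idx)
        return AlleleFrequencyMatrix(
            list(self.sample_ids), [self.locus_ids[i] for i in idx],
            self.af[:, idx], self.depth[:, idx])

    def take_samples(self, idx) -> "AlleleFrequencyMatrix":
        idx = np.asarray(idx)
        return AlleleFrequencyMatrix(
            [self.sample_ids[i] for i in idx], list(self.locus_ids),
            self.af[idx], self.depth[idx])

    def select_samples(self, ids: list[str]) -> "AlleleFrequencyMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([pos[s] for s in ids])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.af, index=self.sample_ids, columns=self.locus_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


@dataclass
class FilterConfig:
    """Marker/sample filter thresholds.

    Defaults: locus mean coverage within [5, 60],
    mean allele frequency strictly inside (0.01, 0.99), at most 50% missing
    cells per marker, and samples with more than 70% missing removed.
    """

    maf_min: float = 0.01
    coverage_min: float = 5.0
    coverage_max: float = 60.0
    marker_missing_max: float = 0.50
    sample_missing_max: float = 0.70

    def __post_init__(self):
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.coverage_min > self.coverage_max:
            raise ValueError("coverage_min must be <= coverage_max")
        for name in ("marker_missing_max", "sample_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-rule removal tallies, in application order."""

    n_input_samples: int
    n_input_loci: int
    steps: list = field(default_factory=list)   # dicts: rule, axis, removed
    n_output_samples: int = 0
    n_output_loci: int = 0

    def add(self, rule: str, axis: str, removed: int) -> None:
        self.steps.append({"rule": rule, "axis": axis, "removed": int(removed)})

    def removed(self, axis: str) -> int:
        return sum(s["removed"] for s in self.steps if s["axis"] == axis)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def read_vcf_allele_depths(path, on_multiallelic: str = "error") -> AlleleDepthMatrix:
    """Read per-sample AD from a VCF with biallelic SNP records.

    ``on_multiallelic`` is "error" or "skip".  Missing AD entries become
    depth (0, 0).
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    locus_ids, refs, alts = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at {variant.CHROM}:{variant.POS}")
            continue
        ad = variant.format("AD")
        if ad is None:
            r = np.zeros(len(samples), dtype=np.int64)
            a = np.zeros(len(samples), dtype=np.int64)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0       # htslib encodes missing as large negatives
            if ad.shape[1] < 2:  # every sample missing: width-1 fill array
                ad = np.zeros((ad.shape[0], 2), dtype=np.int64)
            r, a = ad[:, 0], ad[:, 1]
        locus_ids.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}")
        refs.append(r)
        alts.append(a)
    vcf.close()
    if not locus_ids:
        raise ValueError(f"no usable biallelic records in {path}")
    return AlleleDepthMatrix(samples, locus_ids,
                             np.column_stack(refs), np.column_stack(alts))


def write_vcf_allele_depths(depths: AlleleDepthMatrix, path) -> None:
    """Write a minimal VCFv4.2 with a single FORMAT field AD ("ref,alt").

    Cells with zero total depth are written as the missing value ".".
    """
    parsed = [lid.split(":") for lid in depths.locus_ids]
    if any(len(p) != 4 for p in parsed):
        raise ValueError("locus ids must look like 'chrom:pos:ref:alt'")
    chroms = list(dict.fromkeys(p[0] for p in parsed))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tetrags\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(depths.sample_ids) + "\n")
        for k, (chrom, pos, ref, alt) in enumerate(parsed):
            cells = []
            for i in range(len(depths.sample_ids)):
                r, a = depths.ref_depth[i, k], depths.alt_depth[i, k]
                cells.append("." if r + a == 0 else f"{r},{a}")
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tAD\t"
                     + "\t".join(cells) + "\n")


def compute_allele_frequencies(depths: AlleleDepthMatrix) -> AlleleFrequencyMatrix:
    """AF = alt / (ref + alt); missing (NaN) where the total depth is zero."""
    total = depths.total_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, depths.alt_depth / np.maximum(total, 1), np.nan)
    return AlleleFrequencyMatrix(list(depths.sample_ids), list(depths.locus_ids),
                                 af.astype(float), total.astype(np.int64))


def allele_frequencies_from_dosages(dosages: np.ndarray, sample_ids=None,
                                    locus_ids=None, ploidy: int = 4,
                                    depth: int = 12,
                                    dtype=np.float64) -> AlleleFrequencyMatrix:
    """Noise-free AF matrix (dosage/ploidy) — handy for simulation baselines.

    ``dtype`` may be lowered to float32 for very large marker panels; the
    relationship-matrix cross-product then runs in single precision.
    """
    n, L = dosages.shape
    sample_ids = sample_ids or [f"S{i:05d}" for i in range(n)]
    locus_ids = locus_ids or [f"1:{k + 1}:A:C" for k in range(L)]
    af = dosages.astype(dtype) / ploidy
    return AlleleFrequencyMatrix(list(sample_ids), list(locus_ids), af,
                                 np.full((n, L), depth, dtype=np.int8 if depth < 128 else np.int64))


def _locus_missing_fraction(af: AlleleFrequencyMatrix) -> np.ndarray:
    return np.isnan(af.af).mean(axis=0)


def filter_markers(af: AlleleFrequencyMatrix,
                   config: FilterConfig | None = None
                   ) -> tuple[AlleleFrequencyMatrix, FilterReport]:
    """Apply the coverage / MAF / missingness filters, in that order.

    Rules, applied sequentially: (1) locus mean depth (over non-missing
    cells) within [coverage_min, coverage_max]; (2) locus mean allele
    frequency strictly inside (maf_min, 1 - maf_min) — skipped entirely when
    maf_min = 0; (3) locus missing fraction <= marker_missing_max;
    (4) sample missing fraction, computed on the surviving loci,
    <= sample_missing_max.  Raises if nothing survives.
    """
    config = config or FilterConfig()
    report = FilterReport(af.n_samples, af.n_loci)
    current = af

    # 1. locus mean coverage over non-missing cells
    miss = current.missing
    n_obs = (~miss).sum(axis=0)
    depth_sum = np.where(miss, 0, current.depth).sum(axis=0)
    mean_depth = np.where(n_obs > 0, depth_sum / np.maximum(n_obs, 1), 0.0)
    keep = (mean_depth >= config.coverage_min) & (mean_depth <= config.coverage_max)
    report.add("coverage", "loci", (~keep).sum())
    current = current.take_loci(np.flatnonzero(keep))

    # 2. mean-AF (MAF) rule, strict bounds as configured
    if config.maf_min > 0:
        with np.errstate(invalid="ignore"):
            mean_af = np.nanmean(current.af, axis=0)
        keep = (mean_af > config.maf_min) & (mean_af < 1.0 - config.maf_min)
        keep &= ~np.isnan(mean_af)
    else:
        keep = np.ones(current.n_loci, dtype=bool)
    report.add("maf", "loci", (~keep).sum())
    current = current.take_loci(np.flatnonzero(keep))

    # 3. marker missingness
    keep = _locus_missing_fraction(current) <= config.marker_missing_max
    report.add("marker_missingness", "loci", (~keep).sum())
    current = current.take_loci(np.flatnonzero(keep))

    # 4. sample missingness on the surviving loci
    if current.n_loci > 0:
        sample_miss = current.missing.mean(axis=1)
    else:
        sample_miss = np.zeros(current.n_samples)
    keep_s = sample_miss <= config.sample_missing_max
    report.add("sample_missingness", "samples", (~keep_s).sum())
    current = current.take_samples(np.flatnonzero(keep_s))

    report.n_output_samples = current.n_samples
    report.n_output_loci = current.n_loci
    if current.n_loci == 0 or current.n_samples == 0:
        raise ValueError("no markers or samples survive filtering; "
                         f"report: {report.to_json()}")
    return current, report


def stringent_marker_set(af: AlleleFrequencyMatrix,
                         marker_missing_max: float = 0.01,
                         sample_missing_max: float = 0.10
                         ) -> tuple[AlleleFrequencyMatrix, FilterReport]:
    """High-completeness marker set: <=1% missing per locus, then samples
    with more than 10% missing markers removed."""
    report = FilterReport(af.n_samples, af.n_loci)
    keep = _locus_missing_fraction(af) <= marker_missing_max
    report.add("stringent_marker_missingness", "loci", (~keep).sum())
    current = af.take_loci(np.flatnonzero(keep))
    if current.n_loci == 0:
        raise ValueError("no markers survive stringent filtering")
    keep_s = current.missing.mean(axis=1) <= sample_missing_max
    report.add("stringent_sample_missingness", "samples", (~keep_s).sum())
    current = current.take_samples(np.flatnonzero(keep_s))
    report.n_output_samples = current.n_samples
    report.n_output_loci = current.n_loci
    if current.n_samples == 0:
        raise ValueError("no samples survive stringent filtering")
    return current, report


def random_marker_set(af: AlleleFrequencyMatrix, n_markers: int,
                      seed: int) -> AlleleFrequencyMatrix:
    """Uniform random subset of markers, without replacement."""
    if n_markers > af.n_loci:
        raise ValueError(f"n_markers={n_markers} exceeds {af.n_loci} loci")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(af.n_loci, size=n_markers, replace=False))
    return af.take_loci(idx)


def random_marker_sets(af: AlleleFrequencyMatrix, n_markers: int,
                       n_sets: int = 10, seed: int = 0) -> list[AlleleFrequencyMatrix]:
    """The repeated-sampling facility: n_sets independent random marker sets."""
    ss = np.random.SeedSequence(seed)
    return [random_marker_set(af, n_markers, int(c.generate_state(1)[0] % (2**31)))
            for c in ss.spawn(n_sets)]


def subsample_individuals(af: AlleleFrequencyMatrix, n: int,
                          seed: int) -> AlleleFrequencyMatrix:
    """Uniform random subset of samples, without replacement."""
    if n > af.n_samples:
        raise ValueError(f"n={n} exceeds {af.n_samples} samples")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(af.n_samples, size=n, replace=False))
    return af.take_samples(idx)
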