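"""Synthetic structured-population genotypes under the Balding-Nichols
model, with VCF/PLINK writers for I/O round-trip testing and a
Hudson-style differentiation estimator to close the recovery loop.

Each SNP draws an ancestral frequency uniformly from a configurable
range; each population perturbs it with a Beta distribution whose
dispersion is set by the differentiation parameter F: frequencies are
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so the across-population variance is
``p(1-p)F``. Genotypes are binomial draws at the population frequency.
SNPs are simulated independently (no linkage), matching the pruned,
quasi-independent input the classifier expects.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import ParameterError
from .genotype_io import GenotypeMatrix, SampleLabels

__all__ = [
    "SimulationSpec",
    "SimulatedCohort",
    "FstEstimate",
    "simulate_cohort",
    "write_vcf",
    "write_labels",
    "write_bed",
    "estimate_fst",
]


@dataclass
class SimulationSpec:
    n_populations: int = 4
    samples_per_population: int = 50
    n_snps: int = 1000
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    ploidy: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.samples_per_population, self.n_snps) < 1:
            raise ParameterError("counts must be positive")
        if not 0 < self.fst < 1:
            raise ParameterError("fst must lie strictly inside (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ParameterError("ancestral_maf_range must sit within (0, 0.5]")
        if self.ploidy < 1:
            raise ParameterError("ploidy must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.samples_per_population


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    true_labels: SampleLabels
    per_population_allele_frequencies: np.ndarray  # populations x variants
    spec: SimulationSpec = field(repr=False, default=None)

    @property
    def label_array(self) -> np.ndarray:
        return self.true_labels.for_samples(self.genotypes.sample_ids)


def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Draw a multi-population biallelic SNP cohort; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=spec.n_snps)
    F = spec.fst
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    pop_freqs = rng.beta(
        a[None, :], b[None, :], size=(spec.n_populations, spec.n_snps)
    )

    n = spec.n_samples
    dense = np.empty((n, spec.n_snps), dtype=np.float64)
    sample_ids = []
    labels = {}
    for pop in range(spec.n_populations):
        rows = slice(
            pop * spec.samples_per_population,
            (pop + 1) * spec.samples_per_population,
        )
        dense[rows] = rng.binomial(
            spec.ploidy,
            pop_freqs[pop][None, :],
            size=(spec.samples_per_population, spec.n_snps),
        )
        for s in range(spec.samples_per_population):
            sid = f"pop{pop}_s{s:03d}"
            sample_ids.append(sid)
            labels[sid] = f"pop{pop}"

    if spec.missing_rate > 0:
        mask = rng.random((n, spec.n_snps)) < spec.missing_rate
        dense[mask] = 0.0
    else:
        mask = np.zeros((n, spec.n_snps), dtype=bool)

    variant_ids = [f"1:{100 * (j + 1)}:A:T" for j in range(spec.n_snps)]
    G = GenotypeMatrix(
        dosages=sparse.csr_matrix(dense),
        missing_mask=sparse.csr_matrix(mask),
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        ploidy=spec.ploidy,
    )
    return SimulatedCohort(
        genotypes=G,
        true_labels=SampleLabels(mapping=labels),
        per_population_allele_frequencies=pop_freqs,
        spec=spec,
    )


def _gt_string(dosage: float, missing: bool, ploidy: int) -> str:
    if ploidy == 1:
        return "." if missing else str(int(dosage))
    if missing:
        return "/".join(["."] * ploidy)
    d = int(dosage)
    return "/".join(["0"] * (ploidy - d) + ["1"] * d)


def write_vcf(cohort: SimulatedCohort, path: str | os.PathLike) -> None:
    """Write the cohort as a VCF 4.2 file (gzip when path ends in .gz)."""
    G = cohort.genotypes
    if G.ploidy > 2:
        raise ParameterError("VCF writer supports haploid or diploid cohorts")
    spec = cohort.spec
    dense = G.to_dense()
    mask = G.missing_mask.toarray()
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dapcy.popsim\n")
        if spec is not None:
            fh.write(
                "##dapcy_simulation="
                f"pops={spec.n_populations},per_pop={spec.samples_per_population},"
                f"snps={spec.n_snps},fst={spec.fst},ploidy={spec.ploidy},"
                f"missing_rate={spec.missing_rate},seed={spec.seed}\n"
            )
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(G.variant_ids):
            chrom, pos, ref, alt = vid.split(":")
            calls = "\t".join(
                _gt_string(dense[i, j], mask[i, j], G.ploidy)
                for i in range(G.n_samples)
            )
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n")


def write_labels(cohort: SimulatedCohort, path: str | os.PathLike) -> None:
    """Two-column sample/population table consumable by --labels."""
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sid in cohort.genotypes.sample_ids:
            fh.write(f"{sid}\t{cohort.true_labels.mapping[sid]}\n")


def write_bed(cohort: SimulatedCohort, prefix: str | os.PathLike) -> None:
    """Write a PLINK 1 BED/BIM/FAM trio (diploid, SNP-major, A1 = ALT).

    Missing calls use the PLINK missing code (01). Provided so format
    round-trips can be exercised without an external converter.
    """
    G = cohort.genotypes
    if G.ploidy != 2:
        raise ParameterError("PLINK BED encodes diploid genotypes only")
    dense = G.to_dense().astype(int)
    mask = G.missing_mask.toarray()
    prefix = str(prefix)

    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fam = cohort.true_labels.mapping.get(sid, "0")
            fh.write(f"{fam} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for vid in G.variant_ids:
            chrom, pos, ref, alt = vid.split(":")
            fh.write(f"{chrom} {chrom}:{pos} 0 {pos} {alt} {ref}\n")

    # dosage -> 2-bit code: 2 -> 00 (hom A1), 1 -> 10 (het), 0 -> 11 (hom A2)
    code_lut = {2: 0b00, 1: 0b10, 0: 0b11}
    n, m = dense.shape
    bytes_per_variant = math.ceil(n / 4)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        for j in range(m):
            buf = bytearray(bytes_per_variant)
            for i in range(n):
                code = 0b01 if mask[i, j] else code_lut[dense[i, j]]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


@dataclass
class FstEstimate:
    per_snp: np.ndarray  # NaN where skipped
    mean: float
    n_skipped: int


def estimate_fst(cohort: SimulatedCohort, from_genotypes: bool = False) -> FstEstimate:
    """Hudson-style differentiation estimate.

    By default the estimator runs on the cohort's per-population allele
    frequencies: for each population pair, numerator ``(p1 - p2)^2`` and
    denominator ``p1(1 - p2) + p2(1 - p1)``, summed over pairs per SNP,
    with the overall mean taken as the ratio of averages across SNPs
    (the stable form). With ``from_genotypes=True`` frequencies are
    re-estimated from observed calls and the finite-sample correction
    ``p(1-p)/(n-1)`` is subtracted from each squared difference.

    Monomorphic SNPs (zero denominator) are skipped and counted.
    """
    n_pops = cohort.per_population_allele_frequencies.shape[0]
    if n_pops < 2:
        raise ParameterError("need at least 2 populations")

    if from_genotypes:
        G = cohort.genotypes
        y = cohort.label_array
        pops = sorted(set(y))
        freqs = np.empty((len(pops), G.n_variants))
        counts = np.empty((len(pops), G.n_variants))
        for pi, pop in enumerate(pops):
            idx = np.flatnonzero(y == pop)
            sub = G.take_samples(idx)
            obs = sub.observed_counts()
            alt = np.asarray(sub.dosages.sum(axis=0)).ravel()
            counts[pi] = obs * G.ploidy  # allele count
            with np.errstate(divide="ignore", invalid="ignore"):
                freqs[pi] = np.where(obs > 0, alt / np.maximum(counts[pi], 1), np.nan)
    else:
        freqs = cohort.per_population_allele_frequencies
        counts = None

    m = freqs.shape[1]
    num = np.zeros(m)
    den = np.zeros(m)
    valid = np.ones(m, dtype=bool)
    for i in range(freqs.shape[0]):
        for j in range(i + 1, freqs.shape[0]):
            p1, p2 = freqs[i], freqs[j]
            pair_valid = np.isfinite(p1) & np.isfinite(p2)
            n_term = (p1 - p2) ** 2
            if counts is not None:
                n1, n2 = counts[i], counts[j]
                pair_valid &= (n1 > 1) & (n2 > 1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    n_term = (
                        n_term
                        - p1 * (1 - p1) / (n1 - 1)
                        - p2 * (1 - p2) / (n2 - 1)
                    )
            d_term = p1 * (1 - p2) + p2 * (1 - p1)
            n_term = np.where(pair_valid, n_term, 0.0)
            d_term = np.where(pair_valid, d_term, 0.0)
            num += n_term
            den += d_term
            valid &= pair_valid

    polymorphic = valid & (den > 0)
    n_skipped = int(m - polymorphic.sum())
    per_snp = np.full(m, np.nan)
    per_snp[polymorphic] = num[polymorphic] / den[polymorphic]
    if polymorphic.sum() == 0:
        raise ParameterError("no polymorphic SNPs available for the estimate")
    mean = float(num[polymorphic].sum() / den[polymorphic].sum())
    return FstEstimate(per_snp=per_snp, mean=mean, n_skipped=n_skipped)
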