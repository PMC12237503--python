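"""Sparse genotype ingestion from VCF and PLINK BED files.

Genotypes are stored as allele-dosage matrices (samples x variants, entry =
count of alternate alleles) in compressed sparse row form, together with a
sparse mask of missing calls. Samples are rows throughout the package.
"""

from __future__ import annotations

import gzip
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import FormatError, InputError, ParameterError, ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SampleLabels",
    "encode_genotype",
    "read_vcf",
    "read_bed",
    "impute_missing",
    "filter_maf",
    "save_matrix",
    "load_matrix",
    "load_labels",
]

_BED_MAGIC = b"\x6c\x1b\x01"


@dataclass
class GenotypeMatrix:
    """Samples x variants sparse dosage matrix with missing-call mask.

    Attributes
    ----------
    dosages : scipy.sparse.csr_matrix
        Alternate-allele counts, shape ``(n_samples, n_variants)``. Entries
        at missing positions are stored as 0 and flagged in ``missing_mask``.
    missing_mask : scipy.sparse.csr_matrix of bool
        True where the genotype call is missing.
    sample_ids : list of str
    variant_ids : list of str
        ``chrom:pos:ref:alt`` identifiers, one per column.
    ploidy : int
        Upper bound for any dosage (1 for haploid, 2 for diploid).
    """

    dosages: sparse.csr_matrix
    missing_mask: sparse.csr_matrix
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = sparse.csr_matrix(self.dosages)
        self.missing_mask = sparse.csr_matrix(self.missing_mask, dtype=bool)
        self.sample_ids = list(self.sample_ids)
        self.variant_ids = list(self.variant_ids)
        if self.dosages.shape != self.missing_mask.shape:
            raise ShapeError("dosages and missing_mask shapes differ")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ShapeError("sample_ids length does not match matrix rows")
        if len(self.variant_ids) != self.dosages.shape[1]:
            raise ShapeError("variant_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise FormatError("duplicate variant identifiers")
        if self.ploidy < 1:
            raise ParameterError("ploidy must be a positive integer")
        if self.dosages.nnz:
            d = self.dosages.data
            if d.min() < 0 or d.max() > self.ploidy:
                raise ParameterError(
                    f"dosages must lie in [0, ploidy={self.ploidy}]"
                )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.nnz)

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Row-subset preserving variant metadata."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            missing_mask=self.missing_mask[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=self.variant_ids,
            ploidy=self.ploidy,
        )

    def take_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Column-subset preserving sample metadata."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx].tocsr(),
            missing_mask=self.missing_mask[:, idx].tocsr(),
            sample_ids=self.sample_ids,
            variant_ids=[self.variant_ids[i] for i in idx],
            ploidy=self.ploidy,
        )

    def observed_counts(self) -> np.ndarray:
        """Number of non-missing calls per variant."""
        missing_per_variant = np.asarray(
            self.missing_mask.sum(axis=0)
        ).ravel()
        return self.n_samples - missing_per_variant

    def alt_frequencies(self) -> np.ndarray:
        """ALT-allele frequency per variant over observed calls.

        Variants with no observed call get frequency NaN.
        """
        alt = np.asarray(self.dosages.sum(axis=0)).ravel()
        obs = self.observed_counts().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(obs > 0, alt / (self.ploidy * np.maximum(obs, 1)), np.nan)
        return p

    def to_dense(self) -> np.ndarray:
        return self.dosages.toarray()


@dataclass
class SampleLabels:
    """Mapping from sample identifier to population label."""

    mapping: dict[str, str]

    @property
    def k(self) -> int:
        return len(set(self.mapping.values()))

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        known = set(genotypes.sample_ids)
        orphans = [s for s in self.mapping if s not in known]
        if orphans:
            raise FormatError(
                f"{len(orphans)} labelled samples absent from genotype matrix "
                f"(first: {orphans[0]!r})"
            )

    def for_samples(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Label array aligned with the given sample order."""
        try:
            return np.array([self.mapping[s] for s in sample_ids], dtype=object)
        except KeyError as exc:  # pragma: no cover - defensive
            raise FormatError(f"sample {exc} has no label") from exc


def encode_genotype(gt_call: str, ploidy: int = 2) -> int | None:
    """Encode a VCF GT string as an ALT-allele count.

    Returns ``None`` when any allele is missing ('.'); raises
    :class:`ParameterError` for allele indices above 1 (multiallelic calls
    are resolved by the caller's policy, never coerced to a dosage).
    """
    alleles = gt_call.replace("|", "/").split("/")
    if len(alleles) != ploidy:
        raise ParameterError(
            f"GT {gt_call!r} has {len(alleles)} alleles, expected ploidy {ploidy}"
        )
    if any(a == "." for a in alleles):
        return None
    counts = [int(a) for a in alleles]
    if any(a > 1 for a in counts):
        raise ParameterError(f"GT {gt_call!r} is not biallelic")
    if any(a < 0 for a in counts):
        return None
    return sum(counts)


def _chunk_to_sparse(dense: np.ndarray, mask: np.ndarray):
    return sparse.csr_matrix(dense), sparse.csr_matrix(mask)


def read_vcf(
    path: str | os.PathLike,
    chunk_size: int = 10_000,
    multiallelic: str = "drop",
    ploidy: int | None = None,
):
    """Read a VCF (plain or gzip/BGZF) into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str
        VCF or VCF.gz with per-sample GT fields.
    chunk_size : int
        Variants accumulated per dense staging block; the result is
        invariant to this value, only peak memory depends on it.
    multiallelic : {'drop', 'split'}
        Drop multi-ALT records (counted, logged) or split each ALT allele
        into its own biallelic pseudo-variant.
    ploidy : int, optional
        Expected call ploidy; inferred from the first call when omitted.

    Returns
    -------
    (GenotypeMatrix, list of sample ids)
    """
    if chunk_size < 1:
        raise ParameterError("chunk_size must be >= 1")
    if multiallelic not in ("drop", "split"):
        raise ParameterError("multiallelic must be 'drop' or 'split'")
    try:
        from cyvcf2 import VCF

        reader = VCF(str(path), gts012=False)
    except Exception as exc:
        raise InputError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(reader.samples)
    if not samples:
        raise InputError(f"VCF {path!r} contains no samples")
    n = len(samples)

    dosage_blocks: list[sparse.csr_matrix] = []
    mask_blocks: list[sparse.csr_matrix] = []
    variant_ids: list[str] = []
    chunk_cols: list[tuple[np.ndarray, np.ndarray, str]] = []
    n_multi_dropped = 0
    inferred_ploidy = ploidy

    def flush() -> None:
        if not chunk_cols:
            return
        dense = np.column_stack([c[0] for c in chunk_cols])
        mask = np.column_stack([c[1] for c in chunk_cols])
        variant_ids.extend(c[2] for c in chunk_cols)
        d, m = _chunk_to_sparse(dense, mask)
        dosage_blocks.append(d)
        mask_blocks.append(m)
        chunk_cols.clear()

    for var in reader:
        gts = var.genotypes
        # cyvcf2 yields [a1, ..., a_ploidy, phased] per sample
        call_len = len(gts[0]) - 1
        if inferred_ploidy is None:
            inferred_ploidy = call_len
        alts = var.ALT
        if len(alts) != 1:
            if multiallelic == "drop":
                n_multi_dropped += 1
                continue
            for alt_idx, alt in enumerate(alts, start=1):
                col = np.zeros(n, dtype=np.float64)
                mcol = np.zeros(n, dtype=bool)
                for i, call in enumerate(gts):
                    alleles = call[:-1]
                    if any(a < 0 for a in alleles):
                        mcol[i] = True
                    else:
                        col[i] = sum(1 for a in alleles if a == alt_idx)
                vid = f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
                chunk_cols.append((col, mcol, vid))
                if len(chunk_cols) >= chunk_size:
                    flush()
            continue
        col = np.zeros(n, dtype=np.float64)
        mcol = np.zeros(n, dtype=bool)
        for i, call in enumerate(gts):
            alleles = call[:-1]
            if any(a < 0 for a in alleles):
                mcol[i] = True
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        vid = f"{var.CHROM}:{var.POS}:{var.REF}:{alts[0]}"
        chunk_cols.append((col, mcol, vid))
        if len(chunk_cols) >= chunk_size:
            flush()
    flush()

    if n_multi_dropped:
        logger.warning("dropped %d multiallelic records", n_multi_dropped)
    if not variant_ids:
        raise InputError(f"VCF {path!r} contains no usable biallelic variants")

    dosages = sparse.hstack(dosage_blocks, format="csr")
    mask = sparse.hstack(mask_blocks, format="csr").astype(bool)
    G = GenotypeMatrix(
        dosages=dosages,
        missing_mask=mask,
        sample_ids=samples,
        variant_ids=variant_ids,
        ploidy=int(inferred_ploidy or 2),
    )
    return G, samples


def read_bed(prefix: str | os.PathLike, chunk_size: int = 10_000):
    """Read a PLINK 1 binary trio ``prefix.bed/.bim/.fam``.

    The BED payload must be SNP-major (third magic byte 0x01). Allele 1
    from the BIM is taken as the counted (ALT) allele, matching PLINK's
    default minor-allele-first convention; variant ids are therefore
    ``chrom:pos:a2:a1``.

    Returns
    -------
    (GenotypeMatrix, list of sample ids)
    """
    prefix = str(prefix)
    paths = {ext: f"{prefix}.{ext}" for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not os.path.exists(p):
            raise InputError(f"missing {ext.upper()} file: {p}")

    with open(paths["fam"]) as fh:
        fam_rows = [line.split() for line in fh if line.strip()]
    sample_ids = [row[1] for row in fam_rows]
    if not sample_ids:
        raise InputError("FAM file lists no samples")

    variant_ids: list[str] = []
    with open(paths["bim"]) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            chrom, _vid, _cm, pos, a1, a2 = f[:6]
            variant_ids.append(f"{chrom}:{pos}:{a2}:{a1}")
    if not variant_ids:
        raise InputError("BIM file lists no variants")

    n, m = len(sample_ids), len(variant_ids)
    bytes_per_variant = math.ceil(n / 4)
    with open(paths["bed"], "rb") as fh:
        magic = fh.read(3)
        if magic[:2] != _BED_MAGIC[:2]:
            raise FormatError(f"{paths['bed']} is not a PLINK BED file")
        if magic[2:3] != b"\x01":
            raise FormatError("only SNP-major BED files are supported")
        payload = fh.read()
    if len(payload) != bytes_per_variant * m:
        raise FormatError(
            f"BED payload has {len(payload)} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample-major within each byte (LSB first)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]  # variants x samples
    # PLINK codes: 00 hom A1, 01 missing, 10 het, 11 hom A2
    dosage_lut = np.array([2, 0, 1, 0], dtype=np.float64)
    dense = dosage_lut[codes].T  # samples x variants
    mask = (codes == 0b01).T

    G = GenotypeMatrix(
        dosages=sparse.csr_matrix(dense),
        missing_mask=sparse.csr_matrix(mask),
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        ploidy=2,
    )
    return G, sample_ids


def impute_missing(G: GenotypeMatrix, strategy: str = "mean") -> GenotypeMatrix:
    """Fill missing calls so downstream SVD sees complete data.

    ``mean`` replaces each missing entry by that variant's mean dosage over
    observed calls; ``zero`` keeps the stored zeros. Variants whose calls
    are all missing are dropped with a warning. Non-missing entries are
    never touched.
    """
    if strategy not in ("mean", "zero"):
        raise ParameterError("strategy must be 'mean' or 'zero'")
    if G.n_missing == 0:
        return G

    if strategy == "zero":
        empty = sparse.csr_matrix(G.dosages.shape, dtype=bool)
        return replace(G, missing_mask=empty)

    obs = G.observed_counts()
    dead = np.flatnonzero(obs == 0)
    if dead.size:
        logger.warning("dropping %d variants with all calls missing", dead.size)
        keep = np.flatnonzero(obs > 0)
        G = G.take_variants(keep)
        obs = obs[keep]

    alt_totals = np.asarray(G.dosages.sum(axis=0)).ravel()
    col_means = alt_totals / obs
    mask_coo = G.missing_mask.tocoo()
    fill = sparse.csr_matrix(
        (col_means[mask_coo.col], (mask_coo.row, mask_coo.col)),
        shape=G.dosages.shape,
    )
    empty = sparse.csr_matrix(G.dosages.shape, dtype=bool)
    return replace(G, dosages=(G.dosages + fill).tocsr(), missing_mask=empty)


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop variants whose minor-allele frequency is below ``min_maf``.

    Frequencies are computed over observed calls only; column order is
    preserved. ``min_maf = 0`` is the identity.
    """
    if not 0 <= min_maf <= 0.5:
        raise ParameterError("min_maf must lie in [0, 0.5]")
    if min_maf == 0:
        return G
    p = G.alt_frequencies()
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), -1.0, maf)  # all-missing columns never pass
    keep = np.flatnonzero(maf >= min_maf)
    return G.take_variants(keep)


_ARCHIVE_VERSION = "dapcy-matrix-1"


def save_matrix(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as an ``.npz`` archive of named arrays."""
    mask = G.missing_mask.tocsr()
    np.savez_compressed(
        path,
        format_version=np.array(_ARCHIVE_VERSION),
        data=G.dosages.data,
        indices=G.dosages.indices,
        indptr=G.dosages.indptr,
        shape=np.array(G.dosages.shape),
        mask_indices=mask.indices,
        mask_indptr=mask.indptr,
        sample_ids=np.array(G.sample_ids, dtype=object),
        variant_ids=np.array(G.variant_ids, dtype=object),
        ploidy=np.array(G.ploidy),
    )


def load_matrix(path: str | os.PathLike) -> GenotypeMatrix:
    try:
        with np.load(path, allow_pickle=True) as z:
            version = str(z["format_version"])
            if version != _ARCHIVE_VERSION:
                raise ModelFormatErrorForMatrix(version)
            shape = tuple(z["shape"])
            dosages = sparse.csr_matrix(
                (z["data"], z["indices"], z["indptr"]), shape=shape
            )
            mask = sparse.csr_matrix(
                (
                    np.ones(len(z["mask_indices"]), dtype=bool),
                    z["mask_indices"],
                    z["mask_indptr"],
                ),
                shape=shape,
            )
            return GenotypeMatrix(
                dosages=dosages,
                missing_mask=mask,
                sample_ids=list(z["sample_ids"]),
                variant_ids=list(z["variant_ids"]),
                ploidy=int(z["ploidy"]),
            )
    except (OSError, KeyError, ValueError) as exc:
        raise InputError(f"cannot load matrix archive {path!r}: {exc}") from exc


class ModelFormatErrorForMatrix(FormatError):
    def __init__(self, version: str) -> None:
        super().__init__(
            f"matrix archive version {version!r} is not supported "
            f"(expected {_ARCHIVE_VERSION!r})"
        )


_HEADER_TOKENS = {"sample", "sample_id", "id", "iid", "name"}


def load_labels(path: str | os.PathLike) -> SampleLabels:
    """Parse a two-column (sample_id, population) delimited text table.

    Tab, comma, and whitespace delimiters are accepted; a header row is
    skipped when its first field looks like a column name.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    mapping: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for delim in ("\t", ","):
                if delim in line:
                    fields = [f.strip() for f in line.split(delim)]
                    break
            else:
                fields = line.split()
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno + 1}: expected two columns, got {len(fields)}"
                )
            if lineno == 0 and fields[0].lower() in _HEADER_TOKENS:
                continue
            mapping[fields[0]] = fields[1]
    if not mapping:
        raise InputError(f"label table {path!r} is empty")
    return SampleLabels(mapping=mapping)
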