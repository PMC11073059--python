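"""Binary incidence data: loading, sufficient statistics, splits, truth counts.

Samples are rows, features are columns.  The model consumes data only
through the sufficient statistics (N, K_N, frequency vector m), but the raw
matrix is kept around for extrapolation experiments: row splits share one
feature-identifier universe so that held-out features remain addressable.

Supported dialects
------------------
tsv
    First column sample identifier, header row of feature identifiers,
    cells in {0, 1}.
coo
    Header line ``sample feature`` followed by one (sample, feature) pair
    per line; dimensions inferred from the pairs.  An optional sidecar
    ``<path>.samples`` (one sample id per line) declares the sample
    universe, including all-zero samples.
vcf
    Standard VCF 4.x with GT fields, gzip-transparent.  A sample has a
    feature iff its genotype carries at least one copy of the corresponding
    ALT allele; missing genotypes (./.) count as absence; multi-allelic
    sites are split so each ALT allele is a distinct feature, identified as
    ``CHROM:POS:REF:ALT``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "BinaryFeatureMatrix",
    "FeatureFrequencies",
    "load_matrix",
    "sufficient_stats",
    "split_rows",
    "true_unseen",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureFrequencies:
    """Sufficient statistics of a binary sample.

    ``n`` samples, ``k`` distinct observed features, and the per-feature
    frequency counts ``m`` (each in 1..n, one entry per observed feature).
    """

    n: int
    k: int
    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.n < 0:
            raise ValidationError(f"n must be >= 0, got {self.n}")
        if self.k != self.m.size:
            raise ValidationError(f"k={self.k} does not match len(m)={self.m.size}")
        if self.k and (self.m.min() < 1 or self.m.max() > self.n):
            raise ValidationError("frequencies must lie in 1..n")

    def to_dict(self) -> dict:
        return {"n": int(self.n), "k": int(self.k), "m": [int(v) for v in self.m]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureFrequencies":
        return cls(n=int(d["n"]), k=int(d["k"]), m=np.asarray(d["m"], dtype=np.int64))


@dataclass
class BinaryFeatureMatrix:
    """N samples x K features incidence matrix with 0/1 entries.

    All-zero columns are dropped at construction (the model only observes
    displayed features); the number dropped is logged and recorded.  The
    incidence is stored densely — the package targets the small-N pilot
    regime, not biobank-scale streaming.
    """

    incidence: np.ndarray
    sample_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.ndim != 2:
            raise ValidationError("incidence must be a 2-D array")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.incidence.shape[0])]
        if not self.feature_ids and self.incidence.shape[1]:
            self.feature_ids = list(range(self.incidence.shape[1]))
        if len(self.sample_ids) != self.incidence.shape[0]:
            raise ValidationError("sample_ids length does not match incidence rows")
        if len(self.feature_ids) != self.incidence.shape[1]:
            raise ValidationError("feature_ids length does not match incidence columns")

    @classmethod
    def from_dense(
        cls,
        array,
        sample_ids: list | None = None,
        feature_ids: list | None = None,
    ) -> "BinaryFeatureMatrix":
        arr = np.asarray(array)
        if arr.ndim != 2:
            raise ValidationError("incidence must be a 2-D array")
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))].flat[0]
            raise ValidationError(f"non-binary entry {bad!r} in incidence matrix")
        arr = arr.astype(np.int8)
        if feature_ids is None:
            feature_ids = list(range(arr.shape[1]))
        keep = arr.sum(axis=0) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            arr = arr[:, keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        mat = cls(
            incidence=arr,
            sample_ids=list(sample_ids) if sample_ids is not None else [],
            feature_ids=list(feature_ids),
            n_dropped=n_dropped,
        )
        logger.info(
            "matrix: %d samples, %d features (%d all-zero columns dropped)",
            mat.n_samples, mat.n_features, n_dropped,
        )
        return mat

    @property
    def n_samples(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_features(self) -> int:
        return self.incidence.shape[1]

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.incidence.sum(axis=0), dtype=np.int64)

    def subset_rows(self, indices) -> "BinaryFeatureMatrix":
        """Row submatrix; keeps the shared feature-id universe (its own
        all-zero columns are dropped, but ids identify features globally)."""
        idx = np.asarray(indices, dtype=np.int64)
        return BinaryFeatureMatrix.from_dense(
            self.incidence[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(str(f) for f in self.feature_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.incidence):
                fh.write(str(sid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    def to_coo(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tfeature\n")
            rows, cols = np.nonzero(self.incidence)
            for i, j in zip(rows, cols):
                fh.write(f"{self.sample_ids[i]}\t{self.feature_ids[j]}\n")
        with open(str(path) + ".samples", "w") as fh:
            for sid in self.sample_ids:
                fh.write(f"{sid}\n")


def _load_tsv(path) -> BinaryFeatureMatrix:
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError("empty file or blank header", line=1)
        feature_ids = header.rstrip("\n").split("\t")[1:]
        width = len(feature_ids)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width + 1:
                raise FormatError(
                    f"expected {width + 1} columns, found {len(parts)}", line=lineno
                )
            sample_ids.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell not in ("0", "1"):
                    raise ValidationError(
                        f"line {lineno}: non-binary entry {cell!r}"
                    )
                row.append(int(cell))
            rows.append(row)
    arr = np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, width), dtype=np.int8)
    return BinaryFeatureMatrix.from_dense(arr, sample_ids=sample_ids, feature_ids=feature_ids)


def _load_coo(path) -> BinaryFeatureMatrix:
    import os

    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        tokens = header.split()
        if tokens[:2] != ["sample", "feature"]:
            raise FormatError("expected header 'sample feature'", line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"expected 2 tokens, found {len(parts)}", line=lineno)
            pairs.append((parts[0], parts[1]))

    sample_ids: list[str] = []
    sidecar = str(path) + ".samples"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            sample_ids = [ln.strip() for ln in fh if ln.strip()]
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    feature_ids: list[str] = []
    feature_index: dict[str, int] = {}
    entries = []
    for s, f in pairs:
        if s not in sample_index:
            sample_index[s] = len(sample_ids)
            sample_ids.append(s)
        if f not in feature_index:
            feature_index[f] = len(feature_ids)
            feature_ids.append(f)
        entries.append((sample_index[s], feature_index[f]))
    arr = np.zeros((len(sample_ids), len(feature_ids)), dtype=np.int8)
    for i, j in entries:
        arr[i, j] = 1
    return BinaryFeatureMatrix.from_dense(arr, sample_ids=sample_ids, feature_ids=feature_ids)


def _load_vcf(path) -> BinaryFeatureMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot open VCF: {exc}") from exc
    sample_ids = list(vcf.samples)
    feature_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        genotypes = variant.genotypes  # per sample: [allele1, allele2, ..., phased]
        for alt_index, alt in enumerate(variant.ALT, start=1):
            present = np.fromiter(
                (
                    any(a == alt_index for a in gt[:-1] if a is not None and a >= 0)
                    for gt in genotypes
                ),
                dtype=np.int8,
                count=len(sample_ids),
            )
            feature_ids.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}")
            columns.append(present)
    arr = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return BinaryFeatureMatrix.from_dense(arr, sample_ids=sample_ids, feature_ids=feature_ids)


_LOADERS = {"tsv": _load_tsv, "coo": _load_coo, "vcf": _load_vcf}


def load_matrix(path, format: str = "tsv") -> BinaryFeatureMatrix:
    """Load a binary incidence matrix in one of the supported dialects."""
    try:
        loader = _LOADERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_LOADERS)}")
    return loader(path)


def sufficient_stats(matrix: BinaryFeatureMatrix) -> FeatureFrequencies:
    """Reduce a matrix to (N, K_N, m): the model sees nothing else."""
    m = matrix.column_sums()
    return FeatureFrequencies(n=matrix.n_samples, k=int(m.size), m=m)


def split_rows(matrix: BinaryFeatureMatrix, n_train: int, seed):
    """Disjoint uniform train/test row partition, deterministic per seed."""
    if not 0 < n_train < matrix.n_samples:
        raise ValueError(
            f"n_train must lie in (0, {matrix.n_samples}), got {n_train}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(matrix.n_samples)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return matrix.subset_rows(train_idx), matrix.subset_rows(test_idx)


def true_unseen(
    train: BinaryFeatureMatrix,
    test: BinaryFeatureMatrix,
    r: int | None = None,
) -> int:
    """Ground-truth unseen count from a held-out split.

    With ``r`` absent: features with no presence in ``train`` and at least
    one in ``test``.  With ``r`` given: exactly ``r`` presences in ``test``.
    """
    if r is not None and r < 1:
        raise ValueError(f"prevalence r must be >= 1, got {r}")
    train_ids = set(train.feature_ids)
    sums = test.column_sums()
    unseen = [s for f, s in zip(test.feature_ids, sums) if f not in train_ids]
    if r is None:
        return len(unseen)
    return sum(1 for s in unseen if s == r)
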