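"""Molecular feature sets and the two distance functions used for neighbor search.

Three fingerprint metrics (ECFP4, FCFP4, MACCS) are compared with Tanimoto
distance (1 - Tanimoto similarity); the 2D descriptor panel (DES) is compared
with a dimension-normalized Euclidean distance over min-max scaled values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

TANIMOTO = "tanimoto"
EUCLIDEAN = "euclidean_normalized"

FINGERPRINT_METRICS = ("ECFP4", "FCFP4", "MACCS")
DESCRIPTOR_METRIC = "DES"
ALL_METRICS = FINGERPRINT_METRICS + (DESCRIPTOR_METRIC,)

MACCS_WIDTH = 166


class FeatureError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """A per-metric representation of a compound set.

    ``vectors`` is an (n_compounds, width) array: {0,1} bits for Tanimoto
    metrics, min-max normalized reals in [0, 1] for the Euclidean metric.
    """

    metric_name: str
    kind: str
    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2:
            raise FeatureError("vectors must be a 2-D array")
        if len(self.ids) != self.vectors.shape[0]:
            raise FeatureError("ids and vectors disagree on compound count")
        if self.kind not in (TANIMOTO, EUCLIDEAN):
            raise FeatureError(f"unknown distance kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return self.vectors.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.vectors[i]


@dataclass
class FingerprintSet(FeatureMatrix):
    n_bits: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_bits == 0:
            self.n_bits = self.vectors.shape[1]
        bad = ~np.isin(self.vectors, (0, 1))
        if bad.any():
            raise FeatureError("fingerprint vectors must contain only 0/1 bits")


@dataclass
class NormalizationParams:
    """Per-descriptor (min, max) fitted on a reference set, keyed by name."""

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            names=list(d["names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
        )


@dataclass
class DescriptorSet(FeatureMatrix):
    raw: Optional[np.ndarray] = None
    descriptor_names: list[str] = field(default_factory=list)
    params: Optional[NormalizationParams] = None

    @classmethod
    def fit(
        cls,
        ids: Sequence[str],
        raw: np.ndarray,
        names: Sequence[str],
        metric_name: str = DESCRIPTOR_METRIC,
    ) -> "DescriptorSet":
        """Fit normalization on a reference set.

        Descriptors with zero variance, or that are undefined (non-finite) for
        any compound, are removed before min-max scaling to [0, 1].
        """
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != len(ids):
            raise FeatureError("raw descriptor matrix shape mismatch")
        finite = np.isfinite(raw).all(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            variable = np.nanmax(raw, axis=0) > np.nanmin(raw, axis=0)
        keep = finite & variable
        if not keep.any():
            raise FeatureError("no descriptors left after zero-variance/NaN filtering")
        kept_raw = raw[:, keep]
        kept_names = [n for n, k in zip(names, keep) if k]
        mins = kept_raw.min(axis=0)
        maxs = kept_raw.max(axis=0)
        normalized = (kept_raw - mins) / (maxs - mins)
        params = NormalizationParams(names=kept_names, mins=mins, maxs=maxs)
        return cls(
            metric_name=metric_name,
            kind=EUCLIDEAN,
            ids=list(ids),
            vectors=normalized,
            raw=kept_raw,
            descriptor_names=kept_names,
            params=params,
        )

    @classmethod
    def transform(
        cls,
        ids: Sequence[str],
        raw: np.ndarray,
        names: Sequence[str],
        params: NormalizationParams,
        metric_name: str = DESCRIPTOR_METRIC,
    ) -> "DescriptorSet":
        """Normalize a query set with *reference* (min, max), clipping to [0, 1].

        Query descriptor values that are non-finite map to 0.5 (the scale
        midpoint) with a warning; the reference filter decides the panel.
        """
        raw = np.asarray(raw, dtype=float)
        index = {n: j for j, n in enumerate(names)}
        missing = [n for n in params.names if n not in index]
        if missing:
            raise FeatureError(f"query descriptor panel lacks {missing[:5]}")
        cols = [index[n] for n in params.names]
        kept_raw = raw[:, cols]
        span = params.maxs - params.mins
        normalized = np.clip((kept_raw - params.mins) / span, 0.0, 1.0)
        bad = ~np.isfinite(normalized)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-finite query descriptor values mapped to 0.5"
            )
            normalized = np.where(bad, 0.5, normalized)
        return cls(
            metric_name=metric_name,
            kind=EUCLIDEAN,
            ids=list(ids),
            vectors=normalized,
            raw=kept_raw,
            descriptor_names=list(params.names),
            params=params,
        )


@dataclass(frozen=True)
class DistanceReport:
    value: float
    kind: str


def _mols(cset):
    return [rec.to_mol() for rec in cset]


def compute_fingerprints(cset, metric_name: str, n_bits: int = 1024) -> FingerprintSet:
    """Compute ECFP4 / FCFP4 (hashed Morgan, diameter 4) or MACCS key fingerprints."""
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    metric_name = metric_name.upper()
    if metric_name not in FINGERPRINT_METRICS:
        raise FeatureError(f"unknown fingerprint metric {metric_name!r}")

    vectors = []
    if metric_name == "MACCS":
        for mol in _mols(cset):
            bv = MACCSkeys.GenMACCSKeys(mol)
            arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
            arr[list(bv.GetOnBits())] = 1
            vectors.append(arr[1:])  # bit 0 of the RDKit vector is unused padding
        width = MACCS_WIDTH
    else:
        kwargs = dict(radius=2, fpSize=n_bits)
        if metric_name == "FCFP4":
            kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)
        for mol in _mols(cset):
            bv = gen.GetFingerprint(mol)
            arr = np.zeros(n_bits, dtype=np.uint8)
            arr[list(bv.GetOnBits())] = 1
            vectors.append(arr)
        width = n_bits

    return FingerprintSet(
        metric_name=metric_name,
        kind=TANIMOTO,
        ids=cset.ids,
        vectors=np.vstack(vectors) if vectors else np.zeros((0, width), dtype=np.uint8),
        n_bits=width,
    )


def compute_descriptors(cset, reference_params: Optional[NormalizationParams] = None) -> DescriptorSet:
    """Compute the standard RDKit 2D descriptor panel for a compound set.

    Without ``reference_params`` this fits the filter + normalization (a
    reference set); with them the set is treated as queries and normalized
    with the reference (min, max), clipped to [0, 1].
    """
    from rdkit.Chem import Descriptors

    names = [name for name, _ in Descriptors.descList]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mol in _mols(cset):
            vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
            rows.append([float(vals[name]) for name in names])
    raw = np.asarray(rows, dtype=float)
    if reference_params is None:
        return DescriptorSet.fit(cset.ids, raw, names)
    return DescriptorSet.transform(cset.ids, raw, names, reference_params)


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> DistanceReport:
    """Dimension-normalized Euclidean distance: sqrt(sum((a_i-b_i)^2) / d).

    On vectors with coordinates in [0, 1] the result is bounded by 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise FeatureError(f"length mismatch: {a.shape} vs {b.shape}")
    value = float(np.sqrt(np.sum((a - b) ** 2) / a.size))
    return DistanceReport(value=value, kind=EUCLIDEAN)


def tanimoto_distance(a: np.ndarray, b: np.ndarray) -> DistanceReport:
    """Tanimoto distance 1 - |a&b| / (|a| + |b| - |a&b|) on bit vectors.

    An all-zero pair has undefined similarity; it is defined here as 0
    (distance 1) with a warning so batch jobs do not abort mid-run.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise FeatureError(f"width mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum(a != 0)) + int(np.sum(b != 0)) - inter
    if union == 0:
        warnings.warn("Tanimoto similarity of two all-zero vectors defined as 0")
        return DistanceReport(value=1.0, kind=TANIMOTO)
    return DistanceReport(value=1.0 - inter / union, kind=TANIMOTO)


def distance_matrix(A: np.ndarray, B: np.ndarray, kind: str) -> np.ndarray:
    """Pairwise distances between the rows of A (n, w) and B (m, w)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise FeatureError(f"width mismatch: {A.shape} vs {B.shape}")
    if kind == EUCLIDEAN:
        sq = (
            np.sum(A**2, axis=1)[:, None]
            + np.sum(B**2, axis=1)[None, :]
            - 2.0 * (A @ B.T)
        )
        np.maximum(sq, 0.0, out=sq)
        return np.sqrt(sq / A.shape[1])
    if kind == TANIMOTO:
        Ab = (A != 0).astype(float)
        Bb = (B != 0).astype(float)
        inter = Ab @ Bb.T
        union = Ab.sum(axis=1)[:, None] + Bb.sum(axis=1)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
        return 1.0 - sim
    raise FeatureError(f"unknown distance kind {kind!r}")


def distances_to(query_vec: np.ndarray, features: FeatureMatrix) -> np.ndarray:
    """Distances from one query vector to every row of a feature matrix."""
    q = np.asarray(query_vec, dtype=float).reshape(1, -1)
    return distance_matrix(q, features.vectors, features.kind)[0]
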