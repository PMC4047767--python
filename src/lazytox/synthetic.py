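"""Synthetic fixture worlds with known local structure-activity relationships.

These generators produce clustered reference/query sets — as feature vectors
(descriptor worlds), bit vectors (fingerprint worlds), or both keyed to the
same clusters (joint worlds) — so every local model, the applicability
domain, and consensus behavior can be exercised offline with known ground
truth.  Queries are drawn either from cluster interiors (in-domain) or from a
remote region (out-of-domain) and labeled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from lazytox.features import EUCLIDEAN, TANIMOTO, FeatureMatrix
from lazytox.mol_io import CompoundSet, MoleculeRecord

ACTIVITY_MODELS = ("local_linear", "cluster_constant")


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    n_clusters: int = 4
    compounds_per_cluster: int = 25
    feature_dim: int = 8
    within_cluster_spread: float = 0.03
    activity_model: str = "local_linear"
    noise_sigma: float = 0.0
    seed: int = 0
    # knobs beyond the core contract, with safe defaults
    queries_per_cluster: int = 3
    n_remote_queries: int = 4
    n_background: int = 0  # scattered unclustered reference compounds
    planted_dim: int = 0
    slope_range: tuple[float, float] = (1.5, 4.0)
    intercept_range: tuple[float, float] = (1.0, 4.0)
    activity_band: tuple[float, float] = (2.0, 7.0)

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.compounds_per_cluster, self.feature_dim) < 1:
            raise SyntheticError("counts must be positive")
        if self.within_cluster_spread < 0 or self.noise_sigma < 0:
            raise SyntheticError("spread and noise must be >= 0")
        if self.activity_model not in ACTIVITY_MODELS:
            raise SyntheticError(f"unknown activity model {self.activity_model!r}")
        if not (0 <= self.planted_dim < self.feature_dim):
            raise SyntheticError("planted_dim out of range")


@dataclass
class World:
    """One generated reference/query pair in a single feature space."""

    reference: FeatureMatrix
    ref_activities: np.ndarray
    queries: FeatureMatrix
    query_activities: np.ndarray  # noise-free truth
    query_domain: list[str]  # "in" | "out" per query
    ref_clusters: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    query_clusters: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class JointWorld:
    """The same clusters and activities seen through several feature spaces."""

    spaces: dict  # metric name -> (reference FeatureMatrix, query FeatureMatrix)
    ref_activities: np.ndarray
    query_activities: np.ndarray
    query_domain: list[str]


def _cluster_rules(spec: SyntheticSpec, rng: np.random.Generator):
    """Per-cluster activity rules: (slope, intercept) pairs or constant levels."""
    lo, hi = spec.activity_band
    if spec.activity_model == "local_linear":
        slopes = rng.uniform(*spec.slope_range, size=spec.n_clusters)
        intercepts = rng.uniform(*spec.intercept_range, size=spec.n_clusters)
        return slopes, intercepts
    levels = np.linspace(lo, hi, spec.n_clusters)
    rng.shuffle(levels)
    return levels, None


def _activity(spec: SyntheticSpec, rules, cluster: int, x: np.ndarray) -> float:
    if spec.activity_model == "local_linear":
        slopes, intercepts = rules
        return float(intercepts[cluster] + slopes[cluster] * x[spec.planted_dim])
    levels, _ = rules
    return float(levels[cluster])


def generate_descriptor_world(
    spec: SyntheticSpec, rng: Optional[np.random.Generator] = None
) -> World:
    """Clustered [0,1]-scaled descriptor vectors with a planted activity rule.

    Reference clusters live in the lower corner of feature space; in-domain
    queries are drawn from cluster interiors, out-of-domain queries from a
    remote region near the upper corner with activities unrelated to any
    cluster rule.  Observed reference activities carry Gaussian noise
    (``noise_sigma``); query truths are noise-free.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    d = spec.feature_dim
    centers = rng.uniform(0.10, 0.60, size=(spec.n_clusters, d))
    rules = _cluster_rules(spec, rng)

    ref_vecs, ref_y, ref_cl = [], [], []
    for c in range(spec.n_clusters):
        for _ in range(spec.compounds_per_cluster):
            x = np.clip(centers[c] + rng.normal(0, spec.within_cluster_spread, d), 0, 1)
            ref_vecs.append(x)
            ref_y.append(_activity(spec, rules, c, x) + rng.normal(0, spec.noise_sigma))
            ref_cl.append(c)

    lo, hi = spec.activity_band
    for _ in range(spec.n_background):
        x = rng.uniform(0.05, 0.95, size=d)
        ref_vecs.append(x)
        ref_y.append(float(rng.uniform(lo, hi)))
        ref_cl.append(-1)

    q_vecs, q_y, q_dom, q_cl = [], [], [], []
    for c in range(spec.n_clusters):
        for _ in range(spec.queries_per_cluster):
            x = np.clip(centers[c] + rng.normal(0, spec.within_cluster_spread, d), 0, 1)
            q_vecs.append(x)
            q_y.append(_activity(spec, rules, c, x))
            q_dom.append("in")
            q_cl.append(c)
    for _ in range(spec.n_remote_queries):
        x = rng.uniform(0.15, 0.85, size=d)
        q_vecs.append(x)
        q_y.append(float(rng.uniform(lo, hi)))
        q_dom.append("out")
        q_cl.append(-1)

    ref = FeatureMatrix(
        metric_name="DES",
        kind=EUCLIDEAN,
        ids=[f"ref_{i:04d}" for i in range(len(ref_vecs))],
        vectors=np.asarray(ref_vecs),
    )
    queries = FeatureMatrix(
        metric_name="DES",
        kind=EUCLIDEAN,
        ids=[f"q_{dom}_{i:04d}" for i, dom in enumerate(q_dom)],
        vectors=np.asarray(q_vecs).reshape(len(q_vecs), d),
    )
    return World(
        reference=ref,
        ref_activities=np.asarray(ref_y),
        queries=queries,
        query_activities=np.asarray(q_y),
        query_domain=q_dom,
        ref_clusters=np.asarray(ref_cl),
        query_clusters=np.asarray(q_cl),
    )


def generate_planted_linear_world(
    n_clusters: int = 10,
    members_per_cluster: int = 10,
    feature_dim: int = 6,
    planted_span: float = 0.3,
    planted_dim: int = 0,
    slope: float = 3.0,
    noise_sigma: float = 0.0,
    queries_per_cluster: int = 5,
    seed: int = 0,
) -> World:
    """A descriptor world where activity = slope * x[planted_dim] exactly.

    Within each cluster the planted coordinate takes evenly spaced values
    spanning ``+-planted_span`` around the cluster center while every other
    coordinate is constant, so any interior query's two nearest neighbors
    straddle it in the planted coordinate — the local univariate regression
    is never forced to extrapolate.  Reference activities carry Gaussian
    noise; query truths are noise-free.
    """
    rng = np.random.default_rng(seed)
    d = feature_dim
    centers = rng.uniform(0.2, 0.8, size=(n_clusters, d))
    centers[:, planted_dim] = rng.uniform(
        planted_span + 0.02, 1.0 - planted_span - 0.02, size=n_clusters
    )
    grid = np.linspace(-planted_span, planted_span, members_per_cluster)
    step = grid[1] - grid[0] if members_per_cluster > 1 else planted_span

    ref_vecs, ref_y, ref_cl = [], [], []
    for c in range(n_clusters):
        for g in grid:
            x = centers[c].copy()
            x[planted_dim] += g
            ref_vecs.append(x)
            ref_y.append(slope * x[planted_dim] + rng.normal(0, noise_sigma))
            ref_cl.append(c)

    q_vecs, q_y, q_cl = [], [], []
    margin = planted_span - 2.0 * step
    for c in range(n_clusters):
        for _ in range(queries_per_cluster):
            x = centers[c].copy()
            x[planted_dim] += rng.uniform(-margin, margin)
            q_vecs.append(x)
            q_y.append(slope * x[planted_dim])
            q_cl.append(c)

    ref = FeatureMatrix(
        metric_name="DES", kind=EUCLIDEAN,
        ids=[f"ref_{i:04d}" for i in range(len(ref_vecs))],
        vectors=np.asarray(ref_vecs),
    )
    queries = FeatureMatrix(
        metric_name="DES", kind=EUCLIDEAN,
        ids=[f"q_in_{i:04d}" for i in range(len(q_vecs))],
        vectors=np.asarray(q_vecs),
    )
    return World(
        reference=ref,
        ref_activities=np.asarray(ref_y),
        queries=queries,
        query_activities=np.asarray(q_y),
        query_domain=["in"] * len(q_vecs),
        ref_clusters=np.asarray(ref_cl),
        query_clusters=np.asarray(q_cl),
    )


def _flip_bits(proto: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(proto.size) < rate
    return np.where(flips, 1 - proto, proto).astype(np.uint8)


def generate_fingerprint_world(
    spec: SyntheticSpec,
    n_bits: int = 256,
    metric_name: str = "ECFP4",
    prototypes: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    rules=None,
    bit_density: float = 0.3,
) -> World:
    """Clustered bit vectors: per-cluster random prototypes plus bit flips.

    Each cluster member flips every prototype bit independently with
    probability ``within_cluster_spread``; activities are keyed to prototype
    identity (per-cluster constants over the activity band, plus noise on the
    reference).  Out-of-domain queries are dense random vectors unrelated to
    any prototype.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if prototypes is None:
        prototypes = (rng.random((spec.n_clusters, n_bits)) < bit_density).astype(np.uint8)
    else:
        prototypes = np.asarray(prototypes, dtype=np.uint8)
        if prototypes.shape[0] != spec.n_clusters:
            raise SyntheticError("one prototype per cluster required")
        n_bits = prototypes.shape[1]
    if rules is None:
        lo, hi = spec.activity_band
        levels = np.linspace(lo, hi, spec.n_clusters)
        rng.shuffle(levels)
    else:
        levels = rules

    ref_vecs, ref_y, ref_cl = [], [], []
    for c in range(spec.n_clusters):
        for _ in range(spec.compounds_per_cluster):
            ref_vecs.append(_flip_bits(prototypes[c], spec.within_cluster_spread, rng))
            ref_y.append(float(levels[c]) + rng.normal(0, spec.noise_sigma))
            ref_cl.append(c)

    q_vecs, q_y, q_dom, q_cl = [], [], [], []
    for c in range(spec.n_clusters):
        for _ in range(spec.queries_per_cluster):
            q_vecs.append(_flip_bits(prototypes[c], spec.within_cluster_spread, rng))
            q_y.append(float(levels[c]))
            q_dom.append("in")
            q_cl.append(c)
    lo, hi = spec.activity_band
    for _ in range(spec.n_remote_queries):
        q_vecs.append((rng.random(n_bits) < 0.5).astype(np.uint8))
        q_y.append(float(rng.uniform(lo, hi)))
        q_dom.append("out")
        q_cl.append(-1)

    ref = FeatureMatrix(
        metric_name=metric_name,
        kind=TANIMOTO,
        ids=[f"ref_{i:04d}" for i in range(len(ref_vecs))],
        vectors=np.asarray(ref_vecs),
    )
    queries = FeatureMatrix(
        metric_name=metric_name,
        kind=TANIMOTO,
        ids=[f"q_{dom}_{i:04d}" for i, dom in enumerate(q_dom)],
        vectors=np.asarray(q_vecs, dtype=np.uint8).reshape(len(q_vecs), n_bits),
    )
    return World(
        reference=ref,
        ref_activities=np.asarray(ref_y),
        queries=queries,
        query_activities=np.asarray(q_y),
        query_domain=q_dom,
        ref_clusters=np.asarray(ref_cl),
        query_clusters=np.asarray(q_cl),
    )


def generate_joint_world(
    spec: SyntheticSpec,
    fingerprint_metrics: tuple[str, ...] = ("ECFP4", "FCFP4", "MACCS"),
    n_bits: int = 256,
) -> JointWorld:
    """One set of clusters and activities seen through four feature spaces.

    The descriptor world fixes cluster membership and activities; each
    fingerprint metric then gets its own prototypes and bit flips for the
    same compounds, so the 16-model consensus workflow can run end to end on
    synthetic data.  Fingerprint spaces reuse the descriptor world's observed
    reference activities and truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    base = generate_descriptor_world(spec, rng=rng)
    spaces: dict = {"DES": (base.reference, base.queries)}
    for metric in fingerprint_metrics:
        prototypes = (rng.random((spec.n_clusters, n_bits)) < 0.3).astype(np.uint8)
        ref_vecs = np.vstack(
            [
                _flip_bits(prototypes[c], spec.within_cluster_spread, rng)
                if c >= 0
                else (rng.random(n_bits) < 0.5).astype(np.uint8)
                for c in base.ref_clusters
            ]
        )
        q_vecs = []
        for c in base.query_clusters:
            if c >= 0:
                q_vecs.append(_flip_bits(prototypes[c], spec.within_cluster_spread, rng))
            else:
                q_vecs.append((rng.random(n_bits) < 0.5).astype(np.uint8))
        ref = FeatureMatrix(
            metric_name=metric, kind=TANIMOTO, ids=base.reference.ids, vectors=ref_vecs
        )
        qf = FeatureMatrix(
            metric_name=metric, kind=TANIMOTO, ids=base.queries.ids, vectors=np.vstack(q_vecs)
        )
        spaces[metric] = (ref, qf)
    return JointWorld(
        spaces=spaces,
        ref_activities=base.ref_activities,
        query_activities=base.query_activities,
        query_domain=base.query_domain,
    )


_TOY_SMILES = [
    ("tox01", "CCO", 2.1),  # ethanol
    ("tox02", "CC(=O)C", 2.4),  # acetone
    ("tox03", "c1ccccc1", 3.0),  # benzene
    ("tox04", "Cc1ccccc1", 2.8),  # toluene
    ("tox05", "Oc1ccccc1", 3.5),  # phenol
    ("tox06", "Nc1ccccc1", 3.8),  # aniline
    ("tox07", "CC(=O)Oc1ccccc1C(=O)O", 3.2),  # aspirin
    ("tox08", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 3.4),  # ibuprofen
    ("tox09", "CC(=O)Nc1ccc(O)cc1", 3.1),  # paracetamol
    ("tox10", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", 3.9),  # caffeine
    ("tox11", "CN1CCCC1c1cccnc1", 5.3),  # nicotine
    ("tox12", "c1ccc2ccccc2c1", 3.6),  # naphthalene
    ("tox13", "c1ccncc1", 3.7),  # pyridine
    ("tox14", "c1ccoc1", 4.0),  # furan
    ("tox15", "ClC(Cl)Cl", 3.3),  # chloroform
    ("tox16", "NC(=O)N", 2.0),  # urea
    ("tox17", "OC(=O)c1ccccc1", 2.9),  # benzoic acid
    ("tox18", "C=Cc1ccccc1", 3.0),  # styrene
    ("tox19", "OCC(O)C(O)C(O)C(O)CO", 2.2),  # sorbitol
    ("tox20", "Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl", 6.1),  # DDT
    ("tox21", "CCOC(=O)c1ccccc1", 3.1),  # ethyl benzoate
    ("tox22", "CCCCCCO", 2.5),  # hexanol
]


def toy_smiles_set(role: str = "reference") -> CompoundSet:
    """A small hand-curated SMILES set with fabricated activities (2-7 band).

    Shipped for end-to-end CLI and smoke tests; the activities are invented
    and carry no toxicological meaning.
    """
    records = [
        MoleculeRecord(id=cid, structure=smiles, activity=act)
        for cid, smiles, act in _TOY_SMILES
    ]
    # canonicalize on construction so downstream features are dialect-independent
    from lazytox.mol_io import canonical_smiles

    records = [
        MoleculeRecord(id=r.id, structure=canonical_smiles(r.structure), activity=r.activity)
        for r in records
    ]
    return CompoundSet(records=records, role=role)
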