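"""Consensus averaging across models and the distance-based applicability domain.

The applicability domain (AD) for each similarity metric is a nearest-neighbor
distance threshold D_T = d_bar + Z * sigma fitted on the reference set; a
query whose nearest reference compound is farther than D_T is an outlier and
its prediction under that metric is deemed unreliable.  Consensus predictions
are arithmetic means of constituent model values; the consensus prediction
fraction (share of the four metric units covering a query) gates the
reliability of the final consensus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from lazytox.features import FeatureMatrix, distance_matrix, distances_to
from lazytox.lll import PredictionResult

CONSENSUS_KINDS = (
    "LLR_consensus",
    "SA_consensus",
    "SR_consensus",
    "GP_consensus",
    "Final_consensus",
)


class ConsensusError(ValueError):
    pass


@dataclass
class ADModel:
    """Fitted applicability-domain threshold for one similarity metric.

    d_bar and sigma are the mean and population standard deviation of each
    reference compound's distance to its nearest *other* reference compound;
    D_T = d_bar + Z * sigma.
    """

    metric_name: str
    kind: str
    d_bar: float
    sigma: float
    Z: float
    D_T: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConsensusError("sigma must be >= 0")
        if not math.isclose(self.D_T, self.d_bar + self.Z * self.sigma, abs_tol=1e-9):
            raise ConsensusError("D_T must equal d_bar + Z * sigma")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "kind": self.kind,
            "d_bar": self.d_bar,
            "sigma": self.sigma,
            "Z": self.Z,
            "D_T": self.D_T,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ADModel":
        return cls(
            metric_name=d["metric"],
            kind=d["kind"],
            d_bar=float(d["d_bar"]),
            sigma=float(d["sigma"]),
            Z=float(d["Z"]),
            D_T=float(d["D_T"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ADModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ConsensusResult:
    query_id: str
    kind: str
    value: float
    constituents: list[PredictionResult] = field(default_factory=list)
    n_ok: int = 0
    degraded: bool = False
    fraction_reliable: Optional[float] = None
    reliable: Optional[bool] = None


def fit_ad(features: FeatureMatrix, Z: float = 0.5) -> ADModel:
    """Fit the AD threshold on a reference feature set.

    For every reference compound the distance to its nearest other reference
    compound (self-matches excluded by id, so duplicate structures at
    distance 0 still count) feeds d_bar and the population sigma.
    """
    n = len(features)
    if n < 2:
        raise ConsensusError(f"need >= 2 reference compounds, got {n}")
    D = distance_matrix(features.vectors, features.vectors, features.kind)
    ids = np.asarray(features.ids)
    same = ids[:, None] == ids[None, :]
    D = np.where(same, np.inf, D)
    nn = D.min(axis=1)
    d_bar = float(nn.mean())
    sigma = float(nn.std())  # population convention
    return ADModel(
        metric_name=features.metric_name,
        kind=features.kind,
        d_bar=d_bar,
        sigma=sigma,
        Z=Z,
        D_T=d_bar + Z * sigma,
    )


def check_ad(
    query_vec: np.ndarray, ad: ADModel, features: FeatureMatrix
) -> tuple[bool, float]:
    """Whether a query lies within the AD, plus its nearest-reference distance.

    A distance exactly at the threshold counts as reliable (<= comparison).
    """
    if features.metric_name != ad.metric_name:
        raise ConsensusError(
            f"metric mismatch: AD is {ad.metric_name!r}, features are "
            f"{features.metric_name!r}"
        )
    nn = float(distances_to(query_vec, features).min())
    return nn <= ad.D_T + 1e-12, nn


def consensus(predictions: Sequence[PredictionResult], kind: str) -> ConsensusResult:
    """Arithmetic mean over constituents with status ok.

    Failed constituents are excluded from the average; if fewer than half are
    ok the result is marked degraded.  Zero ok constituents raise.
    """
    preds = list(predictions)
    ok = [p for p in preds if p.status != "failed"]
    if not ok:
        raise ConsensusError("no usable constituent predictions")
    qids = {p.query_id for p in preds}
    if len(qids) != 1:
        raise ConsensusError(f"constituents span several queries: {sorted(qids)}")
    value = float(np.mean([p.value for p in ok]))
    return ConsensusResult(
        query_id=ok[0].query_id,
        kind=kind,
        value=value,
        constituents=preds,
        n_ok=len(ok),
        degraded=2 * len(ok) < len(preds),
    )


def consensus_fraction(
    ad_flags: Sequence[bool], threshold: float = 0.75
) -> tuple[float, bool]:
    """Consensus prediction fraction over the four similarity-metric units.

    fraction = reliable units / 4; the final consensus is reliable iff the
    fraction is >= the threshold (default 0.75).
    """
    flags = list(ad_flags)
    if len(flags) != 4:
        raise ConsensusError(f"expected exactly 4 AD unit flags, got {len(flags)}")
    if not (0.0 <= threshold <= 1.0):
        raise ConsensusError("threshold must lie in [0, 1]")
    fraction = sum(bool(f) for f in flags) / 4.0
    return fraction, fraction >= threshold
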