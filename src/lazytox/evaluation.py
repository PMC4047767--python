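"""Scoring predictions (R^2, MAE) and coverage-ranked test subsets.

R^2 defaults to the squared Pearson correlation between predicted and
observed values (shift-invariant); the coefficient of determination is
available via ``method="cod"``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from lazytox.features import FeatureMatrix, distance_matrix


class EvaluationError(ValueError):
    pass


def score(
    pred: Sequence[float],
    obs: Sequence[float],
    method: str = "pearson",
) -> tuple[Optional[float], float]:
    """(R^2, MAE) for paired prediction/observation vectors.

    R^2 is None when either vector has zero variance (correlation undefined).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size == 0:
        raise EvaluationError(f"need equal non-empty vectors, got {pred.shape}/{obs.shape}")
    mae = float(np.mean(np.abs(pred - obs)))
    if method == "pearson":
        if np.std(pred) == 0 or np.std(obs) == 0:
            return None, mae
        r = float(np.corrcoef(pred, obs)[0, 1])
        return r * r, mae
    if method == "cod":
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        if ss_tot == 0:
            return None, mae
        return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot, mae
    raise EvaluationError(f"unknown R^2 method {method!r}")


def coverage_subsets(
    query_features: FeatureMatrix,
    reference_features: FeatureMatrix,
    sizes: Sequence[int],
) -> dict[str, list[str]]:
    """Nested test subsets ranked by distance to the nearest reference compound.

    For each requested size s the s test compounds with the smallest
    nearest-reference distance form subset ``Set_<s>``; smaller subsets are
    prefixes of larger ones.  Distance ties are broken by compound id.
    """
    n = len(query_features)
    for s in sizes:
        if not (1 <= s <= n):
            raise EvaluationError(f"subset size {s} out of range 1..{n}")
    D = distance_matrix(
        query_features.vectors, reference_features.vectors, reference_features.kind
    )
    nn = D.min(axis=1)
    ids = np.asarray(query_features.ids)
    order = np.lexsort((ids, nn))
    ranked = [str(i) for i in ids[order]]
    return {f"Set_{s}": ranked[:s] for s in sizes}


def ad_breakdown(
    pred: Sequence[float],
    obs: Sequence[float],
    within: Sequence[bool],
) -> dict:
    """MAE over the all / within-AD / outside-AD partitions, with counts.

    Empty partitions are reported as None (missing), never as zero error.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    within = np.asarray(within, dtype=bool)
    if pred.size == 0:
        raise EvaluationError("empty input")
    if not (pred.shape == obs.shape == within.shape):
        raise EvaluationError("pred/obs/within length mismatch")
    err = np.abs(pred - obs)

    def _mae(mask: np.ndarray) -> Optional[float]:
        return float(err[mask].mean()) if mask.any() else None

    all_mask = np.ones_like(within)
    return {
        "n_all": int(pred.size),
        "n_within": int(within.sum()),
        "n_outside": int((~within).sum()),
        "mae_all": _mae(all_mask),
        "mae_within": _mae(within),
        "mae_outside": _mae(~within),
    }
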