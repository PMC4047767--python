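"""Orchestration: run all individual and consensus models over feature spaces.

The entry point `predict_all` works on per-metric ``FeatureMatrix`` pairs so
it serves both real molecule sets (via `build_feature_spaces`) and synthetic
worlds.  Output is a tidy DataFrame with one row per query per model — the
individual (model kind x metric) combinations plus the per-kind and final
consensus rows, with applicability-domain columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lazytox.consensus_ad import ADModel, check_ad, consensus, consensus_fraction, fit_ad
from lazytox.features import (
    ALL_METRICS,
    DESCRIPTOR_METRIC,
    FeatureMatrix,
    compute_descriptors,
    compute_fingerprints,
)
from lazytox.lll import (
    PredictionResult,
    find_neighbors,
    fit_predict_llr,
    predict_gp,
    predict_sa,
    predict_sr,
    rank_reference,
    select_n_by_cv,
)

MODEL_KINDS = ("LLR", "SA", "SR", "GP")


@dataclass
class RunConfig:
    metrics: tuple[str, ...] = ALL_METRICS
    models: tuple[str, ...] = MODEL_KINDS
    n_bits: int = 1024
    llr_k_min: int = 5
    gp_k_init: int = 3
    k_max: int = 20
    n_neighbors: int = 5  # SA/SR n when CV selection is off
    select_n: bool = False
    n_grid: tuple[int, ...] = tuple(range(1, 21))
    cv_folds: int = 10
    Z: float = 0.5
    consensus_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        self.metrics = tuple(m.upper() for m in self.metrics)
        self.models = tuple(m.upper() for m in self.models)


def build_feature_spaces(
    reference, queries, metrics: Sequence[str] = ALL_METRICS, n_bits: int = 1024
) -> dict[str, tuple[FeatureMatrix, FeatureMatrix]]:
    """Compute per-metric (reference, query) feature matrices for molecule sets."""
    spaces: dict[str, tuple[FeatureMatrix, FeatureMatrix]] = {}
    for metric in metrics:
        metric = metric.upper()
        if metric == DESCRIPTOR_METRIC:
            ref = compute_descriptors(reference)
            q = compute_descriptors(queries, reference_params=ref.params)
        else:
            ref = compute_fingerprints(reference, metric, n_bits=n_bits)
            q = compute_fingerprints(queries, metric, n_bits=n_bits)
        spaces[metric] = (ref, q)
    return spaces


def _failed(query_id: str, kind: str, metric: str) -> PredictionResult:
    return PredictionResult(
        query_id=query_id, model_kind=kind, metric_name=metric,
        value=math.nan, k_used=0, status="failed",
    )


def predict_all(
    spaces: dict[str, tuple[FeatureMatrix, FeatureMatrix]],
    ref_activities: Sequence[float],
    config: Optional[RunConfig] = None,
    descriptor_space: Optional[tuple[FeatureMatrix, FeatureMatrix]] = None,
) -> pd.DataFrame:
    """Run the configured model kinds over every metric space for every query.

    ``spaces`` maps metric name -> (reference features, query features); all
    spaces must list the same compounds in the same order.  LLR regresses on
    the descriptor space (the ``DES`` entry, or ``descriptor_space``) while
    retrieving neighbors with each metric.  Returns one row per query per
    individual model plus per-kind and final consensus rows.
    """
    config = config or RunConfig()
    metrics = [m for m in config.metrics if m in spaces]
    if not metrics:
        raise ValueError("no configured metric has a feature space")
    ref_activities = np.asarray(ref_activities, dtype=float)

    ref_ids = spaces[metrics[0]][0].ids
    query_ids = spaces[metrics[0]][1].ids
    for m in metrics:
        if spaces[m][0].ids != ref_ids or spaces[m][1].ids != query_ids:
            raise ValueError(f"feature space {m!r} lists different compounds")

    desc_pair = descriptor_space or spaces.get(DESCRIPTOR_METRIC)
    if "LLR" in config.models and desc_pair is None:
        raise ValueError("LLR requires a descriptor space (DES) for its regression")

    ad_models: dict[str, ADModel] = {m: fit_ad(spaces[m][0], Z=config.Z) for m in metrics}

    n_per_metric: dict[str, dict[str, int]] = {}
    for m in metrics:
        n_per_metric[m] = {}
        for kind in ("SA", "SR"):
            if kind in config.models:
                if config.select_n:
                    n_per_metric[m][kind] = select_n_by_cv(
                        spaces[m][0], ref_activities, kind,
                        n_grid=config.n_grid, folds=config.cv_folds, seed=config.seed,
                    )
                else:
                    n_per_metric[m][kind] = config.n_neighbors

    rows: list[dict] = []
    for qi, qid in enumerate(query_ids):
        per_kind: dict[str, list[PredictionResult]] = {k: [] for k in config.models}
        flags: list[bool] = []
        for m in metrics:
            ref_f, q_f = spaces[m]
            qvec = q_f.vectors[qi]
            within, nn_dist = check_ad(qvec, ad_models[m], ref_f)
            flags.append(within)
            k_retrieve = max(config.k_max, config.n_neighbors, max(config.n_grid, default=0))
            nset = find_neighbors(qvec, ref_f, ref_activities, k_retrieve, query_id=qid)

            preds: list[PredictionResult] = []
            if "SA" in config.models:
                preds.append(predict_sa(nset, n_per_metric[m]["SA"]))
            if "SR" in config.models:
                try:
                    preds.append(predict_sr(nset, n_per_metric[m]["SR"]))
                except ValueError:
                    preds.append(_failed(qid, "SR", m))
            if "GP" in config.models:
                try:
                    preds.append(
                        predict_gp(nset, ref_f, k_init=config.gp_k_init, k_max=config.k_max)
                    )
                except ValueError:
                    preds.append(_failed(qid, "GP", m))
            if "LLR" in config.models:
                desc_ref, desc_q = desc_pair
                order, _ = rank_reference(qvec, ref_f, query_id=qid)
                llr_pred, _fit = fit_predict_llr(
                    desc_q.vectors[qi], desc_ref, ref_activities,
                    neighbor_order=order, query_id=qid, metric_name=m,
                    k_min=config.llr_k_min, k_max=config.k_max,
                )
                preds.append(llr_pred)

            for p in preds:
                per_kind[p.model_kind].append(p)
                rows.append(
                    {
                        "query_id": qid,
                        "model_kind": p.model_kind,
                        "metric": m,
                        "prediction": p.value,
                        "k_used": p.k_used,
                        "status": p.status,
                        "neighbors": ";".join(p.neighbor_ids),
                        "nn_distance": nn_dist,
                        "within_ad": within,
                        "consensus_fraction": math.nan,
                    }
                )

        if len(metrics) == 4:
            fraction, reliable = consensus_fraction(flags, config.consensus_threshold)
        else:
            fraction = sum(flags) / len(flags)
            reliable = fraction >= config.consensus_threshold

        all_ok: list[PredictionResult] = []
        for kind in config.models:
            preds = per_kind[kind]
            ok = [p for p in preds if p.status != "failed"]
            all_ok.extend(preds)
            if not ok:
                continue
            cres = consensus(preds, f"{kind}_consensus")
            rows.append(
                {
                    "query_id": qid,
                    "model_kind": cres.kind,
                    "metric": "consensus",
                    "prediction": cres.value,
                    "k_used": cres.n_ok,
                    "status": "degraded" if cres.degraded else "ok",
                    "neighbors": "",
                    "nn_distance": math.nan,
                    "within_ad": reliable,
                    "consensus_fraction": fraction,
                }
            )
        if len(config.models) > 1 and any(p.status != "failed" for p in all_ok):
            cres = consensus([p for p in all_ok], "Final_consensus")
            rows.append(
                {
                    "query_id": qid,
                    "model_kind": "Final_consensus",
                    "metric": "consensus",
                    "prediction": cres.value,
                    "k_used": cres.n_ok,
                    "status": "degraded" if cres.degraded else "ok",
                    "neighbors": "",
                    "nn_distance": math.nan,
                    "within_ad": reliable,
                    "consensus_fraction": fraction,
                }
            )
    return pd.DataFrame(rows)


def evaluate_predictions(
    predictions: pd.DataFrame, observed: dict[str, float], r2_method: str = "pearson"
) -> pd.DataFrame:
    """Score each (model kind, metric) slice of a prediction table.

    Returns rows of n / R^2 / MAE per model, plus within/outside-AD MAE when
    the prediction table carries AD flags.
    """
    from lazytox.evaluation import ad_breakdown, score

    missing = set(predictions["query_id"]) - set(observed)
    if missing:
        raise ValueError(f"no observed activity for {sorted(missing)[:5]}")
    out = []
    grouped = predictions[predictions["status"] != "failed"].groupby(
        ["model_kind", "metric"], sort=False
    )
    for (kind, metric), grp in grouped:
        obs = np.array([observed[q] for q in grp["query_id"]])
        pred = grp["prediction"].to_numpy(dtype=float)
        r2, mae = score(pred, obs, method=r2_method)
        row = {
            "model_kind": kind,
            "metric": metric,
            "n": len(grp),
            "r2": r2,
            "mae": mae,
        }
        if grp["within_ad"].notna().all():
            bd = ad_breakdown(pred, obs, grp["within_ad"].astype(bool).to_numpy())
            row.update(
                {
                    "mae_within": bd["mae_within"],
                    "mae_outside": bd["mae_outside"],
                    "n_within": bd["n_within"],
                }
            )
        out.append(row)
    return pd.DataFrame(out)
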