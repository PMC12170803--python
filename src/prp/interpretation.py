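"""Shapley-value feature attribution for trained models.

Attributions are computed on the log-odds margin (the natural output scale
of tree ensembles) and converted to probability only at export. Tree
ensembles use their exact tree-path Shapley decomposition (the
``pred_contribs`` machinery built into XGBoost/LightGBM); any other model
falls back to a seeded permutation-sampling estimate against a background
sample. In both routes the local-additivity contract holds: base value
plus the sum of contributions equals the model's margin output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from prp.features import apply_preprocessor
from prp.training import TrainedModel

logger = logging.getLogger(__name__)

EXPORT_STYLES = ("bar", "summary", "waterfall", "decision")


@dataclass
class Attribution:
    """Per-variant Shapley decomposition of a model prediction."""

    key: object
    base_value: float  # expected margin (log-odds)
    contributions: dict  # feature -> signed contribution (log-odds units)
    output: float  # final margin
    feature_values: dict  # raw (pre-normalization) feature values

    @property
    def probability(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.output)))


@dataclass
class GlobalImportance:
    """Mean absolute contribution per feature over a dataset."""

    mean_abs: dict
    ranking: list = field(default_factory=list)  # features, descending importance

    def top(self, k: int) -> list:
        return self.ranking[: min(k, len(self.ranking))]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def margin(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Model output on the log-odds scale for preprocessed inputs."""
    est = model.estimator
    if model.algorithm_id == "gbt_xgb_style":
        import xgboost as xgb

        return est.get_booster().predict(xgb.DMatrix(X), output_margin=True)
    if model.algorithm_id == "gbt_hist_style":
        return est.booster_.predict(X, raw_score=True)
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return _logit(est.predict_proba(X)[:, 1])


def _tree_contributions(model: TrainedModel, X: np.ndarray) -> Optional[np.ndarray]:
    """(n, p+1) array of contributions + bias column, or None if unsupported."""
    if model.algorithm_id == "gbt_xgb_style":
        import xgboost as xgb

        return model.estimator.get_booster().predict(
            xgb.DMatrix(X), pred_contribs=True
        )
    if model.algorithm_id == "gbt_hist_style":
        return np.asarray(
            model.estimator.booster_.predict(X, pred_contrib=True)
        )
    return None


def _sampling_contributions(
    model: TrainedModel,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Permutation-sampling Shapley estimate on the margin scale.

    For each random feature ordering, features enter the coalition one by
    one; the marginal change in the mean margin over the background sample
    is that feature's contribution for the ordering. Averaging over
    orderings converges to the Shapley value.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    out = np.zeros((n, p + 1))
    base = float(np.mean(margin(model, background)))
    out[:, p] = base
    for row in range(n):
        x = X[row]
        contrib = np.zeros(p)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            current = background.copy()
            prev_val = float(np.mean(margin(model, current)))
            for j in order:
                current[:, j] = x[j]
                new_val = float(np.mean(margin(model, current)))
                contrib[j] += new_val - prev_val
                prev_val = new_val
        out[row, :p] = contrib / n_permutations
    return out


def explain(
    model: TrainedModel,
    feature_table: pd.DataFrame,
    background: Optional[pd.DataFrame] = None,
    keys: Optional[Sequence] = None,
    n_permutations: int = 20,
    background_size: int = 64,
    seed: int = 0,
    method: str = "auto",
) -> list:
    """Shapley attributions for every row of ``feature_table``.

    ``feature_table`` (and ``background``, defaulting to the table itself)
    hold raw features in the model's canonical order; preprocessing is
    applied internally. Tree models use exact tree-path attribution;
    others a seeded sampling fallback (``method='sampling'`` forces it).
    """
    if tuple(feature_table.columns) != model.feature_names:
        raise ValueError("feature schema mismatch with the trained model")
    if method not in ("auto", "sampling"):
        raise ValueError("method must be 'auto' or 'sampling'")
    X = apply_preprocessor(model.preprocessor, feature_table).to_numpy()
    contribs = _tree_contributions(model, X) if method == "auto" else None
    if contribs is None:
        bg_table = background if background is not None else feature_table
        bg = apply_preprocessor(model.preprocessor, bg_table).to_numpy()
        if len(bg) > background_size:
            rng = np.random.default_rng(seed)
            bg = bg[rng.choice(len(bg), size=background_size, replace=False)]
        contribs = _sampling_contributions(model, X, bg, n_permutations, seed)
    outputs = margin(model, X)
    names = list(model.feature_names)
    attributions = []
    for row in range(len(feature_table)):
        attributions.append(
            Attribution(
                key=keys[row] if keys is not None else feature_table.index[row],
                base_value=float(contribs[row, -1]),
                contributions={
                    name: float(contribs[row, j]) for j, name in enumerate(names)
                },
                output=float(outputs[row]),
                feature_values=dict(feature_table.iloc[row]),
            )
        )
    return attributions


def explain_local(
    model: TrainedModel,
    feature_vector: pd.DataFrame,
    background: Optional[pd.DataFrame] = None,
    **kwargs,
) -> Attribution:
    """Attribution for a single variant (1-row feature table)."""
    return explain(model, feature_vector, background=background, **kwargs)[0]


def global_importance(
    model: TrainedModel,
    feature_table: pd.DataFrame,
    **kwargs,
) -> GlobalImportance:
    """Mean |contribution| per feature, ranked descending."""
    if len(feature_table) == 0:
        raise ValueError("feature table is empty")
    attributions = explain(model, feature_table, **kwargs)
    names = list(model.feature_names)
    mean_abs = {
        name: float(
            np.mean([abs(a.contributions[name]) for a in attributions])
        )
        for name in names
    }
    ranking = sorted(names, key=lambda n: (-mean_abs[n], n))
    return GlobalImportance(mean_abs=mean_abs, ranking=ranking)


def export_explanations(
    attributions: Sequence[Attribution],
    style: str,
    k: int = 20,
) -> pd.DataFrame:
    """Tabular exports of attributions.

    * ``bar``: top-k features by mean |contribution| over the set;
    * ``summary``: long table (key, feature, raw value, contribution);
    * ``waterfall``: per-variant rows ordered by |contribution| descending,
      raw feature values attached;
    * ``decision``: per-variant cumulative path from base value to final
      output, with the probability-scale conversion of each step.
    """
    if style not in EXPORT_STYLES:
        raise ValueError(f"unknown style {style!r}; expected one of {EXPORT_STYLES}")
    if not attributions:
        raise ValueError("no attributions to export")
    names = list(attributions[0].contributions)

    if style == "bar":
        mean_abs = {
            n: float(np.mean([abs(a.contributions[n]) for a in attributions]))
            for n in names
        }
        rows = sorted(mean_abs.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            rows[: min(k, len(rows))], columns=["feature", "mean_abs_contribution"]
        )

    if style == "summary":
        rows = [
            {
                "key": str(a.key),
                "feature": n,
                "value": a.feature_values.get(n),
                "contribution": a.contributions[n],
            }
            for a in attributions
            for n in names
        ]
        return pd.DataFrame(rows)

    if style == "waterfall":
        rows = []
        for a in attributions:
            ordered = sorted(
                names, key=lambda n: (-abs(a.contributions[n]), n)
            )
            for rank, n in enumerate(ordered, 1):
                rows.append(
                    {
                        "key": str(a.key),
                        "rank": rank,
                        "feature": n,
                        "value": a.feature_values.get(n),
                        "contribution": a.contributions[n],
                        "base_value": a.base_value,
                        "output": a.output,
                    }
                )
        return pd.DataFrame(rows)

    # decision: cumulative path, most important feature applied last so the
    # plot fans out from the base value
    rows = []
    for a in attributions:
        ordered = sorted(names, key=lambda n: (abs(a.contributions[n]), n))
        cumulative = a.base_value
        for n in ordered:
            cumulative += a.contributions[n]
            rows.append(
                {
                    "key": str(a.key),
                    "feature": n,
                    "value": a.feature_values.get(n),
                    "cumulative_logodds": cumulative,
                    "cumulative_probability": float(
                        1.0 / (1.0 + np.exp(-cumulative))
                    ),
                }
            )
    return pd.DataFrame(rows)
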