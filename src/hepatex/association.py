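"""Elastic-net association of texture features with clinical chemistry.

For each selected texture feature the 13 clinical predictors (age, race,
sex, WBC, BUN, creatinine, total bilirubin, albumin, AST, ALT, platelet
count, MELD, cirrhosis) are entered into an elastic-net regression with
the texture feature as outcome.  The mixing parameter and penalty
strength are chosen by cross-validated RMSE over a grid; the predictor
with the largest absolute standardized coefficient at the optimum is the
feature's "top predictor".  Because penalized coefficients are shrunk, a
debiasing refit follows: the top predictor alone enters an ordinary
least-squares model, whose slope and two-sided t-test p-value are
reported.  P-values across the family of texture features are adjusted by
the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .io import CLINICAL_PREDICTORS
from .manifest import FEATURE_NAMES

__all__ = [
    "AssociationRecord",
    "ElasticNetFit",
    "NONE_PREDICTOR",
    "fit_elastic_net",
    "debiased_fit",
    "bh_fdr",
    "associate_all",
    "encode_predictors",
]

logger = logging.getLogger(__name__)

#: Sentinel top predictor when the elastic net shrinks everything to zero.
NONE_PREDICTOR = "none"

DEFAULT_L1_RATIOS: tuple[float, ...] = tuple(
    round(0.1 * k, 1) for k in range(1, 11)
)

NAN = float("nan")


@dataclass(frozen=True)
class ElasticNetFit:
    """Optimum of the cross-validated elastic-net grid for one outcome."""

    coefficients: dict[str, float]  # standardized coefs per design column
    elastic_rmse: float             # CV RMSE at the selected (l1_ratio, alpha)
    top_predictor: str              # parent clinical predictor or "none"
    top_column: str | None          # winning design column (one-hot level)
    l1_ratio: float
    alpha: float


@dataclass(frozen=True)
class AssociationRecord:
    """One row of the association report (one texture feature)."""

    texture_feature: str
    elastic_rmse: float
    top_predictor: str
    linear_coefficient: float
    p_value: float
    fdr_p: float
    testable: bool = True


def encode_predictors(
    clinical: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """One-hot encode categorical predictors; returns (design, column->parent).

    The largest category of each categorical predictor is the (dropped)
    reference level.
    """
    missing = [c for c in CLINICAL_PREDICTORS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing predictor(s) {missing}")
    cols: dict[str, np.ndarray] = {}
    parent: dict[str, str] = {}
    for name in CLINICAL_PREDICTORS:
        series = clinical[name]
        if name in ("race", "sex"):
            counts = series.value_counts()
            reference = counts.index[0]
            for level in sorted(c for c in counts.index if c != reference):
                col = f"{name}[{level}]"
                cols[col] = (series == level).to_numpy(dtype=float)
                parent[col] = name
        else:
            cols[name] = series.to_numpy(dtype=float)
            parent[name] = name
    design = pd.DataFrame(cols, index=clinical.index)
    return design, parent


def fit_elastic_net(
    y: np.ndarray,
    X: pd.DataFrame,
    cv_folds: int = 10,
    seed: int = 0,
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS,
    n_alphas: int = 50,
    alphas: list[float] | None = None,
) -> ElasticNetFit:
    """Cross-validated elastic net of one texture outcome on the predictors.

    ``X`` holds the raw clinical predictor columns (categoricals included);
    predictors are one-hot encoded and standardized to zero mean / unit
    variance internally, so coefficient magnitudes are comparable across
    predictors.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("y and X must have the same number of subjects")
    design, parent = encode_predictors(X)
    mu = design.mean(axis=0)
    sd = design.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "dropping zero-variance predictor column(s) %s",
            list(design.columns[~keep]),
        )
    Z = (design.loc[:, keep] - mu[keep]) / sd[keep]
    folds = min(cv_folds, len(y))
    model = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        # int: length of the automatic path; list: explicit penalty grid
        alphas=alphas if alphas is not None else n_alphas,
        cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
        max_iter=5000,
    )
    model.fit(Z.to_numpy(), y)
    # CV RMSE at the selected point of the (l1_ratio, alpha) grid
    li = int(np.argmin(np.abs(np.asarray(model.l1_ratio) - model.l1_ratio_)))
    ai = int(np.argmin(np.abs(model.alphas_[li] - model.alpha_)))
    elastic_rmse = float(np.sqrt(model.mse_path_[li, ai].mean()))
    coefs = dict(zip(Z.columns, model.coef_))
    if not any(abs(c) > 1e-12 for c in coefs.values()):
        logger.info("elastic net shrank all coefficients to zero")
        return ElasticNetFit(
            coefficients=coefs,
            elastic_rmse=elastic_rmse,
            top_predictor=NONE_PREDICTOR,
            top_column=None,
            l1_ratio=float(model.l1_ratio_),
            alpha=float(model.alpha_),
        )
    top_column = max(coefs, key=lambda c: abs(coefs[c]))
    return ElasticNetFit(
        coefficients=coefs,
        elastic_rmse=elastic_rmse,
        top_predictor=parent[top_column],
        top_column=top_column,
        l1_ratio=float(model.l1_ratio_),
        alpha=float(model.alpha_),
    )


def debiased_fit(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Unpenalized univariate OLS of y on x (with intercept).

    Returns the slope in the outcome's raw units per unit of x and the
    two-sided t-test p-value on the slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        raise ValueError("debiased fit needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("top predictor is constant; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    adj_(k) = min_{m >= k} ( p_(m) * n / m ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _design_column_values(
    clinical: pd.DataFrame, fit: ElasticNetFit
) -> np.ndarray:
    design, _ = encode_predictors(clinical)
    assert fit.top_column is not None
    return design[fit.top_column].to_numpy()


def associate_all(
    selected: pd.DataFrame,
    clinical: pd.DataFrame,
    seed: int = 0,
    cv_folds: int = 10,
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS,
    n_alphas: int = 50,
) -> list[AssociationRecord]:
    """Run the full association stage for every selected texture feature.

    Both tables are indexed by subject_id and must match exactly.  The BH
    family is exactly the set of testable features (non-degenerate texture
    column with a non-"none" top predictor); degenerate features are
    reported flagged, outside the family.  Records come back in canonical
    manifest order.
    """
    if set(selected.index) != set(clinical.index):
        raise ValueError("subject ids of feature and clinical tables differ")
    clinical = clinical.loc[selected.index]
    order = {name: k for k, name in enumerate(FEATURE_NAMES)}
    columns = sorted(selected.columns, key=lambda c: order.get(c, len(order)))

    seeds = np.random.SeedSequence(seed).spawn(len(columns))
    partial: list[dict] = []
    for col, ss in zip(columns, seeds):
        y = selected[col].to_numpy(dtype=float)
        if np.ptp(y[np.isfinite(y)]) == 0 or not np.all(np.isfinite(y)):
            logger.warning(
                "texture feature %r is degenerate (constant or non-finite); "
                "excluded from the FDR family", col,
            )
            partial.append(dict(
                texture_feature=col, elastic_rmse=NAN,
                top_predictor=NONE_PREDICTOR, linear_coefficient=NAN,
                p_value=NAN, testable=False,
            ))
            continue
        fit = fit_elastic_net(
            y, clinical, cv_folds=cv_folds,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            l1_ratios=l1_ratios, n_alphas=n_alphas,
        )
        if fit.top_predictor == NONE_PREDICTOR:
            partial.append(dict(
                texture_feature=col, elastic_rmse=fit.elastic_rmse,
                top_predictor=NONE_PREDICTOR, linear_coefficient=NAN,
                p_value=NAN, testable=False,
            ))
            continue
        x = _design_column_values(clinical, fit)
        coef, p = debiased_fit(y, x)
        partial.append(dict(
            texture_feature=col, elastic_rmse=fit.elastic_rmse,
            top_predictor=fit.top_predictor, linear_coefficient=coef,
            p_value=p, testable=True,
        ))

    testable = [r for r in partial if r["testable"]]
    adjusted = bh_fdr([r["p_value"] for r in testable])
    fdr_map = {
        r["texture_feature"]: float(a) for r, a in zip(testable, adjusted)
    }
    return [
        AssociationRecord(fdr_p=fdr_map.get(r["texture_feature"], NAN), **r)
        for r in partial
    ]


def association_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Association records as the report CSV layout."""
    return pd.DataFrame(
        [
            {
                "texture_feature": r.texture_feature,
                "elastic_rmse": r.elastic_rmse,
                "top_predictor": r.top_predictor,
                "linear_coefficient": r.linear_coefficient,
                "p_value": r.p_value,
                "fdr_p": r.fdr_p,
            }
            for r in records
        ]
    )
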