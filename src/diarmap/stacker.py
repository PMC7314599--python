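"""Stacked generalisation of component learners for cluster prevalence.

Component learners (a penalized linear model, a boosted tree ensemble, and an
additive spline model) are fit to cluster-level prevalence against the retained
covariates.  Their out-of-sample (OOS) predictions — produced under a
source-stratified K-fold split so a record is never predicted by a model that
saw its own source — become candidate covariates for the geostatistical model,
and full-data refits supply the prediction surface for every cell-year.

The linear and spline learners regress the empirical logit of cluster
prevalence with weights ``n_children``; the tree ensemble is a classifier fit
on case/non-case expanded weights.  Predictions are clamped to
[1e-6, 1 - 1e-6] so downstream logits are always finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer

from .worldgen import World, survey_cell_index

__all__ = [
    "StackResult",
    "StackingError",
    "LEARNER_FAMILIES",
    "fit_stack",
    "assign_folds",
    "empirical_logit",
]

PROB_CLAMP = 1e-6
LOGIT_ADJUST = 0.5  # empirical-logit shrinkage constant


class StackingError(RuntimeError):
    """Every component learner failed."""


def empirical_logit(cases: np.ndarray, children: np.ndarray,
                    adjust: float = LOGIT_ADJUST) -> np.ndarray:
    return np.log((cases + adjust) / (children - cases + adjust))


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)


@dataclass
class StackResult:
    learner_names: list[str]
    oos: pd.DataFrame  # per-record OOS prediction per learner, index = record index
    folds: np.ndarray  # fold id per record
    surfaces: dict[str, np.ndarray]  # learner -> (ncells, nyears), full-data fit
    covariate_names: list[str]
    # cross-fitted surfaces: mean over the K fold models' predictions; these
    # carry less memorisation of individual clusters than the full-data refit
    # and are what the geostatistical model uses as its fixed-effect offset
    cv_surfaces: dict[str, np.ndarray] | None = None

    def oos_matrix(self) -> np.ndarray:
        return self.oos[self.learner_names].to_numpy()

    def surface_matrix(self, cross_fitted: bool = False) -> np.ndarray:
        """Stacked learner surfaces, shape (ncells, nyears, n_learners)."""
        source = self.cv_surfaces if (cross_fitted and self.cv_surfaces) else self.surfaces
        return np.stack([source[n] for n in self.learner_names], axis=-1)


class _RateLearner:
    """Weighted regression on the empirical logit of cluster prevalence."""

    def __init__(self, model_factory):
        self._factory = model_factory
        self._model = None
        self._pooled = None

    def fit(self, x, cases, children):
        y = empirical_logit(cases, children)
        if np.ptp(y) == 0.0:  # degenerate outcome: constant predictor
            self._pooled = float(
                (cases.sum() + LOGIT_ADJUST) / (children.sum() + 2 * LOGIT_ADJUST)
            )
            return self
        self._model = self._factory()
        self._model.fit(x, y, **_weight_kwargs(self._model, children))
        return self

    def predict(self, x):
        if self._pooled is not None:
            return _clamp(np.full(x.shape[0], self._pooled))
        return _clamp(expit(self._model.predict(x)))


def _weight_kwargs(model, children):
    # pipelines need the step-prefixed parameter name
    if hasattr(model, "steps"):
        final = model.steps[-1][0]
        return {f"{final}__sample_weight": children.astype(float)}
    return {"sample_weight": children.astype(float)}


class _TreeLearner:
    """Boosted classification trees on case/non-case expanded weights."""

    def __init__(self, seed: int):
        self._seed = seed
        self._model = None
        self._pooled = None

    def fit(self, x, cases, children):
        if cases.sum() == 0 or (children - cases).sum() == 0:
            self._pooled = float(
                (cases.sum() + LOGIT_ADJUST) / (children.sum() + 2 * LOGIT_ADJUST)
            )
            return self
        xx = np.vstack([x, x])
        yy = np.concatenate([np.ones(len(x)), np.zeros(len(x))])
        ww = np.concatenate([cases, children - cases]).astype(float)
        keep = ww > 0
        # deliberately conservative settings: cluster rates are noisy binomial
        # observations and an unconstrained boosted ensemble will memorise
        # individual cells through their covariate fingerprints
        self._model = GradientBoostingClassifier(
            n_estimators=60, max_depth=2, learning_rate=0.1,
            subsample=0.8, min_samples_leaf=20, random_state=self._seed,
        )
        self._model.fit(xx[keep], yy[keep], sample_weight=ww[keep])
        return self

    def predict(self, x):
        if self._pooled is not None:
            return _clamp(np.full(x.shape[0], self._pooled))
        return _clamp(self._model.predict_proba(x)[:, 1])


def _make_learner(name: str, seed: int):
    if name == "penalized-linear":
        return _RateLearner(lambda: Ridge(alpha=1.0))
    if name == "spline-additive":
        return _RateLearner(
            lambda: make_pipeline(
                SplineTransformer(n_knots=5, degree=3), Ridge(alpha=1.0)
            )
        )
    if name == "tree-ensemble":
        return _TreeLearner(seed)
    raise ValueError(f"unknown learner family {name!r}")


LEARNER_FAMILIES = ("penalized-linear", "tree-ensemble", "spline-additive")


def assign_folds(source_ids: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Random fold per record, stratified so whole sources stay together."""
    rng = np.random.default_rng(seed)
    sources = np.unique(source_ids)
    perm = rng.permutation(len(sources))
    fold_of_source = {
        s: int(perm[i] % n_folds) for i, s in enumerate(sources)
    }
    return np.array([fold_of_source[s] for s in source_ids])


def fit_stack(
    records: pd.DataFrame,
    world: World,
    covariate_names: list[str],
    n_folds: int = 5,
    learners: tuple[str, ...] = LEARNER_FAMILIES,
    seed: int = 0,
) -> StackResult:
    """Fit component learners and produce OOS + full-surface predictions.

    ``records`` must be point records (polygon records should be resampled
    first).  OOS predictions for a record always come from a fit that excluded
    that record's fold; surfaces come from full-data refits.
    """
    if len(learners) == 0:
        raise StackingError("no learners configured")
    if len(records) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} records")
    if (records["geometry_kind"] != "point").any():
        raise ValueError("fit_stack requires point records; resample polygons first")

    cell = survey_cell_index(records, world.grid)
    year_idx = np.array([world.year_index(int(y)) for y in records["year"]])
    covs = world.covariate_matrix(covariate_names)  # (ncells, nyears, p)
    x = covs[cell, year_idx, :]
    cases = records["n_cases"].to_numpy()
    children = records["n_children"].to_numpy()
    folds = assign_folds(records["source_id"].to_numpy(), n_folds, seed)

    oos = {}
    surfaces = {}
    cv_surfaces = {}
    kept = []
    x_all = covs.reshape(-1, covs.shape[-1])
    for li, name in enumerate(learners):
        # seed by family, not list position: duplicated learner entries must
        # produce byte-identical prediction columns
        lseed = seed + 1000 * (LEARNER_FAMILIES.index(name) + 1)
        try:
            preds = np.full(len(records), np.nan)
            fold_surfs = []
            for f in range(n_folds):
                hold = folds == f
                model = _make_learner(name, lseed)
                model.fit(x[~hold], cases[~hold], children[~hold])
                if hold.any():
                    preds[hold] = model.predict(x[hold])
                fold_surfs.append(model.predict(x_all))
            full = _make_learner(name, lseed)
            full.fit(x, cases, children)
            surface = full.predict(x_all).reshape(covs.shape[:2])
            cv_surface = _clamp(np.mean(fold_surfs, axis=0)).reshape(covs.shape[:2])
        except Exception as err:  # learner failure: drop it, keep going
            warnings.warn(f"learner {name!r} dropped: {err}", stacklevel=2)
            continue
        key = name if name not in oos else f"{name}#{li}"
        oos[key] = preds
        surfaces[key] = surface
        cv_surfaces[key] = cv_surface
        kept.append(key)
    if not kept:
        raise StackingError("all learners failed")
    return StackResult(
        learner_names=kept,
        oos=pd.DataFrame(oos, index=records.index),
        folds=folds,
        surfaces=surfaces,
        covariate_names=list(covariate_names),
        cv_surfaces=cv_surfaces,
    )
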