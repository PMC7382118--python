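"""End-to-end orchestration: simulate/segment -> featurise -> select ->
fit LDA and QDA -> evaluate, as one reproducible, logged run.

Every stochastic step draws from the single config seed, so an identical
config yields a byte-identical feature CSV and report JSON.  The report
carries, per stage, the parameters used (including the per-image Otsu
thresholds) plus both classifiers' resubstitution confusion matrices and
their cross-validated rates, labelled as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .discriminant import GaussianDiscriminant, cross_validate
from .featurize import CANDIDATE_FEATURES, featurize_masks
from .preprocessing import segment_image
from .selection import ForwardDiscriminantSelector
from .synthetic import generate_dataset

logger = logging.getLogger("carrotshape")

__all__ = ["RunConfig", "run_pipeline"]

CLASS_LABELS = {"regular": 1, "irregular": 2}


@dataclass
class RunConfig:
    """Parameters of one pipeline run on the synthetic fixture."""

    n_regular: int = 56
    n_irregular: int = 79
    seed: int = 2020
    cv_seed: int | None = None      # fold shuffling; defaults to seed
    noise_sigma: float | None = None  # None -> generator default
    threshold: str | int = "otsu"
    n_parts: int = 7
    n_folds: int = 5
    classifiers: tuple = ("linear", "quadratic")
    select: bool = True
    outdir: str | None = None

    def resolved_cv_seed(self):
        return self.seed if self.cv_seed is None else self.cv_seed


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config=None, samples=None, truth_table=None):
    """Run the full grading pipeline and return (report, features, models).

    With no ``samples``, the synthetic fixture defined by the config is
    generated first.  ``report`` is a JSON-serialisable dict; ``features``
    the labelled feature DataFrame; ``models`` maps classifier kind to its
    fitted :class:`GaussianDiscriminant`.
    """
    config = config or RunConfig()
    if samples is None:
        logger.info(
            "simulate: %d regular + %d irregular, seed %d",
            config.n_regular, config.n_irregular, config.seed,
        )
        samples, truth_table = generate_dataset(
            config.n_regular, config.n_irregular, seed=config.seed,
            noise_sigma=config.noise_sigma,
        )
    names = list(truth_table.index)
    y = truth_table["shape_class"].map(CLASS_LABELS).to_numpy()

    masks, thresholds = [], []
    for name, sample in zip(names, samples):
        try:
            mask, t = segment_image(sample.image, threshold=config.threshold)
        except Exception as exc:  # annotate with stage + sample id
            raise type(exc)(f"segment[{name}]: {exc}") from exc
        logger.debug("segment[%s]: otsu threshold %.2f", name, t)
        masks.append(mask)
        thresholds.append(round(t, 4))

    features = featurize_masks(masks, n_parts=config.n_parts, index=names)
    features.insert(0, "label", y)

    X = features[list(CANDIDATE_FEATURES)]
    cv_seed = config.resolved_cv_seed()
    if config.select:
        selector = ForwardDiscriminantSelector(
            kind="quadratic", n_folds=config.n_folds, seed=cv_seed
        ).fit(X, y)
        selected = selector.selected_
        selection_report = selector.result_.to_dict()
        logger.info("select: %d features %s", len(selected), selected)
    else:
        selected = list(CANDIDATE_FEATURES)
        selection_report = {"selected": selected, "trajectory": [],
                            "scheme": None}

    Xs = X[selected]
    models, model_reports = {}, {}
    for kind in config.classifiers:
        model = GaussianDiscriminant(kind=kind).fit(Xs, y)
        resub = model.evaluate(Xs, y)
        cv = cross_validate(Xs, y, kind=kind, scheme="kfold",
                            n_folds=config.n_folds, seed=cv_seed)
        logger.info("%s: resubstitution CCR %.2f%%, %d-fold CV CCR %.2f%%",
                    kind, resub.ccr, config.n_folds, cv.ccr)
        models[kind] = model
        model_reports[kind] = {
            "resubstitution": resub.to_dict(),
            "cv": {"scheme": f"stratified {config.n_folds}-fold",
                   "seed": cv_seed, "ccr": cv.ccr,
                   "confusion": cv.confusion.to_dict()},
        }

    report = _jsonify({
        "version": __version__,
        "config": asdict(config),
        "stages": {
            "segment": {"threshold_method": config.threshold,
                        "thresholds": thresholds},
            "features": {"n_samples": len(names),
                         "columns": list(features.columns)},
            "selection": selection_report,
        },
        "class_labels": CLASS_LABELS,
        "models": model_reports,
    })

    if config.outdir:
        import os

        os.makedirs(config.outdir, exist_ok=True)
        features.to_csv(os.path.join(config.outdir, "features.csv"))
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        for kind, model in models.items():
            model.save(os.path.join(config.outdir, f"model_{kind}.json"))

    return report, features, models
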