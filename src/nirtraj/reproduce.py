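"""End-to-end reproduction pipeline for the two published NIR datasets.

The study's headline numbers were produced with toolbox settings that are
not on record (interval count, CV scheme, ensemble size), so reproduction
is a tolerance-band exercise: this module runs the full trajectory over a
sweep of the unstated settings and reports, per sweep point, the best path
and the stepwise baseline. Numbers are expected to land within roughly
+/-15% of the published RMSEP/RPD values, not to match them exactly.

The datasets themselves (the 310 x 404 tablet set, public at
models.life.ku.dk/Tablets, and the 216 x 2,800 honeysuckle-extract set)
are not redistributed with this package; place them as CSVs in the
package's I/O dialect (see :func:`nirtraj.dataset.read_dataset`) and point
:func:`reproduce_study` at them.
"""

from __future__ import annotations

from dataclasses import replace

from .bagging import BaggingConfig
from .dataset import SpectralDataset, crop_region, kennard_stone_split
from .pls import CVConfig
from .trajectory import Trajectory, TrajectoryConfig

__all__ = ["reproduce_study", "DEFAULT_SWEEP"]

# sweep of the settings the original analysis never recorded
DEFAULT_SWEEP = {
    "n_intervals": (10, 20, 40),
    "n_models": (25, 50, 100),
    "folds": (5, "loo"),
}


def _run_one(train, validation, n_intervals, n_models, folds, seed):
    n = train.n_samples
    cv = CVConfig(folds=n if folds == "loo" else folds, shuffle=True, seed=seed)
    config = TrajectoryConfig(
        n_intervals=n_intervals,
        cv=cv,
        bagging=BaggingConfig(n_models=n_models),
        seed=seed,
    )
    report = Trajectory(train, validation, config).run()
    return {
        "n_intervals": n_intervals,
        "n_models": n_models,
        "folds": folds,
        "best_path": report.best.spec.key if report.best else None,
        "best_rmsep": report.best.metrics.rmsep if report.best else None,
        "best_rpd": report.best.metrics.rpd if report.best else None,
        "n_good": report.class_counts["good"],
        "n_very_good": report.class_counts["very_good"],
        "stepwise_path": report.stepwise_baseline.spec.key,
        "stepwise_rmsep": report.stepwise_baseline.metrics.rmsep
        if report.stepwise_baseline.ok
        else None,
        "stepwise_rpd": report.stepwise_baseline.metrics.rpd
        if report.stepwise_baseline.ok
        else None,
    }


def reproduce_study(
    tablet: SpectralDataset | None = None,
    lonicera: SpectralDataset | None = None,
    sweep: dict = DEFAULT_SWEEP,
    seed: int = 0,
) -> dict:
    """Run the trajectory sweep on one or both study datasets.

    The tablet set is Kennard-Stone split 207/103; the extract set is
    cropped to 1,100-1,900 nm first and split 144/72. Returns
    ``{dataset_name: [one row per sweep point]}``.
    """
    jobs = {}
    if tablet is not None:
        jobs["tablet"] = kennard_stone_split(tablet, 207)
    if lonicera is not None:
        cropped = crop_region(lonicera, 1100.0, 1900.0)
        jobs["lonicera"] = kennard_stone_split(cropped, 144)
    if not jobs:
        raise ValueError("pass at least one dataset")
    out = {}
    for name, split in jobs.items():
        rows = []
        for n_intervals in sweep["n_intervals"]:
            for n_models in sweep["n_models"]:
                for folds in sweep["folds"]:
                    rows.append(
                        _run_one(
                            split.train, split.validation,
                            n_intervals, n_models, folds, seed,
                        )
                    )
        out[name] = rows
    return out
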