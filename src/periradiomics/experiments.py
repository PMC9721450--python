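"""Benchmark experiments on phantom cohorts.

These are the package's headline computations, bundled so they can be
re-run reproducibly from one seed: the clinical-table statistics, the
region-comparison study on phantoms with peritumoral signal (does the
combined tumour+rim model beat the tumour-only model?), the chance
check on signal-free phantoms, the label-permutation leakage guard,
and the small-CNN capacity / class-activation-map study.

Each function derives its own sub-seeds from the seed it is given, so
different experiments never share random streams.
"""

from __future__ import annotations

import numpy as np

from . import clinstats, evaluation, study
from .cnn import CNNConfig, TinyCNNClassifier, region_crop
from .phantom import PhantomConfig, generate_dataset
from .regions import build_region_set

__all__ = [
    "chi_square_statistics",
    "signal_recovery_study",
    "null_chance_study",
    "leakage_guard",
    "cnn_capacity_and_cam",
]


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
               % (2 ** 31 - 1))


def chi_square_statistics() -> dict[str, dict]:
    """Chi-square statistics of the packaged NSNCM cohort tables."""
    out = {}
    for name, table in clinstats.NSNCM_COHORT_TABLES.items():
        res = clinstats.chi_square(table)
        out[name] = {"chi2": res.chi2, "p": res.p, "df": res.df,
                     "n": int(table.counts.sum())}
    return out


def signal_recovery_study(seed: int, n_patients: int = 200,
                          n_seeds: int = 5) -> dict[str, float]:
    """Tumoral vs combined-2mm radiomics models on rim-signal phantoms.

    Runs the cross-validated study on ``n_seeds`` independent phantom
    cohorts drawn at the generator's default class-texture contrasts
    (core and rim both active) and averages the mean-over-test-sets
    AUCs. Mirrors the region-comparison question: do peritumoral
    features add discriminative information over the tumour alone?
    """
    acc: dict[str, list[float]] = {}
    for k in range(n_seeds):
        s = _subseed(seed, k)
        cfg = PhantomConfig(n_patients=n_patients, seed=s)
        cases = generate_dataset(cfg)
        table = study.extract_feature_table(
            cases, distances_mm=[2.0], kinds=("tumoral", "combined"))
        res = study.run_study(table, distances_mm=[2.0], seed=s)
        for row in res.summary.itertuples():
            acc.setdefault(f"{row.model}_{row.level}", []).append(
                float(row.auc_mean))
    out = {name: float(np.mean(v)) for name, v in acc.items()}
    out["combined_minus_tumoral_roi"] = \
        out["combined_2mm_roi"] - out["tumoral_roi"]
    out["combined_minus_tumoral_patient"] = \
        out["combined_2mm_patient"] - out["tumoral_patient"]
    out["n_seeds"] = n_seeds
    out["n_patients"] = n_patients
    return out


def null_chance_study(seed: int, n_patients: int = 400) -> dict[str, float]:
    """All 11 region models on a signal-free phantom cohort.

    With ``core_effect = rim_effect = 0`` the classes are statistically
    identical; every cross-validated AUC must sit in the chance band.
    The cohort is larger than the signal studies (800 lesions) because
    the check bounds the *maximum* deviation from 0.5 across 11
    correlated models: per-model AUC noise must be well inside the
    band.
    """
    s = _subseed(seed, 101)
    cfg = PhantomConfig(n_patients=n_patients, core_effect=0.0,
                        rim_effect=0.0, seed=s)
    cases = generate_dataset(cfg)
    table = study.extract_feature_table(cases)
    res = study.run_study(table, seed=s)
    roi = res.summary[res.summary.level == "roi"]
    return {
        "auc_min": float(roi.auc_mean.min()),
        "auc_max": float(roi.auc_mean.max()),
        "n_models": int(len(roi)),
        "n_patients": n_patients,
    }


def leakage_guard(seed: int, n_patients: int = 100) -> dict[str, float]:
    """Label-permutation control on a cohort with real signal.

    The full pipeline (correlation filter, standardisation, penalty
    choice) is re-run after permuting patient labels; any residual AUC
    above chance would reveal information leaking across CV folds.
    """
    s = _subseed(seed, 202)
    cfg = PhantomConfig(n_patients=n_patients, core_effect=0.5,
                        rim_effect=0.5, seed=s)
    cases = generate_dataset(cfg)
    table = study.extract_feature_table(
        cases, distances_mm=[2.0], kinds=("tumoral", "combined"))
    res = study.run_study(table, distances_mm=[2.0], seed=s,
                          permute_labels=True)
    roi = res.summary[res.summary.level == "roi"]
    return {"auc_min": float(roi.auc_mean.min()),
            "auc_max": float(roi.auc_mean.max()),
            "n_patients": n_patients}


def _crops_and_supports(cases, distance_mm=2.0, input_size=64):
    crops, supports, labels = [], [], []
    for case in cases:
        img, mask = case.image, case.mask
        rs = build_region_set(img, mask, distances_mm=[distance_mm])
        crop, sup = region_crop(img.pixels, rs.combineds[distance_mm],
                                input_size, return_support=True)
        crops.append(crop)
        supports.append(sup)
        labels.append(img.label)
    return np.array(crops), np.array(supports), np.array(labels)


def cnn_capacity_and_cam(seed: int, n_cam_patients: int = 30
                         ) -> dict[str, float]:
    """Small-CNN overfit capacity and CAM localisation.

    Capacity: the tiny variant must reach training accuracy 1.0 on a
    16-image strong-signal subset within its 100-epoch budget. CAM:
    after training on rim-signal crops, the class-activation map
    should concentrate inside the combined-region support (pixels
    outside the region were zeroed at input).
    """
    s = _subseed(seed, 303)
    cfg16 = PhantomConfig(n_patients=8, core_effect=1.0, rim_effect=1.0,
                          seed=s)
    X16, _, y16 = _crops_and_supports(generate_dataset(cfg16))
    clf = TinyCNNClassifier(CNNConfig.tiny(epochs=100, seed=0)).fit(X16, y16)
    train_acc = float((clf.predict(X16) == y16).mean())

    cam_cfg = PhantomConfig(n_patients=n_cam_patients, core_effect=0.0,
                            rim_effect=1.0, seed=_subseed(seed, 304))
    Xc, Sc, yc = _crops_and_supports(generate_dataset(cam_cfg))
    cam_clf = TinyCNNClassifier(
        CNNConfig.tiny(epochs=40, seed=0)).fit(Xc, yc)
    inside, outside = [], []
    for x, sup in zip(Xc, Sc):
        cam = cam_clf.cam(x)
        inside.append(float(cam[sup].mean()))
        outside.append(float(cam[~sup].mean()))
    return {
        "train_accuracy_16": train_acc,
        "cam_inside_mean": float(np.mean(inside)),
        "cam_outside_mean": float(np.mean(outside)),
        "n_cam_images": int(len(Xc)),
    }
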