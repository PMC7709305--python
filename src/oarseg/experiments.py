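"""Six-fold cross-validated experiment designs on phantom cohorts.

Each experiment varies exactly one factor of a common base setup — training
set size, augmentation count/mode, cost function, inference windowing, or
ensembling — holding folds and model-initialisation seeds fixed across arms
so the factor is the only thing that changes.  Every case appears in exactly
one test fold, augmented copies inherit the fold of their source case (no
train/test leakage), and results are pooled over all folds before
aggregation.

Reported aggregates are mean and sample SD (n-1 denominator) of the
Sørensen–Dice coefficient and the Hausdorff distance over all test cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .augment import (DomainAugParams, TraditionalAugParams,
                      domain_specific_augment, traditional_augment)
from .core import ROISpec, SegCase, ValidationError, default_roi_spec, HUWindow
from .ensemble import majority_cutoff, sweep_cutoffs, threshold_votes, vote
from .losses import LossSpec
from .metrics import UndefinedMetricError, hausdorff_3d, sdc
from .phantom import PhantomConfig
from .preprocess import preprocess_case
from .trainer import ModelConfig, TrainConfig, build_model, predict, train
from .windowing import WindowGrid, coarse_grid, search_best_window

__all__ = [
    "FoldPlan", "ExperimentResult", "make_folds", "aggregate", "format_summary",
    "desk_scale_setup", "run_set_size_experiment", "run_augmentation_experiment",
    "run_cost_function_experiment", "run_ensemble_experiment",
    "run_combined_experiment",
]


@dataclass(frozen=True)
class FoldPlan:
    """k-fold partition: disjoint test folds covering every case once; each
    train set is the complement of its test fold."""

    folds: tuple  # of (train_ids, test_ids) tuples
    seed: int
    k: int = 6


@dataclass(frozen=True)
class ExperimentResult:
    """Per-case metric rows (one per test evaluation) plus metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def make_folds(case_ids: Sequence[str], seed: int, k: int = 6) -> FoldPlan:
    """Random balanced partition into k test folds, deterministic by seed."""
    ids = list(case_ids)
    if len(ids) < k:
        raise ValidationError(f"need at least {k} cases for {k}-fold CV, got {len(ids)}")
    perm = np.random.default_rng(seed).permutation(len(ids))
    chunks = np.array_split(perm, k)
    folds = []
    for chunk in chunks:
        test = tuple(ids[i] for i in chunk)
        test_set = set(test)
        trainset = tuple(i for i in ids if i not in test_set)
        folds.append((trainset, test))
    return FoldPlan(folds=tuple(folds), seed=seed, k=k)


def aggregate(result: ExperimentResult | pd.DataFrame) -> dict:
    """Pooled mean and sample SD (ddof=1) of SDC and HD over all rows of all
    folds combined; single-row inputs report SD 0 with an ``n=1`` flag."""
    df = result.table if isinstance(result, ExperimentResult) else result
    if len(df) < 1:
        raise ValidationError("cannot aggregate an empty result")
    n = len(df)
    ddof = 1 if n > 1 else 0
    out = {
        "n": n,
        "mean_sdc": float(df["sdc"].mean()),
        "sd_sdc": float(df["sdc"].std(ddof=ddof)) if n > 1 else 0.0,
        "mean_hd": float(df["hd"].mean(skipna=True)),
        "sd_hd": float(df["hd"].std(ddof=ddof)) if n > 1 else 0.0,
    }
    if n == 1:
        out["single_row"] = True
    return out


def format_summary(agg: dict) -> str:
    """Table-style formatting: SDC to two decimals, HD to one."""
    return (f"SDC {agg['mean_sdc']:.2f} ± {agg['sd_sdc']:.2f}, "
            f"HD {agg['mean_hd']:.1f} ± {agg['sd_hd']:.1f} (n={agg['n']})")


def desk_scale_setup(organ: str = "SMG"):
    """Shared desk-scale preset: small phantom grid (32x32x16), a 12x12x8
    ROI crop, an 8-filter depth-2 network with 0.1 dropout, and Adam at 1e-3
    with the standard early-stopping rule.  Full six-fold designs with these
    sizes run in seconds-to-minutes on one CPU."""
    phantom_cfg = PhantomConfig.desk_scale(organ)
    spec = default_roi_spec(organ, crop_shape=(12, 12, 8))
    model_cfg = ModelConfig(input_shape=(12, 12, 8), depth=2, base_filters=8, dropout=0.1)
    train_cfg = TrainConfig(max_epochs=30)
    return phantom_cfg, spec, model_cfg, train_cfg


# ---------------------------------------------------------------------------
# internals


def _model_seed(seed: int, fold: int, member: int = 0) -> int:
    return int(np.random.SeedSequence([seed, fold, member]).generate_state(1)[0] % (2 ** 31))


def _eval_mask(mask: np.ndarray, ref: np.ndarray) -> dict:
    row = {"sdc": sdc(mask, ref)}
    try:
        row["hd"] = hausdorff_3d(mask, ref)
        row["hd_defined"] = True
    except UndefinedMetricError:
        row["hd"] = np.nan
        row["hd_defined"] = False
    return row


def _run_fold(pre: Mapping[str, SegCase], train_ids, test_ids, model_cfg, train_cfg,
              model_seed: int, extra_train: Sequence[SegCase] = ()) -> List[dict]:
    model = build_model(model_cfg, seed=model_seed)
    train_cases = [pre[i] for i in train_ids] + list(extra_train)
    cfg = replace(train_cfg, seed=model_seed)
    train(model, train_cases, cfg)
    rows = []
    for cid in test_ids:
        case = pre[cid]
        _, mask = predict(model, case)
        rows.append({"case_id": cid, **_eval_mask(mask, case.organ_mask)})
    return rows


def _preprocess_all(cohort: Sequence[SegCase], spec: ROISpec) -> Dict[str, SegCase]:
    return {c.case_id: preprocess_case(c, spec) for c in cohort}


# ---------------------------------------------------------------------------
# experiment designs


def run_set_size_experiment(cohort: Sequence[SegCase], sizes: Sequence[int],
                            spec: ROISpec, model_cfg: ModelConfig,
                            train_cfg: TrainConfig, seed: int,
                            k: int = 6) -> Dict[int, ExperimentResult]:
    """Train/evaluate the base setup at several cohort sizes.

    For each size a random subsample of the cohort is drawn, partitioned into
    k folds and run end to end; larger training sets are expected to help,
    with diminishing returns.
    """
    if max(sizes) > len(cohort):
        raise ValidationError(f"size {max(sizes)} exceeds cohort of {len(cohort)}")
    pre = _preprocess_all(cohort, spec)
    ids = [c.case_id for c in cohort]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    results: Dict[int, ExperimentResult] = {}
    for size in sizes:
        sub = list(rng.choice(ids, size=size, replace=False))
        plan = make_folds(sub, seed=seed, k=k)
        rows = []
        for f, (tr, te) in enumerate(plan.folds):
            for row in _run_fold(pre, tr, te, model_cfg, train_cfg, _model_seed(seed, f)):
                rows.append({"fold": f, "size": size, **row})
        results[size] = ExperimentResult(
            table=pd.DataFrame(rows),
            metadata={"design": "set_size", "size": size, "seed": seed, "k": k})
    return results


def _augment_copies(raw_by_id: Mapping[str, SegCase], train_ids, mode: str, count: int,
                    spec: ROISpec, rng: np.random.Generator,
                    trad_params: TraditionalAugParams,
                    dom_params: DomainAugParams) -> List[SegCase]:
    """Draw ``count`` source cases from the fold's train set with replacement,
    augment each, and preprocess the copies."""
    out = []
    for j in range(count):
        src = raw_by_id[train_ids[int(rng.integers(len(train_ids)))]]
        if mode == "traditional":
            aug = traditional_augment(src, trad_params, rng)
        elif mode == "domain":
            aug = domain_specific_augment(src, dom_params, rng)
        else:
            raise ValidationError(f"unknown augmentation mode {mode!r}")
        out.append(preprocess_case(aug.replace(case_id=f"{src.case_id}-aug{j}"), spec))
    return out


def run_augmentation_experiment(cohort: Sequence[SegCase], mode: str,
                                counts: Sequence[int], spec: ROISpec,
                                model_cfg: ModelConfig, train_cfg: TrainConfig,
                                seed: int, k: int = 6,
                                trad_params: TraditionalAugParams | None = None,
                                dom_params: DomainAugParams | None = None
                                ) -> Dict[int, ExperimentResult]:
    """Supplement each fold's train set with augmented copies of its own
    train cases (one case may be augmented multiple times); test folds are
    untouched, so augmented derivatives never leak across the fold boundary.
    """
    trad_params = trad_params or TraditionalAugParams()
    dom_params = dom_params or DomainAugParams.for_organ(spec.organ)
    raw_by_id = {c.case_id: c for c in cohort}
    pre = _preprocess_all(cohort, spec)
    plan = make_folds(list(raw_by_id), seed=seed, k=k)
    results: Dict[int, ExperimentResult] = {}
    for count in counts:
        rows = []
        for f, (tr, te) in enumerate(plan.folds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 13, f, count]))
            extra = _augment_copies(raw_by_id, tr, mode, count, spec, rng,
                                    trad_params, dom_params)
            for row in _run_fold(pre, tr, te, model_cfg, train_cfg,
                                 _model_seed(seed, f), extra_train=extra):
                rows.append({"fold": f, "count": count, **row})
        results[count] = ExperimentResult(
            table=pd.DataFrame(rows),
            metadata={"design": "augmentation", "mode": mode, "count": count,
                      "seed": seed, "k": k})
    return results


def run_cost_function_experiment(cohort: Sequence[SegCase],
                                 loss_specs: Mapping[str, LossSpec],
                                 spec: ROISpec, model_cfg: ModelConfig,
                                 train_cfg: TrainConfig, seed: int,
                                 k: int = 6) -> Dict[str, ExperimentResult]:
    """Controlled cost-function comparison: identical folds and model seeds
    across losses, so the loss is the only varying factor."""
    for name, ls in loss_specs.items():
        if ls.kind == "sdc_plus_hd" and not ls.roi_diagonal:
            raise ValidationError(f"loss {name!r}: sdc_plus_hd requires roi_diagonal")
    pre = _preprocess_all(cohort, spec)
    plan = make_folds(list(pre), seed=seed, k=k)
    results: Dict[str, ExperimentResult] = {}
    for name, ls in loss_specs.items():
        cfg = replace(train_cfg, loss=ls)
        rows = []
        for f, (tr, te) in enumerate(plan.folds):
            for row in _run_fold(pre, tr, te, model_cfg, cfg, _model_seed(seed, f)):
                rows.append({"fold": f, "loss": name, **row})
        results[name] = ExperimentResult(
            table=pd.DataFrame(rows),
            metadata={"design": "cost_function", "loss": name, "seed": seed, "k": k,
                      "fold_plan": plan.folds})
    return results


def run_ensemble_experiment(cohort: Sequence[SegCase], n_models: int,
                            spec: ROISpec, model_cfg: ModelConfig,
                            train_cfg: TrainConfig, seed: int, k: int = 6
                            ) -> ExperimentResult:
    """Per fold, train ``n_models`` networks differing only in their random
    initialisation seed, then evaluate every voting cut-off 1..N per test
    case alongside the stand-alone members.

    The returned table has one row per (case, cutoff) with kind='ensemble'
    and one per (case, member) with kind='standalone'.
    """
    if n_models < 2:
        raise ValidationError("ensemble experiment needs n_models >= 2")
    pre = _preprocess_all(cohort, spec)
    plan = make_folds(list(pre), seed=seed, k=k)
    rows = []
    for f, (tr, te) in enumerate(plan.folds):
        models = []
        for m in range(n_models):
            ms = _model_seed(seed, f, m)
            model = build_model(model_cfg, seed=ms)
            train(model, [pre[i] for i in tr], replace(train_cfg, seed=ms))
            models.append(model)
        for cid in te:
            case = pre[cid]
            preds = [predict(model, case)[1] for model in models]
            sweep = sweep_cutoffs(preds, case.organ_mask)
            for _, r in sweep.table.iterrows():
                rows.append({"fold": f, "case_id": cid, "kind": "ensemble",
                             "cutoff": int(r["cutoff"]), "sdc": r["sdc"],
                             "hd": r["hd"], "hd_defined": bool(r["hd_defined"])})
            for m, p in enumerate(preds):
                rows.append({"fold": f, "case_id": cid, "kind": "standalone",
                             "member": m, **_eval_mask(p, case.organ_mask)})
    return ExperimentResult(
        table=pd.DataFrame(rows),
        metadata={"design": "ensemble", "n_models": n_models, "seed": seed, "k": k,
                  "majority_cutoff": majority_cutoff(n_models)})


def run_combined_experiment(cohort: Sequence[SegCase], spec: ROISpec,
                            model_cfg: ModelConfig, train_cfg: TrainConfig,
                            seed: int, n_models: int = 5, k: int = 6,
                            dom_params: DomainAugParams | None = None,
                            window_grid: WindowGrid | None = None
                            ) -> ExperimentResult:
    """Paired comparison of the maximum-set-size single model (arm A) against
    the full pipeline (arm B): a seed-diverse ensemble trained on the train
    set doubled by domain-specific augmentation, with patient-specific
    windowing at inference.  Both arms share folds and test cases.
    """
    dom_params = dom_params or DomainAugParams.for_organ(spec.organ)
    window_grid = window_grid or coarse_grid()
    raw_by_id = {c.case_id: c for c in cohort}
    pre = _preprocess_all(cohort, spec)
    plan = make_folds(list(pre), seed=seed, k=k)
    cutoff = majority_cutoff(n_models)
    rows = []
    for f, (tr, te) in enumerate(plan.folds):
        # arm A: single model, full train set, set window
        for row in _run_fold(pre, tr, te, model_cfg, train_cfg, _model_seed(seed, f)):
            rows.append({"fold": f, "arm": "max_set_size", **row})
        # arm B: double the train set with domain-specific copies, train the
        # ensemble, apply patient-specific windowing per test case
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17, f]))
        extra = _augment_copies(raw_by_id, tr, "domain", len(tr), spec, rng,
                                TraditionalAugParams(), dom_params)
        models = []
        for m in range(n_models):
            ms = _model_seed(seed, f, 100 + m)
            model = build_model(model_cfg, seed=ms)
            train(model, [pre[i] for i in tr] + extra, replace(train_cfg, seed=ms))
            models.append(model)

        def ensemble_predictor(pcase: SegCase) -> np.ndarray:
            preds = [predict(model, pcase)[1] for model in models]
            return threshold_votes(vote(preds), cutoff, n=n_models).astype(np.float32)

        for cid in te:
            res = search_best_window(ensemble_predictor, raw_by_id[cid], spec,
                                     grid=window_grid)
            best_spec = replace(spec, hu_window=res.best_window)
            best_pre = preprocess_case(raw_by_id[cid], best_spec)
            mask = (ensemble_predictor(best_pre) >= 0.5).astype(np.uint8)
            rows.append({"fold": f, "arm": "combined", "case_id": cid,
                         "best_center": res.best_window.center,
                         "best_width": res.best_window.width,
                         **_eval_mask(mask, best_pre.organ_mask)})
    return ExperimentResult(
        table=pd.DataFrame(rows),
        metadata={"design": "combined", "n_models": n_models, "seed": seed, "k": k,
                  "cutoff": cutoff, "grid_size": len(window_grid)})
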