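"""Patient-specific HU-window search.

At inference time, a window tuned per patient can expose more contrast than
one fixed window for the whole dataset.  The search preprocesses a case with
every window of a center/width grid, runs the model, and keeps the window
whose prediction scores the highest Dice against the reference contour.  The
default grid is centers -100..400 in steps of 10 by widths 100..1000 in steps
of 50 — 969 candidate windows.

Because the selection criterion is the Dice against a reference, the search
is an evaluation/research tool: it is not applicable to de-novo contouring,
where no reference exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .core import HUWindow, ROISpec, SegCase
from .metrics import UndefinedMetricError, hausdorff_3d, sdc
from .preprocess import preprocess_case

__all__ = ["WindowGrid", "WindowSearchResult", "enumerate_grid",
           "search_best_window", "compare_set_vs_patient_window"]

Predictor = Callable[[SegCase], np.ndarray]  # preprocessed case -> soft mask


@dataclass(frozen=True)
class WindowGrid:
    """Candidate HU windows in scan order (center-major, width-minor)."""

    centers: tuple
    widths: tuple

    @property
    def windows(self) -> List[HUWindow]:
        return [HUWindow(center=c, width=w) for c in self.centers for w in self.widths]

    def __len__(self) -> int:
        return len(self.centers) * len(self.widths)


def enumerate_grid(center_start: float = -100.0, center_stop: float = 400.0,
                   center_step: float = 10.0, width_start: float = 100.0,
                   width_stop: float = 1000.0, width_step: float = 50.0) -> WindowGrid:
    """The default search grid: 51 centers x 19 widths = 969 windows, both
    range endpoints inclusive."""
    centers = tuple(np.arange(center_start, center_stop + center_step / 2, center_step))
    widths = tuple(np.arange(width_start, width_stop + width_step / 2, width_step))
    return WindowGrid(centers=centers, widths=widths)


def coarse_grid(center_step: float = 50.0, width_step: float = 150.0) -> WindowGrid:
    """A sub-sampled grid over the same ranges, for desk-scale experiments."""
    return enumerate_grid(center_step=center_step, width_step=width_step)


@dataclass(frozen=True)
class WindowSearchResult:
    best_window: HUWindow
    best_sdc: float
    table: pd.DataFrame  # columns: center, width, sdc


def search_best_window(predictor: Predictor, case: SegCase, spec: ROISpec,
                       grid: WindowGrid | None = None) -> WindowSearchResult:
    """Exhaustively score every grid window and return the first maximizer.

    For each window the case is re-preprocessed (crop, clip, normalize) with
    that window, predicted, binarized at 0.5 and scored with Dice against the
    cropped reference organ mask.  Ties keep the first window in scan order.
    """
    grid = grid or enumerate_grid()
    rows = []
    best = (-1.0, None)
    for w in grid.windows:
        pre = preprocess_case(case, replace(spec, hu_window=w))
        try:
            prob = predictor(pre)
        except Exception as exc:  # identify the offending window
            raise RuntimeError(
                f"predictor failed at window center={w.center} width={w.width}: {exc}"
            ) from exc
        score = sdc((np.asarray(prob) >= 0.5).astype(np.uint8), pre.organ_mask)
        rows.append({"center": w.center, "width": w.width, "sdc": score})
        if score > best[0]:
            best = (score, w)
    return WindowSearchResult(best_window=best[1], best_sdc=best[0],
                              table=pd.DataFrame(rows))


def _eval_window(predictor: Predictor, case: SegCase, spec: ROISpec) -> tuple:
    pre = preprocess_case(case, spec)
    mask = (np.asarray(predictor(pre)) >= 0.5).astype(np.uint8)
    score = sdc(mask, pre.organ_mask)
    try:
        hd = hausdorff_3d(mask, pre.organ_mask)
    except UndefinedMetricError:
        hd = np.nan
    return score, hd


def compare_set_vs_patient_window(predictor: Predictor, cases: Sequence[SegCase],
                                  spec: ROISpec, grid: WindowGrid | None = None) -> pd.DataFrame:
    """Per-case Dice/HD under the organ's set window versus the searched
    patient-specific window; one row per case."""
    if len(cases) < 1:
        raise ValueError("need at least one case")
    rows = []
    for case in cases:
        set_sdc, set_hd = _eval_window(predictor, case, spec)
        res = search_best_window(predictor, case, spec, grid=grid)
        best_spec = replace(spec, hu_window=res.best_window)
        pat_sdc, pat_hd = _eval_window(predictor, case, best_spec)
        rows.append({"case_id": case.case_id, "set_sdc": set_sdc, "set_hd": set_hd,
                     "patient_sdc": pat_sdc, "patient_hd": pat_hd,
                     "best_center": res.best_window.center,
                     "best_width": res.best_window.width})
    return pd.DataFrame(rows)
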