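"""Patient-specific HU-window search with a trained model.

The full grid spans centers -100..400 (step 10) and widths 100..1000
(step 50) — 969 windows; here a coarse sub-grid keeps the example fast.  The
search re-preprocesses the case under each window and keeps the window whose
prediction scores the best Dice against the reference contour.
"""

from oarseg.experiments import desk_scale_setup
from oarseg.phantom import generate_cohort
from oarseg.preprocess import preprocess_case
from oarseg.trainer import build_model, predict, train
from oarseg.windowing import coarse_grid, enumerate_grid, search_best_window

ph_cfg, spec, model_cfg, train_cfg = desk_scale_setup()
cohort = generate_cohort(20, ph_cfg, seed=5)
pre = [preprocess_case(c, spec) for c in cohort[:18]]

model = build_model(model_cfg, seed=0)
train(model, pre, train_cfg)

print(f"full grid: {len(enumerate_grid())} windows; "
      f"this example searches {len(coarse_grid())}")
predictor = lambda p: predict(model, p)[0]
for case in cohort[18:]:
    res = search_best_window(predictor, case, spec, grid=coarse_grid())
    set_pre = preprocess_case(case, spec)
    from oarseg.metrics import sdc
    set_sdc = sdc(predict(model, set_pre)[1], set_pre.organ_mask)
    print(f"{case.case_id}: set window ({spec.hu_window.lower:.0f}, "
          f"{spec.hu_window.upper:.0f}) SDC {set_sdc:.3f} -> best window "
          f"center {res.best_window.center:.0f} width {res.best_window.width:.0f} "
          f"SDC {res.best_sdc:.3f}")
# The searched window can only match or beat any single window inside the
# grid for that patient; it needs the reference contour, so it is an
# evaluation tool, not a de-novo contouring step.
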