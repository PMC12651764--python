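# prepscore

Automated scoring of 3D dental cavity preparations for preclinical
assessment. Dental students practise Class II (occlusal + mesial) cavity
preparations on simulation molars; examiners mark each preparation on a
structured 20-point rubric. `prepscore` reimplements, as a tested and
reusable package, a clinician-built pipeline that predicts those rubric
scores directly from an intraoral surface scan:

```
OBJ surface mesh ──► 100,000-point cloud ──► unit-sphere pose
(prepared tooth +      (deterministic,         normalization
 adjacent teeth)        area-weighted)              │
                                                    ▼
  examiner agreement ◄── agreement suite ◄── PointNet-style regressor
  (MAE, RMSE, r, ρ,                          (9 bounded outputs: 8 rubric
   Lin's ρc/Cb, Bland–Altman,                 criteria + total)
   ICC(2,1), ±1/±2-point accuracy)
```

## The rubric

| criterion | range |
|---|---|
| complete caries removal | 0–9 |
| proximal clearance, buccal / lingual / gingival | 0–2 each |
| preservation between the cavities | 0–2 |
| avoidance of cusp weakening (occlusal preservation) | 0–1 |
| no undermined enamel at the margins | 0–2 |
| damage to the adjacent tooth (deduction) | −4–0 |

Positive maxima sum to 20. Simulated pulp exposure zeroes the sheet.
Reference scores are the average of two examiners (so half-points occur);
inter-examiner reliability is quantified with ICC(2,1).

## The model

Each case is sampled into a fixed-size point cloud by area-weighted face
selection with uniform barycentric placement (seeded, bit-reproducible),
centred at the origin and rescaled so the farthest point lies on the unit
sphere. A PointNet-style network — a shared per-point MLP, a symmetric
max-pool into a global feature, and a fully connected head — maps the
cloud to nine outputs, each squashed through a sigmoid affinely rescaled
to its rubric range: the eight criteria plus a jointly trained total.
Training minimizes mean absolute error in rubric points, in two blocks of
50 epochs with a fresh Adam state per block, checkpoints every epoch, and
restores the epoch with the lowest training MAE.

Because the original scan dataset is not deposited, the package ships a
parametric synthetic-tooth generator (`prepscore.synthetic`): molar-like
displaced-sphere surfaces with an occlusal and a mesial cavity, adjacent
teeth, and explicit geometric parameters (clearance gaps, residual
caries, isthmus thickness, undermined margins, adjacent-tooth damage,
pulp exposure) that map deterministically to ground-truth score sheets.

## Worked example

```bash
prepscore generate --n 30 --seed 0 --out cohort/
prepscore train cohort/ --checkpoint ckpt/ --n-points 2048 --seed 0
prepscore score cohort/test/case_005.obj --checkpoint ckpt/best.npz \
    --n-points 2048 --seed 0 --out score.json
prepscore evaluate cohort/ --checkpoint ckpt/best.npz --out report/ \
    --n-points 2048
```

`generate` writes 20 training and 10 test cases (OBJ + JSON label pairs
and a manifest). `train` runs 100 epochs (two blocks of 50) and reports:

```
trained 100 epochs; best epoch 99 (training MAE 0.8464 rubric points); checkpoints in ckpt
```

`score` prints the predicted sheet for one scan — criterion scores, their
rubric sum, and the total head. On this run, for `case_005`:

```json
{
  "criteria": {
    "caries_removal": 8.208001, "clearance_buccal": 1.00142,
    "clearance_lingual": 1.862873, "clearance_gingival": 1.426469,
    "preservation_between": 1.01261, "occlusal_preservation": 0.999313,
    "no_undermined_enamel": 1.352607, "adjacent_damage": -0.020584
  },
  "sum_of_criteria": 15.842709,
  "predicted_total": 14.573254
}
```

(the sum of the predicted criteria and the directly predicted total are
both reported and need not agree exactly — they are separate outputs
trained against the same target). `evaluate` writes
`agreement_report.json` with the full statistic set — on the run above:
MAE 4.82, RMSE 5.51, Spearman ρ 0.20 against ground truth on the 10
held-out synthetic cases — plus a per-criterion true-vs-predicted CSV.
At this desk scale the network memorizes the 20 training cases (training
MAE below one rubric point) but generalizes only weakly; the end-to-end
tests assert exactly that learning signal (training MAE at least halves;
held-out rank correlation positive over seeds), not clinical-grade
accuracy.

The same library surface is available programmatically via
`prepscore.PointNetScoreRegressor`, a scikit-learn-style estimator
(`fit(X, y)` on arrays of normalized clouds, `predict`,
`get_params`/`set_params`), which composes with sklearn model selection.

`prepscore.datasets` ships the per-case score tables of the original
feasibility evaluation (20 training / 10 test preparations, rounded to
one decimal) for use as fixed inputs to the agreement suite.

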