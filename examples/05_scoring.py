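"""Scoring predicted change-points against ground truth.

Shows the two headline metrics: ScoreRegimes (count-aware, offline) and the
Prediction Loss MAE (count-free, online), including how an inflated
detection count is penalized.
"""

from lsuss import prediction_loss_mae, score_dataset, score_recording, score_regimes

n = 10_000
gt = [2000, 5000, 8000]

good = [1990, 5030, 7985]        # right count, small errors
extra = [1990, 3500, 5030, 7985]  # one false positive

print(f"ground truth {gt}, series length {n}")
for name, pred in [("good", good), ("extra detection", extra)]:
    sr = score_regimes(pred, gt, n)
    plm = prediction_loss_mae(pred, gt, n)
    print(f"{name:16s} pred={pred}")
    print(f"{'':16s} ScoreRegimes {sr:.5f}   PredictionLossMAE {plm:.1f}")
print("ScoreRegimes only measures how close each true boundary is to its")
print("nearest prediction; the prediction-loss MAE additionally inflates")
print("the error when the detected count deviates from the truth.")

table = score_dataset([score_recording(good, gt, n),
                       score_recording(extra, gt, n)])
print("\nper-recording score table (last row = unweighted mean):")
print(table[["score_regimes", "mae", "prediction_ratio",
             "prediction_loss_mae"]].to_string())
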