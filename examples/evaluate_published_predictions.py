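"""Reproduce the published evaluation of model 1 on the 23 experimental
mouse Wnt-Fzd CRD affinities shipped with the package."""

from wntcrd import evaluation_frame, evaluation_table, fixture_table2, rmse

measurements, predictions = fixture_table2()
rows = evaluation_table(predictions, measurements)

frame = evaluation_frame(rows)
print(frame.round({"dG_exp": 2, "dG_pred": 2, "abs_diff": 2,
                   "Kd_exp_nM": 1, "Kd_pred_nM": 1}).to_string(index=False))

for label in ("training", "test"):
    subset = [r for r in rows if r.set_label == label]
    value = rmse([r.dg_pred for r in subset], [r.dg_exp for r in subset])
    print(f"RMSE_{label} = {value:.2f} kcal/mol over {len(subset)} complexes")

flagged = [r.complex_id for r in rows if r.range_mismatch]
print(f"complexes predicted in a different affinity range: {flagged}")
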