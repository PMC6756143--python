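"""Train the modified LeNet-5 on a synthetic cohort and score held-out
recordings per segment and per recording (AHI)."""

from apneascan import model as m
from apneascan.harness import prepare_cohort, run_cnn_experiment
from apneascan.simulate import SimConfig, simulate_cohort

cohort = simulate_cohort(8, (0.0, 0.5, 0.5), SimConfig(duration_min=20), seed=3)
prepared = prepare_cohort(cohort)
ids = [c.record_id for c in cohort]
train_ids, test_ids = ids[:3] + ids[4:7], [ids[3], ids[7]]  # one B + one C held out

spec = m.modified_lenet5()
counts, total = m.count_parameters(spec)
print(f"modified LeNet-5: {total} trainable parameters, per layer {counts}")

res = run_cnn_experiment(prepared, train_ids, test_ids, m.TrainConfig(max_epochs=20, seed=0))
print(f"cross-entropy: initial {res.history[0]:.3f} -> final {res.history[-1]:.3f}")

seg = res.segment_report
print(
    f"\nheld-out per-segment: accuracy {seg['accuracy']:.3f}, "
    f"sensitivity {seg['sensitivity']:.3f}, specificity {seg['specificity']:.3f}, "
    f"AUC {seg['auc']:.3f} (majority-class rate {res.majority_rate:.3f})"
)
for d in res.diagnoses:
    verdict = "SA" if d.predicted_sa else "normal"
    print(
        f"  {d.record_id}: estimated AHI {d.estimated_ahi:.1f} vs true {d.true_ahi:.1f}"
        f" -> {verdict}"
    )
print("\nA recording whose estimated AHI exceeds 5 events/hour is diagnosed SA.")
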