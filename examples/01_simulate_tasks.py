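"""Generate a synthetic session of the numerical-operation task.

Builds trial tables for both tasks, simulates choices with a numerical size
effect, and plants a small neural population with known selectivity.
"""

from pmdarith import synth, task

ds = synth.make_fixture_dataset("paper_like", seed=7, n_cells=120)

print(f"numerical-operation trials simulated : {len(ds.raw_trials)}")
print(f"correct minimum-step trials retained : {len(ds.trials)}")
print(f"instructed-task analysis trials      : {len(ds.instructed_trials)}")
print(f"cells x trials x bins                : {ds.pop.counts.shape}")
print("\nplanted cell categories:")
print(ds.ground_truth["category"].value_counts().to_string())

conds = task.enumerate_conditions(task.TASK_NUMERICAL)
print(f"\ncondition set: {len(conds)} target/preoperational pairs "
      "(|difference| <= 2, holds included)")
# The category table is the ground truth every later analysis stage is
# checked against: e.g. 'arith_to_hand' cells code arithmetic early and a
# matched hand signal late, emulating the arithmetic-to-motor transition.
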