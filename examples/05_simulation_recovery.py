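"""Simulator power check: does the pipeline recover the generating ring?

Families are evolved on the six-taxon ring at increasing loss rates, and
for each replicate the ring is scored against all nine rootings of the
three-cherry tree.  At low loss rates the true ring strictly beats every
tree; heavy loss erodes the signal.
"""

from ringroot import datasets
from ringroot.synthetic_data import SimulationConfig, recovery_experiment

ring = datasets.inner_ring_six()
tree = datasets.three_cherry_tree()
sites = [("root", "L"), ("root", "R"), ("L", "AD"), ("R", "HE")]

for loss_prob in (0.0, 0.05, 0.3):
    cfg = SimulationConfig(
        ring=ring,
        allocations={s: 30 for s in sites},
        loss_prob=loss_prob,
        seed=42,
    )
    out = recovery_experiment(cfg, 10, tree=tree)
    print(f"loss rate {loss_prob:4.2f}: ring beats all 9 rootings in "
          f"{out['ring_win_fraction']:.0%} of 10 replicates")

print()
print("Losses mimic tree-like explanations, so the ring's advantage — and")
print("the power of the parsimony comparison — decays as losses get common.")
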