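"""From raw trajectories to a normalized transition dataset.

Applies the exclusion filters, hourly binning, missingness handling,
glucose-history feature engineering, [0,1] normalization and transition
construction, and prints what each stage did.
"""

from glycorl import SimConfig, preprocess_cohort, simulate_cohort

traj, patients = simulate_cohort(SimConfig(n_patients=300, seed=1))
prep = preprocess_cohort(traj, patients, seed=0)

print("patients excluded per criterion (applied in order):")
for flag, n in prep["tally"].items():
    print(f"  {flag}: {n}")

print(f"\nfeatures dropped for >30% missingness: {prep['missingness'].dropped_}")
print(f"state features ({len(prep['feature_names'])}): {prep['feature_names'][:6]} ...")

train, test = prep["train"], prep["test"]
print(f"\ntrain: {train.n_episodes} episodes / {len(train)} transitions")
print(f"test:  {test.n_episodes} episodes / {len(test)} transitions")
print(f"reward range: [{train.rewards.min():.2f}, {train.rewards.max():.2f}]")
print(f"actions capped to [0, 10]: max {train.actions.max():.1f} U")
# states are min-max normalized with training-split statistics only, so the
# held-out episodes cannot influence scaling (no leakage)
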