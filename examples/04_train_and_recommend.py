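"""Train a small dosing agent and query it.

Trains the conservative distributional agent briefly on a small cohort
(desk-scale settings) and shows integer dose recommendations and the
critic's return-distribution quantiles.
"""

from glycorl import SimConfig, preprocess_cohort, simulate_cohort, train_agent
from glycorl.config import desk_scale_agent_config

traj, patients = simulate_cohort(SimConfig(n_patients=200, seed=1))
prep = preprocess_cohort(traj, patients, seed=0)

config = desk_scale_agent_config(gradient_steps=1500, seed=0)
artifact = train_agent(prep["train"], config)

states = prep["test"].states[:8]
doses = artifact.recommend(states)
glucose = prep["test"].raw_glucose[:8]
for g, d, observed in zip(glucose, doses, prep["test"].actions[:8]):
    print(f"glucose {g:5.0f} mg/dL -> model {d:>2} U (clinician gave {observed:.0f} U)")
# recommendations are the actor's mean action, clipped to [0, 10] and
# rounded to whole units as deployed at the bedside

qv = artifact.critic_quantiles(states[0], float(doses[0]), [0.1, 0.5, 0.9])
print("\nreturn-distribution quantiles at the first state's recommended dose:")
for q in qv:
    print(f"  tau={q.tau:.1f}: {q.value:+.3f}")
# the spread between low and high quantiles is the critic's estimate of
# outcome uncertainty for this patient-hour
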