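"""The glycemic reward and the dose penalty.

Evaluates the piecewise reward across the physiologic glucose range and
shows how the quadratic penalty shapes the reward of a dosing decision.
"""

import numpy as np

from glycorl import glycemic_reward, shaped_reward

for glucose in (60, 105, 160, 200, 250):
    print(f"glucose {glucose:>3} mg/dL -> reward {glycemic_reward(float(glucose)):+.3f}")
# the reward peaks at +0.2 on the 140-180 mg/dL target band and falls to -1
# for hypoglycemia (<70) and severe hyperglycemia (>=220)

print()
for dose in (0, 4, 10):
    r = shaped_reward(160.0, float(dose))
    print(f"dose {dose:>2} U at 160 mg/dL -> shaped reward {r:+.3f}")
# the 0.001*dose^2 penalty leaves small doses almost free but discourages
# large overcorrections: 10 U costs 0.1 reward even at perfect glucose

x = np.arange(20.0, 600.0, 0.1)
r = np.asarray(glycemic_reward(x))
print(f"\nsweep of {len(x)} glucose values: reward range [{r.min():.1f}, {r.max():.1f}]")
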