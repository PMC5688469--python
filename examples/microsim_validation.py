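"""Validate the deterministic engine against the per-birth microsimulation.

For a handful of random country scenarios, each simulated birth draws its
cause-specific death and its exposure to every matching intervention
effect; the resulting death counts should agree with the engine's
closed-form cascade within Monte-Carlo error (|z| mostly < 2, essentially
always < 3).
"""

import math

from livessaved import make_random_scenario, microsim_oracle, run_projection

print("scenario  group      engine      microsim     |z|")
for index in range(5):
    scenario, library = make_random_scenario(seed=200 + index)
    engine = run_projection(scenario, library)
    sim = microsim_oracle(scenario, library, n_births_per_year=200_000,
                          seed=index)
    for group in ("neonatal", "maternal"):
        expected = sum(engine.deaths(group).values())
        observed = sum(sim.deaths(group).values())
        se = math.sqrt(sum(v * v for v in sim.se(group).values()))
        z = abs(expected - observed) / se
        print(f"{index:>8d}  {group:9s} {expected:10.1f}  {observed:10.1f}"
              f"  {z:6.2f}")
print("\nAgreement within ~3 standard errors confirms the multiplicative "
      "residual cascade matches its per-birth probabilistic definition.")
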