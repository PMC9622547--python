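"""Simulate one EWA agent through the 11-stage serial-reversal task.

Builds the default task (80/20 contingencies for the discrimination, first
reversal and SRL1 stages; 80/40 with 2-or-6-credit wins for SRL2), runs a
moderately skilled agent, and prints its model-free behaviour summary.
"""

import numpy as np

from revlearn import EWAParams, build_default_task, simulate_agent, summarize_session

config = build_default_task()
rng = np.random.default_rng(7)
agent = EWAParams(phi=0.70, rho=0.30, beta=3.5)
session = simulate_agent("ewa", agent, config, rng, subject_id="demo")

s = summarize_session(session)
print(f"trials overall:        {s.total_trials}")
print(f"discrimination trials: {s.discrimination_trials}")
print(f"first reversal trials: {s.first_reversal_trials}")
print(f"SRL1 mean trials:      {s.srl1_mean_trials:.1f}")
print(f"SRL2 mean trials:      {s.srl2_mean_trials:.1f}")
print(f"win-stay / lose-shift: {s.win_stay:.3f} / {s.lose_shift:.3f}")
print(f"SRL2 win-stay by win magnitude: "
      f"{ {c: round(p, 3) for c, (p, _, _) in s.win_stay_by_credit.items()} }")

# Trials-to-criterion has a floor of 6 (the criterion run itself); values
# near it mean near-immediate adaptation after each silent reversal.
# Win-stay is the probability of repeating a rewarded choice; for a
# learned, fairly deterministic agent it sits close to 1.
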