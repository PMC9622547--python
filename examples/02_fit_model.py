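"""Fit the EWA model to a simulated subject and check the estimates.

Generates one long fixed-reversal session (25 blocks x 20 trials = 500
trials, reversal every 20 trials) from known parameters, then recovers
them by multi-start MAP estimation.
"""

import numpy as np

from revlearn import EWAParams, build_fixed_length_task, fit_subject, simulate_agent

true = EWAParams(phi=0.65, rho=0.40, beta=3.0)
config = build_fixed_length_task()  # 500 trials
rng = np.random.default_rng(42)
session = simulate_agent("ewa", true, config, rng, subject_id="sim")

fit = fit_subject("ewa", session, n_starts=4, rng=rng, config=config)
est = fit.params
print(f"{'':8s}{'true':>8s}{'estimate':>10s}")
for name in ("phi", "rho", "beta"):
    print(f"{name:8s}{true.as_dict()[name]:8.2f}{est.as_dict()[name]:10.2f}")
print(f"negative log-posterior at optimum: {fit.neg_log_posterior:.1f}")
print(f"reported learning rate (1 - phi):  {est.reported()['learning_rate']:.2f}")

# Estimates come from a single 500-trial session, so expect them near but
# not equal to the generating values; beta is the noisiest of the three.
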