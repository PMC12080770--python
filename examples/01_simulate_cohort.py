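"""Simulate a graded-treadmill cohort with known fatigue ground truth.

Six subjects walk seven 4-minute stages, starting at 4 km/h and speeding
up 1 km/h per stage; after each stage they report a Borg 6-20 rating and
take a reaction-time test while the stage's RR intervals are recorded.
"""

from opfatigue import ProtocolConfig, simulate_cohort

series, observations, latent = simulate_cohort(ProtocolConfig(seed=7))

print(f"{len(series)} RR series, {len(observations)} observations\n")
print(observations.head(7).to_string(index=False))
print(
    "\nEach row is one subject-stage: Borg climbs toward 20 and reaction"
    "\ntime lengthens as the latent fatigue (heart-rate reserve fraction"
    "\nin use, column true_fatigue) rises with treadmill speed."
)

first = series[0]
print(
    f"\nFirst series: subject {first.subject_id}, stage {first.stage}, "
    f"{len(first)} beats over {first.duration_s:.0f} s"
)
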