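"""Build counterbalanced divided-field schedules for both experiments.

Prints the signal:noise composition per block and the counterbalancing cell
occupancy for a 26-subject cohort.
"""

from collections import Counter

from pareidolia import build_block_schedule, build_subject_schedule, counterbalance_cohort

for experiment in (1, 2):
    trials = build_block_schedule(experiment, "face", None, seed=0)
    kinds = Counter(t.stimulus_type for t in trials)
    sides = Counter(t.visual_field for t in trials if t.stimulus_type == "signal")
    print(f"experiment {experiment}: {kinds['signal']} signal / "
          f"{kinds['noise_only']} noise trials per 256-trial block; "
          f"signal trials {sides['LVF']} LVF / {sides['RVF']} RVF")

cohort = counterbalance_cohort(26, seed=1)
cells = Counter(cohort)
print(f"26 subjects over {len(cells)} counterbalance cells, "
      f"occupancies {sorted(cells.values())}")

spec = cohort[0]
schedule = build_subject_schedule(0, 1, spec, None, seed=2)
print(f"subject 0 runs blocks in order {schedule.block_sequence} "
      f"(responds with the {spec.responding_hand} hand, "
      f"'{spec.response_mapping}' key mapping); practice trials are flagged "
      "and excluded from analysis")
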