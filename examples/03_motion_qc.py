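"""Flag high-motion volumes and apply the participant-exclusion rule.

A volume is flagged above 1 mm relative movement or beyond 2.5 SD in global
intensity; a participant is dropped when strictly more than a quarter of
their volumes are flagged.
"""

from gicanet.motion import exclude_participant, flag_high_motion
from gicanet.simulate import simulate_motion_trace

trace = simulate_motion_trace(
    n_volumes=200, spike_positions={20, 21, 95}, spike_magnitude=2.0, seed=5
)
flags = flag_high_motion(trace, movement_mm=1.0, intensity_z=2.5)
print(f"flagged volumes: {sorted(flags)}")
print(
    f"flagged fraction {len(flags)}/200 = {len(flags) / 200:.3f}; "
    f"exclude participant: {exclude_participant(flags, 200, fraction=0.25)}"
)
# Three spikes of 200 volumes is 1.5% -- far below the quarter rule, so the
# participant is kept and only the flagged volumes are dropped downstream.
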