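"""Fission/fusion event detection and rates on a scripted time-lapse.

Renders capsule-shaped mitochondria at one frame per 13 s over 10 min with
two scripted fissions and one fusion, tracks particles by mask overlap,
detects events and reports rates in events per cell per second.
"""

from mitophos import (
    DynamicsSimConfig,
    detect_events,
    event_rates,
    simulate_timelapse,
    track_components,
)

config = DynamicsSimConfig(
    seed=0,
    n_mitochondria=5,
    fission_events=[(130.0, 1), (300.0, 2)],
    fusion_events=[(450.0, (4, 5))],  # fuse neighbouring capsules
)
stack, truth = simulate_timelapse(config)
print(f"{stack.n_frames} frames at {stack.frame_interval:.0f} s/frame, "
      f"{truth.true_particle_count_per_frame[0]} -> "
      f"{truth.true_particle_count_per_frame[-1]} particles")

correspondence = track_components(stack.labels)
events = detect_events(correspondence, stack.frame_interval)
for e in events:
    print(f"  {e.type} at t={e.time:.0f} s: {e.parents} -> {e.children}")

rates = event_rates(events, n_cells=1, duration_s=stack.duration)
print(f"fission rate {rates.fission_rate:.5f} events/cell/s, "
      f"fusion rate {rates.fusion_rate:.5f} events/cell/s")
# A fission rate of ~0.003 events/cell/s means about 2 divisions per
# mitochondrial network per 10-minute observation window.
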