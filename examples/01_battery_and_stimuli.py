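"""Build the 25-sound battery and assemble a five-sound sequence.

Loads the packaged battery, synthesizes deterministic stand-in audio
for each sound, RMS-normalizes the clips, and concatenates one coherent
sequence with 250 ms inter-sound gaps.
"""

import fest

battery = fest.load_battery()
print(f"battery: {len(battery.sounds)} sounds, {len(battery.sequences)} sequences")

durations = {q.name: fest.sequence_duration(q, battery) for q in battery.sequences}
print("sequence durations (s):")
for name, d in sorted(durations.items()):
    print(f"  {name:<15} {d:6.2f}")
print(f"range: {min(durations.values()):.2f} - {max(durations.values()):.2f} s")
# every sequence lies in the 12-17 s window the test protocol targets

clips = fest.make_fixture_audio(battery, rate=16000, seed=1)
clips = {l: fest.rms_normalize(c, 0.05) for l, c in clips.items()}

seq = battery.sequence("Waking up")
out = fest.assemble_sequence(seq, clips)
print(f"\nassembled '{seq.name}' ({' -> '.join(seq.labels)}):")
print(f"  {out.duration:.2f} s at {out.rate} Hz")
# duration = the five member durations plus four 0.25 s silent gaps
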