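"""Build the interlaced auditory stimulus sequence and inspect its timeline.

Each 5 s cycle holds one spoken word pair (prime then target) followed by
four tones; rare loud deviant tones (exactly 20%) drive the P300 and
semantically incongruent word pairs (exactly 50%) drive the N400.
"""

import neurovitals as nv

seq = nv.build_sequence(nv.SequenceConfig(n_cycles=60, seed=7))
tones = [e for e in seq.events if e.code.endswith("_tone")]
pairs = [e for e in seq.events if e.code == "target_word"]

print(f"total duration      : {seq.duration:.0f} s ({seq.config.n_cycles} cycles)")
print(f"tones               : {len(tones)} "
      f"({sum(e.condition == 'deviant' for e in tones)} deviant)")
print(f"word pairs          : {len(pairs)} "
      f"({sum(e.condition == 'incongruent' for e in pairs)} incongruent)")

print("\nfirst cycle timeline (onset s, code, condition):")
for e in seq.events[:6]:
    print(f"  {e.onset_time:7.3f}  {e.code:13s}  {e.condition}")

table = nv.sequence_to_event_table(seq, sample_rate=500.0)
print(f"\nevent table: {len(table)} rows; first onset at sample "
      f"{table.iloc[0]['sample_index']} (0-based, 500 Hz)")
# A 5-minute run yields 240 tone trials and 60 word-pair trials — near the
# maximum trial count per unit time for these two interleaved paradigms.
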