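"""Design balanced context-probe sound sequences.

For N sounds, full sampling of every (context, probe) event — including
silence and self-contexts — takes N sequences of N+1 sounds.  This script
designs a 4-sound set, validates the exact-coverage contract, and counts
the contextual instances the design supports.
"""

from ctxcode.stimdesign import (design_sequences, enumerate_instances,
                                validate_sequences)

seqs = design_sequences(4, seed=1)
print("sequences (sound ids, 0 = silence precedes the first):")
for s in seqs.sequences:
    print("  ", list(s))

report = validate_sequences(seqs)
print(f"valid exact cover: {report['valid']}"
      f" ({report['n_events']} (context, probe) events, each exactly once)")

inst = enumerate_instances(4)
print(f"contextual instances (probe x unordered context pair): {len(inst)}")
print("example instance:", inst[0],
      "-> probe 1 compared across silence and itself as context")
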