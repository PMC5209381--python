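"""Classify syllable types and compute the two repertoire entropies.

Every call's pitch contour is assigned one of nine types from its jump
pattern and slope; the usage entropy summarizes how evenly the repertoire is
used and the first-order Markov entropy how variable the call-to-call
sequencing is (conditioning on the previous type can only lower it).
"""

from collections import Counter

import pupcalls as pc
from pupcalls.features import detect_jumps, track_from_annotation
from pupcalls.syllables import classify_call, markov_entropy, usage_entropy_of_labels

params = pc.preset("WT", 8)
meta = pc.RecordingMeta("ent", "WT", 8, duration=210.0)
truth = pc.synth_events(params, meta, seed=5)

labels = []
for c in truth.calls:
    tr = track_from_annotation(c)
    labels.append(classify_call(tr, detect_jumps(tr, 5_000)))

print("type usage:", dict(Counter(labels).most_common()))
print(f"usage entropy: {usage_entropy_of_labels(labels):.3f} bits")
print(f"Markov sequence entropy: {markov_entropy(labels):.3f} bits")
# The Markov entropy is below the usage entropy because consecutive calls
# repeat their type more often than chance (sticky sequencing).
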