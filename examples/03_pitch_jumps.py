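"""Quantify pitch jumps over the standard threshold grid.

Tracks the dominant frequency of every synthesized call and counts abrupt
jumps at thresholds from 0.5 to 20 kHz, split by direction; knockout pups
jump less often, so their per-call counts sit below wild type at every
threshold.
"""

import numpy as np

import pupcalls as pc
from pupcalls.features import detect_jumps, max_jump, track_from_annotation
from pupcalls.params import JUMP_THRESHOLDS

for genotype in ("WT", "KO"):
    params = pc.preset(genotype, 8)
    meta = pc.RecordingMeta("jumps", genotype, 8, duration=120.0)
    truth = pc.synth_events(params, meta, seed=3)
    tracks = [track_from_annotation(c) for c in truth.calls]
    counts = {
        th: np.mean([len(detect_jumps(t, th)) for t in tracks]) for th in JUMP_THRESHOLDS
    }
    mj = np.nanmean([max_jump(t) for t in tracks])
    grid = ", ".join(f"{th/1000:g}k:{c:.2f}" for th, c in counts.items())
    print(f"{genotype}: jumps/call at [{grid}]; mean max jump {mj:.0f} Hz")
# Counts fall monotonically with threshold; WT mean max jump ~12.7 kHz vs
# ~8.7 kHz in KO, mirroring the configured group difference.
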