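"""Render one recording to audio and detect its calls from the waveform.

Synthesizes 20 s of a wild-type pup recording (250 kHz PCM with background
noise at 20 dB SNR), runs the band-pass -> sonogram -> purity/mean-frequency
detector, and scores the detected intervals against the generator's truth.
"""

import pupcalls as pc
from pupcalls.evaluate import detection_scores
from pupcalls.pipeline import analyze_audio

params = pc.preset("WT", 8)
meta = pc.RecordingMeta("demo", "WT", 8, duration=20.0)
wave, truth = pc.synth_recording(params, meta, seed=2)

analysis = analyze_audio(wave, 250_000, meta)
scores = detection_scores(truth.call_intervals, analysis.intervals)
print(f"true calls: {truth.n_calls}, detected: {analysis.n_calls}")
print(f"recall {scores.recall:.3f}, precision {scores.precision:.3f}")
print(f"onset error {scores.onset_mae_s*1e3:.2f} ms (mean absolute)")
# Both recall and precision should be 1.000 at this SNR, with boundary errors
# well under the 1.02 ms frame step.
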