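"""Estimate the intra/inter-bout pause cutoff and partition calls into bouts.

Pools all inter-call gaps of a small cohort, finds the trough of the
pause-length histogram (averaged over bin sizes from 50 to 300 ms within the
0.15-0.32 s window), and reports bout metrics per genotype.
"""

import warnings

import numpy as np

import pupcalls as pc
from pupcalls.bouts import bout_metrics, estimate_bout_cutoff, partition_bouts, pause_lengths

records, _ = pc.sample_cohort({("WT", 8): 8, ("KO", 8): 6}, seed=4)
gaps = np.concatenate([pause_lengths(t.call_intervals) for _, _, t in records])
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cutoff = estimate_bout_cutoff(gaps)
print(f"estimated bout cutoff: {cutoff*1000:.0f} ms from {gaps.size} pauses")

for genotype in ("WT", "KO"):
    metrics = [
        bout_metrics(partition_bouts(t.call_intervals, cutoff))
        for m, _, t in records
        if m.genotype == genotype
    ]
    print(
        f"{genotype}: {np.mean([m.n_bouts for m in metrics]):.1f} bouts/recording, "
        f"{np.mean([m.calls_per_bout for m in metrics]):.2f} calls/bout, "
        f"{np.mean([m.percent_isolated for m in metrics]):.1f}% isolated"
    )
# The cutoff lands in the low-0.2 s range; KO recordings show more bouts,
# fewer calls per bout and more isolated calls.
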