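"""Generator parameter sets for pup isolation-call cohorts.

A :class:`GenotypeParams` describes the *group-level* call statistics of one
genotype on one postnatal day: per-animal means are drawn around these values
(between-animal spread), and individual calls/pauses are drawn around each
animal's means (within-animal spread).  The shipped presets encode the group
summaries measured for Gnptab wild-type (WT), heterozygous (HET) and knockout
(KO) pups on postnatal days 5 and 8; between-animal standard deviations are
reconstructed from standard errors as SEM * sqrt(n) with the per-group sample
sizes (P5: 40 WT / 13 KO, P8: 41 WT / 15 KO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

GENOTYPES = ("WT", "HET", "KO")
DAYS = (5, 8)

#: USV analysis band (Hz); calls live inside this band.
BAND_LOW = 25_000.0
BAND_HIGH = 110_000.0

#: Nominal recording format.
SAMPLE_RATE = 250_000
RECORDING_DURATION = 210.0  # 3.5 min

#: Pitch-jump detection threshold grid (Hz).
JUMP_THRESHOLDS = (500, 1000, 3000, 5000, 10_000, 15_000, 20_000)

# Contour construction constants (Hz). Smooth frequency modulation is kept
# below the smallest jump threshold per sonogram frame, and planted jumps are
# kept well above the 5 kHz classification threshold, so jump counts in the
# synthetic truth are unambiguous.
MAX_RAMP_STEP_HZ = 440.0
MIN_JUMP_HZ = 6_000.0
MAX_JUMP_HZ = 34_000.0
#: Mean of the largest smooth (non-jump) frequency step within a call,
#: used when calibrating per-jump sizes from a per-call max-jump target.
NONJUMP_MAX_STEP_HZ = 600.0

#: Given that a call has jumps, distribution of the number of jumps.
N_JUMPS_GIVEN_JUMPY = ((1, 0.75), (2, 0.18), (3, 0.07))
#: Expected max of k draws from the jump-size distribution, relative to its
#: mean, folded over N_JUUMPS weights: E[max]/mean ~= 0.75*1 + 0.25*1.2.
_MAX_OF_K_FACTOR = 0.75 + 0.25 * 1.2


def calibrate_jump_size_mean(max_jump_target: float, jump_prob: float) -> float:
    """Per-jump size mean that makes the per-call max jump average to target.

    E[max jump per call] = p * E[max of planted jumps] + (1-p) * E[max smooth step].
    """
    if jump_prob <= 0:
        return 0.0
    mu = (max_jump_target - (1.0 - jump_prob) * NONJUMP_MAX_STEP_HZ) / (
        jump_prob * _MAX_OF_K_FACTOR
    )
    return float(min(max(mu, MIN_JUMP_HZ), MAX_JUMP_HZ))


@dataclass(frozen=True)
class GenotypeParams:
    """Group-level call statistics for one genotype x day cell.

    All durations are seconds, frequencies Hz, weights grams.  Fields with the
    ``_sd_between`` suffix are between-animal standard deviations of the
    corresponding per-animal mean.
    """

    mean_call_duration: float
    intra_bout_pause_mean: float
    inter_bout_pause_mean: float
    calls_per_bout_mean: float
    isolated_call_prob: float
    jump_prob_per_call: float
    max_jump_mean: float
    jump_size_sd: float = 4_000.0
    # within-animal (per call / per pause) spread
    call_duration_sd: float = 0.013
    intra_bout_pause_sd: float = 0.030
    # between-animal spread of per-animal means
    duration_sd_between: float = 0.010
    intra_sd_between: float = 0.012
    inter_sd_between: float = 1.0
    calls_per_bout_sd_between: float = 1.2
    isolated_sd_between: float = 0.04
    max_jump_sd_between: float = 4_000.0
    # acoustics
    base_freq_range: tuple[float, float] = (45_000.0, 95_000.0)
    amplitude: float = 0.25
    snr_db: float = 20.0
    click_rate: float = 0.05
    high_band_power_scale: float = 1.0
    # body weight model
    weight_mean: float = 4.0
    weight_sd_between: float = 0.6
    pause_weight_corr: float = 0.0
    # syllable sequencing: probability the next call repeats the previous type
    label_persistence: float = 0.35
    # relative distribution over non-jump call shapes
    nonjump_type_probs: tuple[tuple[str, float], ...] = (
        ("flat", 0.24),
        ("up-fm", 0.26),
        ("down-fm", 0.22),
        ("chevron", 0.18),
        ("other", 0.10),
    )

    def __post_init__(self) -> None:
        if self.mean_call_duration <= 0:
            raise ValueError("mean_call_duration must be > 0")
        if self.intra_bout_pause_mean <= 0 or self.inter_bout_pause_mean <= 0:
            raise ValueError("pause means must be > 0")
        if self.inter_bout_pause_mean <= self.intra_bout_pause_mean:
            raise ValueError("inter_bout_pause_mean must exceed intra_bout_pause_mean")
        if not 0.0 <= self.isolated_call_prob <= 1.0:
            raise ValueError("isolated_call_prob must be in [0, 1]")
        if self.calls_per_bout_mean < 0:
            raise ValueError("calls_per_bout_mean must be >= 0")
        lo, hi = self.base_freq_range
        if not (BAND_LOW <= lo < hi <= BAND_HIGH):
            raise ValueError("base_freq_range must be ordered and inside the USV band")
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must be in (0, 1]")
        if self.click_rate < 0:
            raise ValueError("click_rate must be >= 0")
        if not 0.0 < self.high_band_power_scale <= 1.0:
            raise ValueError("high_band_power_scale must be in (0, 1]")

    @property
    def jump_size_mean(self) -> float:
        """Per-jump magnitude mean implied by the per-call max-jump target."""
        return calibrate_jump_size_mean(self.max_jump_mean, self.jump_prob_per_call)

    def scaled_effect(self, baseline: "GenotypeParams", scale: float) -> "GenotypeParams":
        """Move every group mean ``scale`` times its offset from ``baseline``.

        Used to build exaggerated- or null-effect cohorts for classifier
        benchmarking; ``scale=0`` returns the baseline means, ``scale=1`` this
        parameter set.
        """

        def mix(a: float, b: float, lo: float, hi: float) -> float:
            return float(min(max(a + scale * (b - a), lo), hi))

        return replace(
            self,
            mean_call_duration=mix(baseline.mean_call_duration, self.mean_call_duration, 0.015, 0.2),
            intra_bout_pause_mean=mix(
                baseline.intra_bout_pause_mean, self.intra_bout_pause_mean, 0.04, 0.21
            ),
            inter_bout_pause_mean=mix(
                baseline.inter_bout_pause_mean, self.inter_bout_pause_mean, 0.5, 20.0
            ),
            calls_per_bout_mean=mix(
                baseline.calls_per_bout_mean, self.calls_per_bout_mean, 1.05, 30.0
            ),
            isolated_call_prob=mix(
                baseline.isolated_call_prob, self.isolated_call_prob, 0.003, 0.6
            ),
            max_jump_mean=mix(baseline.max_jump_mean, self.max_jump_mean, 1_000.0, 30_000.0),
            jump_prob_per_call=mix(
                baseline.jump_prob_per_call, self.jump_prob_per_call, 0.02, 0.95
            ),
        )


@dataclass(frozen=True)
class RecordingMeta:
    """Identity and session metadata for one recording."""

    animal_id: str
    genotype: str
    day: int
    weight: float | None = None
    sex: str | None = None
    duration: float = RECORDING_DURATION

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}, got {self.day!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M', 'F' or None")


def _sd(sem: float, n: int) -> float:
    return sem * math.sqrt(n)


# Group summaries: per-animal means +/- SEM, reconstructed to SDs with the
# reported group sizes. HET groups mirror WT (no HET/WT difference was found).
_P8_WT = GenotypeParams(
    mean_call_duration=0.052,
    intra_bout_pause_mean=0.133,
    inter_bout_pause_mean=2.31,
    calls_per_bout_mean=5.28,
    isolated_call_prob=0.078,
    jump_prob_per_call=0.64,
    max_jump_mean=12_689.0,
    duration_sd_between=_sd(0.002, 41),
    intra_sd_between=_sd(0.002, 41),
    inter_sd_between=_sd(0.169, 41),
    calls_per_bout_sd_between=_sd(0.243, 41),
    isolated_sd_between=_sd(0.007, 41),
    max_jump_sd_between=_sd(746, 41),
    weight_mean=4.34,
    weight_sd_between=_sd(0.11, 41),
)

_P8_KO = GenotypeParams(
    mean_call_duration=0.046,
    intra_bout_pause_mean=0.144,
    inter_bout_pause_mean=1.96,
    calls_per_bout_mean=3.66,
    isolated_call_prob=0.129,
    jump_prob_per_call=0.43,
    max_jump_mean=8_687.0,
    duration_sd_between=_sd(0.002, 15),
    intra_sd_between=_sd(0.003, 15),
    inter_sd_between=_sd(0.360, 15),
    calls_per_bout_sd_between=_sd(0.26, 15),
    isolated_sd_between=_sd(0.015, 15),
    max_jump_sd_between=_sd(953, 15),
    weight_mean=3.85,
    weight_sd_between=_sd(0.14, 15),
    high_band_power_scale=0.6,
    # knockouts use a narrower, more repetitive repertoire: both entropies drop
    nonjump_type_probs=(
        ("flat", 0.55),
        ("up-fm", 0.08),
        ("down-fm", 0.25),
        ("chevron", 0.07),
        ("other", 0.05),
    ),
    label_persistence=0.55,
)

_P5_WT = GenotypeParams(
    mean_call_duration=0.044,
    intra_bout_pause_mean=0.157,
    inter_bout_pause_mean=2.61,
    calls_per_bout_mean=6.04,
    isolated_call_prob=0.106,
    jump_prob_per_call=0.60,
    max_jump_mean=11_485.0,
    duration_sd_between=_sd(0.002, 40),
    intra_sd_between=_sd(0.003, 40),
    inter_sd_between=_sd(0.228, 40),
    calls_per_bout_sd_between=_sd(0.449, 40),
    isolated_sd_between=_sd(0.017, 40),
    max_jump_sd_between=_sd(550, 40),
    weight_mean=3.25,
    weight_sd_between=_sd(0.09, 40),
)

_P5_KO = GenotypeParams(
    mean_call_duration=0.041,
    intra_bout_pause_mean=0.170,
    inter_bout_pause_mean=3.78,
    calls_per_bout_mean=3.69,
    isolated_call_prob=0.179,
    jump_prob_per_call=0.40,
    max_jump_mean=8_947.0,
    duration_sd_between=_sd(0.002, 13),
    intra_sd_between=_sd(0.005, 13),
    inter_sd_between=_sd(1.37, 13),
    calls_per_bout_sd_between=_sd(0.45, 13),
    isolated_sd_between=_sd(0.031, 13),
    max_jump_sd_between=_sd(1141, 13),
    weight_mean=2.97,
    weight_sd_between=_sd(0.10, 13),
    high_band_power_scale=0.7,
    nonjump_type_probs=(
        ("flat", 0.55),
        ("up-fm", 0.08),
        ("down-fm", 0.25),
        ("chevron", 0.07),
        ("other", 0.05),
    ),
    label_persistence=0.55,
)

PRESETS: dict[tuple[str, int], GenotypeParams] = {
    ("WT", 8): _P8_WT,
    ("HET", 8): _P8_WT,
    ("KO", 8): _P8_KO,
    ("WT", 5): _P5_WT,
    ("HET", 5): _P5_WT,
    ("KO", 5): _P5_KO,
}

#: Group sizes of the study cohorts (genotype, day) -> n animals.
COHORT_SIZES: dict[tuple[str, int], int] = {
    ("WT", 5): 40,
    ("KO", 5): 13,
    ("WT", 8): 41,
    ("KO", 8): 15,
}


def preset(genotype: str, day: int) -> GenotypeParams:
    """Return the shipped parameter set for one genotype/day cell."""
    try:
        return PRESETS[(genotype, day)]
    except KeyError:
        raise KeyError(f"no preset for genotype={genotype!r}, day={day!r}") from None
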