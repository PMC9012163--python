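import numpy as np
import pytest

from penkin.kinematics import SegmentationParams
from penkin.simulate import GeneratorConfig, generate_cohort


def noiseless_config(**kw) -> GeneratorConfig:
    """Generator with all noise scales effectively off."""
    base = dict(
        seed=0,
        subject_sd_duration=1e-12, subject_sd_trajectory=1e-12,
        trial_sd_duration=1e-12, trial_sd_trajectory=1e-12,
        position_jitter_sd=0.0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 6-subject-per-group cohort with default noise."""
    return generate_cohort(GeneratorConfig(seed=42, n_subjects_per_group=6,
                                           trials_per_bigram=3))


def brute_force_peak_count(x: np.ndarray, prominence_frac: float,
                           min_separation_samples: int) -> int:
    """Independent O(n^2) reimplementation of the dysfluency peak count.

    Interior local maxima (plateaus once, at their midpoint), topographic
    prominence computed by exhaustive scans, threshold relative to the
    profile maximum, then greedy removal of smaller peaks closer than the
    separation.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return 0
    # plateau-aware interior local maxima
    peaks = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    if not peaks:
        return 0
    # exhaustive topographic prominence
    prominences = []
    for p in peaks:
        left_min = x[p]
        k = p - 1
        while k >= 0 and x[k] <= x[p]:
            left_min = min(left_min, x[k])
            k -= 1
        if k < 0:
            left_base = left_min
        else:
            left_base = left_min
        right_min = x[p]
        k = p + 1
        while k < n and x[k] <= x[p]:
            right_min = min(right_min, x[k])
            k += 1
        right_base = right_min
        prominences.append(x[p] - max(left_base, right_base))
    thr = prominence_frac * float(x.max())
    cand = [p for p, pr in zip(peaks, prominences) if pr >= thr]
    # greedy separation filter: tallest first (ties by index), a peak is
    # counted only if every already-counted peak is far enough away
    order = sorted(cand, key=lambda p: (-x[p], p))
    kept = []
    for p in order:
        if all(abs(p - k) >= min_separation_samples for k in kept):
            kept.append(p)
    return len(kept)
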