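"""Pulse normalization and dataset splitting.

Every raw beat is brought onto the canonical representation used throughout
the package: 100 samples, linearly resampled over the pulse duration, then
min-max scaled to [0, 1].  Splits are pulse-level (a subject may contribute
to several partitions), 70/30 train+val/test with the validation set taken
as 30% of the training portion.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateInputError",
    "N_SAMPLES",
    "normalize_pulse",
    "normalize_pulses",
    "znormalize_pulse",
    "split_dataset",
]

N_SAMPLES = 100


class DegenerateInputError(ValueError):
    """Raised for constant (zero-range / zero-variance) pulses."""


def normalize_pulse(raw: np.ndarray, n_samples: int = N_SAMPLES) -> np.ndarray:
    """Resample a raw beat to ``n_samples`` points and min-max scale to [0, 1].

    Resampling is linear interpolation onto equally spaced points over the
    pulse duration; amplitude scaling follows resampling.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("pulse must be a 1-D array of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("pulse contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("constant pulse cannot be amplitude-normalized")
    grid = np.linspace(0.0, x.size - 1.0, n_samples)
    y = np.interp(grid, np.arange(x.size), x)
    return (y - y.min()) / (y.max() - y.min())


def normalize_pulses(pulses, n_samples: int = N_SAMPLES) -> np.ndarray:
    """Stack :func:`normalize_pulse` over a sequence of raw beats -> (n, 100)."""
    return np.vstack([normalize_pulse(p, n_samples) for p in pulses])


def znormalize_pulse(pulse: np.ndarray) -> np.ndarray:
    """Zero-mean, unit population-variance (ddof=0) version of a pulse."""
    x = np.asarray(pulse, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance pulse cannot be z-normalized")
    return (x - x.mean()) / sd


def split_dataset(
    n_pulses: int,
    test_frac: float = 0.30,
    val_frac: float = 0.30,
    seed: int = 0,
) -> np.ndarray:
    """Random pulse-level partition into 'train' / 'val' / 'test'.

    ``test_frac`` of all pulses go to the test set; ``val_frac`` of the
    remaining training portion to validation.  Sizes are rounded to the
    nearest integer; deterministic under ``seed``.
    """
    if n_pulses < 10:
        raise ValueError("need at least 10 pulses to split")
    for f in (test_frac, val_frac):
        if not 0.0 < f < 1.0:
            raise ValueError("split fractions must lie in (0, 1)")
    n_test = int(round(test_frac * n_pulses))
    n_val = int(round(val_frac * (n_pulses - n_test)))
    if min(n_test, n_val, n_pulses - n_test - n_val) < 1:
        raise ValueError("split fractions leave an empty partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pulses)
    tags = np.empty(n_pulses, dtype="<U5")
    tags[order[:n_test]] = "test"
    tags[order[n_test:n_test + n_val]] = "val"
    tags[order[n_test + n_val:]] = "train"
    return tags
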