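"""Small descriptive-statistics helpers shared across modules.

The study design reports group values as mean ± SEM only (no hypothesis
testing), so this is deliberately minimal.
"""
from __future__ import annotations

import math

import numpy as np

from .exceptions import ParameterError


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD, n-1 denominator).

    A single observation yields SEM 0.0 (callers flag n == 1 where the
    distinction matters); an empty input is a parameter error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ParameterError("mean_sem requires at least one value")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
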