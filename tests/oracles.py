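"""Independent brute-force oracles used to check the package's fast paths.

Everything here is written with explicit Python loops and textbook formulas,
deliberately sharing no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def max_projection_loop(volume: np.ndarray) -> np.ndarray:
    """Pixelwise max over slices of a (slices, rows, cols) volume, by loops."""
    n_slices, rows, cols = volume.shape
    out = np.zeros((rows, cols), dtype=volume.dtype)
    for r in range(rows):
        for c in range(cols):
            best = volume[0, r, c]
            for z in range(1, n_slices):
                if volume[z, r, c] > best:
                    best = volume[z, r, c]
            out[r, c] = best
    return out


def clipped_subtract_loop(ch2: np.ndarray, ch1: np.ndarray, gain: float) -> np.ndarray:
    rows, cols = ch2.shape
    out = np.zeros((rows, cols), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            v = float(ch2[r, c]) - gain * float(ch1[r, c])
            out[r, c] = v if v > 0 else 0.0
    return out


def nested_anova_loop(y, treatments, containers):
    """Two-level nested ANOVA sums of squares by explicit accumulation.

    Returns a dict with ss/df/ms for treatment, container-within-treatment
    and residual, plus the F ratio of ms_treatment over ms_container.
    """
    y = [float(v) for v in y]
    n = len(y)
    grand = sum(y) / n

    trt_values: dict = {}
    cont_values: dict = {}
    cont_of: dict = {}
    for yi, t, c in zip(y, treatments, containers):
        trt_values.setdefault(t, []).append(yi)
        cont_values.setdefault(c, []).append(yi)
        cont_of[c] = t

    ss_treatment = 0.0
    for t, vals in trt_values.items():
        mean_t = sum(vals) / len(vals)
        ss_treatment += len(vals) * (mean_t - grand) ** 2

    ss_container = 0.0
    ss_residual = 0.0
    for c, vals in cont_values.items():
        mean_c = sum(vals) / len(vals)
        t_vals = trt_values[cont_of[c]]
        mean_t = sum(t_vals) / len(t_vals)
        ss_container += len(vals) * (mean_c - mean_t) ** 2
        for v in vals:
            ss_residual += (v - mean_c) ** 2

    a = len(trt_values)
    ctot = len(cont_values)
    df_treatment = a - 1
    df_container = ctot - a
    df_residual = n - ctot
    ms_treatment = ss_treatment / df_treatment
    ms_container = ss_container / df_container if df_container > 0 else float("nan")
    ms_residual = ss_residual / df_residual if df_residual > 0 else float("nan")
    F = ms_treatment / ms_container if ms_container else float("inf")
    return {
        "ss_treatment": ss_treatment,
        "ss_container": ss_container,
        "ss_residual": ss_residual,
        "df_treatment": df_treatment,
        "df_container": df_container,
        "df_residual": df_residual,
        "ms_treatment": ms_treatment,
        "ms_container": ms_container,
        "ms_residual": ms_residual,
        "F": F,
    }


def pooled_t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b):
    """Student's pooled t from summary statistics (textbook closed form)."""
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    t = (mean_a - mean_b) / math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return t, df


def sample_with_moments(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Draw a sample and affinely rescale it to have the exact sample
    mean/SD requested (ddof=1)."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
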