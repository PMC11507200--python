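"""Shared fixtures and literal per-pixel oracle implementations.

The oracles re-state each stain's color rule as a plain Python loop,
independent of the vectorized code paths, so equivalence tests are meaningful.
"""

from __future__ import annotations

import statistics

import numpy as np
import pytest

from scarquant.classifiers import StainParams


@pytest.fixture(params=["mts", "ttc", "psr", "he"])
def stain(request) -> str:
    return request.param


@pytest.fixture
def default_params(stain) -> StainParams:
    return StainParams.for_stain(stain)


def random_rgb(rng: np.random.Generator, shape=(32, 32)) -> np.ndarray:
    return rng.integers(0, 256, size=(*shape, 3), dtype=np.uint8)


# --- literal per-pixel rules -------------------------------------------------


def mts_rule_oracle(image: np.ndarray, r_limit: int, br_ratio_min: float) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in image[i, j])
            blue_dominant = (b >= br_ratio_min * r) if r > 0 else (b > 0)
            out[i, j] = r <= r_limit and blue_dominant
    return out


def ttc_rule_oracle(image: np.ndarray, std_max: float) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = statistics.stdev(int(v) for v in image[i, j]) <= std_max
    return out


def psr_rule_oracle(image: np.ndarray, thd: float) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in image[i, j])
            out[i, j] = 2 * r - g - b >= 2 * thd
    return out


def he_transform_oracle(image: np.ndarray, r_limit: int) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w, 3), np.uint8)
    for i in range(h):
        for j in range(w):
            r, g, b = (int(v) for v in image[i, j])
            r = 0 if r > r_limit else r
            g = 0 if g > r_limit else g
            b = 0 if b > r_limit else b
            if r < g or b < g:
                out[i, j] = (0, g, 0)
            else:
                out[i, j] = (0, 0, 0)
    return out


def background_rule_oracle(image: np.ndarray, white_min: int) -> np.ndarray:
    h, w, _ = image.shape
    out = np.zeros((h, w), bool)
    for i in range(h):
        for j in range(w):
            out[i, j] = min(int(v) for v in image[i, j]) < white_min
    return out
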