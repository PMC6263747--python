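"""Symbolic Aggregate approXimation: PAA, Gaussian breakpoints, words, MINDIST.

A segment is z-normalized, reduced to ``word_length`` frame means by Piecewise
Aggregate Approximation, and each mean is mapped to a letter through
equal-probability breakpoints of the standard normal.  Bins are half-open
``[beta_{i-1}, beta_i)``: a value exactly at a breakpoint takes the higher
letter.  Consecutive identical words can be dropped losslessly (numerosity
reduction) because every word keeps its start index.  The symbolic distance
``sax_mindist`` lower-bounds the Euclidean distance between the z-normalized
raw windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model import AlphabetConfig, ParameterError, Segment, SymbolicWord, WordSequence
from .segmentation import SD_FLOOR, znormalize

__all__ = [
    "paa",
    "gaussian_breakpoints",
    "SAXModel",
    "sax_transform",
    "sax_word_sequence",
    "numerosity_reduce",
    "numerosity_expand",
    "sax_mindist",
]


def paa(values: np.ndarray, m: int) -> np.ndarray:
    """Piecewise Aggregate Approximation: ``m`` frame means of the input.

    When ``m`` divides ``n`` the frames are the contiguous blocks of length
    ``n/m``; otherwise fractional frame boundaries weight boundary samples
    proportionally so frame means are exact for any length.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 1 <= m <= n:
        raise ParameterError(f"PAA size {m} must be in [1, {n}]")
    if n % m == 0:
        return values.reshape(m, n // m).mean(axis=1)
    out = np.empty(m)
    bounds = np.linspace(0.0, float(n), m + 1)
    for i in range(m):
        lo, hi = bounds[i], bounds[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        idx = np.arange(j0, j1)
        weights = np.minimum(idx + 1.0, hi) - np.maximum(idx.astype(float), lo)
        out[i] = float(np.dot(values[j0:j1], weights) / (hi - lo))
    return out


def gaussian_breakpoints(c: int) -> np.ndarray:
    """Breakpoints splitting the standard normal into ``c`` equal-area bins."""
    if not 2 <= c <= 26:
        raise ParameterError("alphabet size must be in [2, 26]")
    return stats.norm.ppf(np.arange(1, c) / c)


@dataclass
class SAXModel:
    alphabet: AlphabetConfig = field(default_factory=AlphabetConfig)
    breakpoints: np.ndarray | None = None
    sd_floor: float = SD_FLOOR

    def __post_init__(self) -> None:
        if self.breakpoints is None:
            self.breakpoints = gaussian_breakpoints(self.alphabet.size)
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if len(self.breakpoints) != self.alphabet.size - 1:
            raise ParameterError("need exactly c - 1 breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ParameterError("breakpoints must be strictly increasing")


def _letters_for(values: np.ndarray, model: SAXModel) -> str:
    # half-open bins: value exactly at a breakpoint takes the higher letter
    indices = np.searchsorted(model.breakpoints, values, side="right")
    return "".join(model.alphabet.letter(i) for i in indices)


def sax_transform(segment: Segment, model: SAXModel) -> SymbolicWord:
    """z-normalize, PAA-average, and map frame means to letters."""
    if len(segment) < model.alphabet.word_length:
        raise ParameterError("segment shorter than word_length")
    means = paa(znormalize(segment.values, model.sd_floor), model.alphabet.word_length)
    return SymbolicWord(
        letters=_letters_for(means, model),
        start_index=segment.start_index,
        axis_tag=segment.axis_tag,
    )


def sax_word_sequence(segments: list[Segment], model: SAXModel) -> WordSequence:
    return WordSequence([sax_transform(s, model) for s in segments])


def _paa_operator(n: int, m: int) -> np.ndarray:
    """(n, m) linear operator so that ``values @ op == paa(values, m)``."""
    op = np.zeros((n, m))
    bounds = np.linspace(0.0, float(n), m + 1)
    for i in range(m):
        lo, hi = bounds[i], bounds[i + 1]
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        idx = np.arange(j0, j1)
        op[j0:j1, i] = (np.minimum(idx + 1.0, hi) - np.maximum(idx.astype(float), lo)) / (hi - lo)
    return op


def sax_words_batch(
    windows: np.ndarray, starts: np.ndarray, model: SAXModel, axis_tag: str = "x"
) -> list[SymbolicWord]:
    """Vectorized :func:`sax_transform` over a (n_windows, w) array."""
    windows = np.asarray(windows, dtype=float)
    mean = windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, keepdims=True)
    normed = np.where(sd < model.sd_floor, 0.0, (windows - mean) / np.where(sd == 0, 1.0, sd))
    means = normed @ _paa_operator(windows.shape[1], model.alphabet.word_length)
    indices = np.searchsorted(model.breakpoints, means.ravel(), side="right").reshape(means.shape)
    letters = model.alphabet.letters
    return [
        SymbolicWord("".join(letters[k] for k in row), int(s), axis_tag)
        for row, s in zip(indices, starts)
    ]


def numerosity_reduce(seq: WordSequence) -> WordSequence:
    """Collapse runs of equal consecutive words to their first occurrence.

    Lossless: with the window stride and final start index,
    :func:`numerosity_expand` reconstructs the original sequence exactly.
    """
    if seq.reduced:
        raise ParameterError("sequence already reduced")
    kept: list[SymbolicWord] = []
    for word in seq.words:
        if kept and kept[-1].letters == word.letters and kept[-1].axis_tag == word.axis_tag:
            continue
        kept.append(word)
    return WordSequence(kept, reduced=True)


def numerosity_expand(seq: WordSequence, stride: int, last_start: int) -> WordSequence:
    """Invert :func:`numerosity_reduce` given the stride and final start index."""
    if not seq.reduced:
        raise ParameterError("sequence is not reduced")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    words: list[SymbolicWord] = []
    for i, word in enumerate(seq.words):
        end = seq.words[i + 1].start_index if i + 1 < len(seq.words) else last_start + stride
        for start in range(word.start_index, end, stride):
            words.append(SymbolicWord(word.letters, start, word.axis_tag))
    return WordSequence(words, reduced=False)


def sax_mindist(w1: SymbolicWord, w2: SymbolicWord, model: SAXModel, n: int) -> float:
    """Lower-bounding symbolic distance between two words from length-``n`` windows.

    Letters at most one bin apart contribute 0; otherwise the gap between the
    breakpoints separating them.  Scaled by ``sqrt(n / l)`` this never exceeds
    the Euclidean distance of the z-normalized raw windows.
    """
    l = model.alphabet.word_length
    if len(w1.letters) != l or len(w2.letters) != l:
        raise ParameterError("word length does not match the model")
    letters = model.alphabet.letters
    try:
        a = np.array([letters.index(ch) for ch in w1.letters])
        b = np.array([letters.index(ch) for ch in w2.letters])
    except ValueError as exc:
        raise ParameterError("word contains letters outside the alphabet") from exc
    hi, lo = np.maximum(a, b), np.minimum(a, b)
    top = model.breakpoints[np.clip(hi - 1, 0, len(model.breakpoints) - 1)]
    bot = model.breakpoints[np.clip(lo, 0, len(model.breakpoints) - 1)]
    cells = np.where(hi - lo <= 1, 0.0, top - bot)
    return float(np.sqrt(n / l) * np.sqrt(np.sum(cells**2)))
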