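"""Symbolic Fourier Approximation: DFT/MFT, MCB quantization, supervised SFA-W.

A window is approximated by the interleaved real/imaginary parts of its first
Fourier coefficients and each coefficient is quantized against per-column
breakpoints learned from training data (Multiple Coefficient Binning).  The
sliding-window coefficients can be maintained incrementally (momentary Fourier
transform), which matches a direct transform of every window to numerical
precision.

The supervised variant used by WEASEL ("SFA-W") z-normalizes the windows,
ranks all available coefficient columns by a one-way ANOVA F statistic against
the class labels, keeps the top ``l``, and places breakpoints per kept column
by recursive information-gain splitting instead of equi-depth quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import f_classif

from .data_model import (
    AlphabetConfig,
    InsufficientDataError,
    ParameterError,
    Segment,
    SymbolicWord,
    WordSequence,
)
from .segmentation import SD_FLOOR, znormalize

__all__ = [
    "fourier_approximate",
    "mft_sliding",
    "MCBModel",
    "fit_mcb",
    "fit_mcb_from_matrix",
    "sfa_transform",
    "sfa_word_sequence",
    "anova_f_select",
    "info_gain_breakpoints",
    "fit_sfa_w",
]


# ---------------------------------------------------------------------------
# approximation
# ---------------------------------------------------------------------------

def _interleave(coeffs: np.ndarray) -> np.ndarray:
    """(..., k) complex -> (..., 2k) real with (real, imag) pairs."""
    out = np.empty(coeffs.shape[:-1] + (2 * coeffs.shape[-1],))
    out[..., 0::2] = coeffs.real
    out[..., 1::2] = coeffs.imag
    return out


def fourier_approximate(segment: Segment | np.ndarray, l: int, drop_dc: bool = False) -> np.ndarray:
    """First ``l/2`` Fourier coefficients as ``l`` interleaved real values.

    Uses the plain forward transform (negative-exponent, unnormalized).  With
    ``drop_dc`` the first retained coefficient is the fundamental instead of
    the DC term.
    """
    values = segment.values if isinstance(segment, Segment) else np.asarray(segment, float)
    if l % 2 != 0 or l < 2:
        raise ParameterError("l must be a positive even number of real values")
    start = 1 if drop_dc else 0
    if l // 2 + start > len(values):
        raise ParameterError(f"l={l} requests more coefficients than the window provides")
    coeffs = np.fft.fft(values)[start : start + l // 2]
    return _interleave(coeffs)


def mft_sliding(
    series: np.ndarray,
    window: int,
    l: int,
    drop_dc: bool = False,
    stride: int = 1,
) -> np.ndarray:
    """Momentary Fourier transform of every sliding window of ``series``.

    Maintains the coefficients of window ``p + 1`` from window ``p`` via
    ``X_k(p+1) = e^{2 pi i k / w} (X_k(p) - x_p + x_{p+w})`` and returns the
    interleaved coefficients for window starts ``0, stride, 2*stride, ...``.
    Equal to a direct transform of each window to ~1e-9.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < window:
        raise InsufficientDataError("series shorter than the window")
    if l % 2 != 0 or l < 2:
        raise ParameterError("l must be a positive even number of real values")
    start = 1 if drop_dc else 0
    ks = np.arange(start, start + l // 2)
    if ks.size and ks[-1] >= window:
        raise ParameterError("requested coefficients beyond the window length")
    twiddle = np.exp(2j * np.pi * ks / window)
    state = np.fft.fft(series[:window])[ks].astype(complex)
    keep = [state.copy()]
    for p in range(n - window):
        state = twiddle * (state - series[p] + series[p + window])
        if (p + 1) % stride == 0:
            keep.append(state.copy())
    return _interleave(np.vstack(keep))


# ---------------------------------------------------------------------------
# quantization (MCB)
# ---------------------------------------------------------------------------

@dataclass
class MCBModel:
    """Fitted Multiple Coefficient Binning quantizer.

    ``coeff_indices`` are positions in the interleaved coefficient vector
    (after DC removal when ``drop_dc``); one strictly increasing breakpoint
    row per selected column.  With ``normalize`` windows are z-normalized
    before the transform, making words invariant to offset and scale.
    """

    alphabet: AlphabetConfig
    coeff_indices: list[int]
    breakpoints: np.ndarray
    normalize: bool = False
    drop_dc: bool = False
    sd_floor: float = SD_FLOOR
    variant: str = "equi_depth"

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if self.breakpoints.shape != (len(self.coeff_indices), self.alphabet.size - 1):
            raise ParameterError("need one breakpoint row of length c - 1 per column")
        if np.any(np.diff(self.breakpoints, axis=1) <= 0):
            raise ParameterError("breakpoint rows must be strictly increasing")
        if len(self.coeff_indices) != self.alphabet.word_length:
            raise ParameterError("number of selected columns must equal word_length")


def _strictly_increasing(values: np.ndarray) -> np.ndarray:
    """Stable de-duplication: bump ties by a tiny epsilon so rows increase."""
    out = np.array(values, dtype=float)
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            eps = max(abs(out[i - 1]) * 1e-9, 1e-9)
            out[i] = out[i - 1] + eps
    return out


def _equi_depth_row(column: np.ndarray, c: int) -> np.ndarray:
    ordered = np.sort(column)
    n = len(ordered)
    idx = [max(int(math.ceil(i * n / c)) - 1, 0) for i in range(1, c)]
    return _strictly_increasing(ordered[idx])


def _sorted_prefix_row(column: np.ndarray, c: int) -> np.ndarray:
    ordered = np.sort(column)
    return _strictly_increasing(ordered[: c - 1])


def _coefficient_matrix(segments: list[Segment], l: int, normalize: bool) -> np.ndarray:
    rows = []
    for seg in segments:
        values = znormalize(seg.values, SD_FLOOR) if normalize else seg.values
        rows.append(fourier_approximate(values, l, drop_dc=normalize))
    return np.vstack(rows)


def fit_mcb(
    training: list[Segment],
    l: int = 8,
    c: int = 4,
    variant: str = "equi_depth",
    normalize: bool = False,
) -> MCBModel:
    """Fit per-column breakpoints from training windows.

    ``equi_depth`` (default) places breakpoints at the ``i*N/c``-th order
    statistics of each coefficient column; ``sorted_prefix`` takes the first
    ``c - 1`` ascending-sorted values of the column.  Training windows should
    be extracted without overlap so they are independent.
    """
    if variant not in ("equi_depth", "sorted_prefix"):
        raise ParameterError(f"unknown MCB variant {variant!r}")
    if len(training) < c:
        raise InsufficientDataError(f"MCB needs >= {c} training segments")
    matrix = _coefficient_matrix(training, l, normalize)
    return fit_mcb_from_matrix(
        matrix,
        coeff_indices=list(range(l)),
        alphabet=AlphabetConfig(size=c, word_length=l),
        variant=variant,
        normalize=normalize,
    )


def fit_mcb_from_matrix(
    matrix: np.ndarray,
    coeff_indices: list[int],
    alphabet: AlphabetConfig,
    variant: str = "equi_depth",
    normalize: bool = False,
    breakpoint_rows: np.ndarray | None = None,
) -> MCBModel:
    c = alphabet.size
    if breakpoint_rows is None:
        row_fn = _equi_depth_row if variant == "equi_depth" else _sorted_prefix_row
        breakpoint_rows = np.vstack([row_fn(matrix[:, j], c) for j in coeff_indices])
    return MCBModel(
        alphabet=alphabet,
        coeff_indices=list(coeff_indices),
        breakpoints=breakpoint_rows,
        normalize=normalize,
        drop_dc=normalize,
        variant=variant,
    )


def sfa_transform(segment: Segment, model: MCBModel) -> SymbolicWord:
    """Quantize the selected coefficients of one window into a word."""
    values = znormalize(segment.values, model.sd_floor) if model.normalize else segment.values
    needed = 2 * ((max(model.coeff_indices) // 2) + 1)
    coeffs = fourier_approximate(values, needed, drop_dc=model.drop_dc)
    letters = []
    for row, j in enumerate(model.coeff_indices):
        # half-open bins: a coefficient exactly at a breakpoint takes the higher letter
        k = int(np.searchsorted(model.breakpoints[row], coeffs[j], side="right"))
        letters.append(model.alphabet.letter(k))
    return SymbolicWord(
        letters="".join(letters), start_index=segment.start_index, axis_tag=segment.axis_tag
    )


def sfa_word_sequence(segments: list[Segment], model: MCBModel) -> WordSequence:
    return WordSequence([sfa_transform(s, model) for s in segments])


def sfa_words_batch(
    windows: np.ndarray, starts: np.ndarray, model: MCBModel, axis_tag: str = "x"
) -> list[SymbolicWord]:
    """Vectorized :func:`sfa_transform` over a (n_windows, w) array."""
    windows = np.asarray(windows, dtype=float)
    if model.normalize:
        mean = windows.mean(axis=1, keepdims=True)
        sd = windows.std(axis=1, keepdims=True)
        windows = np.where(
            sd < model.sd_floor, 0.0, (windows - mean) / np.where(sd == 0, 1.0, sd)
        )
    start = 1 if model.drop_dc else 0
    k = (max(model.coeff_indices) // 2) + 1
    coeffs = _interleave(np.fft.fft(windows, axis=1)[:, start : start + k])
    cols = np.empty((windows.shape[0], len(model.coeff_indices)), dtype=int)
    for row, j in enumerate(model.coeff_indices):
        cols[:, row] = np.searchsorted(model.breakpoints[row], coeffs[:, j], side="right")
    letters = model.alphabet.letters
    return [
        SymbolicWord("".join(letters[k] for k in row), int(s), axis_tag)
        for row, s in zip(cols, starts)
    ]


# ---------------------------------------------------------------------------
# supervised selection and binning (SFA-W)
# ---------------------------------------------------------------------------

def anova_f_select(coeff_table: np.ndarray, labels, l: int) -> list[int]:
    """Indices of the ``l`` columns with the largest one-way ANOVA F statistic.

    Columns that are constant within and across classes get F = 0 and rank
    last; columns with zero within-class variance but distinct class means
    rank first.
    """
    coeff_table = np.asarray(coeff_table, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("ANOVA selection needs >= 2 classes")
    if np.any(counts < 1) or len(labels) < len(classes) + 1:
        raise ParameterError("every class needs samples and N must exceed the class count")
    if not 1 <= l <= coeff_table.shape[1]:
        raise ParameterError("keep count l out of range")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(coeff_table, labels)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-f_stat, kind="stable")
    return [int(i) for i in order[:l]]


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray) -> tuple[float, float] | None:
    """Best midpoint cut and its information gain inside one sorted partition."""
    n = len(values)
    base = _entropy(labels)
    best = None
    for i in range(n - 1):
        if values[i + 1] <= values[i]:
            continue  # only cut between distinct adjacent values
        cut = 0.5 * (values[i] + values[i + 1])
        left, right = labels[: i + 1], labels[i + 1 :]
        gain = base - (len(left) * _entropy(left) + len(right) * _entropy(right)) / n
        if best is None or gain > best[1] + 1e-12:
            best = (cut, gain)
    return best


def _equi_depth_distinct(column: np.ndarray, c: int) -> np.ndarray:
    distinct = np.unique(column)
    if len(distinct) == 1:
        return _strictly_increasing(np.repeat(distinct[0], c - 1))
    idx = [max(int(math.ceil(i * len(distinct) / c)) - 1, 0) for i in range(1, c)]
    return _strictly_increasing(distinct[idx])


def info_gain_breakpoints(column: np.ndarray, labels, c: int) -> np.ndarray:
    """Place ``c - 1`` breakpoints by recursive binary information-gain splits.

    Each split picks the midpoint between adjacent distinct values that
    maximizes label information gain; recursion continues on the remaining
    partition with the largest label entropy.  Columns with fewer distinct
    values than ``c`` or with no informative cut fall back to equi-depth
    placement over the distinct values.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    if len(column) != len(labels):
        raise ParameterError("column and labels must align")
    if not 2 <= c <= 26:
        raise ParameterError("alphabet size must be in [2, 26]")
    if len(np.unique(column)) < c:
        return _equi_depth_distinct(column, c)
    order = np.argsort(column, kind="stable")
    values, labs = column[order], labels[order]
    # partitions are index ranges into the sorted arrays
    partitions: list[tuple[int, int]] = [(0, len(values))]
    cuts: list[float] = []
    while len(cuts) < c - 1:
        # split the partition with the largest label entropy first
        scored = sorted(
            range(len(partitions)),
            key=lambda i: (
                -_entropy(labs[partitions[i][0] : partitions[i][1]]),
                -(partitions[i][1] - partitions[i][0]),
                i,
            ),
        )
        placed = False
        for pi in scored:
            lo, hi = partitions[pi]
            found = _best_cut(values[lo:hi], labs[lo:hi])
            if found is None or found[1] <= 0:
                continue
            cut, _ = found
            mid = lo + int(np.searchsorted(values[lo:hi], cut, side="right"))
            partitions[pi : pi + 1] = [(lo, mid), (mid, hi)]
            cuts.append(cut)
            placed = True
            break
        if not placed:  # no informative cut anywhere: fill with equi-depth
            for cand in _equi_depth_distinct(column, c):
                if len(cuts) < c - 1 and all(abs(cand - x) > 1e-12 for x in cuts):
                    cuts.append(float(cand))
            while len(cuts) < c - 1:
                cuts.append((max(cuts) if cuts else float(values[-1])) + 1e-9)
            break
    return _strictly_increasing(np.sort(np.asarray(cuts)))


def fit_sfa_w(
    training: list[Segment],
    labels,
    l: int = 8,
    c: int = 4,
) -> MCBModel:
    """Fit the supervised quantizer: ANOVA column selection + info-gain bins.

    Windows are z-normalized (required by the F test's normality assumption),
    all coefficient columns the window length supports are ranked, the top
    ``l`` are kept, and each kept column gets ``c - 1`` information-gain
    breakpoints.
    """
    if len(training) < c:
        raise InsufficientDataError(f"need >= {c} training segments")
    labels = np.asarray(labels)
    w = len(training[0])
    l_full = 2 * max((w - 1) // 2, l // 2)  # every post-DC column the window supports
    matrix = _coefficient_matrix(training, l_full, normalize=True)
    selected = anova_f_select(matrix, labels, l)
    rows = np.vstack([info_gain_breakpoints(matrix[:, j], labels, c) for j in selected])
    return fit_mcb_from_matrix(
        matrix,
        coeff_indices=selected,
        alphabet=AlphabetConfig(size=c, word_length=l),
        variant="info_gain",
        normalize=True,
        breakpoint_rows=rows,
    )
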