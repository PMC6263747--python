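"""Core domain types and readers/writers for raw sensor logs and symbolic artifacts.

The central container is :class:`SignalFrame`, a labeled multi-user stream of
triaxial accelerometer samples with a declared sampling rate.  Symbolic
artifacts produced downstream (word sequences, word histograms, tf-idf weight
matrices) are plain-text serializable: words as TSV, histograms and weight
matrices as JSON.
"""

from __future__ import annotations

import csv
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "InsufficientDataError",
    "EmptyInputError",
    "IrregularSamplingError",
    "NoEvidenceError",
    "SignalFrame",
    "Segment",
    "AlphabetConfig",
    "SymbolicWord",
    "WordSequence",
    "Histogram",
    "WeightMatrix",
    "CostProfile",
    "LoadReport",
    "read_har_csv",
    "write_har_csv",
    "write_words",
    "read_words",
    "write_histogram",
    "read_histogram",
    "write_weight_matrix",
    "read_weight_matrix",
]


class ParameterError(ValueError):
    """An argument is outside the valid range of a model or operation."""


class InsufficientDataError(ValueError):
    """Fewer samples / segments than an operation requires."""


class EmptyInputError(ValueError):
    """A source yielded no parseable content."""


class IrregularSamplingError(ValueError):
    """Timestamp spacing deviates too far from the median to infer a rate."""


class NoEvidenceError(RuntimeError):
    """A query shares no vocabulary with any trained class."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

COLUMNS = ("user", "activity", "timestamp", "x", "y", "z")


@dataclass
class LoadReport:
    parsed: int = 0
    skipped: int = 0


@dataclass
class SignalFrame:
    """Labeled triaxial sample stream.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``user, activity, timestamp, x, y, z``; one row per sample.
    fs : float
        Sampling rate in Hz (declared metadata; streams are not resampled).
    """

    data: pd.DataFrame
    fs: float
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ParameterError(f"SignalFrame missing columns {missing}")
        if not self.fs > 0:
            raise ParameterError("sampling rate fs must be > 0")
        for user, grp in self.data.groupby("user", sort=False):
            ts = grp["timestamp"].to_numpy(float)
            if len(ts) > 1 and np.any(np.diff(ts) < 0):
                raise ParameterError(f"timestamps decrease within user {user!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def users(self) -> list:
        return list(pd.unique(self.data["user"]))

    @property
    def labels(self) -> list:
        return sorted(pd.unique(self.data["activity"]))

    def axis(self, name: str) -> np.ndarray:
        if name not in ("x", "y", "z"):
            raise ParameterError(f"unknown axis {name!r}")
        return self.data[name].to_numpy(float)


AXIS_TAGS = ("x", "y", "z", "mag", "pc1", "stacked")


@dataclass
class Segment:
    """A fixed-length window of one axis (or fused 1-D signal)."""

    values: np.ndarray
    label: object = None
    axis_tag: str = "x"
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ParameterError("segment values must be a nonempty 1-D vector")
        if self.start_index < 0:
            raise ParameterError("start_index must be >= 0")
        if self.axis_tag not in AXIS_TAGS:
            raise ParameterError(f"axis_tag must be one of {AXIS_TAGS}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AlphabetConfig:
    """Alphabet size ``c`` and word length ``l`` shared by all discretizers."""

    size: int = 4
    word_length: int = 8

    def __post_init__(self) -> None:
        if not 2 <= self.size <= 26:
            raise ParameterError("alphabet size must be in [2, 26]")
        if self.word_length < 1:
            raise ParameterError("word_length must be >= 1")

    @property
    def letters(self) -> str:
        return string.ascii_lowercase[: self.size]

    def letter(self, index: int) -> str:
        return self.letters[index]


@dataclass(frozen=True)
class SymbolicWord:
    letters: str
    start_index: int = 0
    axis_tag: str = "x"

    @property
    def key(self) -> str:
        """Histogram key; axis-tagged so per-axis vocabularies never collide."""
        return f"{self.axis_tag}:{self.letters}"


@dataclass
class WordSequence:
    """Ordered symbolic words with original-series start indexes."""

    words: list[SymbolicWord] = field(default_factory=list)
    reduced: bool = False

    def __post_init__(self) -> None:
        starts = [w.start_index for w in self.words]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("word start_index must be strictly increasing")
        if self.reduced:
            for a, b in zip(self.words, self.words[1:]):
                if a.letters == b.letters and a.axis_tag == b.axis_tag:
                    raise ParameterError("reduced sequence has equal consecutive words")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


@dataclass
class Histogram:
    """Word -> count mapping (bag of words); absent words are implicitly 0."""

    counts: dict[str, int] = field(default_factory=dict)
    class_label: object = None

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.counts.values()):
            raise ParameterError("histogram counts must be >= 1")

    def add(self, word: str, n: int = 1) -> None:
        self.counts[word] = self.counts.get(word, 0) + n

    def get(self, word: str) -> int:
        return self.counts.get(word, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "Histogram") -> "Histogram":
        out = Histogram(dict(self.counts), self.class_label)
        for w, n in other.counts.items():
            out.add(w, n)
        return out


@dataclass
class WeightMatrix:
    """Per-class tf-idf weight vectors over a shared vocabulary."""

    vocabulary: list[str]
    class_labels: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.class_labels), len(self.vocabulary)):
            raise ParameterError("weights must be class x word shaped")
        if np.any(self.weights < 0):
            raise ParameterError("tf-idf weights must be nonnegative")

    def row(self, label) -> np.ndarray:
        return self.weights[self.class_labels.index(label)]


@dataclass
class CostProfile:
    """Canonical byte accounting and stage timings for one pipeline run."""

    bytes_raw: int = 0
    bytes_repr: int = 0
    extract_ms: float = 0.0
    train_ms: float = 0.0

    def __post_init__(self) -> None:
        if min(self.bytes_raw, self.bytes_repr) < 0 or min(self.extract_ms, self.train_ms) < 0:
            raise ParameterError("cost profile fields must be >= 0")


# ---------------------------------------------------------------------------
# raw-log reader
# ---------------------------------------------------------------------------

def _infer_fs(df: pd.DataFrame) -> float:
    diffs = []
    for _, grp in df.groupby("user", sort=False):
        ts = grp["timestamp"].to_numpy(float)
        if len(ts) > 1:
            diffs.append(np.diff(ts))
    if not diffs:
        raise EmptyInputError("cannot infer sampling rate from a single sample")
    dt = np.concatenate(diffs)
    med = float(np.median(dt))
    if med <= 0:
        raise IrregularSamplingError("median timestamp spacing is not positive")
    # conservative guard: declared-rate datasets are near-uniform
    if np.any(np.abs(dt - med) > 0.2 * med):
        raise IrregularSamplingError("timestamp spacing varies > 20% from median")
    return 1.0 / med


def read_har_csv(path, dialect: str = "clean", fs: float | None = None) -> SignalFrame:
    """Read a delimited accelerometer log.

    ``clean`` expects a ``user,activity,timestamp,x,y,z`` header; ``wisdm``
    is the raw headerless dialect with a trailing ``";"`` per line.  Malformed
    lines are skipped and counted in the returned frame's ``load_report``.
    """
    if dialect not in ("clean", "wisdm"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    path = Path(path)
    report = LoadReport()
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        first = True
        for raw in reader:
            if dialect == "clean" and first:
                first = False
                if [c.strip().lower() for c in raw] == list(COLUMNS):
                    continue  # header
            if dialect == "wisdm" and raw:
                raw = list(raw)
                raw[-1] = raw[-1].rstrip().rstrip(";")
            fields = [f.strip() for f in raw if f.strip() != ""]
            if len(fields) != 6:
                report.skipped += 1
                continue
            try:
                rows.append(
                    (fields[0], fields[1], float(fields[2]),
                     float(fields[3]), float(fields[4]), float(fields[5]))
                )
            except ValueError:
                report.skipped += 1
                continue
            report.parsed += 1
    if not rows:
        raise EmptyInputError(f"no parseable sample lines in {path}")
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if fs is None:
        fs = _infer_fs(df)
    return SignalFrame(df, fs=fs, load_report=report)


def write_har_csv(frame: SignalFrame, path) -> None:
    """Write a SignalFrame in the clean header dialect."""
    frame.data.to_csv(path, index=False, columns=list(COLUMNS))


# ---------------------------------------------------------------------------
# symbolic-artifact persistence (TSV for words, JSON otherwise)
# ---------------------------------------------------------------------------

def write_words(seq: WordSequence, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("axis_tag\tstart_index\tletters\n")
        for w in seq.words:
            fh.write(f"{w.axis_tag}\t{w.start_index}\t{w.letters}\n")
        fh.write(f"# reduced={seq.reduced}\n")


def read_words(path) -> WordSequence:
    words = []
    reduced = False
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "axis_tag\tstart_index\tletters":
            raise ParameterError(f"not a word archive: {path}")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# reduced="):
                reduced = line.split("=", 1)[1] == "True"
                continue
            if not line:
                continue
            tag, start, letters = line.split("\t")
            words.append(SymbolicWord(letters=letters, start_index=int(start), axis_tag=tag))
    return WordSequence(words, reduced=reduced)


def write_histogram(hist: Histogram, path) -> None:
    payload = {"class_label": hist.class_label, "counts": hist.counts}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_histogram(path) -> Histogram:
    payload = json.loads(Path(path).read_text())
    return Histogram(counts=dict(payload["counts"]), class_label=payload["class_label"])


def write_weight_matrix(wm: WeightMatrix, path) -> None:
    payload = {
        "vocabulary": wm.vocabulary,
        "class_labels": list(wm.class_labels),
        "weights": [list(map(float, row)) for row in wm.weights],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_weight_matrix(path) -> WeightMatrix:
    payload = json.loads(Path(path).read_text())
    return WeightMatrix(
        vocabulary=list(payload["vocabulary"]),
        class_labels=list(payload["class_labels"]),
        weights=np.asarray(payload["weights"], dtype=float),
    )
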