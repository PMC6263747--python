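"""Cross-validation, accuracy reporting, and cost profiling.

Stratified k-fold cross-validation at the instance (default) or user level.
All fitting — MCB quantizers, idf tables, chi-squared masks, PCA fusion,
linear models — happens inside the training folds only.  Reports are
reproducible bit-for-bit given (data, config, seed).

Cost accounting is representation-canonical rather than in-memory: raw data
costs 8 bytes per sample per axis; a symbolic word costs
``ceil(l * log2(c) / 8)`` packed letter bytes plus a 4-byte start index; a
feature table costs 8 bytes per value.  Timings are reported, never asserted.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .data_model import CostProfile, ParameterError, SignalFrame, WordSequence
from .fusion import make_fusion

__all__ = [
    "EvaluationReport",
    "cross_validate",
    "profile_cost",
    "packed_word_bytes",
    "pack_letters",
    "unpack_letters",
]


@dataclass
class EvaluationReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray
    class_labels: list
    cost: CostProfile
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "class_labels": [str(c) for c in self.class_labels],
            "cost": {
                "bytes_raw": self.cost.bytes_raw,
                "bytes_repr": self.cost.bytes_repr,
                "extract_ms": self.cost.extract_ms,
                "train_ms": self.cost.train_ms,
            },
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _folds(labels, users, k, unit, seed):
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    offending = classes[counts < k]
    if unit == "instance":
        if offending.size:
            raise ParameterError(
                f"cannot stratify: class {offending[0]!r} has fewer than {k} instances"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(labels)), labels))
    if unit == "user":
        if users is None:
            raise ParameterError("user-level folds need a users vector")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(labels)), labels, groups=np.asarray(users)))
    raise ParameterError("unit must be 'instance' or 'user'")


def cross_validate(
    instances: list[dict[str, np.ndarray]],
    labels,
    make_classifier,
    fusion: str = "stack",
    k: int = 10,
    unit: str = "instance",
    users=None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold evaluation of a symbolic pipeline.

    ``make_classifier`` is a zero-argument factory returning a fresh
    fit/predict object; the fusion transform (including PCA) is refit inside
    every training fold so no test information leaks into fitting.
    """
    labels = np.asarray(labels)
    if len(instances) < k:
        raise ParameterError("fewer instances than folds")
    class_order = sorted(np.unique(labels))
    folds = _folds(labels, users, k, unit, seed)
    fold_acc: list[float] = []
    confusion = np.zeros((len(class_order), len(class_order)), dtype=int)
    train_ms = 0.0
    for train_idx, test_idx in folds:
        missing = set(class_order) - set(labels[train_idx])
        if missing:
            raise ParameterError(f"class {sorted(missing)[0]!r} absent from a training fold")
        fuser = make_fusion(fusion).fit([instances[i] for i in train_idx])
        train = [fuser.transform(instances[i]) for i in train_idx]
        test = [fuser.transform(instances[i]) for i in test_idx]
        clf = make_classifier()
        t0 = time.perf_counter()
        clf.fit(train, list(labels[train_idx]))
        train_ms += (time.perf_counter() - t0) * 1e3
        pred = clf.predict(test)
        truth = labels[test_idx]
        fold_acc.append(float(np.mean(np.asarray(pred) == truth)))
        confusion += confusion_matrix(truth, pred, labels=class_order)
    cost = CostProfile(train_ms=train_ms / k)
    return EvaluationReport(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=confusion,
        class_labels=class_order,
        cost=cost,
        config={"fusion": fusion, "k": k, "unit": unit},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cost accounting
# ---------------------------------------------------------------------------

def packed_word_bytes(word_length: int, alphabet_size: int) -> int:
    """Canonical packed size of one word: letter bits rounded up plus index."""
    letter_bits = word_length * math.ceil(math.log2(alphabet_size))
    return math.ceil(letter_bits / 8) + 4  # 4-byte start index


# letter codes for the 4-letter alphabet; larger alphabets use sequential codes
_CODES_C4 = {"a": 0b00, "b": 0b10, "c": 0b11, "d": 0b01}
_DECODE_C4 = {v: k for k, v in _CODES_C4.items()}


def pack_letters(letters: str, alphabet_size: int = 4) -> bytes:
    """Pack a word's letters into bits (2 bits per letter for alphabet 4)."""
    bits_per = math.ceil(math.log2(alphabet_size))
    acc = 0
    nbits = 0
    for ch in letters:
        if alphabet_size == 4:
            code = _CODES_C4[ch]
        else:
            code = ord(ch) - ord("a")
            if not 0 <= code < alphabet_size:
                raise ParameterError(f"letter {ch!r} outside alphabet of size {alphabet_size}")
        acc = (acc << bits_per) | code
        nbits += bits_per
    pad = (-nbits) % 8
    acc <<= pad
    return acc.to_bytes((nbits + pad) // 8, "big")


def unpack_letters(data: bytes, word_length: int, alphabet_size: int = 4) -> str:
    bits_per = math.ceil(math.log2(alphabet_size))
    acc = int.from_bytes(data, "big")
    total_bits = len(data) * 8
    letters = []
    for i in range(word_length):
        shift = total_bits - (i + 1) * bits_per
        code = (acc >> shift) & ((1 << bits_per) - 1)
        if alphabet_size == 4:
            letters.append(_DECODE_C4[code])
        else:
            letters.append(chr(ord("a") + code))
    return "".join(letters)


def profile_cost(
    raw: SignalFrame,
    word_sequences: list[WordSequence] | None = None,
    n_features: int | None = None,
    n_instances: int = 0,
    extract_ms: float = 0.0,
    train_ms: float = 0.0,
    word_length: int = 8,
    alphabet_size: int = 4,
) -> CostProfile:
    """Canonical byte accounting for one pipeline run.

    Raw cost is ``samples x 3 axes x 8`` bytes.  Symbolic cost is the packed
    word size times the word count; feature-table cost is
    ``instances x features x 8``.
    """
    bytes_raw = len(raw) * 3 * 8
    bytes_repr = 0
    if word_sequences is not None:
        per_word = packed_word_bytes(word_length, alphabet_size)
        bytes_repr += per_word * sum(len(seq) for seq in word_sequences)
    if n_features is not None:
        bytes_repr += n_instances * n_features * 8
    return CostProfile(
        bytes_raw=bytes_raw, bytes_repr=bytes_repr, extract_ms=extract_ms, train_ms=train_ms
    )
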