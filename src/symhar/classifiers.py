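"""Bag-of-words classification of symbolic sensor words.

Four classifiers over word histograms:

* ``SAXVSM``   — per-class tf-idf vectors from SAX words, cosine similarity.
* ``BOSSVS``   — the same vector-space scheme over SFA words.
* ``BOSS``     — 1-nearest-neighbor over per-instance SFA histograms with the
  asymmetric BOSS distance.
* ``WEASEL``   — supervised SFA words (ANOVA + information-gain bins), unigram
  and non-overlapping-bigram counts over several window sizes, chi-squared
  feature filtering, multinomial logistic regression.

An *instance* throughout is a mapping ``axis_tag -> 1-D signal`` (three axes
for the stacking strategy, a single fused axis for magnitude/PCA); words are
axis-tagged so per-axis vocabularies never collide in a shared histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.linear_model import LogisticRegression

from .data_model import (
    AlphabetConfig,
    Histogram,
    NoEvidenceError,
    ParameterError,
    Segment,
    SymbolicWord,
    WeightMatrix,
    WordSequence,
)
from .sax import SAXModel, numerosity_reduce, sax_transform, sax_words_batch
from .segmentation import WindowingConfig, sliding_windows
from .sfa import MCBModel, fit_mcb, fit_sfa_w, sfa_transform, sfa_words_batch

logger = logging.getLogger(__name__)

__all__ = [
    "build_class_bags",
    "tf_weight",
    "idf_weight",
    "tfidf_matrix",
    "cosine_similarity",
    "VSMModel",
    "classify_vsm",
    "boss_distance",
    "BOSSModel",
    "classify_boss_1nn",
    "make_bigrams",
    "WeaselFeatures",
    "weasel_featurize",
    "weasel_transform",
    "train_linear_classifier",
    "SAXVSM",
    "BOSS",
    "BOSSVS",
    "WEASEL",
]


# ---------------------------------------------------------------------------
# bags and tf-idf weighting
# ---------------------------------------------------------------------------

def build_class_bags(
    sequences: list[tuple[WordSequence, object]], reduce: bool = True
) -> dict[object, Histogram]:
    """Group word counts by class label, optionally after numerosity reduction."""
    if not sequences:
        raise ParameterError("no word sequences supplied")
    bags: dict[object, Histogram] = {}
    for seq, label in sequences:
        if reduce and not seq.reduced:
            seq = numerosity_reduce(seq)
        bag = bags.setdefault(label, Histogram(class_label=label))
        for word in seq:
            bag.add(word.key)
    return bags


def tf_weight(f: float, base: float = 10.0) -> float:
    """Logarithmic term frequency: ``log(1 + f)`` for positive counts, else 0."""
    if f < 0:
        raise ParameterError("count must be nonnegative")
    return float(np.log(1.0 + f) / np.log(base)) if f > 0 else 0.0


def idf_weight(word: str, class_bags: dict[object, Histogram], base: float = 10.0) -> float:
    """``log(T / df)`` with ``T`` classes and ``df`` classes containing the word."""
    t = len(class_bags)
    df = sum(1 for bag in class_bags.values() if bag.get(word) > 0)
    if df == 0:
        raise ParameterError(f"word {word!r} occurs in no class bag")
    return float(np.log(t / df) / np.log(base))


def tfidf_matrix(class_bags: dict[object, Histogram], base: float = 10.0) -> WeightMatrix:
    """Per-class tf-idf weights; a word absent from a class has weight exactly 0."""
    if len(class_bags) < 2:
        logger.warning("tf-idf over a single class: all idf values are 0")
    labels = list(class_bags)
    vocabulary = sorted({w for bag in class_bags.values() for w in bag.counts})
    idf = np.array([idf_weight(w, class_bags, base) for w in vocabulary])
    weights = np.zeros((len(labels), len(vocabulary)))
    for i, label in enumerate(labels):
        bag = class_bags[label]
        weights[i] = [tf_weight(bag.get(w), base) for w in vocabulary]
    return WeightMatrix(vocabulary=vocabulary, class_labels=labels, weights=weights * idf)


def cosine_similarity(q: np.ndarray, a: np.ndarray) -> float:
    q, a = np.asarray(q, float), np.asarray(a, float)
    nq, na = np.linalg.norm(q), np.linalg.norm(a)
    if nq == 0 and na == 0:
        raise NoEvidenceError("both vectors are zero; similarity undefined")
    if nq == 0 or na == 0:
        return 0.0
    return float(np.dot(q, a) / (nq * na))


@dataclass
class VSMModel:
    """Trained vector-space model: weight matrix plus the training idf table."""

    weight_matrix: WeightMatrix
    idf_table: dict[str, float]
    discretizer: object = None
    config: dict = field(default_factory=dict)
    class_priors: dict = field(default_factory=dict)
    tf_base: float = 10.0


def classify_vsm(
    query_words,
    model: VSMModel,
    on_no_evidence: str = "error",
):
    """Assign the class whose tf-idf vector is most cosine-similar to the query.

    Query weights are ``tf(query count) * training idf``; words unseen in
    training contribute 0.  A query sharing no word with any class raises
    :class:`NoEvidenceError` or, with ``on_no_evidence='fallback'``, returns
    the most frequent training class.
    """
    wm = model.weight_matrix
    query = Histogram()
    for word in query_words:
        query.add(word.key)
    index = {w: i for i, w in enumerate(wm.vocabulary)}
    q = np.zeros(len(wm.vocabulary))
    for word, count in query.counts.items():
        if word in index:
            q[index[word]] = tf_weight(count, model.tf_base) * model.idf_table[word]
    if not np.any(q):
        if on_no_evidence == "fallback" and model.class_priors:
            return max(model.class_priors, key=model.class_priors.get)
        raise NoEvidenceError("query shares no weighted word with any class")
    sims = np.array([cosine_similarity(q, row) for row in wm.weights])
    best = int(np.argmax(sims))
    if np.sum(np.isclose(sims, sims[best])) > 1:
        logger.warning("cosine-similarity tie; keeping the first class in order")
    return wm.class_labels[best]


# ---------------------------------------------------------------------------
# BOSS distance and 1-NN
# ---------------------------------------------------------------------------

def boss_distance(h1: Histogram, h2: Histogram) -> float:
    """Asymmetric squared histogram distance over words present in ``h1``."""
    return float(sum((n1 - h2.get(w)) ** 2 for w, n1 in h1.counts.items()))


@dataclass
class BOSSModel:
    histograms: list[Histogram]
    labels: list
    discretizer: object = None

    def __post_init__(self) -> None:
        if not self.histograms or len(self.histograms) != len(self.labels):
            raise ParameterError("need one label per training histogram")


def classify_boss_1nn(query: Histogram, model: BOSSModel):
    """Label of the training histogram minimizing the BOSS distance."""
    dists = [boss_distance(query, h) for h in model.histograms]
    best = int(np.argmin(dists))
    if dists.count(dists[best]) > 1:
        logger.warning("BOSS 1-NN distance tie; keeping the smallest training index")
    return model.labels[best]


# ---------------------------------------------------------------------------
# WEASEL features
# ---------------------------------------------------------------------------

def make_bigrams(words: list[str]) -> list[str]:
    """Pair consecutive non-overlapping words: (w1 w2), (w3 w4), ..."""
    return [f"{words[i]} {words[i + 1]}" for i in range(0, len(words) - 1, 2)]


@dataclass
class WeaselFeatures:
    """Fitted WEASEL feature space: vocabulary, chi2 scores and keep-mask."""

    vocabulary: list[str]
    chi2_scores: np.ndarray
    keep_mask: np.ndarray
    keep_high: bool = True

    @property
    def kept_vocabulary(self) -> list[str]:
        return [w for w, k in zip(self.vocabulary, self.keep_mask) if k]


def _instance_feature_counts(words_by_window: dict) -> dict[str, int]:
    """Unigram + bigram counts, tagged by window size and axis."""
    counts: dict[str, int] = {}
    for (win, axis), words in words_by_window.items():
        letters = [w.letters if isinstance(w, SymbolicWord) else str(w) for w in words]
        for token in letters:
            key = f"u:{win}:{axis}:{token}"
            counts[key] = counts.get(key, 0) + 1
        for token in make_bigrams(letters):
            key = f"b:{win}:{axis}:{token}"
            counts[key] = counts.get(key, 0) + 1
    return counts


def _counts_to_csr(all_counts: list[dict[str, int]], vocab_index: dict[str, int]) -> sparse.csr_matrix:
    data, indices, indptr = [], [], [0]
    for counts in all_counts:
        for word, n in counts.items():
            j = vocab_index.get(word)
            if j is not None:
                indices.append(j)
                data.append(n)
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (data, indices, indptr), shape=(len(all_counts), len(vocab_index))
    )


def weasel_featurize(
    words_by_instance: list[dict],
    labels,
    chi2_threshold: float = 2.0,
    keep_high: bool = True,
) -> tuple[WeaselFeatures, sparse.csr_matrix]:
    """Build the unigram/bigram feature space and its chi-squared keep-mask.

    Each instance supplies ``{(window_size, axis): [words]}``.  A feature's
    chi-squared statistic is computed from its counts against the class
    labels; with ``keep_high`` (default) class-discriminative features — large
    statistic — are retained and the rest masked out.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("chi-squared filtering needs >= 2 classes")
    all_counts = [_instance_feature_counts(w) for w in words_by_instance]
    vocabulary = sorted({w for counts in all_counts for w in counts})
    if not vocabulary:
        raise ParameterError("no words to featurize")
    vocab_index = {w: i for i, w in enumerate(vocabulary)}
    matrix = _counts_to_csr(all_counts, vocab_index)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores, _ = sk_chi2(matrix, labels)
    scores = np.nan_to_num(scores, nan=0.0)
    mask = scores >= chi2_threshold if keep_high else scores < chi2_threshold
    if not mask.any():
        logger.warning("chi-squared mask removed every feature; keeping all")
        mask = np.ones_like(mask, dtype=bool)
    features = WeaselFeatures(vocabulary, scores, mask, keep_high)
    return features, matrix[:, mask]


def weasel_transform(words_by_instance: list[dict], features: WeaselFeatures) -> sparse.csr_matrix:
    """Apply a fitted vocabulary and keep-mask to new instances."""
    vocab_index = {w: i for i, w in enumerate(features.vocabulary)}
    matrix = _counts_to_csr(
        [_instance_feature_counts(w) for w in words_by_instance], vocab_index
    )
    return matrix[:, features.keep_mask]


def train_linear_classifier(
    features: sparse.csr_matrix,
    labels,
    regularization: float = 1.0,
    seed: int = 0,
) -> LogisticRegression:
    """Multinomial logistic regression over the kept WEASEL features."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("need >= 2 classes")
    if np.any(counts < 2):
        raise ParameterError("need >= 2 instances per class")
    model = LogisticRegression(
        C=1.0 / regularization, max_iter=5000, random_state=seed
    )
    model.fit(features, labels)
    return model


# ---------------------------------------------------------------------------
# end-to-end symbolic classifiers over instances
# ---------------------------------------------------------------------------

def _axis_windows(series: np.ndarray, window: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    series = np.asarray(series, dtype=float)
    if len(series) < window:
        raise ParameterError(f"instance length {len(series)} < window {window}")
    views = np.lib.stride_tricks.sliding_window_view(series, window)[::stride]
    starts = np.arange(0, len(series) - window + 1, stride)
    return views, starts


def _instance_histogram(seqs: list[WordSequence]) -> Histogram:
    hist = Histogram()
    for seq in seqs:
        for word in seq:
            hist.add(word.key)
    return hist


def _nonoverlap_segments(instances, labels, window: int) -> tuple[list[Segment], list]:
    """Windows without overlap for MCB training (keeps them independent)."""
    cfg = WindowingConfig(window_samples=window, overlap_fraction=0.0)
    segs: list[Segment] = []
    seg_labels: list = []
    for inst, label in zip(instances, labels):
        for axis, series in inst.items():
            for seg in sliding_windows(series, cfg, axis_tag=axis):
                segs.append(seg)
                seg_labels.append(label)
    return segs, seg_labels


class _BagClassifierBase:
    """Shared windowing / word-extraction plumbing for the bag classifiers.

    ``stride`` overrides ``overlap`` when given; the BOSS-family classifiers
    default to dense stride-1 sliding (the bag-of-patterns construction),
    SAX-VSM to 50% overlap.
    """

    def __init__(
        self,
        window_samples: int = 50,
        word_length: int = 8,
        alphabet_size: int = 4,
        overlap: float = 0.5,
        stride: int | None = None,
        reduce_numerosity: bool = True,
    ) -> None:
        self.window_samples = window_samples
        self.alphabet = AlphabetConfig(size=alphabet_size, word_length=word_length)
        if stride is None:
            stride = WindowingConfig(
                window_samples=window_samples, overlap_fraction=overlap
            ).stride
        if stride < 1:
            raise ParameterError("stride must be >= 1")
        self.stride = stride
        self.reduce_numerosity = reduce_numerosity
        self.classes_: list = []

    def _words_batch(self, windows, starts, axis_tag):  # pragma: no cover - abstract
        raise NotImplementedError

    def _sequences(self, instance) -> list[WordSequence]:
        seqs = []
        for axis, series in instance.items():
            views, starts = _axis_windows(series, self.window_samples, self.stride)
            seq = WordSequence(self._words_batch(views, starts, axis))
            seqs.append(numerosity_reduce(seq) if self.reduce_numerosity else seq)
        return seqs

    def instance_histogram(self, instance) -> Histogram:
        return _instance_histogram(self._sequences(instance))


class SAXVSM(_BagClassifierBase):
    """SAX words + per-class tf-idf vectors + cosine similarity."""

    def __init__(self, on_no_evidence: str = "fallback", **kwargs) -> None:
        super().__init__(**kwargs)
        self.on_no_evidence = on_no_evidence
        self.sax_model = SAXModel(alphabet=self.alphabet)
        self.model_: VSMModel | None = None

    def _words_batch(self, windows, starts, axis_tag):
        return sax_words_batch(windows, starts, self.sax_model, axis_tag)

    def fit(self, instances, labels):
        sequences = []
        for inst, label in zip(instances, labels):
            for seq in self._sequences(inst):
                sequences.append((seq, label))
        bags = build_class_bags(sequences, reduce=False)  # already reduced per sequence
        wm = tfidf_matrix(bags)
        idf = {w: idf_weight(w, bags) for w in wm.vocabulary}
        priors: dict = {}
        for label in labels:
            priors[label] = priors.get(label, 0) + 1
        self.model_ = VSMModel(
            weight_matrix=wm,
            idf_table=idf,
            discretizer=self.sax_model,
            config={"window_samples": self.window_samples},
            class_priors=priors,
        )
        self.classes_ = list(wm.class_labels)
        return self

    def predict(self, instances):
        out = []
        for inst in instances:
            words = [w for s in self._sequences(inst) for w in s]
            out.append(classify_vsm(words, self.model_, on_no_evidence=self.on_no_evidence))
        return out


class _SFABagBase(_BagClassifierBase):
    """Fits one MCB quantizer per axis tag on non-overlapping training windows."""

    def __init__(self, normalize: bool = False, mcb_variant: str = "equi_depth", **kwargs) -> None:
        kwargs.setdefault("stride", 1)  # dense bag-of-patterns sliding
        super().__init__(**kwargs)
        self.normalize = normalize
        self.mcb_variant = mcb_variant
        self.mcb_: dict[str, MCBModel] = {}

    def _words_batch(self, windows, starts, axis_tag):
        return sfa_words_batch(windows, starts, self.mcb_[axis_tag], axis_tag)

    def _fit_mcb(self, instances):
        cfg = WindowingConfig(window_samples=self.window_samples, overlap_fraction=0.0)
        per_axis: dict[str, list[Segment]] = {}
        for inst in instances:
            for axis, series in inst.items():
                per_axis.setdefault(axis, []).extend(
                    sliding_windows(series, cfg, axis_tag=axis)
                )
        self.mcb_ = {
            axis: fit_mcb(
                segs,
                l=self.alphabet.word_length,
                c=self.alphabet.size,
                variant=self.mcb_variant,
                normalize=self.normalize,
            )
            for axis, segs in per_axis.items()
        }


class BOSS(_SFABagBase):
    """Bag-of-SFA-symbols with 1-NN classification under the BOSS distance."""

    def __init__(self, **kwargs) -> None:
        super().__init__(**kwargs)
        self.model_: BOSSModel | None = None

    def fit(self, instances, labels):
        self._fit_mcb(instances)
        hists = [self.instance_histogram(inst) for inst in instances]
        self.model_ = BOSSModel(histograms=hists, labels=list(labels), discretizer=self.mcb_)
        self.classes_ = sorted(set(labels))
        return self

    def predict(self, instances):
        return [
            classify_boss_1nn(self.instance_histogram(inst), self.model_)
            for inst in instances
        ]


class BOSSVS(_SFABagBase):
    """SFA words + per-class tf-idf vectors + cosine similarity."""

    def __init__(self, on_no_evidence: str = "fallback", **kwargs) -> None:
        super().__init__(**kwargs)
        self.on_no_evidence = on_no_evidence
        self.model_: VSMModel | None = None

    def fit(self, instances, labels):
        self._fit_mcb(instances)
        sequences = []
        for inst, label in zip(instances, labels):
            for seq in self._sequences(inst):
                sequences.append((seq, label))
        bags = build_class_bags(sequences, reduce=False)
        wm = tfidf_matrix(bags)
        idf = {w: idf_weight(w, bags) for w in wm.vocabulary}
        priors: dict = {}
        for label in labels:
            priors[label] = priors.get(label, 0) + 1
        self.model_ = VSMModel(
            weight_matrix=wm,
            idf_table=idf,
            discretizer=self.mcb_,
            config={"window_samples": self.window_samples, "normalize": self.normalize},
            class_priors=priors,
        )
        self.classes_ = list(wm.class_labels)
        return self

    def predict(self, instances):
        out = []
        for inst in instances:
            words = [w for s in self._sequences(inst) for w in s]
            out.append(classify_vsm(words, self.model_, on_no_evidence=self.on_no_evidence))
        return out


class WEASEL:
    """Supervised SFA words over several window sizes, chi2-filtered bigram
    features, multinomial logistic regression."""

    def __init__(
        self,
        window_sizes: tuple[int, ...] = (25, 50),
        word_length: int = 8,
        alphabet_size: int = 4,
        overlap: float = 0.5,
        chi2_threshold: float = 2.0,
        keep_high: bool = True,
        regularization: float = 1.0,
        seed: int = 0,
    ) -> None:
        self.window_sizes = tuple(window_sizes)
        self.word_length = word_length
        self.alphabet_size = alphabet_size
        self.overlap = overlap
        self.chi2_threshold = chi2_threshold
        self.keep_high = keep_high
        self.regularization = regularization
        self.seed = seed
        self.quantizers_: dict = {}
        self.features_: WeaselFeatures | None = None
        self.linear_: LogisticRegression | None = None
        self.classes_: list = []

    def _words_for_instance(self, instance) -> dict:
        out = {}
        for win in self.window_sizes:
            cfg = WindowingConfig(window_samples=win, overlap_fraction=self.overlap)
            for axis, series in instance.items():
                segs = sliding_windows(series, cfg, axis_tag=axis)
                model = self.quantizers_[(win, axis)]
                out[(win, axis)] = [sfa_transform(s, model) for s in segs]
        return out

    def fit(self, instances, labels):
        labels = list(labels)
        word_len = self.word_length
        for win in self.window_sizes:
            cfg = WindowingConfig(window_samples=win, overlap_fraction=0.0)
            per_axis: dict[str, tuple[list, list]] = {}
            for inst, label in zip(instances, labels):
                for axis, series in inst.items():
                    segs, labs = per_axis.setdefault(axis, ([], []))
                    new = sliding_windows(series, cfg, axis_tag=axis)
                    segs.extend(new)
                    labs.extend([label] * len(new))
            for axis, (segs, labs) in per_axis.items():
                self.quantizers_[(win, axis)] = fit_sfa_w(
                    segs, labs, l=min(word_len, 2 * ((win - 1) // 2)), c=self.alphabet_size
                )
        words = [self._words_for_instance(inst) for inst in instances]
        self.features_, matrix = weasel_featurize(
            words, labels, chi2_threshold=self.chi2_threshold, keep_high=self.keep_high
        )
        self.linear_ = train_linear_classifier(
            matrix, labels, regularization=self.regularization, seed=self.seed
        )
        self.classes_ = list(self.linear_.classes_)
        return self

    def predict(self, instances):
        words = [self._words_for_instance(inst) for inst in instances]
        matrix = weasel_transform(words, self.features_)
        return list(self.linear_.predict(matrix))


CLASSIFIERS = {"saxvsm": SAXVSM, "boss": BOSS, "bossvs": BOSSVS, "weasel": WEASEL}
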