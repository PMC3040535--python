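"""Feature extraction: peptide windows, KNN similarity scores, intrinsic
disorder, and amino-acid frequencies.

The feature vector for one candidate site is the concatenation of three
blocks, in fixed order::

    [ knn scores (one per k-fraction) | mean window disorder | 20 AA frequencies ]

KNN scores measure, for several neighborhood sizes k, the fraction of the k
reference windows most similar to the query that are known positive sites.
Similarity between two equal-length windows is the position-wise sum of
substitution-matrix entries (BLOSUM62 by default); any position where either
symbol is the pad character contributes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .core import Dataset, Label, STANDARD_AA
from .errors import MissingTrackError

PAD = "-"
#: Internal symbol alphabet: 20 standard residues, ambiguity codes, pad.
ALPHABET = STANDARD_AA + "XBZU" + PAD
_SYM_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_PAD_INDEX = _SYM_INDEX[PAD]
_N_SYMBOLS = len(ALPHABET)

DEFAULT_K_FRACTIONS = (0.0025, 0.005, 0.01, 0.02, 0.04, 0.08)
DEFAULT_HALF_WIDTH = 12


# ---------------------------------------------------------------------------
# Windows


@dataclass(frozen=True)
class SiteWindow:
    """Fixed-length peptide context centered on a candidate residue.

    ``peptide`` has length ``2 * half_width + 1``; positions outside the
    protein are filled with the pad symbol ``-``. The center is never a pad.
    """

    peptide: str
    half_width: int

    def __post_init__(self) -> None:
        if len(self.peptide) != 2 * self.half_width + 1:
            raise ValueError(
                f"window peptide length {len(self.peptide)} != {2 * self.half_width + 1}"
            )
        if self.peptide[self.half_width] == PAD:
            raise ValueError("window center must not be the pad symbol")

    @property
    def center_index(self) -> int:
        return self.half_width

    @property
    def center(self) -> str:
        return self.peptide[self.half_width]

    @property
    def pad_mask(self) -> list[bool]:
        return [c == PAD for c in self.peptide]

    def __len__(self) -> int:
        return len(self.peptide)


def extract_window(sequence: str, position: int, half_width: int) -> SiteWindow:
    """Inclusive ``[position - w, position + w]`` slice, pad-filled at the ends.

    ``position`` is 1-based.
    """
    n = len(sequence)
    if not 1 <= position <= n:
        raise IndexError(f"position {position} outside 1..{n}")
    lo = position - 1 - half_width
    hi = position - 1 + half_width
    left_pad = max(0, -lo)
    right_pad = max(0, hi - (n - 1))
    core = sequence[max(lo, 0) : min(hi, n - 1) + 1].upper()
    return SiteWindow(PAD * left_pad + core + PAD * right_pad, half_width)


def encode_windows(windows: Sequence[SiteWindow | str]) -> np.ndarray:
    """Integer-encode windows as an ``(n, L)`` array over :data:`ALPHABET`.

    Letters outside the alphabet map to ``X``.
    """
    x_index = _SYM_INDEX["X"]
    rows = []
    for w in windows:
        pep = w.peptide if isinstance(w, SiteWindow) else w
        rows.append([_SYM_INDEX.get(c, x_index) for c in pep])
    return np.asarray(rows, dtype=np.int64)


# ---------------------------------------------------------------------------
# Substitution matrix


def _build_matrix_array(entries: dict[tuple[str, str], float]) -> np.ndarray:
    m = np.zeros((_N_SYMBOLS, _N_SYMBOLS), dtype=np.float64)
    for (a, b), v in entries.items():
        if a in _SYM_INDEX and b in _SYM_INDEX and a != PAD and b != PAD:
            m[_SYM_INDEX[a], _SYM_INDEX[b]] = v
            m[_SYM_INDEX[b], _SYM_INDEX[a]] = v
    return m


@lru_cache(maxsize=4)
def load_substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    mat = substitution_matrices.load(name)
    entries: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            if a == "*" or b == "*":
                continue
            entries[(a, b)] = float(mat[a, b])
    return _build_matrix_array(entries)


def matrix_from_entries(entries: dict[tuple[str, str], float]) -> np.ndarray:
    """Array form of a user-supplied symmetric substitution map."""
    return _build_matrix_array(entries)


@dataclass(frozen=True)
class KNNConfig:
    """Configuration of the KNN score block.

    ``k_fractions`` are fractions of the (effective) reference size; the
    neighborhood size for fraction ``f`` is ``max(1, round(f * n_reference))``.
    """

    k_fractions: tuple[float, ...] = DEFAULT_K_FRACTIONS
    matrix_name: str = "BLOSUM62"
    matrix_entries: tuple | None = None  # overrides matrix_name when given
    exclude_self: bool = True

    def __post_init__(self) -> None:
        ks = tuple(self.k_fractions)
        if not ks or any(not 0 < f <= 1 for f in ks):
            raise ValueError("k_fractions must be in (0, 1]")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_fractions must be strictly increasing")
        object.__setattr__(self, "k_fractions", ks)

    def matrix(self) -> np.ndarray:
        if self.matrix_entries is not None:
            return _build_matrix_array(
                {(a, b): v for a, b, v in self.matrix_entries}
            )
        return load_substitution_matrix(self.matrix_name)

    def k_values(self, n_reference: int) -> list[int]:
        return [max(1, int(round(f * n_reference))) for f in self.k_fractions]


# ---------------------------------------------------------------------------
# Similarity and KNN scores


def window_similarity(
    a: SiteWindow | str, b: SiteWindow | str, matrix: np.ndarray | None = None
) -> float:
    """Position-wise substitution-score sum; pad positions contribute zero."""
    pa = a.peptide if isinstance(a, SiteWindow) else a
    pb = b.peptide if isinstance(b, SiteWindow) else b
    if len(pa) != len(pb):
        raise ValueError(f"window length mismatch: {len(pa)} vs {len(pb)}")
    if matrix is None:
        matrix = load_substitution_matrix()
    ea = encode_windows([pa])[0]
    eb = encode_windows([pb])[0]
    return float(matrix[ea, eb].sum())


def similarity_matrix(
    query_enc: np.ndarray, ref_enc: np.ndarray, matrix: np.ndarray
) -> np.ndarray:
    """All-pairs window similarity, ``(n_query, n_reference)``.

    Computed as a dense matmul between the one-hot encoded queries and the
    matrix-transformed references; exact for integer-valued matrices.
    """
    nq, length = query_enc.shape
    one_hot = np.zeros((nq, length, _N_SYMBOLS), dtype=np.float64)
    one_hot[np.arange(nq)[:, None], np.arange(length)[None, :], query_enc] = 1.0
    ref_scores = matrix[ref_enc]  # (nr, L, A): score of each symbol vs ref position
    return one_hot.reshape(nq, -1) @ ref_scores.reshape(ref_enc.shape[0], -1).T


def _knn_from_similarities(
    sims: np.ndarray, positive: np.ndarray, k_values: Sequence[int]
) -> np.ndarray:
    """Score one query given its similarity to every reference window.

    Ranking is by descending similarity; ties break by ascending reference
    index (stable sort), which makes the result deterministic.
    """
    order = np.argsort(-sims, kind="stable")
    cum_pos = np.cumsum(positive[order])
    return np.array([cum_pos[k - 1] / k for k in k_values], dtype=np.float64)


def knn_score_matrix(
    query_enc: np.ndarray,
    ref_enc: np.ndarray,
    ref_positive: np.ndarray,
    config: KNNConfig,
    self_indices: np.ndarray | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """KNN score block for many queries at once, ``(n_query, n_fractions)``.

    ``self_indices[i]``, when given, is the reference row that corresponds to
    query ``i`` and is excluded from its own neighborhood (leakage guard for
    training-set features); use -1 for queries with no counterpart.
    """
    n_ref = ref_enc.shape[0]
    excluding = self_indices is not None
    n_eff = n_ref - 1 if excluding else n_ref
    if n_eff < 1:
        raise ValueError("reference is empty after self-exclusion")
    k_values = config.k_values(n_eff)
    matrix = config.matrix()
    positive = np.asarray(ref_positive, dtype=np.float64)
    out = np.empty((query_enc.shape[0], len(k_values)), dtype=np.float64)
    for start in range(0, query_enc.shape[0], chunk):
        stop = min(start + chunk, query_enc.shape[0])
        sims = similarity_matrix(query_enc[start:stop], ref_enc, matrix)
        if excluding:
            for i in range(start, stop):
                si = self_indices[i]
                if si >= 0:
                    sims[i - start, si] = -np.inf
        for i in range(start, stop):
            out[i] = _knn_from_similarities(sims[i - start], positive, k_values)
    return out


def knn_scores(
    query: SiteWindow,
    reference: Dataset,
    config: KNNConfig | None = None,
    self_index: int | None = None,
) -> np.ndarray:
    """KNN score vector for a single query window against a labeled dataset.

    ``self_index`` identifies the query's own row in the reference (excluded
    from ranking when ``config.exclude_self``).
    """
    if config is None:
        config = KNNConfig()
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    ref_enc = encode_windows(reference.windows)
    positive = np.array(
        [s.label is Label.POSITIVE for s in reference.sites], dtype=np.float64
    )
    selfs = None
    if config.exclude_self and self_index is not None:
        if len(reference) == 1:
            raise ValueError("reference is empty after self-exclusion")
        selfs = np.array([self_index], dtype=np.int64)
    return knn_score_matrix(
        encode_windows([query]), ref_enc, positive, config, self_indices=selfs
    )[0]


# ---------------------------------------------------------------------------
# Amino-acid frequencies


_AA_INDEX = {c: i for i, c in enumerate(STANDARD_AA)}


def aa_frequencies(window: SiteWindow | str) -> np.ndarray:
    """Frequencies of the 20 standard residues over non-pad window positions.

    Ambiguity codes (X, U, B, Z) are excluded from both numerator and
    denominator. Returns the zero vector if no standard residue is present.
    """
    pep = window.peptide if isinstance(window, SiteWindow) else window
    counts = np.zeros(20, dtype=np.float64)
    for c in pep:
        i = _AA_INDEX.get(c)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


# ---------------------------------------------------------------------------
# Disorder

# TOP-IDP disorder propensity scale (Campen et al. 2008); higher values are
# more disorder-promoting. Ambiguity codes get the neutral value 0.
DISORDER_PROPENSITY = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

DISORDER_WINDOW = 21
_DISORDER_GAIN = 4.0


def default_disorder_track(sequence: str) -> list[float]:
    """Built-in per-residue disorder heuristic in [0, 1].

    Logistic transform of a width-21 sliding average of per-residue disorder
    propensities. A stand-in for an external disorder predictor; externally
    computed tracks can be supplied instead via protein tracks.
    """
    n = len(sequence)
    if n == 0:
        return []
    prop = np.array(
        [DISORDER_PROPENSITY.get(c, 0.0) for c in sequence.upper()], dtype=np.float64
    )
    half = DISORDER_WINDOW // 2
    csum = np.concatenate([[0.0], np.cumsum(prop)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return (1.0 / (1.0 + np.exp(-_DISORDER_GAIN * means))).tolist()


def disorder_feature(
    track: Sequence[float] | None, position: int, half_width: int
) -> float:
    """Mean track value over the window around ``position``, clipped at ends."""
    if track is None:
        raise MissingTrackError(
            "no disorder track present and no provider configured; "
            "run disorder prediction first (see the `disorder` command)"
        )
    n = len(track)
    if not 1 <= position <= n:
        raise IndexError(f"position {position} outside 1..{n}")
    lo = max(0, position - 1 - half_width)
    hi = min(n - 1, position - 1 + half_width)
    vals = track[lo : hi + 1]
    return float(sum(vals) / len(vals))


# ---------------------------------------------------------------------------
# Feature vector assembly


@dataclass
class FeatureVector:
    """Ordered numeric encoding of one candidate site."""

    values: np.ndarray
    layout: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != sum(n for _, n in self.layout):
            raise ValueError("values length does not match layout")

    def block(self, name: str) -> np.ndarray:
        start = 0
        for bname, n in self.layout:
            if bname == name:
                return self.values[start : start + n]
            start += n
        raise KeyError(name)


def feature_layout(config: KNNConfig) -> tuple[tuple[str, int], ...]:
    return (("knn", len(config.k_fractions)), ("disorder", 1), ("aa_freq", 20))


def assemble_feature_vector(
    window: SiteWindow,
    reference: Dataset,
    knn_config: KNNConfig,
    track: Sequence[float] | None,
    position: int,
    self_index: int | None = None,
) -> FeatureVector:
    """Concatenate [knn | disorder | aa_freq] for one site.

    ``track`` is the protein-level disorder track and ``position`` the site's
    1-based position in its protein.
    """
    knn = knn_scores(window, reference, knn_config, self_index=self_index)
    dis = disorder_feature(track, position, window.half_width)
    freqs = aa_frequencies(window)
    values = np.concatenate([knn, [dis], freqs])
    return FeatureVector(values=values, layout=feature_layout(knn_config))
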