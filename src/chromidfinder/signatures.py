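"""Strand-symmetrized k-mer relative-abundance signatures and distances.

The genomic signature of a replicon is the vector of relative abundances

    rho(w) = f*(w) / (f*(x1) * ... * f*(xk))      for w = x1..xk,

where f* are k-mer frequencies accumulated from the sequence *and* its
reverse complement (strand symmetrization), so the signature of a molecule
does not depend on which strand was deposited. The distance between two
signatures f and g is the scaled mean absolute difference

    delta(f, g) = scale * (1 / 4^k) * sum_w | rho_f(w) - rho_g(w) |.

Dinucleotide (k=2) signatures are used as an optional pre-screen, and
tetranucleotide (k=4) signatures drive the cluster distance filter. The
scale factor is configuration (default x10): classification thresholds are
always interpreted on the configured scale and reported together with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InsufficientSequenceError, ValidationError

DEFAULT_SCALE = 10.0

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


@lru_cache(maxsize=None)
def kmer_words(k: int) -> tuple[str, ...]:
    """All 4^k words over ACGT in lexicographic order."""
    words = [""]
    for _ in range(k):
        words = [w + b for w in words for b in "ACGT"]
    return tuple(words)


@lru_cache(maxsize=None)
def _rc_permutation(k: int) -> np.ndarray:
    """Index permutation mapping each word index to its reverse complement's index."""
    idx = np.arange(4**k)
    rc = np.zeros_like(idx)
    rest = idx.copy()
    for _ in range(k):
        digit = rest % 4
        rest //= 4
        rc = rc * 4 + (3 - digit)
    return rc


@lru_cache(maxsize=None)
def _digit_matrix(k: int) -> np.ndarray:
    """(4^k, k) matrix of base codes, most significant digit first."""
    idx = np.arange(4**k)
    out = np.empty((4**k, k), dtype=np.int64)
    for j in range(k - 1, -1, -1):
        out[:, j] = idx % 4
        idx = idx // 4
    return out


@dataclass
class CompositionSignature:
    """Relative-abundance signature of one sequence.

    Attributes
    ----------
    k : word size (2 or 4)
    values : array of 4^k relative-abundance ratios, lexicographic word order
    n_informative : number of words whose mononucleotide product is non-zero
    """

    k: int
    values: np.ndarray
    n_informative: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4**self.k,):
            raise ValidationError(
                f"signature for k={self.k} must have {4**self.k} entries, "
                f"got {self.values.shape}"
            )


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string to base codes 0..3 (A,C,G,T); anything else is 255."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_frequencies(sequence: str, k: int, symmetrize: bool = True) -> np.ndarray:
    """Sliding-window k-mer frequencies over windows containing only ACGT.

    Windows overlapping N (or any non-ACGT character) are dropped, not
    imputed. With ``symmetrize`` the counts of the reverse complement are
    accumulated before normalizing, so frequencies of complementary word
    pairs are identical. Frequencies sum to 1.
    """
    if k not in (1, 2, 4):
        raise ValidationError(f"k must be 1, 2 or 4, got {k}")
    codes = encode_sequence(sequence)
    n = codes.size
    if n < k:
        raise InsufficientSequenceError(
            f"sequence of length {n} has no window of size {k}"
        )
    m = n - k + 1
    idx = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        c = codes[j : j + m]
        ok &= c < 4
        idx = idx * 4 + np.where(c < 4, c, 0)
    counts = np.bincount(idx[ok], minlength=4**k).astype(float)
    if symmetrize:
        counts = counts + counts[_rc_permutation(k)]
    total = counts.sum()
    if total == 0:
        raise InsufficientSequenceError(
            f"no window of size {k} free of ambiguous bases"
        )
    return counts / total


def relative_abundance(sequence: str, k: int = 4) -> CompositionSignature:
    """Zero-order (mononucleotide-normalized) relative-abundance signature.

    Every word w = x1..xk gets rho(w) = f*(w) / prod_i f*(xi) with
    strand-symmetrized frequencies f*. Words whose mononucleotide product is
    zero get rho = 0 and are excluded from ``n_informative``.
    """
    if k not in (2, 4):
        raise ValidationError(f"relative abundance is defined for k in {{2, 4}}, got {k}")
    f_k = kmer_frequencies(sequence, k, symmetrize=True)
    f_1 = kmer_frequencies(sequence, 1, symmetrize=True)
    digits = _digit_matrix(k)
    mono_product = f_1[digits].prod(axis=1)
    informative = mono_product > 0
    values = np.zeros(4**k)
    values[informative] = f_k[informative] / mono_product[informative]
    return CompositionSignature(k=k, values=values, n_informative=int(informative.sum()))


def signature_distance(
    sig_f: CompositionSignature,
    sig_g: CompositionSignature,
    scale: float = DEFAULT_SCALE,
) -> float:
    """Scaled mean absolute difference between two signatures of equal k."""
    if sig_f.k != sig_g.k:
        raise ValidationError(f"signature word sizes differ: {sig_f.k} vs {sig_g.k}")
    return float(scale * np.abs(sig_f.values - sig_g.values).mean())


def sequence_distance(
    seq_a: str, seq_b: str, k: int = 4, scale: float = DEFAULT_SCALE
) -> float:
    """Relative-abundance distance between two raw sequences."""
    return signature_distance(
        relative_abundance(seq_a, k), relative_abundance(seq_b, k), scale=scale
    )
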