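"""Scoring schemes, sequence encoding, and striped query profiles.

Three substitution schemes are supported:

``actgn``
    Nucleotides A, C, T, G plus the ambiguity symbol N.  Match +2,
    mismatch -2, any pairing involving N scores 0, so ambiguous bases
    neither help nor hurt an alignment.  Any byte outside ``ACGTacgt``
    encodes to N.

``blosum62``
    The standard 24-symbol BLOSUM62 protein matrix (20 amino acids plus
    B, Z, X and the stop symbol ``*``) in NCBI ordering.  Unknown bytes
    encode to X.

``ascii``
    General text: 256 byte classes after ASCII case folding, match +2,
    mismatch -2 uniformly.

All schemes fold case, and all use affine gap penalties where a gap of
length L costs ``gap_open + (L - 1) * gap_extend`` (defaults 3 and 1).

The striped profile is the Farrar query-profile layout: query positions
are interleaved across vector lanes so that segment position ``i`` of
lane ``j`` holds the substitution score for query position
``j * segment_length + i``.  The unsigned-8-bit variant stores scores
with the scheme bias added so saturating unsigned arithmetic can
represent negative substitution scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

MATRIX_NAMES = ("actgn", "blosum62", "ascii")

NUC_ALPHABET = b"ACTGN"

BLOSUM62_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

# Published BLOSUM62 in NCBI ordering; embedded so the scheme has no
# runtime dependency, and cross-checked against Biopython in the tests.
_BLOSUM62_ROWS = (
    (4, -1, -2, -2, 0, -1, -1, 0, -2, -1, -1, -1, -1, -2, -1, 1, 0, -3, -2, 0, -2, -1, 0, -4),
    (-1, 5, 0, -2, -3, 1, 0, -2, 0, -3, -2, 2, -1, -3, -2, -1, -1, -3, -2, -3, -1, 0, -1, -4),
    (-2, 0, 6, 1, -3, 0, 0, 0, 1, -3, -3, 0, -2, -3, -2, 1, 0, -4, -2, -3, 3, 0, -1, -4),
    (-2, -2, 1, 6, -3, 0, 2, -1, -1, -3, -4, -1, -3, -3, -1, 0, -1, -4, -3, -3, 4, 1, -1, -4),
    (0, -3, -3, -3, 9, -3, -4, -3, -3, -1, -1, -3, -1, -2, -3, -1, -1, -2, -2, -1, -3, -3, -2, -4),
    (-1, 1, 0, 0, -3, 5, 2, -2, 0, -3, -2, 1, 0, -3, -1, 0, -1, -2, -1, -2, 0, 3, -1, -4),
    (-1, 0, 0, 2, -4, 2, 5, -2, 0, -3, -3, 1, -2, -3, -1, 0, -1, -3, -2, -2, 1, 4, -1, -4),
    (0, -2, 0, -1, -3, -2, -2, 6, -2, -4, -4, -2, -3, -3, -2, 0, -2, -2, -3, -3, -1, -2, -1, -4),
    (-2, 0, 1, -1, -3, 0, 0, -2, 8, -3, -3, -1, -2, -1, -2, -1, -2, -2, 2, -3, 0, 0, -1, -4),
    (-1, -3, -3, -3, -1, -3, -3, -4, -3, 4, 2, -3, 1, 0, -3, -2, -1, -3, -1, 3, -3, -3, -1, -4),
    (-1, -2, -3, -4, -1, -2, -3, -4, -3, 2, 4, -2, 2, 0, -3, -2, -1, -2, -1, 1, -4, -3, -1, -4),
    (-1, 2, 0, -1, -3, 1, 1, -2, -1, -3, -2, 5, -1, -3, -1, 0, -1, -3, -2, -2, 0, 1, -1, -4),
    (-1, -1, -2, -3, -1, 0, -2, -3, -2, 1, 2, -1, 5, 0, -2, -1, -1, -1, -1, 1, -3, -1, -1, -4),
    (-2, -3, -3, -3, -2, -3, -3, -3, -1, 0, 0, -3, 0, 6, -4, -2, -2, 1, 3, -1, -3, -3, -1, -4),
    (-1, -2, -2, -1, -3, -1, -1, -2, -2, -3, -3, -1, -2, -4, 7, -1, -1, -4, -3, -2, -2, -1, -2, -4),
    (1, -1, 1, 0, -1, 0, 0, 0, -1, -2, -2, 0, -1, -2, -1, 4, 1, -3, -2, -2, 0, 0, 0, -4),
    (0, -1, 0, -1, -1, -1, -1, -2, -2, -1, -1, -1, -1, -2, -1, 1, 5, -2, -2, 0, -1, -1, 0, -4),
    (-3, -3, -4, -4, -2, -2, -3, -2, -2, -3, -2, -3, -1, 1, -4, -3, -2, 11, 2, -3, -4, -3, -2, -4),
    (-2, -2, -2, -3, -2, -1, -2, -3, 2, -1, -1, -2, -1, 3, -3, -2, -2, 2, 7, -1, -3, -2, -1, -4),
    (0, -3, -3, -3, -1, -2, -2, -3, -3, 3, 1, -2, 1, -1, -2, -2, 0, -3, -1, 4, -3, -2, -1, -4),
    (-2, -1, 3, 4, -3, 0, 1, -1, 0, -3, -4, 0, -3, -3, -2, 0, -1, -4, -3, -3, 4, 1, -1, -4),
    (-1, 0, 0, 1, -3, 3, 4, -2, 0, -3, -3, 1, -1, -3, -1, 0, -1, -3, -2, -2, 1, 4, -1, -4),
    (0, -1, -1, -1, -2, -1, -1, -1, -1, -1, -1, -1, -1, -1, -2, 0, 0, -2, -1, -1, -1, -1, -1, -4),
    (-4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, -4, 1),
)


@dataclass(eq=False)
class ScoringScheme:
    """Alphabet encoding plus substitution matrix plus affine gap model."""

    name: str
    alphabet_size: int
    encode_table: np.ndarray  # (256,) -> symbol index
    matrix: np.ndarray  # (alphabet_size, alphabet_size) int32
    gap_open: int
    gap_extend: int
    bias: int
    case_fold: bool = True

    @property
    def max_score(self) -> int:
        return int(self.matrix.max())


@dataclass(eq=False)
class StripedProfile:
    """Lane-striped substitution scores for a fixed query (Farrar layout).

    ``scores_i16[a, i, j]`` holds ``matrix[a, q[j * segment_length + i]]``
    (0 at padding positions past the query end); ``scores_u8`` is the same
    with the scheme bias added (padding = bias).  ``valid[i, j]`` marks
    real (non-padding) positions.
    """

    encoded_query: np.ndarray
    lanes: int
    segment_length: int
    scores_u8: np.ndarray  # (A, segment_length, lanes) int32, biased
    scores_i16: np.ndarray  # (A, segment_length, lanes) int32, raw
    valid: np.ndarray  # (segment_length, lanes) bool
    scheme: ScoringScheme = field(repr=False)


def _uniform_matrix(size: int, match: int = 2, mismatch: int = -2) -> np.ndarray:
    m = np.full((size, size), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    return m


def _build_actgn() -> tuple[np.ndarray, np.ndarray, int]:
    matrix = _uniform_matrix(5)
    matrix[4, :] = 0  # N against anything
    matrix[:, 4] = 0
    table = np.full(256, 4, dtype=np.int64)  # default: N
    for idx, byte in enumerate(NUC_ALPHABET[:4]):
        table[byte] = idx
        table[byte + 32] = idx  # lower case
    return table, matrix, 5


def _build_blosum62() -> tuple[np.ndarray, np.ndarray, int]:
    matrix = np.array(_BLOSUM62_ROWS, dtype=np.int32)
    x_index = BLOSUM62_ALPHABET.index("X")
    table = np.full(256, x_index, dtype=np.int64)
    for idx, ch in enumerate(BLOSUM62_ALPHABET):
        table[ord(ch)] = idx
        if ch.isalpha():
            table[ord(ch.lower())] = idx
    return table, matrix, len(BLOSUM62_ALPHABET)


def _build_ascii() -> tuple[np.ndarray, np.ndarray, int]:
    matrix = _uniform_matrix(256)
    table = np.arange(256, dtype=np.int64)
    for byte in range(ord("A"), ord("Z") + 1):
        table[byte] = byte + 32  # fold onto lower case
    return table, matrix, 256


_BUILDERS = {
    "actgn": _build_actgn,
    "blosum62": _build_blosum62,
    "ascii": _build_ascii,
}


def build_scheme(name: str, gap_open: int = 3, gap_extend: int = 1) -> ScoringScheme:
    """Construct one of the three supported scoring schemes.

    Parameters
    ----------
    name : {"actgn", "blosum62", "ascii"}
    gap_open : int
        Cost of a length-1 gap (non-negative).
    gap_extend : int
        Cost of each additional gapped position (non-negative).
    """
    if name not in _BUILDERS:
        raise ConfigError(
            f"unknown scoring matrix {name!r}; valid choices: {', '.join(MATRIX_NAMES)}"
        )
    if gap_open < 0 or gap_extend < 0:
        raise ConfigError("gap penalties must be non-negative")
    table, matrix, size = _BUILDERS[name]()
    bias = int(-matrix.min())
    return ScoringScheme(
        name=name,
        alphabet_size=size,
        encode_table=table,
        matrix=matrix,
        gap_open=int(gap_open),
        gap_extend=int(gap_extend),
        bias=bias,
        case_fold=True,
    )


def encode_sequence(scheme: ScoringScheme, raw: bytes | str) -> np.ndarray:
    """Map a byte string onto symbol indices (length preserving).

    Case is folded; bytes outside the alphabet map to the wildcard class
    (N for actgn, X for blosum62; the ascii scheme accepts every byte).
    """
    if isinstance(raw, str):
        raw = raw.encode("latin-1")
    data = np.frombuffer(bytes(raw), dtype=np.uint8)
    return scheme.encode_table[data]


def optimal_score(scheme: ScoringScheme, encoded_query: np.ndarray) -> int:
    """Gapless self-alignment score of the query.

    This is the denominator of the normalized filter score.  A warning is
    emitted when it is not positive (e.g. an all-N query under actgn),
    because normalization is then undefined.
    """
    if len(encoded_query) == 0:
        raise ValueError("optimal_score requires a non-empty query")
    score = int(scheme.matrix[encoded_query, encoded_query].sum())
    if score <= 0:
        warnings.warn(
            "query has a non-positive self-alignment score; "
            "normalized filtering is undefined",
            stacklevel=2,
        )
    return score


def build_striped_profile(
    scheme: ScoringScheme, encoded_query: np.ndarray, lanes: int
) -> StripedProfile:
    """Build the striped (Farrar) query profile for a given lane count."""
    m = len(encoded_query)
    if m == 0:
        raise ValueError("cannot build a profile for an empty query")
    if lanes < 2 or (lanes & (lanes - 1)) != 0:
        raise ConfigError(f"lane count must be a power of two >= 2, got {lanes}")
    seg_len = -(-m // lanes)
    # query index addressed by (segment position i, lane j)
    kk = np.arange(lanes)[None, :] * seg_len + np.arange(seg_len)[:, None]
    valid = kk < m
    q_padded = np.where(valid, encoded_query[np.minimum(kk, m - 1)], 0)
    scores_i16 = scheme.matrix[:, q_padded].astype(np.int32)
    scores_i16[:, ~valid] = 0
    scores_u8 = scores_i16 + scheme.bias
    return StripedProfile(
        encoded_query=np.asarray(encoded_query, dtype=np.int64),
        lanes=lanes,
        segment_length=seg_len,
        scores_u8=scores_u8,
        scores_i16=scores_i16,
        valid=valid,
        scheme=scheme,
    )
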