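"""Shared fixtures: the worked nucleotide example, schemes, random-pair
generation, and independent pure-Python DP oracles.

The pure-Python oracles are deliberately naive full-matrix textbook
implementations, sharing no code with the package kernels, so they can
serve as an independent cross-check.
"""

import itertools

import numpy as np
import pytest

from seqsift.align_core import EndFlags
from seqsift.scoring import build_scheme, encode_sequence

# The usage example: a 31-nt query against a 53-nt contig; the embedded
# copy of the query (target bytes [11, 42)) carries 3 substitutions, so
# the best alignment scores 28*2 - 3*2 = 50 against an optimal of 62.
GOLDEN_QUERY = b"CACTTGGGCCTCAGCTTTCAGAGCCCTCGGG"
GOLDEN_TARGET = b"CGGACTCTGGGCACTTGGGCCTCAGCAAACAGAGCCCTCGGGAGGATCCGGCT"
GOLDEN_SCORE = 50
GOLDEN_OPTIMAL = 62
GOLDEN_TARGET_SPAN = (11, 42)

ALL_END_FLAGS = [EndFlags(*bits)
                 for bits in itertools.product([False, True], repeat=4)]


@pytest.fixture(scope="session")
def actgn():
    return build_scheme("actgn")


@pytest.fixture(scope="session")
def blosum62():
    return build_scheme("blosum62")


@pytest.fixture(scope="session")
def ascii_scheme():
    return build_scheme("ascii")


@pytest.fixture(scope="session")
def all_schemes(actgn, blosum62, ascii_scheme):
    return {"actgn": actgn, "blosum62": blosum62, "ascii": ascii_scheme}


@pytest.fixture(scope="session")
def golden(actgn):
    q = encode_sequence(actgn, GOLDEN_QUERY)
    t = encode_sequence(actgn, GOLDEN_TARGET)
    return actgn, q, t


@pytest.fixture(scope="session")
def make_random_pair(all_schemes):
    """Factory: (rng, scheme_name, max_len) -> (scheme, q_enc, t_enc).

    Draws symbol indices directly.  For blosum62 the draw excludes X
    (whose published self-score is not its row maximum) and *, keeping
    self-alignment normalization well-defined for generated queries.
    """

    def _make(rng, name, max_len=200):
        scheme = all_schemes[name]
        high = {"actgn": 5, "blosum62": 22, "ascii": 256}[name]
        m = int(rng.integers(1, max_len + 1))
        n = int(rng.integers(1, max_len + 1))
        q = rng.integers(0, high, size=m)
        t = rng.integers(0, high, size=n)
        return scheme, q, t

    return _make


def _py_matrices(scheme, q, t, local, fqp, ftp):
    """Naive full-matrix Gotoh DP in pure Python (the test oracle)."""
    neg = -(10 ** 9)
    go, ge = scheme.gap_open, scheme.gap_extend
    S = scheme.matrix
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[neg] * (n + 1) for _ in range(m + 1)]
    F = [[neg] * (n + 1) for _ in range(m + 1)]
    if not local:
        for i in range(1, m + 1):
            H[i][0] = 0 if fqp else -(go + (i - 1) * ge)
        for j in range(1, n + 1):
            H[0][j] = 0 if ftp else -(go + (j - 1) * ge)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            h = max(H[i - 1][j - 1] + S[q[i - 1], t[j - 1]], E[i][j], F[i][j])
            H[i][j] = max(h, 0) if local else h
    return H


@pytest.fixture(scope="session")
def py_local_oracle():
    """Pure-Python Smith-Waterman best score."""

    def _local(scheme, q, t):
        H = _py_matrices(scheme, q, t, local=True, fqp=False, ftp=False)
        return max(max(row) for row in H)

    return _local


@pytest.fixture(scope="session")
def py_semiglobal_oracle():
    """Pure-Python semi-global / global best score under end flags."""

    def _sg(scheme, q, t, ends):
        H = _py_matrices(scheme, q, t, local=False,
                         fqp=ends.free_query_prefix,
                         ftp=ends.free_target_prefix)
        m, n = len(q), len(t)
        cells = []
        if ends.free_target_suffix:
            cells.extend(H[m])
        if ends.free_query_suffix:
            cells.extend(H[i][n] for i in range(m + 1))
        if not cells:
            cells = [H[m][n]]
        return max(cells)

    return _sg
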