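"""Scalar reference alignment: local and semi-global affine-gap DP.

This module is the correctness oracle for the striped implementations
and hosts span recovery by traceback.  ``batch_align_scalar`` mirrors a
naive one-alignment-per-thread batch kernel (length-sorted dispatch,
results restored to caller order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import SeqSiftError
from .scoring import ScoringScheme


@dataclass(frozen=True)
class EndFlags:
    """Which sequence termini are free (unpenalized) in semi-global mode.

    All four False is global (Needleman-Wunsch) alignment.  The default
    leaves both target ends free: the query must align in full, target
    overhangs cost nothing.
    """

    free_query_prefix: bool = False
    free_query_suffix: bool = False
    free_target_prefix: bool = True
    free_target_suffix: bool = True

    @classmethod
    def global_(cls) -> "EndFlags":
        return cls(False, False, False, False)

    @classmethod
    def parse(cls, spec: str) -> "EndFlags":
        """Parse a comma list over {qs, qe, ts, te} (e.g. ``"ts,te"``)."""
        mapping = {
            "qs": "free_query_prefix",
            "qe": "free_query_suffix",
            "ts": "free_target_prefix",
            "te": "free_target_suffix",
        }
        kwargs = dict.fromkeys(mapping.values(), False)
        spec = spec.strip()
        if spec:
            for token in spec.split(","):
                token = token.strip().lower()
                if token not in mapping:
                    raise ValueError(
                        f"unknown end flag {token!r}; valid: qs, qe, ts, te"
                    )
                kwargs[mapping[token]] = True
        return cls(**kwargs)


@dataclass(frozen=True)
class AlignmentResult:
    """Best DP score with 0-based inclusive end coordinates.

    ``query_end == target_end == -1`` denotes the empty local alignment.
    ``precision`` records which kernel produced the score.
    """

    score: int
    query_end: int
    target_end: int
    precision: str = "scalar"
    overflowed: bool = False


@dataclass(frozen=True)
class AlignmentSpan:
    """Half-open aligned interval on both sequences, with its score."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: int


def _as_arrays(scheme: ScoringScheme, q, t):
    q = np.ascontiguousarray(q, dtype=np.int64)
    t = np.ascontiguousarray(t, dtype=np.int64)
    if q.size == 0 or t.size == 0:
        raise ValueError("alignment requires non-empty sequences")
    return q, t


def local_align_scalar(scheme: ScoringScheme, q, t) -> AlignmentResult:
    """Affine-gap Smith-Waterman; ties broken by smallest target end,
    then smallest query end."""
    q, t = _as_arrays(scheme, q, t)
    score, qe, te = _kernels.sw_scalar(
        scheme.matrix, q, t, scheme.gap_open, scheme.gap_extend
    )
    return AlignmentResult(int(score), int(qe), int(te))


def reduce_semiglobal(last_row, last_col, m: int, n: int, ends: EndFlags):
    """Pick the final (score, query_end, target_end) from the suffix-flag
    cell set.

    Shared by the scalar and striped paths so tie-breaking (smallest
    target end, then smallest query end) agrees exactly.  ``last_row`` is
    H[m][0..n]; ``last_col`` is H[0..m][n].
    """
    candidates = []
    if ends.free_target_suffix:
        j = int(np.argmax(last_row))  # argmax takes the first = smallest j
        candidates.append((int(last_row[j]), j - 1, m - 1))
    if ends.free_query_suffix:
        i = int(np.argmax(last_col))
        candidates.append((int(last_col[i]), n - 1, i - 1))
    if not candidates:
        candidates.append((int(last_row[n]), n - 1, m - 1))
    score = max(c[0] for c in candidates)
    te, qe = min((c[1], c[2]) for c in candidates if c[0] == score)
    return score, qe, te


def semiglobal_align_scalar(
    scheme: ScoringScheme, q, t, ends: EndFlags = EndFlags()
) -> AlignmentResult:
    """Semi-global (free-end) affine alignment; global when all flags are
    False."""
    q, t = _as_arrays(scheme, q, t)
    last_row, last_col = _kernels.sg_scalar(
        scheme.matrix,
        q,
        t,
        scheme.gap_open,
        scheme.gap_extend,
        ends.free_query_prefix,
        ends.free_target_prefix,
    )
    score, qe, te = reduce_semiglobal(last_row, last_col, len(q), len(t), ends)
    return AlignmentResult(score, qe, te)


def traceback_span(
    scheme: ScoringScheme,
    q,
    t,
    mode: str,
    ends: EndFlags,
    result: AlignmentResult,
) -> AlignmentSpan:
    """Recover the full span of the optimal alignment ending at
    ``(result.query_end, result.target_end)``.

    Reruns the scalar DP on the prefix rectangle and walks back through
    the H/E/F states.  Tie preference: diagonal, then horizontal gap,
    then vertical gap (deterministic; the span score is tie-invariant).
    """
    if result.query_end < 0 or result.target_end < 0:
        raise ValueError("cannot trace back an empty alignment")
    q, t = _as_arrays(scheme, q, t)
    local = mode == "local"
    qe, te = result.query_end, result.target_end
    qs_arr = q[: qe + 1]
    ts_arr = t[: te + 1]
    H, E, F = _kernels.fill_matrices(
        scheme.matrix,
        qs_arr,
        ts_arr,
        scheme.gap_open,
        scheme.gap_extend,
        local,
        ends.free_query_prefix,
        ends.free_target_prefix,
    )
    i, j = qe + 1, te + 1
    if H[i, j] != result.score:
        raise SeqSiftError(
            "inconsistent alignment result: end cell does not hold the score"
        )
    go, ge = scheme.gap_open, scheme.gap_extend
    state = "H"
    while True:
        if state == "H":
            if local and H[i, j] == 0:
                break
            if not local and (i == 0 or j == 0):
                break
            if H[i, j] == H[i - 1, j - 1] + scheme.matrix[q[i - 1], t[j - 1]]:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - would indicate a kernel defect
                raise SeqSiftError("traceback failed to explain a DP cell")
        elif state == "E":
            from_open = E[i, j] == H[i, j - 1] - go
            j -= 1
            if from_open:
                state = "H"
        else:
            from_open = F[i, j] == H[i - 1, j] - go
            i -= 1
            if from_open:
                state = "H"
    return AlignmentSpan(
        query_start=i,
        query_end=qe + 1,
        target_start=j,
        target_end=te + 1,
        score=result.score,
    )


def batch_align_scalar(
    scheme: ScoringScheme,
    q,
    targets,
    mode: str = "semiglobal",
    ends: EndFlags = EndFlags(),
    coarse_factor: int = 1,
):
    """Align one query against many targets with the scalar kernel.

    Targets are length-sorted and dispatched in chunks of
    ``coarse_factor`` (mirroring a coarse-grained batch kernel); results
    are returned in the caller's original order and are element-wise
    identical to mapping the scalar aligner.
    """
    if coarse_factor < 1:
        raise ValueError("coarse_factor must be >= 1")
    targets = list(targets)
    order = sorted(range(len(targets)), key=lambda k: len(targets[k]))
    results: list[AlignmentResult | None] = [None] * len(targets)
    for start in range(0, len(order), coarse_factor):
        chunk = order[start : start + coarse_factor]
        for idx in chunk:
            try:
                if mode == "local":
                    results[idx] = local_align_scalar(scheme, q, targets[idx])
                else:
                    results[idx] = semiglobal_align_scalar(
                        scheme, q, targets[idx], ends
                    )
            except ValueError as exc:
                raise ValueError(f"target {idx}: {exc}") from exc
    return results
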