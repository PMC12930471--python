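"""Striped vectorized alignment over an abstract lane model.

The lanes are an abstract array axis (numpy's vector dimension), not
hardware registers: what is preserved from the SIMD formulation is the
algorithm itself — the Farrar striped query profile, the lazy-F
correction loop, saturating unsigned 8-bit arithmetic with a score
bias, and adaptive 8-bit -> 16-bit precision escalation.  Results are
bit-identical to the scalar oracle for every lane count.

Local alignment offers a biased unsigned-8-bit kernel (fast path) and a
signed-16-bit kernel; ``local_adaptive`` runs the 8-bit kernel first and
escalates on saturation.  Semi-global alignment is 16-bit only: signed
8-bit scores overflow too quickly once the zero floor is removed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .align_core import AlignmentResult, EndFlags, reduce_semiglobal
from .errors import AlignmentOverflowError, ConfigError
from .scoring import ScoringScheme, StripedProfile, build_striped_profile, encode_sequence

U8_CEIL = 255
I16_CEIL = 32767
NEG = -(1 << 28)

DEFAULT_LANES = 16
LANES_ENV_VAR = "SEQSIFT_LANES"


def default_lanes() -> int:
    """Default lane count, overridable via the SEQSIFT_LANES env var."""
    raw = os.environ.get(LANES_ENV_VAR)
    if raw is None:
        return DEFAULT_LANES
    try:
        lanes = int(raw)
    except ValueError as exc:
        raise ConfigError(f"{LANES_ENV_VAR} must be an integer, got {raw!r}") from exc
    if lanes < 2 or lanes & (lanes - 1):
        raise ConfigError(f"{LANES_ENV_VAR} must be a power of two >= 2, got {lanes}")
    return lanes


@dataclass(frozen=True)
class LaneConfig:
    """Abstract vector width and score precision for the striped kernels."""

    lanes: int = DEFAULT_LANES
    precision: str = "i16"

    def __post_init__(self):
        if self.lanes < 2 or self.lanes & (self.lanes - 1):
            raise ConfigError(
                f"lane count must be a power of two >= 2, got {self.lanes}"
            )
        if self.precision not in ("u8", "i16"):
            raise ConfigError(f"unknown precision {self.precision!r}")


def _check_profile(profile: StripedProfile, config: LaneConfig):
    if profile.lanes != config.lanes:
        raise ConfigError(
            f"profile built for {profile.lanes} lanes, config requests {config.lanes}"
        )


def _column_best(vH, valid, seg):
    """(max value over real cells, smallest de-striped query index at it)."""
    masked = np.where(valid, vH, NEG)
    colmax = int(masked.max())
    ii, ll = np.nonzero(masked == colmax)
    k = int((ll.astype(np.int64) * seg + ii).min())
    return colmax, k


def _shift_lanes(v, fill):
    out = np.empty_like(v)
    out[0] = fill
    out[1:] = v[:-1]
    return out


def _local_striped_u8(profile: StripedProfile, t_enc):
    """Biased saturating unsigned-8-bit striped Smith-Waterman.

    Cell values carry +bias (bias = the floor representing a true score
    of 0); saturation at 255 is emulated by clipping, and the run is
    flagged overflowed once the biased maximum enters the region where
    saturation could have clipped a true score.
    """
    scheme = profile.scheme
    go, ge, bias = scheme.gap_open, scheme.gap_extend, scheme.bias
    P = profile.scores_u8
    seg, L = profile.segment_length, profile.lanes
    valid = profile.valid
    max_p = int(P.max())
    vHprev = np.full((seg, L), bias, np.int32)
    vH = np.empty((seg, L), np.int32)
    vE = np.zeros((seg, L), np.int32)
    best, bq, bt = bias, -1, -1
    of_max = bias
    lazy_iters = 0  # max per-column lazy-F iterations (bound: seg * L)
    for j in range(len(t_enc)):
        col_iters = 0
        Pj = P[t_enc[j]]
        vE = np.maximum(np.maximum(vHprev - go, vE - ge), 0)
        vF = np.zeros(L, np.int32)
        diag = _shift_lanes(vHprev[seg - 1], bias)
        for i in range(seg):
            h = diag + Pj[i]
            np.minimum(h, U8_CEIL, out=h)  # saturating add of the biased score
            h -= bias
            np.maximum(h, 0, out=h)  # saturating subtract of the bias
            np.maximum(h, vE[i], out=h)
            np.maximum(h, vF, out=h)
            np.maximum(h, bias, out=h)  # local zero floor (biased)
            vH[i] = h
            vF = np.maximum(np.maximum(vF - ge, h - go), 0)
            diag = vHprev[i]
        converged = False
        for _ in range(L):
            vF = _shift_lanes(vF, 0)
            for i in range(seg):
                col_iters += 1
                np.maximum(vH[i], vF, out=vH[i])
                vF = np.maximum(vF - ge, 0)
                if not np.any(vF > vH[i] - go):
                    converged = True
                    break
            if converged:
                break
        lazy_iters = max(lazy_iters, col_iters)
        colmax, k = _column_best(vH, valid, seg)
        if colmax > best:
            best, bq, bt = colmax, k, j
        of_max = max(of_max, int(vH.max()))
        vHprev, vH = vH, vHprev
    overflowed = of_max >= U8_CEIL - max_p
    score = best - bias
    if score <= 0:
        return 0, -1, -1, overflowed, lazy_iters
    return score, bq, bt, overflowed, lazy_iters


def _local_striped_i16(profile: StripedProfile, t_enc):
    """Signed 16-bit striped Smith-Waterman (computed exactly, with an
    overflow flag at the 16-bit ceiling)."""
    scheme = profile.scheme
    go, ge = scheme.gap_open, scheme.gap_extend
    P = profile.scores_i16
    seg, L = profile.segment_length, profile.lanes
    valid = profile.valid
    max_s = scheme.max_score
    vHprev = np.zeros((seg, L), np.int32)
    vH = np.empty((seg, L), np.int32)
    vE = np.full((seg, L), NEG, np.int32)
    best, bq, bt = 0, -1, -1
    lazy_iters = 0  # max per-column lazy-F iterations (bound: seg * L)
    for j in range(len(t_enc)):
        col_iters = 0
        Pj = P[t_enc[j]]
        vE = np.maximum(vHprev - go, vE - ge)
        vF = np.full(L, NEG, np.int32)
        diag = _shift_lanes(vHprev[seg - 1], 0)
        for i in range(seg):
            h = diag + Pj[i]
            np.maximum(h, vE[i], out=h)
            np.maximum(h, vF, out=h)
            np.maximum(h, 0, out=h)
            vH[i] = h
            vF = np.maximum(vF - ge, h - go)
            diag = vHprev[i]
        converged = False
        for _ in range(L):
            vF = _shift_lanes(vF, NEG)
            for i in range(seg):
                col_iters += 1
                np.maximum(vH[i], vF, out=vH[i])
                vF -= ge
                if not np.any(vF > vH[i] - go):
                    converged = True
                    break
            if converged:
                break
        lazy_iters = max(lazy_iters, col_iters)
        colmax, k = _column_best(vH, valid, seg)
        if colmax > best:
            best, bq, bt = colmax, k, j
        vHprev, vH = vH, vHprev
    overflowed = best >= I16_CEIL - max_s
    if best <= 0:
        return 0, -1, -1, overflowed, lazy_iters
    return best, bq, bt, overflowed, lazy_iters


def local_striped(
    profile: StripedProfile, t, config: LaneConfig = LaneConfig()
) -> AlignmentResult:
    """Striped local alignment at the configured precision.

    Identical to ``local_align_scalar`` in score and end coordinates
    whenever ``overflowed`` is False.
    """
    _check_profile(profile, config)
    t = np.ascontiguousarray(t, dtype=np.int64)
    if t.size == 0:
        raise ValueError("alignment requires a non-empty target")
    if config.precision == "u8":
        score, qe, te, overflowed, _ = _local_striped_u8(profile, t)
    else:
        score, qe, te, overflowed, _ = _local_striped_i16(profile, t)
    return AlignmentResult(score, qe, te, precision=config.precision, overflowed=overflowed)


def local_adaptive(
    scheme: ScoringScheme,
    q,
    t,
    lanes: int | None = None,
    profile: StripedProfile | None = None,
) -> AlignmentResult:
    """Adaptive-precision striped local alignment.

    Runs the unsigned 8-bit kernel first; on saturation, reruns at
    16-bit.  Raises :class:`AlignmentOverflowError` when even 16 bits
    cannot hold the score (shorten the query).
    """
    lanes = lanes if lanes is not None else default_lanes()
    if profile is None:
        q = np.ascontiguousarray(q, dtype=np.int64)
        if q.size == 0:
            raise ValueError("alignment requires a non-empty query")
        profile = build_striped_profile(scheme, q, lanes)
    t = np.ascontiguousarray(t, dtype=np.int64)
    if t.size == 0:
        raise ValueError("alignment requires a non-empty target")
    if min(len(profile.encoded_query), len(t)) * scheme.max_score >= I16_CEIL:
        raise AlignmentOverflowError(
            "alignment score can exceed the signed 16-bit range; "
            "use a shorter query"
        )
    score, qe, te, overflowed, _ = _local_striped_u8(profile, t)
    if not overflowed:
        return AlignmentResult(score, qe, te, precision="u8", overflowed=False)
    score, qe, te, overflowed, _ = _local_striped_i16(profile, t)
    if overflowed:
        raise AlignmentOverflowError(
            "alignment score reached the signed 16-bit ceiling; "
            "use a shorter query"
        )
    return AlignmentResult(score, qe, te, precision="i16", overflowed=False)


def semiglobal_striped(
    profile: StripedProfile,
    t,
    ends: EndFlags = EndFlags(),
    config: LaneConfig = LaneConfig(),
) -> AlignmentResult:
    """Striped semi-global alignment with signed 16-bit scoring.

    The 8-bit precision is unsupported by design: without the local zero
    floor, signed 8-bit scores overflow about twice as fast as unsigned
    8-bit scores do in local mode.  Boundary conditions and the final
    row/column reduction match the scalar oracle exactly.
    """
    if config.precision == "u8":
        raise ConfigError(
            "semi-global alignment supports only i16 precision: signed 8-bit "
            "scores overflow too quickly without the local zero floor"
        )
    _check_profile(profile, config)
    t = np.ascontiguousarray(t, dtype=np.int64)
    if t.size == 0:
        raise ValueError("alignment requires a non-empty target")
    scheme = profile.scheme
    go, ge = scheme.gap_open, scheme.gap_extend
    m = len(profile.encoded_query)
    n = len(t)
    guard = max(
        min(m, n) * max(scheme.max_score, 1),
        go + (max(m, n) - 1) * ge,
    )
    if guard >= I16_CEIL:
        raise AlignmentOverflowError(
            "semi-global score range exceeds signed 16-bit precision"
        )
    P = profile.scores_i16
    seg, L = profile.segment_length, profile.lanes

    def h_top(j):  # top boundary H[0][j]
        if j == 0 or ends.free_target_prefix:
            return 0
        return -(go + (j - 1) * ge)

    def h_left(i):  # left boundary H[i][0]
        if i == 0 or ends.free_query_prefix:
            return 0
        return -(go + (i - 1) * ge)

    kk = np.arange(seg * L).reshape(L, seg).T  # de-striping index map
    vHprev = np.where(
        profile.valid,
        np.array([[h_left(k + 1) for k in row] for row in np.minimum(kk, m - 1)],
                 dtype=np.int32),
        NEG,
    ).astype(np.int32)
    vH = np.empty((seg, L), np.int32)
    vE = np.full((seg, L), NEG, np.int32)
    last_row = np.empty(n + 1, np.int64)
    last_row[0] = h_left(m)
    mi, ml = (m - 1) % seg, (m - 1) // seg
    for j in range(1, n + 1):
        Pj = P[t[j - 1]]
        vE = np.maximum(vHprev - go, vE - ge)
        vF = np.full(L, NEG, np.int32)
        vF[0] = h_top(j) - go
        diag = _shift_lanes(vHprev[seg - 1], h_top(j - 1))
        for i in range(seg):
            h = diag + Pj[i]
            np.maximum(h, vE[i], out=h)
            np.maximum(h, vF, out=h)
            vH[i] = h
            vF = np.maximum(vF - ge, h - go)
            diag = vHprev[i]
        converged = False
        for _ in range(L):
            vF = _shift_lanes(vF, NEG)
            for i in range(seg):
                np.maximum(vH[i], vF, out=vH[i])
                vF -= ge
                if not np.any(vF > vH[i] - go):
                    converged = True
                    break
            if converged:
                break
        last_row[j] = int(vH[mi, ml])
        vHprev, vH = vH, vHprev
    ks = np.arange(m)
    last_col = np.empty(m + 1, np.int64)
    last_col[0] = h_top(n)
    last_col[1:] = vHprev[ks % seg, ks // seg]
    score, qe, te = reduce_semiglobal(last_row, last_col, m, n, ends)
    return AlignmentResult(score, qe, te, precision="i16", overflowed=False)
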