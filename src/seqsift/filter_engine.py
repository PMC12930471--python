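"""The filtering core: threshold normalized alignment scores.

A record passes when its best alignment score against the query is at
least ``threshold * optimal``, where *optimal* is the query's gapless
self-alignment score.  The comparison is done with exact rational
arithmetic (the threshold is held as a :class:`fractions.Fraction`), so
a record sitting exactly on the boundary is emitted — the decision rule
is >=, and no floating-point rounding can flip it.

Evaluation is pure per record; with multiple worker threads the output
is re-sequenced into input order, so the stream filter is deterministic
regardless of concurrency.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional

from .align_core import AlignmentSpan, EndFlags, traceback_span
from .align_striped import LaneConfig, local_adaptive, semiglobal_striped
from .errors import ConfigError, SeqSiftError
from .records import SeqRecord
from .scoring import (
    ScoringScheme,
    StripedProfile,
    build_striped_profile,
    encode_sequence,
    optimal_score,
)

log = logging.getLogger(__name__)


def as_fraction(threshold) -> Fraction:
    """Exact threshold: floats go through their shortest decimal repr, so
    a CLI value like 0.8 becomes exactly 4/5."""
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, float):
        return Fraction(repr(threshold))
    return Fraction(threshold)


@dataclass
class FilterConfig:
    """Everything the filter needs besides the query itself."""

    scheme: ScoringScheme
    threshold: Fraction = Fraction(4, 5)
    mode: str = "semiglobal"
    ends: EndFlags = field(default_factory=EndFlags)
    record_type: str = "line"
    lanes: LaneConfig = field(default_factory=LaneConfig)
    threads: int = 1
    permissive: bool = False

    def __post_init__(self):
        self.threshold = as_fraction(self.threshold)
        if not 0 < self.threshold <= 1:
            raise ConfigError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.mode not in ("local", "semiglobal"):
            raise ConfigError(f"unknown alignment mode {self.mode!r}")
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")


@dataclass
class MatchReport:
    """A record that passed the filter."""

    record: SeqRecord
    raw_score: int
    normalized: float
    span: AlignmentSpan


def normalized_score(raw: int, optimal: int) -> float:
    """raw / optimal (the threshold test itself uses exact rationals)."""
    if optimal <= 0:
        raise ConfigError("query has no positive self-alignment score")
    return raw / optimal


def passes_threshold(raw: int, optimal: int, threshold: Fraction) -> bool:
    """Exact >= test via cross multiplication: raw/optimal >= threshold."""
    if optimal <= 0:
        raise ConfigError("query has no positive self-alignment score")
    return Fraction(raw, optimal) >= threshold


def evaluate_record(
    config: FilterConfig,
    query_profile: StripedProfile,
    optimal: int,
    record: SeqRecord,
) -> Optional[MatchReport]:
    """Align the query against one record's sequence and apply the
    threshold; returns None for non-matching or empty-sequence records.

    Alignment is always against the sequence payload, never headers or
    quality strings.
    """
    if len(record.seq) == 0:
        return None
    scheme = config.scheme
    t = encode_sequence(scheme, record.seq)
    try:
        if config.mode == "local":
            result = local_adaptive(
                scheme, query_profile.encoded_query, t,
                lanes=config.lanes.lanes, profile=query_profile,
            )
        else:
            result = semiglobal_striped(
                query_profile, t, config.ends,
                LaneConfig(config.lanes.lanes, "i16"),
            )
    except SeqSiftError as exc:
        raise type(exc)(
            f"{exc} (record at {record.source_path}:{record.line_number})"
        ) from exc
    if not passes_threshold(result.score, optimal, config.threshold):
        return None
    span = traceback_span(
        scheme, query_profile.encoded_query, t, config.mode, config.ends, result
    )
    return MatchReport(
        record=record,
        raw_score=result.score,
        normalized=normalized_score(result.score, optimal),
        span=span,
    )


def filter_stream(
    config: FilterConfig,
    records: Iterable[SeqRecord],
    *,
    query: bytes | str,
) -> Iterator[MatchReport]:
    """Filter a record stream, emitting reports in input order.

    With ``config.threads > 1`` records are evaluated concurrently and
    the output re-sequenced, so results are byte-identical to a serial
    run.  Per-record errors are fatal unless ``config.permissive`` is
    set, in which case they are logged and the record skipped.
    """
    scheme = config.scheme
    q = encode_sequence(scheme, query)
    if len(q) == 0:
        raise ConfigError("query must be non-empty")
    optimal = optimal_score(scheme, q)
    if optimal <= 0:
        raise ConfigError(
            "query has no positive self-alignment score; cannot normalize"
        )
    profile = build_striped_profile(scheme, q, config.lanes.lanes)

    def _eval(record):
        try:
            return evaluate_record(config, profile, optimal, record)
        except SeqSiftError:
            if config.permissive:
                log.warning("skipping record", exc_info=True)
                return None
            raise

    if config.threads == 1:
        for record in records:
            report = _eval(record)
            if report is not None:
                yield report
    else:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            for report in pool.map(_eval, records, chunksize=8):
                if report is not None:
                    yield report
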