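"""Streamed record I/O: FASTA, FASTQ (4-line), and plain text lines.

Streams are read once, sequentially.  gzip input is autodetected from
the two magic bytes.  Directory arguments are walked recursively in
lexicographic order, skipping dot-files and (in line mode) binary
files; explicitly named files bypass both skips, grep-style.  Output is
format preserving: a matched record is re-serialized in its native
format, so the tool stays safe inside pipelines.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import sys
from dataclasses import dataclass
from typing import Iterator

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

STDIN_MARKER = "-"
GZIP_MAGIC = b"\x1f\x8b"
_BINARY_SNIFF_BYTES = 8192
_WHITESPACE = b" \t\r\n\v\f"


@dataclass
class SeqRecord:
    """One FASTA/FASTQ/line record with its source location."""

    kind: str  # fasta | fastq | line
    header: bytes
    seq: bytes
    qual: bytes | None
    source_path: str
    line_number: int


def open_stream(path: str, stdin=None) -> io.BufferedIOBase:
    """Open a path (or the stdin marker) as a binary stream,
    transparently decompressing gzip input (magic-byte autodetect)."""
    if path == STDIN_MARKER:
        raw = stdin if stdin is not None else sys.stdin.buffer
        stream = io.BufferedReader(_ReadableWrapper(raw))
    else:
        try:
            stream = open(path, "rb")
        except OSError as exc:
            raise InputError(f"cannot read {path}: {exc.strerror}") from exc
    head = stream.peek(2)[:2]
    if head == GZIP_MAGIC:
        return io.BufferedReader(_GzipRaw(stream, path))
    return stream


class _ReadableWrapper(io.RawIOBase):
    """Adapt any object with .read into a RawIOBase for buffering."""

    def __init__(self, inner):
        self._inner = inner

    def readable(self):
        return True

    def readinto(self, b):
        data = self._inner.read(len(b))
        b[: len(data)] = data
        return len(data)


class _GzipRaw(io.RawIOBase):
    def __init__(self, stream, path):
        self._gz = gzip.GzipFile(fileobj=stream)
        self._path = path

    def readable(self):
        return True

    def readinto(self, b):
        try:
            data = self._gz.read(len(b))
        except (EOFError, gzip.BadGzipFile, OSError) as exc:
            raise FormatError(f"truncated or corrupt gzip stream: {exc}",
                              path=self._path) from exc
        b[: len(data)] = data
        return len(data)


def detect_record_type(head: bytes, requested: str) -> str:
    """Resolve the requested record type; ``fastx`` sniffs the first
    non-whitespace byte ('>' = FASTA, '@' = FASTQ)."""
    if requested in ("fasta", "fastq", "line"):
        return requested
    if requested != "fastx":
        raise ValueError(f"unknown record type {requested!r}")
    stripped = head.lstrip(_WHITESPACE)
    if stripped.startswith(b">"):
        return "fasta"
    if stripped.startswith(b"@"):
        return "fastq"
    raise FormatError("cannot autodetect record type: stream starts with "
                      "neither '>' nor '@'")


def read_fasta(stream, source_path: str = "<stdin>") -> Iterator[SeqRecord]:
    """Yield FASTA records; multi-line bodies are concatenated with
    internal whitespace stripped."""
    header = None
    header_line = 0
    parts: list[bytes] = []
    for lineno, line in enumerate(stream, start=1):
        if line.startswith(b">"):
            if header is not None:
                yield SeqRecord("fasta", header, b"".join(parts), None,
                                source_path, header_line)
            header = line[1:].rstrip(b"\r\n")
            header_line = lineno
            parts = []
        else:
            if header is None:
                if line.strip(_WHITESPACE):
                    raise FormatError("content before first FASTA header",
                                      path=source_path, line=lineno)
                continue
            parts.append(line.translate(None, delete=_WHITESPACE))
    if header is not None:
        yield SeqRecord("fasta", header, b"".join(parts), None,
                        source_path, header_line)


def read_fastq(stream, source_path: str = "<stdin>") -> Iterator[SeqRecord]:
    """Yield strict 4-line FASTQ records (@header, seq, +, qual)."""
    record_index = 0
    while True:
        lineno = record_index * 4 + 1
        group = [stream.readline() for _ in range(4)]
        if not group[0]:
            return
        if any(not line for line in group[1:]):
            raise FormatError(f"truncated FASTQ record {record_index}",
                              path=source_path, line=lineno)
        if not group[0].startswith(b"@"):
            raise FormatError(
                f"FASTQ record {record_index} does not start with '@'",
                path=source_path, line=lineno)
        if not group[2].startswith(b"+"):
            raise FormatError(
                f"FASTQ record {record_index} separator line is not '+'",
                path=source_path, line=lineno + 2)
        seq = group[1].rstrip(b"\r\n")
        qual = group[3].rstrip(b"\r\n")
        if len(seq) != len(qual):
            raise FormatError(
                f"FASTQ record {record_index}: quality length {len(qual)} "
                f"!= sequence length {len(seq)}",
                path=source_path, line=lineno + 3)
        yield SeqRecord("fastq", group[0][1:].rstrip(b"\r\n"), seq, qual,
                        source_path, lineno)
        record_index += 1


def read_lines(stream, source_path: str = "<stdin>") -> Iterator[SeqRecord]:
    """Yield one record per newline-delimited line (newline excluded);
    a final line without a trailing newline is still yielded."""
    for lineno, line in enumerate(stream, start=1):
        if line.endswith(b"\n"):
            line = line[:-1]
        yield SeqRecord("line", b"", line, None, source_path, lineno)


READERS = {"fasta": read_fasta, "fastq": read_fastq, "line": read_lines}


def is_binary(head: bytes) -> bool:
    """A file is considered binary when its first bytes contain NUL."""
    return b"\x00" in head


def _sniff_binary(path: str) -> bool:
    try:
        with open(path, "rb") as fh:
            return is_binary(fh.read(_BINARY_SNIFF_BYTES))
    except OSError:
        return True


def walk_targets(paths, skip_binary: bool = False) -> Iterator[str]:
    """Yield target file paths.

    Files are yielded as given (explicit arguments bypass all skips);
    directories are walked recursively in lexicographic order, skipping
    dot-file entries and — when ``skip_binary`` (line mode) — binary
    files.  Unreadable subtree entries are logged and skipped.
    """
    for path in paths:
        if path == STDIN_MARKER:
            yield path
        elif os.path.isdir(path):
            yield from _walk_dir(path, skip_binary)
        elif os.path.exists(path):
            yield path
        else:
            raise InputError(f"no such file or directory: {path}")


def _walk_dir(root: str, skip_binary: bool) -> Iterator[str]:
    try:
        entries = sorted(os.scandir(root), key=lambda e: e.name)
    except OSError as exc:
        log.warning("skipping unreadable directory %s: %s", root, exc)
        return
    for entry in entries:
        if entry.name.startswith("."):
            continue
        if entry.is_dir(follow_symlinks=False):
            yield from _walk_dir(entry.path, skip_binary)
        elif entry.is_file():
            if skip_binary and _sniff_binary(entry.path):
                continue
            yield entry.path


def write_record(record: SeqRecord) -> bytes:
    """Serialize a record in its native format (FASTA bodies are
    normalized to a single line)."""
    if record.kind == "fasta":
        return b">" + record.header + b"\n" + record.seq + b"\n"
    if record.kind == "fastq":
        return (b"@" + record.header + b"\n" + record.seq + b"\n+\n"
                + (record.qual or b"") + b"\n")
    return record.seq + b"\n"
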