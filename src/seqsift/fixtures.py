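"""Deterministic synthetic corpora with oracle-computed ground truth.

The generator plants mutated copies of a query inside random flanking
sequence and records, for every record, the scalar-oracle alignment
score of the query against it.  That truth table makes the expected
filter output at any threshold exactly computable, which is what the
end-to-end tests check the full pipeline against.

Everything is driven by ``numpy.random.default_rng`` (PCG64) with an
explicit seed, so a fixed seed yields byte-identical corpora on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .align_core import EndFlags, local_align_scalar, semiglobal_align_scalar
from .scoring import ScoringScheme, encode_sequence, optimal_score

ALPHABETS = {
    "nucleotide": b"ACGT",
    "protein": b"ARNDCQEGHILKMFPSTWYV",
    "printable-ascii": bytes(range(32, 127)),
}


@dataclass(frozen=True)
class MutationSpec:
    """Per-position substitution and indel rates plus the RNG seed."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for rate in (self.substitution_rate, self.insertion_rate,
                     self.deletion_rate):
            if not 0 <= rate < 1:
                raise ValueError("mutation rates must be in [0, 1)")


def random_sequence(alphabet: str, length: int, seed: int) -> bytes:
    """Uniform random sequence over the named alphabet."""
    if length < 1:
        raise ValueError("length must be >= 1")
    symbols = ALPHABETS[alphabet]
    rng = np.random.default_rng(seed)
    return bytes(bytearray(np.frombuffer(symbols, np.uint8)[
        rng.integers(0, len(symbols), size=length)]))


def mutate(seq: bytes, spec: MutationSpec, alphabet: str = "nucleotide"):
    """Apply substitutions, then indels left-to-right.

    Substitutions are forced to differ from the original symbol (so the
    requested rate is realized).  Returns ``(mutant, edits)`` where each
    edit is ``(op, position, payload)`` with op in {sub, ins, del} —
    enough to replay the exact derivation of the mutant.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    symbols = ALPHABETS[alphabet]
    rng = np.random.default_rng(spec.seed)
    edits = []
    out = bytearray()
    # substitution pass
    subbed = bytearray(seq)
    for pos in range(len(subbed)):
        if spec.substitution_rate and rng.random() < spec.substitution_rate:
            choices = [s for s in symbols if s != subbed[pos]]
            new = choices[rng.integers(0, len(choices))]
            edits.append(("sub", pos, bytes([new])))
            subbed[pos] = new
    # indel pass, left to right over the substituted sequence
    for pos, byte in enumerate(subbed):
        if spec.insertion_rate and rng.random() < spec.insertion_rate:
            ins = symbols[rng.integers(0, len(symbols))]
            edits.append(("ins", pos, bytes([ins])))
            out.append(ins)
        if spec.deletion_rate and rng.random() < spec.deletion_rate:
            edits.append(("del", pos, bytes([byte])))
            continue
        out.append(byte)
    return bytes(out), edits


@dataclass
class TruthRow:
    record_id: str
    planted: bool
    raw_score: int
    normalized: float


@dataclass
class Corpus:
    """Generated record file content plus its oracle truth table."""

    kind: str
    text: bytes
    query: bytes
    optimal: int
    truth: list[TruthRow] = field(default_factory=list)

    def truth_tsv(self) -> str:
        lines = ["record_id\tplanted\traw_score\tnormalized"]
        for row in self.truth:
            lines.append(
                f"{row.record_id}\t{int(row.planted)}\t{row.raw_score}"
                f"\t{row.normalized:.6f}"
            )
        return "\n".join(lines) + "\n"

    def expected_ids(self, threshold) -> list[str]:
        """Record ids the filter must emit at the given threshold
        (exact rational >= test)."""
        thr = Fraction(repr(threshold)) if isinstance(threshold, float) \
            else Fraction(threshold)
        return [row.record_id for row in self.truth
                if Fraction(row.raw_score, self.optimal) >= thr]


def make_corpus(
    n_records: int,
    kind: str,
    query: bytes,
    planted_fraction: float,
    spec: MutationSpec,
    scheme: ScoringScheme,
    mode: str = "semiglobal",
    ends: EndFlags = EndFlags(),
    alphabet: str = "nucleotide",
    flank: int = 30,
) -> Corpus:
    """Generate a record corpus with planted mutated queries.

    A ``planted_fraction`` subset of records embeds a mutated copy of the
    query between random flanks; the rest are pure random sequence of a
    comparable length.  Every record's scalar-oracle score against the
    query is logged in the truth table.
    """
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    symbols = ALPHABETS[alphabet]
    q_enc = encode_sequence(scheme, query)
    opt = optimal_score(scheme, q_enc)
    n_planted = round(n_records * planted_fraction)
    planted_idx = set(rng.choice(n_records, size=n_planted, replace=False).tolist()) \
        if n_planted else set()

    def rand_bytes(length):
        if length <= 0:
            return b""
        return bytes(bytearray(np.frombuffer(symbols, np.uint8)[
            rng.integers(0, len(symbols), size=length)]))

    chunks = []
    truth = []
    for idx in range(n_records):
        rid = f"r{idx:04d}"
        left = int(rng.integers(0, flank + 1))
        right = int(rng.integers(0, flank + 1))
        if idx in planted_idx:
            sub_spec = MutationSpec(
                spec.substitution_rate, spec.insertion_rate,
                spec.deletion_rate, seed=int(rng.integers(0, 2**31 - 1)),
            )
            core, _ = mutate(bytes(query), sub_spec, alphabet)
            seq = rand_bytes(left) + core + rand_bytes(right)
        else:
            seq = rand_bytes(left + len(query) + right)
        t_enc = encode_sequence(scheme, seq)
        if mode == "local":
            result = local_align_scalar(scheme, q_enc, t_enc)
        else:
            result = semiglobal_align_scalar(scheme, q_enc, t_enc, ends)
        truth.append(TruthRow(rid, idx in planted_idx, result.score,
                              result.score / opt))
        if kind == "fasta":
            chunks.append(b">" + rid.encode() + b"\n" + seq + b"\n")
        elif kind == "fastq":
            chunks.append(b"@" + rid.encode() + b"\n" + seq + b"\n+\n"
                          + b"I" * len(seq) + b"\n")
        elif kind == "line":
            chunks.append(seq + b"\n")
        else:
            raise ValueError(f"unknown record kind {kind!r}")
    return Corpus(kind=kind, text=b"".join(chunks), query=bytes(query),
                  optimal=opt, truth=truth)
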