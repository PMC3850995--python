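"""Read and write contact predictions in the CASP RR exchange format.

An RR file carries optional header lines (``PFRMAT RR``, ``TARGET``,
``AUTHOR``, ``METHOD``, ``REMARK``, ``MODEL``, bare sequence lines) followed
by five-column records ``i j dmin dmax score`` — one scored residue pair per
line — and an optional ``END``.  The headerless five-column dialect is also
accepted.  Only MODEL 1 is read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

HEADER_KEYWORDS = {"PFRMAT", "TARGET", "AUTHOR", "METHOD", "REMARK", "MODEL", "END"}


class RRFormatError(ValueError):
    """Raised on a malformed or invalid RR record."""


@dataclass(frozen=True)
class ScoredPair:
    """One predicted residue pair, normalized to i < j.

    ``dmin``/``dmax`` are the predicted distance bounds in Å (informational);
    ``score`` is the predictor's confidence in [0, 1], higher = more confident.
    """

    i: int
    j: int
    dmin: float
    dmax: float
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.i < self.j:
            raise ValueError(f"require 1 <= i < j, got ({self.i}, {self.j})")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.dmin > self.dmax:
            raise ValueError(f"dmin {self.dmin} > dmax {self.dmax}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class PredictionSet:
    """Ranked scored pairs for one target from one predictor."""

    target_id: str
    predictor_id: str
    pairs: tuple[ScoredPair, ...]
    length: Optional[int] = None

    def __post_init__(self) -> None:
        seen = {p.pair for p in self.pairs}
        if len(seen) != len(self.pairs):
            raise ValueError("duplicate (i, j) pairs in prediction set")
        if self.length is not None:
            for p in self.pairs:
                if p.j > self.length:
                    raise ValueError(
                        f"pair {p.pair} exceeds target length {self.length}"
                    )


def _parse_record(fields: list[str], lineno: int) -> ScoredPair:
    if len(fields) != 5:
        raise RRFormatError(
            f"line {lineno}: expected 5 columns, got {len(fields)}: {fields}"
        )
    try:
        i, j = int(fields[0]), int(fields[1])
        dmin, dmax = float(fields[2]), float(fields[3])
        score = float(fields[4])
    except ValueError as exc:
        raise RRFormatError(f"line {lineno}: non-numeric field ({exc})") from exc
    if i == j:
        raise RRFormatError(f"line {lineno}: i == j == {i}")
    if not 0.0 <= score <= 1.0:
        raise RRFormatError(f"line {lineno}: score {score} outside [0, 1]")
    if i > j:
        i, j = j, i
    if i < 1:
        raise RRFormatError(f"line {lineno}: position {i} < 1")
    if dmin > dmax:
        raise RRFormatError(f"line {lineno}: dmin {dmin} > dmax {dmax}")
    return ScoredPair(i=i, j=j, dmin=dmin, dmax=dmax, score=score)


def read_rr(text: str, predictor_id: str = "") -> PredictionSet:
    """Parse RR-format text into a PredictionSet.

    Pairs are normalized to i < j; record order is preserved.  Exact
    duplicates are silently dropped; duplicates with conflicting scores are
    an error (resolving them would silently change rankings).
    """
    target_id = ""
    pairs: list[ScoredPair] = []
    by_pair: dict[tuple[int, int], ScoredPair] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        keyword = fields[0].upper()
        if keyword in HEADER_KEYWORDS:
            if keyword == "TARGET" and len(fields) > 1:
                target_id = fields[1]
            elif keyword == "END":
                break
            elif keyword == "MODEL" and len(fields) > 1 and fields[1] != "1":
                break  # only MODEL 1 is evaluated
            continue
        if len(fields) == 1 and fields[0].isalpha():
            continue  # sequence line; the target sequence comes from FASTA
        rec = _parse_record(fields, lineno)
        prior = by_pair.get(rec.pair)
        if prior is not None:
            if prior.score != rec.score:
                raise RRFormatError(
                    f"line {lineno}: duplicate pair {rec.pair} with conflicting "
                    f"scores {prior.score} and {rec.score}"
                )
            continue
        by_pair[rec.pair] = rec
        pairs.append(rec)
    return PredictionSet(
        target_id=target_id, predictor_id=predictor_id, pairs=tuple(pairs)
    )


def write_rr(predictions: PredictionSet) -> str:
    """Serialize a PredictionSet to RR text; read_rr(write_rr(p)) == p.

    Floats use shortest round-trip representation so scores (and hence
    rankings) survive the round trip exactly.
    """
    lines = ["PFRMAT RR"]
    if predictions.target_id:
        lines.append(f"TARGET {predictions.target_id}")
    lines.append("MODEL 1")
    for p in predictions.pairs:
        lines.append(f"{p.i} {p.j} {p.dmin!r} {p.dmax!r} {p.score!r}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def validate_against_target(predictions: PredictionSet, length: int) -> PredictionSet:
    """Check all positions fit the target length L and record L on the set."""
    if length < 1:
        raise ValueError("target length must be >= 1")
    for p in predictions.pairs:
        if p.j > length:
            raise RRFormatError(
                f"pair {p.pair} (score {p.score}) exceeds target length {length}"
            )
    return PredictionSet(
        target_id=predictions.target_id,
        predictor_id=predictions.predictor_id,
        pairs=predictions.pairs,
        length=length,
    )
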