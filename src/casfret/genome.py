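"""Counting PAM-plus-seed query occurrences in a genome.

The query is an IUPAC string over {A, C, G, T, N} (e.g. eight
protospacer-proximal bases followed by the NGG PAM).  ``N`` is a wildcard;
specified bases require an exact match, and ambiguous genome bases never
match a specified query base.  Matches are counted on both strands by
default, overlapping occurrences included, and never span FASTA record
boundaries.

The random-sequence expectation is the probabilistic count
(1/4)^n * L, with n the number of specified (non-N) positions and L the
genome length in base pairs.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeedQuery",
    "GenomeCountResult",
    "count_matches",
    "probabilistic_count",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SeedQuery:
    """A PAM/seed search pattern over {A, C, G, T, N}."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError("query must be non-empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters in query: {sorted(bad)}")

    @property
    def n_specified(self) -> int:
        """Number of non-wildcard positions."""
        return sum(1 for c in self.sequence if c != "N")

    def reverse_complement(self) -> "SeedQuery":
        return SeedQuery(str(Seq(self.sequence).reverse_complement()))

    def to_regex(self) -> re.Pattern:
        # lookahead so that overlapping matches are counted
        pat = "".join("." if c == "N" else c for c in self.sequence)
        return re.compile(f"(?=({pat}))")


@dataclass
class GenomeCountResult:
    """Observed vs expected occurrence counts for one query."""

    query: SeedQuery
    actual_count: int
    probabilistic_count: float
    genome_length_bp: int
    both_strands: bool
    convention: str
    positions: list[tuple[str, int, str]] = field(default_factory=list)
    # (record id, 1-based forward-strand start, strand)


def probabilistic_count(query: SeedQuery | str, genome_length: int) -> float:
    """Expected occurrences in a random uniform sequence: (1/4)^n * L.

    Single-strand convention; double for a two-strand comparison.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if isinstance(query, str):
        query = SeedQuery(query)
    return 0.25 ** query.n_specified * genome_length


def _iter_records(genome):
    if isinstance(genome, (str, Path)):
        path = Path(genome)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from ((rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta"))
    elif isinstance(genome, dict):
        yield from ((k, v.upper()) for k, v in genome.items())
    else:  # iterable of SeqRecord
        yield from ((rec.id, str(rec.seq).upper()) for rec in genome)


def count_matches(
    genome,
    query: SeedQuery | str,
    both_strands: bool = True,
    probabilistic_both_strands: bool | None = None,
    collect_positions: bool = False,
) -> GenomeCountResult:
    """Count query occurrences in a genome (FASTA path, dict of sequences, or
    SeqRecord iterable).

    Overlapping matches are counted; multi-record genomes are summed and
    matches never span record boundaries.  Reverse-strand hits are found by
    scanning the reverse complement of each record; reported positions are
    1-based, inclusive, on the forward strand.
    """
    if isinstance(query, str):
        query = SeedQuery(query)
    if probabilistic_both_strands is None:
        probabilistic_both_strands = both_strands
    fwd_re = query.to_regex()
    m = len(query.sequence)

    total = 0
    length = 0
    positions: list[tuple[str, int, str]] = []
    for rec_id, seq in _iter_records(genome):
        length += len(seq)
        for match in fwd_re.finditer(seq):
            total += 1
            if collect_positions:
                positions.append((rec_id, match.start() + 1, "+"))
        if both_strands:
            rc = str(Seq(seq).reverse_complement())
            for match in fwd_re.finditer(rc):
                total += 1
                if collect_positions:
                    # map the reverse-complement hit back to forward coordinates
                    positions.append((rec_id, len(seq) - match.start() - m + 1, "-"))
    if length == 0:
        raise ValueError("genome is empty")

    prob = probabilistic_count(query, length)
    if probabilistic_both_strands:
        prob *= 2.0
    return GenomeCountResult(
        query=query,
        actual_count=total,
        probabilistic_count=prob,
        genome_length_bp=length,
        both_strands=both_strands,
        convention=(
            "actual: both strands; probabilistic: both strands"
            if both_strands and probabilistic_both_strands
            else "actual: "
            + ("both strands" if both_strands else "forward only")
            + "; probabilistic: "
            + ("both strands" if probabilistic_both_strands else "single strand")
        ),
        positions=positions,
    )
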