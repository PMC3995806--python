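"""In-memory genome container with soft-mask annotation and k-mer index.

Lowercase bases in input FASTA are honoured as repeat (soft-mask)
annotation; sequences are stored upper-cased with a parallel boolean mask.
The k-mer index counts canonical (strand-merged) k-mer occurrences so that
repetitiveness queries see both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Contig:
    name: str
    seq: str  # upper case
    mask: np.ndarray  # bool per base, True = soft-masked

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.seq):
            raise ValueError(f"{self.name}: mask length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_string(cls, name: str, raw: str) -> "Contig":
        """Build from raw FASTA text, reading lowercase as soft-mask."""
        mask = np.fromiter((c.islower() for c in raw), dtype=bool, count=len(raw))
        return cls(name=name, seq=raw.upper(), mask=mask)

    def masked_string(self) -> str:
        """Sequence with soft-masked bases rendered lowercase."""
        if not self.mask.any():
            return self.seq
        chars = np.array(list(self.seq))
        lower = np.char.lower(chars[self.mask])
        chars[self.mask] = lower
        return "".join(chars)


class Genome:
    """Ordered mapping of contig name → :class:`Contig`."""

    def __init__(self, contigs: Optional[Dict[str, Contig]] = None):
        self.contigs: Dict[str, Contig] = dict(contigs or {})

    def __getitem__(self, name: str) -> Contig:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def add(self, contig: Contig) -> None:
        if contig.name in self.contigs:
            raise ValueError(f"duplicate contig id {contig.name!r}")
        self.contigs[contig.name] = contig

    def lengths(self) -> Dict[str, int]:
        return {name: len(c) for name, c in self.contigs.items()}

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs.values())


_VALID = frozenset("ACGT")


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerIndex:
    """Canonical k-mer occurrence counts over a genome.

    Counting is strand-merged: each genome position contributes one count to
    the canonical form of its k-mer, so a query sees occurrences on either
    strand. k-mers containing ambiguity codes are skipped.
    """

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.counts: Counter = Counter()

    @classmethod
    def from_genome(cls, genome: Genome, k: int) -> "KmerIndex":
        idx = cls(k)
        for contig in genome.contigs.values():
            idx.add_sequence(contig.seq)
        return idx

    def add_sequence(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= _VALID:
                self.counts[canonical(kmer)] += 1

    def count(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        return self.counts.get(canonical(kmer.upper()), 0)

    def max_copies(self, seq: str) -> int:
        """Largest genome occurrence count over all k-mers of ``seq``.

        Returns 0 for sequences shorter than k or made only of ambiguous
        k-mers.
        """
        k = self.k
        seq = seq.upper()
        best = 0
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= _VALID:
                best = max(best, self.counts.get(canonical(kmer), 0))
        return best
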