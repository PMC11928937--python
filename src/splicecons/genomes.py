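"""Genome containers and FASTA I/O.

A :class:`GenomeSet` holds the reference genome plus the target genomes of a
multi-species comparison as plain uppercase nucleotide strings.  At the scales
this package operates on (synthetic genomes of a few megabases) whole
chromosomes are kept in memory; on-disk FASTA access goes through ``pyfaidx``
so that indexed access works for larger inputs too.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class GenomeSet:
    """An ordered collection of genomes, one of which is the reference.

    Parameters
    ----------
    genomes
        Mapping ``genome_id -> {contig_id -> sequence}``.  Sequences are
        uppercased on construction.
    reference_id
        The id of the reference genome (``g_1``); it must be present.
    """

    genomes: Dict[str, Dict[str, str]]
    reference_id: str
    _byte_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.reference_id not in self.genomes:
            raise ValueError(f"reference genome {self.reference_id!r} not present")
        for gid, contigs in self.genomes.items():
            for cid, seq in contigs.items():
                if not seq.isupper():
                    contigs[cid] = seq.upper()

    @property
    def m(self) -> int:
        """Number of genomes (reference included)."""
        return len(self.genomes)

    @property
    def target_ids(self) -> list[str]:
        return [g for g in self.genomes if g != self.reference_id]

    @property
    def reference(self) -> Dict[str, str]:
        return self.genomes[self.reference_id]

    def seq(self, genome_id: str, contig: str, start: int, end: int) -> str:
        """Forward-strand slice [start, end) of a contig (0-based half-open)."""
        return self.genomes[genome_id][contig][start:end]

    def base(self, genome_id: str, contig: str, pos: int) -> str:
        return self.genomes[genome_id][contig][pos]

    def contig_bytes(self, genome_id: str, contig: str) -> np.ndarray:
        """Contig as a uint8 array of ASCII codes (cached; read-only view)."""
        key = (genome_id, contig)
        arr = self._byte_cache.get(key)
        if arr is None:
            arr = np.frombuffer(
                self.genomes[genome_id][contig].encode("ascii"), dtype=np.uint8
            )
            self._byte_cache[key] = arr
        return arr


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into ``{contig -> uppercase sequence}`` via pyfaidx."""
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_genome_set(
    paths: Mapping[str, str | os.PathLike], reference_id: str
) -> GenomeSet:
    """Load several FASTA files, one per genome id."""
    return GenomeSet(
        genomes={gid: read_fasta(p) for gid, p in paths.items()},
        reference_id=reference_id,
    )


def write_fasta(
    contigs: Mapping[str, str], path: str | os.PathLike, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def iter_contigs(gs: GenomeSet, genome_id: str) -> Iterable[tuple[str, str]]:
    yield from gs.genomes[genome_id].items()
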