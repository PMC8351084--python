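"""Multiple sequence alignments and supermatrix editing operations.

This module holds the in-memory alignment container and the three editing
operations used when probing a dataset for long-branch attraction:

* concatenation of per-gene alignments into a supermatrix (with a partition
  map recording gene boundaries),
* detection and removal of *singleton* columns — positions where at least one
  sequence carries a character state found in no other sequence, and
* taxon deletion.

Column coordinates are 0-based half-open internally; human-readable reports
use 1-based inclusive coordinates.
"""

from __future__ import annotations

import io
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACID",
    "NUCLEOTIDE",
    "Alphabet",
    "Alignment",
    "PartitionMap",
    "SingletonRecord",
    "concatenate",
    "find_singleton_columns",
    "singleton_report",
    "drop_columns",
    "drop_taxa",
]


@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet plus the symbols treated as missing data.

    Gap ('-') and ambiguity codes ('X' for proteins, 'N' for nucleotides,
    '?' for both) are *missing*: they are skipped when counting character
    states and contribute flat partial likelihoods.
    """

    name: str
    states: str
    missing: str

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.states)}

    def is_valid(self, residue: str) -> bool:
        return residue in self.states or residue in self.missing


#: Amino acids in PAML order (matches the packaged lg.dat frequency row).
AMINO_ACID = Alphabet("amino_acid", "ARNDCQEGHILKMFPSTWYV", "X-?*")
NUCLEOTIDE = Alphabet("nucleotide", "ACGT", "N-?")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PartitionMap:
    """Gene name -> half-open column interval [start, end) in the supermatrix.

    Intervals are contiguous, non-overlapping and cover [0, L).
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        cursor = 0
        for name, start, end in self.intervals:
            if start != cursor or end < start:
                raise AlignmentError(
                    f"partition {name!r}: interval [{start}, {end}) is not "
                    f"contiguous with previous end {cursor}"
                )
            cursor = end

    @property
    def total_length(self) -> int:
        return self.intervals[-1][2] if self.intervals else 0

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def gene_of(self, column: int) -> str:
        for name, start, end in self.intervals:
            if start <= column < end:
                return name
        raise KeyError(column)

    def after_column_drop(self, dropped: Iterable[int]) -> "PartitionMap":
        """Re-index after removing ``dropped`` columns from the supermatrix.

        Genes whose columns are all removed survive as empty intervals.
        """
        dropped = set(dropped)
        out = []
        cursor = 0
        for name, start, end in self.intervals:
            kept = sum(1 for c in range(start, end) if c not in dropped)
            out.append((name, cursor, cursor + kept))
            cursor += kept
        return PartitionMap(tuple(out))


@dataclass(frozen=True)
class Alignment:
    """An ordered taxon -> sequence map over a declared alphabet."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    alphabet: Alphabet = AMINO_ACID
    _matrix_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise AlignmentError("alignment must contain at least one taxon")
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = {c for c in seq if not self.alphabet.is_valid(c)}
            if bad:
                raise AlignmentError(
                    f"sequence for {taxon!r} contains symbols {sorted(bad)} "
                    f"outside alphabet {self.alphabet.name!r}"
                )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping, alphabet: Alphabet = AMINO_ACID) -> "Alignment":
        items = list(mapping.items())
        return cls(
            taxa=tuple(k for k, _ in items),
            sequences=tuple(str(v).upper() for _, v in items),
            alphabet=alphabet,
        )

    # -- basic properties -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(taxon) from None

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) int8 matrix; missing/gap symbols encoded as -1."""
        if "m" not in self._matrix_cache:
            idx = self.alphabet.index()
            m = np.full((self.n_taxa, self.length), -1, dtype=np.int8)
            for i, seq in enumerate(self.sequences):
                m[i] = [idx.get(c, -1) for c in seq]
            m.setflags(write=False)
            self._matrix_cache["m"] = m
        return self._matrix_cache["m"]

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.sequences)

    # -- I/O ---------------------------------------------------------------

    def _records(self):
        return [
            SeqRecord(Seq(seq), id=taxon, description="")
            for taxon, seq in zip(self.taxa, self.sequences)
        ]

    def to_fasta(self, path_or_handle) -> None:
        """Write FASTA, wrapped at 60 columns."""
        SeqIO.write(self._records(), path_or_handle, "fasta")

    def to_phylip(self, path_or_handle) -> None:
        """Write relaxed (whitespace-delimited names) sequential PHYLIP."""
        AlignIO.write(
            MultipleSeqAlignment(self._records()), path_or_handle, "phylip-relaxed"
        )

    @classmethod
    def from_fasta(cls, path_or_handle, alphabet: Alphabet = AMINO_ACID) -> "Alignment":
        records = list(SeqIO.parse(path_or_handle, "fasta"))
        if not records:
            raise AlignmentError("no sequences in FASTA input")
        return cls.from_mapping({r.id: str(r.seq) for r in records}, alphabet)

    @classmethod
    def from_phylip(cls, path_or_handle, alphabet: Alphabet = AMINO_ACID) -> "Alignment":
        aln = AlignIO.read(path_or_handle, "phylip-relaxed")
        return cls.from_mapping({r.id: str(r.seq) for r in aln}, alphabet)

    def to_fasta_string(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()

    # -- editing -----------------------------------------------------------

    def drop_columns(self, columns: Iterable[int]) -> "Alignment":
        return drop_columns(self, columns)

    def drop_taxa(self, labels: Iterable[str]) -> "Alignment":
        return drop_taxa(self, labels)

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Alignment restricted to ``columns`` in the given order (resampling)."""
        cols = list(columns)
        seqs = tuple("".join(seq[j] for j in cols) for seq in self.sequences)
        return Alignment(self.taxa, seqs, self.alphabet)

    def reorder(self, taxa: Sequence[str]) -> "Alignment":
        if set(taxa) != set(self.taxa):
            raise AlignmentError("reorder requires the same taxon set")
        return Alignment(
            tuple(taxa), tuple(self.sequence(t) for t in taxa), self.alphabet
        )


# -- supermatrix construction ---------------------------------------------


def concatenate(
    genes: Sequence[Alignment], names: Sequence[str] | None = None
) -> tuple[Alignment, PartitionMap]:
    """Concatenate per-gene alignments sharing a taxon set into a supermatrix.

    Taxon order follows the first gene; later genes may list taxa in any
    order. Returns the supermatrix and a :class:`PartitionMap` of gene
    boundaries.
    """
    if not genes:
        raise AlignmentError("no gene alignments given")
    if names is None:
        names = [f"gene{i + 1}" for i in range(len(genes))]
    if len(names) != len(genes):
        raise AlignmentError("names and genes differ in count")
    ref = genes[0]
    ref_set = set(ref.taxa)
    for name, gene in zip(names, genes):
        if gene.alphabet.name != ref.alphabet.name:
            raise AlignmentError(
                f"gene {name!r} alphabet {gene.alphabet.name!r} differs from "
                f"{ref.alphabet.name!r}"
            )
        if set(gene.taxa) != ref_set:
            missing = sorted(ref_set - set(gene.taxa))
            extra = sorted(set(gene.taxa) - ref_set)
            raise AlignmentError(
                f"gene {name!r} taxon set mismatch: missing {missing}, "
                f"unexpected {extra}"
            )
    parts = []
    cursor = 0
    chunks = {t: [] for t in ref.taxa}
    for name, gene in zip(names, genes):
        for t in ref.taxa:
            chunks[t].append(gene.sequence(t))
        parts.append((name, cursor, cursor + gene.length))
        cursor += gene.length
    seqs = tuple("".join(chunks[t]) for t in ref.taxa)
    return Alignment(ref.taxa, seqs, ref.alphabet), PartitionMap(tuple(parts))


# -- singleton columns ------------------------------------------------------


@dataclass(frozen=True)
class SingletonRecord:
    """One private character: 0-based column, the state, and its carrier."""

    column: int
    state: str
    taxon: str


def _state_counts(aln: Alignment) -> np.ndarray:
    """(n_states, L) occurrence counts; gap/missing symbols are skipped."""
    m = aln.matrix()
    k = aln.alphabet.size
    counts = np.zeros((k, aln.length), dtype=np.int32)
    for s in range(k):
        counts[s] = (m == s).sum(axis=0)
    return counts


def find_singleton_columns(aln: Alignment) -> set[int]:
    """Columns in which at least one sequence has a private character.

    A state is *private* when exactly one sequence carries it. Gap and
    missing symbols never count as private and never block other states
    from being private. States shared by two sequences (e.g. both strains
    of one lineage) are not private.
    """
    counts = _state_counts(aln)
    return set(np.nonzero((counts == 1).any(axis=0))[0].tolist())


def singleton_report(aln: Alignment) -> list[SingletonRecord]:
    """All private characters, ordered by column then alphabet."""
    counts = _state_counts(aln)
    m = aln.matrix()
    records = []
    state_idx, col_idx = np.nonzero(counts == 1)
    order = np.lexsort((state_idx, col_idx))
    for s, j in zip(state_idx[order], col_idx[order]):
        carrier = aln.taxa[int(np.nonzero(m[:, j] == s)[0][0])]
        records.append(SingletonRecord(int(j), aln.alphabet.states[s], carrier))
    return records


def write_singleton_report(records: Sequence[SingletonRecord], handle) -> None:
    """TSV report with 1-based column numbers."""
    handle.write("column\tstate\tcarrier_taxon\n")
    for r in records:
        handle.write(f"{r.column + 1}\t{r.state}\t{r.taxon}\n")


def prune_singletons(
    aln: Alignment,
    partition: PartitionMap | None = None,
    repeat: bool = False,
) -> tuple[Alignment, PartitionMap | None, list[SingletonRecord]]:
    """Remove singleton columns (single pass by default).

    With ``repeat=True`` the pass is reapplied until no singleton column
    remains; the one-shot edit is the default and matches how such pruning
    is typically scripted over a fixed alignment. Note a single pass is not
    idempotent in general: removing taxa or columns can expose new private
    states.
    """
    records = singleton_report(aln)
    cols = {r.column for r in records}
    pruned = drop_columns(aln, cols)
    part = partition.after_column_drop(cols) if partition is not None else None
    if repeat:
        while True:
            more = find_singleton_columns(pruned)
            if not more:
                break
            pruned = drop_columns(pruned, more)
            part = part.after_column_drop(more) if part is not None else None
    return pruned, part, records


# -- deletion ----------------------------------------------------------------


def drop_columns(aln: Alignment, columns: Iterable[int]) -> Alignment:
    """Remove the given 0-based columns, preserving the order of survivors."""
    cols = set(columns)
    bad = [c for c in cols if not (0 <= c < aln.length)]
    if bad:
        raise AlignmentError(f"column indices out of range [0, {aln.length}): {sorted(bad)}")
    keep = [j for j in range(aln.length) if j not in cols]
    if not keep:
        logger.warning("drop_columns removed every column; alignment now empty")
        return Alignment(aln.taxa, tuple("" for _ in aln.taxa), aln.alphabet)
    seqs = tuple("".join(seq[j] for j in keep) for seq in aln.sequences)
    return Alignment(aln.taxa, seqs, aln.alphabet)


def drop_taxa(aln: Alignment, labels: Iterable[str]) -> Alignment:
    """Remove the given taxa, preserving the order of survivors."""
    labels = set(labels)
    unknown = sorted(labels - set(aln.taxa))
    if unknown:
        raise AlignmentError(f"unknown taxa: {unknown}")
    kept = [(t, s) for t, s in zip(aln.taxa, aln.sequences) if t not in labels]
    if not kept:
        raise AlignmentError("cannot drop every taxon")
    return Alignment(
        tuple(t for t, _ in kept), tuple(s for _, s in kept), aln.alphabet
    )
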