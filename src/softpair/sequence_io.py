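"""Reading, writing and harmonizing species-partitioned sequence collections.

The pairing problem operates on two ordered collections of sequences (aligned
MSAs for mutual-information scoring, arbitrary strings for graph-alignment
scoring), each partitioned into species.  Within a species the two families may
have different numbers of members; the smaller family is padded with all-gap
(aligned) or empty (nonaligned) rows so that every species block is square.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 amino acids followed by the gap symbol.  The gap is an ordinary 21st
#: state everywhere (including in joint frequency counts).
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"
#: Symbols mapped to the gap state when ``ambiguous_to_gap`` is requested.
AMBIGUOUS_SYMBOLS = frozenset("XBZJUO*.")


class SequenceInputError(ValueError):
    """Unparseable or inconsistent sequence input."""


class SpeciesMismatchError(ValueError):
    """The two collections do not cover the same species."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the declared alphabet."""


@dataclass(frozen=True)
class SpeciesPartition:
    """Ordered species blocks with per-species sizes.

    All permutations are block-diagonal with respect to this partition: a
    sequence can only be paired within its own species.
    """

    names: tuple[str, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sizes):
            raise ValueError("names and sizes must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate species names in partition")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("species sizes must be positive")

    @property
    def n_species(self) -> int:
        return len(self.names)

    @property
    def total(self) -> int:
        return int(sum(self.sizes))

    @property
    def offsets(self) -> tuple[int, ...]:
        out, acc = [], 0
        for s in self.sizes:
            out.append(acc)
            acc += s
        return tuple(out)

    def block_slices(self) -> tuple[slice, ...]:
        return tuple(
            slice(o, o + s) for o, s in zip(self.offsets, self.sizes)
        )


@dataclass
class SequenceRecord:
    id: str
    species: str
    seq: str
    is_padding: bool = False


@dataclass
class SequenceCollection:
    """Ordered sequences grouped contiguously by species."""

    records: list[SequenceRecord]
    aligned: bool
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        prev = None
        for r in self.records:
            if r.species != prev:
                if r.species in seen:
                    raise SequenceInputError(
                        f"species {r.species!r} is not contiguous in the collection"
                    )
                seen[r.species] = 0
                prev = r.species
            seen[r.species] += 1
        if self.aligned:
            lengths = {len(r.seq) for r in self.records}
            if len(lengths) > 1:
                raise SequenceInputError(
                    f"aligned collection has unequal sequence lengths: {sorted(lengths)}"
                )
        self._counts = seen

    def __len__(self) -> int:
        return len(self.records)

    @property
    def partition(self) -> SpeciesPartition:
        return SpeciesPartition(
            names=tuple(self._counts), sizes=tuple(self._counts.values())
        )

    @property
    def length(self) -> int:
        """Alignment length (aligned collections only)."""
        if not self.aligned:
            raise SequenceInputError("length is undefined for nonaligned collections")
        return len(self.records[0].seq) if self.records else 0

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def padding_mask(self) -> np.ndarray:
        return np.array([r.is_padding for r in self.records], dtype=bool)

    def to_indices(self, ambiguous_to_gap: bool = False) -> np.ndarray:
        """Integer-encode an aligned collection as an (N, L) matrix."""
        if not self.aligned:
            raise SequenceInputError("integer encoding requires an aligned collection")
        lut = {s: i for i, s in enumerate(self.alphabet)}
        gap_idx = lut.get(GAP)
        out = np.empty((len(self), self.length), dtype=np.int64)
        for n, r in enumerate(self.records):
            for i, sym in enumerate(r.seq):
                idx = lut.get(sym)
                if idx is None and ambiguous_to_gap and sym in AMBIGUOUS_SYMBOLS:
                    idx = gap_idx
                if idx is None:
                    raise AlphabetError(
                        f"symbol {sym!r} at record {r.id!r}, column {i + 1} "
                        f"is not in the alphabet {self.alphabet!r}"
                    )
                out[n, i] = idx
        return out


@dataclass
class OneHotTensor:
    """One-hot encoded aligned collection: (sequence, column, symbol) in {0,1}."""

    data: np.ndarray
    alphabet: str = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("one-hot tensor must have 3 axes")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def flat(self) -> np.ndarray:
        """(N, L*q) view used by the matrix-product loss kernels."""
        n, l, q = self.data.shape
        return self.data.reshape(n, l * q)


@dataclass
class PairedCollections:
    """Two harmonized collections sharing one species partition."""

    a: SequenceCollection
    b: SequenceCollection
    partition: SpeciesPartition


def read_species_map(path) -> dict[str, str]:
    """Two-column tab-separated file: sequence id, species label."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceInputError(
                    f"species map line has fewer than two columns: {line!r}"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def read_collection(
    fasta_path,
    species_map=None,
    header_delimiter: str = "|",
    alphabet: str = PROTEIN_ALPHABET,
) -> SequenceCollection:
    """Read a FASTA file into a species-grouped collection.

    The species of each record is the final header field split on
    ``header_delimiter``; a separate two-column TSV map (id -> species), when
    given, takes precedence over headers.  Records are grouped by species in
    order of first appearance; the collection is flagged aligned iff all
    sequences have equal length.
    """
    mapping = read_species_map(species_map) if species_map is not None else None
    raw: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        raw.append((rec.description, str(rec.seq)))
    if not raw:
        raise SequenceInputError(f"no FASTA records found in {fasta_path}")

    records: list[SequenceRecord] = []
    for header, seq in raw:
        species = None
        rec_id = header
        if mapping is not None and header in mapping:
            species = mapping[header]
        elif mapping is not None and header.split(header_delimiter)[0] in mapping:
            rec_id = header.split(header_delimiter)[0]
            species = mapping[rec_id]
        elif header_delimiter in header:
            fields = header.split(header_delimiter)
            species = fields[-1]
            rec_id = header_delimiter.join(fields[:-1])
        if species is None:
            raise SequenceInputError(
                f"cannot resolve a species for record {header!r}: no map entry "
                f"and no {header_delimiter!r}-delimited species field in the header"
            )
        records.append(SequenceRecord(id=rec_id, species=species, seq=seq))

    # group by species in order of first appearance
    order: dict[str, list[SequenceRecord]] = {}
    for r in records:
        order.setdefault(r.species, []).append(r)
    grouped = [r for group in order.values() for r in group]
    lengths = {len(r.seq) for r in grouped}
    return SequenceCollection(
        records=grouped, aligned=(len(lengths) == 1), alphabet=alphabet
    )


def write_collection(c: SequenceCollection, path, header_delimiter: str = "|") -> None:
    """Write a collection to FASTA with ``<id><delimiter><species>`` headers."""
    out = [
        SeqRecord(Seq(r.seq), id=f"{r.id}{header_delimiter}{r.species}", description="")
        for r in c.records
    ]
    SeqIO.write(out, str(path), "fasta-2line")


def harmonize_pair(
    a: SequenceCollection, b: SequenceCollection, gap_symbol: str = GAP
) -> PairedCollections:
    """Equalize within-species family sizes by gap-padding.

    For each species k the common block size N_k is the larger of the two
    family sizes; the smaller family receives all-gap rows (aligned mode) or
    empty-string rows (nonaligned mode).  Both collections are reordered to the
    species order of ``a``.  Idempotent.
    """
    pa, pb = a.partition, b.partition
    only_a = set(pa.names) - set(pb.names)
    only_b = set(pb.names) - set(pa.names)
    if only_a or only_b:
        raise SpeciesMismatchError(
            "species present in only one collection: "
            f"A-only={sorted(only_a)}, B-only={sorted(only_b)}"
        )

    def groups(c: SequenceCollection) -> dict[str, list[SequenceRecord]]:
        g: dict[str, list[SequenceRecord]] = {}
        for r in c.records:
            g.setdefault(r.species, []).append(r)
        return g

    ga, gb = groups(a), groups(b)
    new_a: list[SequenceRecord] = []
    new_b: list[SequenceRecord] = []
    sizes: list[int] = []
    for sp in pa.names:
        ra, rb = list(ga[sp]), list(gb[sp])
        nk = max(len(ra), len(rb))
        sizes.append(nk)
        for coll, rows, n_pad_start in ((a, ra, len(ra)), (b, rb, len(rb))):
            pad_len = coll.length if coll.aligned else 0
            for i in range(nk - len(rows)):
                rows.append(
                    SequenceRecord(
                        id=f"PAD_{sp}_{n_pad_start + i}",
                        species=sp,
                        seq=gap_symbol * pad_len,
                        is_padding=True,
                    )
                )
        new_a.extend(ra)
        new_b.extend(rb)

    ha = SequenceCollection(records=new_a, aligned=a.aligned, alphabet=a.alphabet)
    hb = SequenceCollection(records=new_b, aligned=b.aligned, alphabet=b.alphabet)
    partition = SpeciesPartition(names=tuple(pa.names), sizes=tuple(sizes))
    return PairedCollections(a=ha, b=hb, partition=partition)


def one_hot_encode(
    c: SequenceCollection, ambiguous_to_gap: bool = False
) -> OneHotTensor:
    """One-hot encode an aligned collection; the gap is an ordinary state."""
    idx = c.to_indices(ambiguous_to_gap=ambiguous_to_gap)
    n, l = idx.shape
    q = len(c.alphabet)
    data = np.zeros((n, l, q), dtype=np.float64)
    data[np.arange(n)[:, None], np.arange(l)[None, :], idx] = 1.0
    return OneHotTensor(data=data, alphabet=c.alphabet)
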