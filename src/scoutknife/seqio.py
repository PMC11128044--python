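"""Gene alignment I/O: per-gene FASTA files, supermatrix concatenation and
RAxML-style partition definitions.

A multi-gene dataset lives either as a directory of per-gene FASTA
alignments (one file per gene) or as a single concatenated FASTA plus a
partition file mapping genes to column ranges. Both views are supported and
interconvertible: :func:`concatenate` builds a supermatrix from gene
alignments, padding taxa absent from a gene with ``'-'``; and
:func:`split_supermatrix` recovers the per-gene alignments, dropping taxa
whose slice is entirely gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "GeneAlignment",
    "SuperMatrix",
    "PartitionMap",
    "read_gene_fastas",
    "read_fasta_alignment",
    "write_fasta",
    "concatenate",
    "split_supermatrix",
    "read_partition_file",
    "write_partition_file",
]

GAP = "-"

# Characters that would break downstream Newick output if embedded in taxon
# names; such names are rejected outright rather than silently sanitized.
_RESERVED = set(",():;[]'") | {" ", "\t"}

_FASTA_SUFFIXES = {".fa", ".fas", ".fasta", ".fna", ".faa", ".aln"}


class SeqIOError(ValueError):
    """Malformed alignment, partition file or taxon name."""


def _check_taxon_name(name: str, context: str) -> None:
    if not name:
        raise SeqIOError(f"empty taxon name in {context}")
    bad = sorted(set(name) & _RESERVED)
    if bad:
        raise SeqIOError(
            f"taxon name {name!r} in {context} contains reserved "
            f"character(s) {''.join(bad)!r}; rename the sequence"
        )


@dataclass(frozen=True)
class GeneAlignment:
    """One gene's multiple sequence alignment keyed by taxon name.

    All sequences share the same aligned length; gap is ``'-'``.
    """

    gene_id: str
    seqs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.seqs:
            raise SeqIOError(f"gene {self.gene_id!r}: no sequences")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{t}:{len(s)}" for t, s in list(self.seqs.items())[:6]
            )
            raise SeqIOError(
                f"gene {self.gene_id!r}: ragged alignment ({detail})"
            )
        if lengths == {0}:
            raise SeqIOError(f"gene {self.gene_id!r}: zero-length alignment")
        for t in self.seqs:
            _check_taxon_name(t, f"gene {self.gene_id!r}")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values())))

    def has_data(self, taxon: str) -> bool:
        """True if *taxon* is present with at least one non-gap residue."""
        s = self.seqs.get(taxon)
        return s is not None and any(c != GAP for c in s)


@dataclass(frozen=True)
class PartitionMap:
    """Ordered gene → column-range map; 1-based inclusive coordinates."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for gene_id, start, end in self.entries:
            if start != prev_end + 1 or end < start:
                raise SeqIOError(
                    f"partition {gene_id!r} = {start}-{end} does not tile "
                    f"contiguously after column {prev_end}"
                )
            prev_end = end

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0


@dataclass(frozen=True)
class SuperMatrix:
    """Concatenated alignment over the union of taxa, with partitions."""

    seqs: dict[str, str]
    partitions: PartitionMap

    def __post_init__(self) -> None:
        total = self.partitions.total_length
        for t, s in self.seqs.items():
            if len(s) != total:
                raise SeqIOError(
                    f"supermatrix: taxon {t!r} has length {len(s)}, "
                    f"partitions cover {total}"
                )

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    @property
    def length(self) -> int:
        return self.partitions.total_length


def read_fasta_alignment(path: str | Path, gene_id: str | None = None) -> GeneAlignment:
    """Read one FASTA file as a gene alignment.

    The taxon name is the header line up to the first whitespace. Raises on
    ragged rows or duplicated taxa, naming the offending file and taxon.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seqs:
            raise SeqIOError(f"{path.name}: duplicate taxon {name!r}")
        seqs[name] = str(rec.seq)
    if not seqs:
        raise SeqIOError(f"{path.name}: no FASTA records")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        by_len: dict[int, str] = {}
        for t, s in seqs.items():
            by_len.setdefault(len(s), t)
        offenders = ", ".join(f"{t} ({n} sites)" for n, t in sorted(by_len.items()))
        raise SeqIOError(f"{path.name}: ragged alignment — {offenders}")
    return GeneAlignment(gene_id=gene_id or path.stem, seqs=seqs)


def read_gene_fastas(directory: str | Path) -> list[GeneAlignment]:
    """Read every FASTA file in *directory* as one gene alignment each.

    Genes are returned sorted by file name (deterministic lexicographic
    order); the gene id is the file stem.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _FASTA_SUFFIXES
    )
    if not files:
        raise SeqIOError(f"no gene alignments found in {directory}")
    return [read_fasta_alignment(p) for p in files]


def write_fasta(aln: GeneAlignment | SuperMatrix, path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for taxon, seq in aln.seqs.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def concatenate(genes: list[GeneAlignment]) -> SuperMatrix:
    """Concatenate gene alignments into a supermatrix on the taxon union.

    A taxon absent from a gene is padded with ``'-'`` across that gene's
    columns. Partition entries follow the input gene order.
    """
    if not genes:
        raise SeqIOError("cannot concatenate an empty gene list")
    taxa: list[str] = []
    seen: set[str] = set()
    for g in genes:
        for t in g.taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for g in genes:
        parts.append((g.gene_id, pos + 1, pos + g.length))
        pad = GAP * g.length
        for t in taxa:
            chunks[t].append(g.seqs.get(t, pad))
        pos += g.length
    seqs = {t: "".join(chunks[t]) for t in taxa}
    return SuperMatrix(seqs=seqs, partitions=PartitionMap(tuple(parts)))


def split_supermatrix(matrix: SuperMatrix) -> list[GeneAlignment]:
    """Inverse of :func:`concatenate`: one gene per partition entry.

    Taxa whose slice within a gene is entirely gaps are dropped from that
    gene's alignment.
    """
    if not matrix.partitions.entries:
        raise SeqIOError("supermatrix has no partitions")
    genes: list[GeneAlignment] = []
    for gene_id, start, end in matrix.partitions.entries:
        if end > matrix.length:
            raise SeqIOError(
                f"partition {gene_id!r} = {start}-{end} exceeds matrix "
                f"length {matrix.length}"
            )
        seqs = {}
        for t, s in matrix.seqs.items():
            piece = s[start - 1 : end]
            if any(c != GAP for c in piece):
                seqs[t] = piece
        if not seqs:
            raise SeqIOError(f"partition {gene_id!r}: all-gap slice for every taxon")
        genes.append(GeneAlignment(gene_id=gene_id, seqs=seqs))
    return genes


_PARTITION_RE = re.compile(
    r"^\s*(?:(?P<model>[^,=]+)\s*,\s*)?(?P<gene>\S+)\s*=\s*(?P<start>\d+)\s*-\s*(?P<end>\d+)\s*$"
)


def read_partition_file(path: str | Path) -> PartitionMap:
    """Parse RAxML-style lines ``<model>, <gene> = <start>-<end>``.

    The leading model token is optional on read.
    """
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.strip().startswith("#"):
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise SeqIOError(f"{path}: line {lineno}: cannot parse {line!r}")
        entries.append((m["gene"], int(m["start"]), int(m["end"])))
    if not entries:
        raise SeqIOError(f"{path}: no partition entries")
    return PartitionMap(tuple(entries))


def write_partition_file(partitions: PartitionMap, path: str | Path, model: str = "DNA") -> None:
    with Path(path).open("w") as fh:
        for gene_id, start, end in partitions.entries:
            fh.write(f"{model}, {gene_id} = {start}-{end}\n")
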