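"""Reading multiple-species alignments and encoding per-base observations.

Every base of the reference genome is summarised, for each non-reference
species, as one of three observations: the species aligns with a non-indel
nucleotide matching the reference, aligns with a non-matching nucleotide, or
contributes no nucleotide at all.  The encoding uses two flags per species:
``y`` (align, 0/1) and ``z`` (match, 0/1, or 2 when undefined because the
species does not align).

Coordinates are 0-based half-open throughout, matching BED conventions.
MAF ``s``-line start fields are interpreted per the MAF standard (0-based,
strand-relative); only plus-strand reference rows are supported.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

log = logging.getLogger(__name__)

#: value of the match flag when a species contributes no nucleotide
MISSING = 2

_NUCS = np.frombuffer(b"ACGT", dtype="S1")


class MafParseError(ValueError):
    """Raised for malformed or unsupported MAF content."""


@dataclass(frozen=True)
class SpeciesSet:
    """The reference assembly plus the ordered non-reference species.

    The order of ``others`` is fixed for a dataset: observation matrices,
    binarized files and model emission parameters all use it as the species
    axis.
    """

    reference: str
    others: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "others", tuple(self.others))
        names = (self.reference, *self.others)
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique and must not repeat the reference")
        if not self.others:
            raise ValueError("at least one non-reference species is required")

    @property
    def n_others(self) -> int:
        return len(self.others)

    @property
    def n_species(self) -> int:
        """Total number of species in the alignment, reference included."""
        return len(self.others) + 1

    def index_of(self, name: str) -> int:
        return self.others.index(name)


@dataclass(frozen=True)
class GenomePartition:
    """A tiling of the reference genome into fixed-length training slices.

    Each chromosome is cut into ``slice_length`` segments (default 200 kb);
    the last slice of a chromosome may be shorter.  Slices are the unit of
    EM subsampling, decoding and the train/test split.
    """

    chromosomes: tuple[tuple[str, int], ...]
    slice_length: int = 200_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        if self.slice_length < 1:
            raise ValueError("slice_length must be positive")
        if len({c for c, _ in self.chromosomes}) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for c, n in self.chromosomes:
            if n < 1:
                raise ValueError(f"chromosome {c} has non-positive length")

    @property
    def slices(self) -> tuple[tuple[str, int, int], ...]:
        out = []
        for chrom, length in self.chromosomes:
            for start in range(0, length, self.slice_length):
                out.append((chrom, start, min(start + self.slice_length, length)))
        return tuple(out)

    def chrom_length(self, chrom: str) -> int:
        for c, n in self.chromosomes:
            if c == chrom:
                return n
        raise KeyError(chrom)

    @property
    def total_bases(self) -> int:
        return sum(n for _, n in self.chromosomes)


@dataclass(eq=False)
class ObservationMatrix:
    """Per-base, per-species align/match observations for one genome slice.

    ``y`` is a ``T x (N-1)`` 0/1 array of align flags; ``z`` is the matching
    match-flag array with ``MISSING`` (2) wherever ``y`` is 0.
    """

    chrom: str
    start: int
    end: int
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.ascontiguousarray(self.y, dtype=np.uint8)
        self.z = np.ascontiguousarray(self.z, dtype=np.uint8)
        if self.y.shape != self.z.shape or self.y.ndim != 2:
            raise ValueError("y and z must be 2-D arrays of identical shape")
        if self.y.shape[0] != self.end - self.start:
            raise ValueError("number of rows must equal slice length")
        if np.any((self.z == MISSING) != (self.y == 0)):
            raise ValueError("z must be MISSING exactly where y == 0")

    @property
    def n_positions(self) -> int:
        return self.y.shape[0]

    @property
    def n_others(self) -> int:
        return self.y.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationMatrix):
            return NotImplemented
        return (
            (self.chrom, self.start, self.end) == (other.chrom, other.start, other.end)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.z, other.z)
        )


@dataclass(frozen=True)
class RefBlock:
    """One MAF block projected onto reference coordinates.

    ``ref`` holds the reference nucleotides with alignment gaps removed, so
    position ``i`` of every row corresponds to reference base ``start + i``.
    ``rows`` maps each declared non-reference species present in the block to
    a string of the same length, with ``'-'`` where the species contributes
    no nucleotide at that reference position.
    """

    chrom: str
    start: int
    ref: str
    rows: dict[str, str] = field(default_factory=dict)
    chrom_size: int | None = None  # srcSize of the reference row

    @property
    def end(self) -> int:
        return self.start + len(self.ref)


def _open_maf(source: str | IO) -> IO[str]:
    if isinstance(source, (str, bytes)):
        name = source if isinstance(source, str) else source.decode()
        if name.endswith(".gz"):
            return gzip.open(name, "rt")
        return open(name, "rt")
    if isinstance(source, io.TextIOBase):
        return source
    return io.TextIOWrapper(source)  # binary handle


def _split_src(src: str) -> tuple[str, str]:
    """Split a MAF ``src`` field into (assembly, sequence-name)."""
    assembly, _, seqname = src.partition(".")
    return assembly, seqname


def parse_maf(source: str | IO | Iterable[str], species: SpeciesSet) -> Iterator[RefBlock]:
    """Parse MAF text into reference-projected blocks.

    Yields one :class:`RefBlock` per alignment block.  The first ``s`` line
    of each block must be the reference assembly on the '+' strand; reference
    gap columns are dropped (they define no reference position).  Rows for
    species not listed in ``species`` are ignored, as are ``a``/``e``/``i``/
    ``q`` and comment lines.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        handle: Iterable[str] = _open_maf(source)  # type: ignore[arg-type]
    else:
        handle = source

    block_rows: list[tuple[int, str, int, int, str, int, str]] = []

    def finish() -> RefBlock | None:
        if not block_rows:
            return None
        lineno, src, start, size, strand, srcsize, text = block_rows[0]
        assembly, seqname = _split_src(src)
        if assembly != species.reference:
            raise MafParseError(
                f"line {lineno}: first 's' row of block is {assembly!r}, expected "
                f"reference {species.reference!r}"
            )
        if strand != "+":
            raise MafParseError(f"line {lineno}: reference row on '-' strand is not supported")
        ref_arr = np.frombuffer(text.encode("ascii"), dtype="S1")
        keep = ref_arr != b"-"
        if int(keep.sum()) != size:
            raise MafParseError(f"line {lineno}: 's' line size field disagrees with sequence text")
        rows: dict[str, str] = {}
        for lineno2, src2, _s2, size2, _st2, _sz2, text2 in block_rows[1:]:
            assembly2, _ = _split_src(src2)
            if assembly2 not in species.others:
                continue
            arr = np.frombuffer(text2.encode("ascii"), dtype="S1")
            if arr.shape != ref_arr.shape:
                raise MafParseError(f"line {lineno2}: row length differs from reference row")
            if int((arr != b"-").sum()) != size2:
                raise MafParseError(f"line {lineno2}: 's' line size field disagrees with sequence text")
            if assembly2 in rows:
                log.warning("species %s listed twice in one block; first row wins", assembly2)
                continue
            rows[assembly2] = arr[keep].tobytes().decode("ascii")
        return RefBlock(chrom=seqname, start=start, ref=ref_arr[keep].tobytes().decode("ascii"),
                        rows=rows, chrom_size=srcsize)

    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            blk = finish()
            block_rows.clear()
            if blk is not None:
                yield blk
            continue
        if line.startswith(("#", "a ", "a\t")) or line == "a":
            blk = finish()
            block_rows.clear()
            if blk is not None:
                yield blk
            continue
        if line.startswith(("e ", "i ", "q ", "e\t", "i\t", "q\t")):
            continue
        if line.startswith(("s ", "s\t")):
            parts = line.split()
            if len(parts) != 7:
                raise MafParseError(f"line {lineno}: malformed 's' line (expected 7 fields, got {len(parts)})")
            _, src, start_s, size_s, strand, srcsize_s, text = parts
            try:
                start, size, srcsize = int(start_s), int(size_s), int(srcsize_s)
            except ValueError as exc:
                raise MafParseError(f"line {lineno}: malformed 's' line: non-integer start/size") from exc
            if strand not in "+-":
                raise MafParseError(f"line {lineno}: malformed 's' line: bad strand {strand!r}")
            block_rows.append((lineno, src, start, size, strand, srcsize, text))
            continue
        # other line types are not part of the supported dialect; ignore
    blk = finish()
    if blk is not None:
        yield blk


def encode_observations(
    blocks: Iterable[RefBlock],
    species: SpeciesSet,
    chrom: str,
    start: int,
    end: int,
    chrom_length: int | None = None,
) -> ObservationMatrix:
    """Encode projected blocks into the (y, z) observation matrix of a slice.

    Positions covered by no block are all-unaligned (``y=0``, ``z=MISSING``).
    Only A/C/G/T (case-insensitive) count as aligned nucleotides; ``N`` and
    other ambiguity codes carry no match information and are treated as not
    aligned.  If two blocks cover the same (position, species) pair, the
    first block in file order wins and a warning is logged.
    """
    if start < 0 or end <= start:
        raise ValueError(f"invalid slice [{start}, {end})")
    if chrom_length is not None and end > chrom_length:
        raise ValueError(f"slice [{start}, {end}) outside chromosome {chrom} of length {chrom_length}")
    T, J = end - start, species.n_others
    y = np.zeros((T, J), dtype=np.uint8)
    z = np.full((T, J), MISSING, dtype=np.uint8)
    covered = np.zeros((T, J), dtype=bool)

    for block in blocks:
        if block.chrom != chrom:
            continue
        lo, hi = max(start, block.start), min(end, block.end)
        if lo >= hi:
            continue
        b0, b1 = lo - block.start, hi - block.start
        ref = np.frombuffer(block.ref.upper().encode("ascii"), dtype="S1")[b0:b1]
        rows = slice(lo - start, hi - start)
        for name, text in block.rows.items():
            j = species.index_of(name)
            chars = np.frombuffer(text.upper().encode("ascii"), dtype="S1")[b0:b1]
            fresh = ~covered[rows, j]
            if not fresh.all():
                log.warning(
                    "block at %s:%d-%d re-covers %d position(s) for %s; first block wins",
                    chrom, block.start, block.end, int((~fresh).sum()), name,
                )
            aligned = np.isin(chars, _NUCS) & fresh
            yj = y[:, j]
            zj = z[:, j]
            idx = np.arange(rows.start, rows.stop)
            yj[idx[aligned]] = 1
            zj[idx[aligned]] = (chars[aligned] == ref[aligned]).astype(np.uint8)
            covered[rows, j] |= fresh
    return ObservationMatrix(chrom=chrom, start=start, end=end, y=y, z=z)


# ---------------------------------------------------------------------------
# Binarized slice files
# ---------------------------------------------------------------------------
#
# Plain-text TSV with a two-line header:
#   <genome>\t<chrom>.<start>.<end>
#   <sp1>_aligned\t<sp1>_matched\t<sp2>_aligned\t...
# followed by one row per base with interleaved align (0/1) and match
# (0/1/2) columns; 2 marks the missing match flag of an unaligned species.


def write_binarized(obs: ObservationMatrix, species: SpeciesSet, genome: str | None = None) -> str:
    """Serialise an observation matrix to the binarized slice format."""
    genome = genome if genome is not None else species.reference
    header1 = f"{genome}\t{obs.chrom}.{obs.start}.{obs.end}"
    header2 = "\t".join(f"{sp}_{kind}" for sp in species.others for kind in ("aligned", "matched"))
    data = np.empty((obs.n_positions, 2 * obs.n_others), dtype=np.uint8)
    data[:, 0::2] = obs.y
    data[:, 1::2] = obs.z
    body = "\n".join("\t".join(str(v) for v in row) for row in data)
    return f"{header1}\n{header2}\n{body}\n"


def read_binarized(text: str | IO[str], species: SpeciesSet | None = None) -> tuple[str, ObservationMatrix]:
    """Parse a binarized slice file; returns ``(genome, observations)``.

    If ``species`` is given, the file's column header must list exactly that
    species order.
    """
    if hasattr(text, "read"):
        text = text.read()  # type: ignore[union-attr]
    lines = text.splitlines()
    if len(lines) < 2:
        raise ValueError("binarized file must have a two-line header")
    genome, _, ident = lines[0].partition("\t")
    try:
        chrom, start_s, end_s = ident.rsplit(".", 2)
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"malformed slice identifier {ident!r}") from exc
    cols = lines[1].split("\t")
    if len(cols) % 2:
        raise ValueError("odd number of data columns")
    file_species = tuple(c[: -len("_aligned")] for c in cols[0::2])
    for a_col, m_col, sp in zip(cols[0::2], cols[1::2], file_species):
        if a_col != f"{sp}_aligned" or m_col != f"{sp}_matched":
            raise ValueError(f"malformed column header pair ({a_col!r}, {m_col!r})")
    if species is not None and file_species != species.others:
        raise ValueError(
            f"species mismatch: file lists {file_species}, expected {species.others}"
        )
    data = np.loadtxt(io.StringIO("\n".join(lines[2:])), dtype=np.uint8, ndmin=2)
    if data.shape != (end - start, 2 * len(file_species)):
        raise ValueError("data block shape disagrees with header")
    return genome, ObservationMatrix(chrom=chrom, start=start, end=end, y=data[:, 0::2], z=data[:, 1::2])


def binarized_filename(genome: str, chrom: str, start: int, end: int) -> str:
    return f"{genome}_{chrom}.{start}.{end}_binary.txt"
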