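"""Locus model: exon annotations, splice junctions, and junction probes.

A locus is a single plus-strand nucleotide sequence carrying an ordered set
of non-overlapping exons (0-based, half-open coordinates). Splice junctions
are ordered exon pairs: *forward* junctions join a donor exon to a
downstream acceptor (linear splicing, including exon skipping), while
*back-splice* junctions join a donor to an acceptor at or upstream of it,
producing a circular RNA. A junction is identified in reads by its *probe*:
the last F bases of the donor exon followed by the first F bases of the
acceptor exon (F = 10 by default), so a read supports the junction iff it
contains the 2F-mer, up to a configured mismatch allowance.

Exon labels are free-form strings; unannotated exons discovered inside
introns (the "3*"-style cryptic exon) carry ``annotated=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FORWARD = "forward"
BACKSPLICE = "backsplice"
LINEAR = "linear"
CIRCULAR = "circular"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ExonAnnotation:
    """One exon interval on the locus (0-based, half-open)."""

    exon_id: str
    start: int
    end: int
    annotated: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"exon {self.exon_id!r}: start must precede end "
                f"({self.start} >= {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Junction:
    """An ordered (donor, acceptor) exon pair with a splice topology."""

    donor_exon: str
    acceptor_exon: str
    topology: str  # FORWARD or BACKSPLICE

    def __post_init__(self) -> None:
        if self.topology not in (FORWARD, BACKSPLICE):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def name(self) -> str:
        return f"{self.donor_exon}-{self.acceptor_exon}"


@dataclass(frozen=True)
class JunctionProbe:
    """The 2F-mer identifying one junction in reads.

    ``donor_flank`` is the last F bases of the donor exon and
    ``acceptor_flank`` the first F bases of the acceptor exon; the probe
    string is their concatenation and spans the splice point (for
    back-splice junctions, the circularisation point).
    """

    junction: Junction
    donor_flank: str
    acceptor_flank: str

    def __post_init__(self) -> None:
        if len(self.donor_flank) != len(self.acceptor_flank):
            raise ValueError("donor and acceptor flanks must have equal length")

    @property
    def flank(self) -> int:
        return len(self.donor_flank)

    @property
    def probe(self) -> str:
        return self.donor_flank + self.acceptor_flank

    @property
    def name(self) -> str:
        return self.junction.name


@dataclass(frozen=True)
class IsoformDefinition:
    """An exon path plus topology; circular paths close back to their head."""

    name: str
    exon_path: tuple[str, ...]
    topology: str  # LINEAR or CIRCULAR

    def __post_init__(self) -> None:
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown isoform topology {self.topology!r}")
        if not self.exon_path:
            raise ValueError("empty exon path")
        object.__setattr__(self, "exon_path", tuple(self.exon_path))

    def junctions(self) -> list[Junction]:
        """All junctions along the path, including the closing back-splice."""
        out = [
            Junction(d, a, FORWARD)
            for d, a in zip(self.exon_path, self.exon_path[1:])
        ]
        if self.topology == CIRCULAR:
            out.append(Junction(self.exon_path[-1], self.exon_path[0], BACKSPLICE))
        return out


@dataclass
class LocusModel:
    """Plus-strand sequence of one cloned locus plus its ordered exons."""

    sequence: str
    exons: list[ExonAnnotation]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand == "-":
            # normalise to the plus strand at load time
            n = len(self.sequence)
            self.sequence = reverse_complement(self.sequence)
            self.exons = [
                replace(e, start=n - e.end, end=n - e.start) for e in self.exons
            ]
            self.strand = "+"
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self._validate()
        self._by_id = {e.exon_id: e for e in self.exons}

    def _validate(self) -> None:
        n = len(self.sequence)
        prev_end = 0
        seen: set[str] = set()
        for e in self.exons:
            if e.exon_id in seen:
                raise ValueError(f"duplicate exon id {e.exon_id!r}")
            seen.add(e.exon_id)
            if e.start < prev_end:
                raise ValueError(f"exon {e.exon_id!r} overlaps its predecessor")
            if e.end > n:
                raise ValueError(f"exon {e.exon_id!r} extends past the sequence")
            prev_end = e.end

    def exon(self, exon_id: str) -> ExonAnnotation:
        try:
            return self._by_id[exon_id]
        except KeyError:
            raise KeyError(f"unknown exon id {exon_id!r}") from None

    def exon_sequence(self, exon_id: str) -> str:
        e = self.exon(exon_id)
        return self.sequence[e.start : e.end]

    def introns(self) -> list[tuple[int, int]]:
        """Complementary intervals between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append((a.end, b.start))
        return out


def enumerate_junctions(
    locus: LocusModel,
    topologies: set[str] | frozenset[str] = frozenset({FORWARD, BACKSPLICE}),
    include_self: bool = True,
) -> list[Junction]:
    """Enumerate every candidate junction of the requested topologies.

    Forward junctions are all ordered exon pairs with the donor strictly
    upstream of the acceptor; back-splice junctions have the donor at or
    downstream of the acceptor (``include_self=False`` drops donor==acceptor
    self-circles, which are enumerable but never observed in practice).
    Output order is deterministic: donor-major in genomic order.
    """
    if not locus.exons:
        raise ValueError("locus has no exons; cannot enumerate junctions")
    bad = set(topologies) - {FORWARD, BACKSPLICE}
    if bad:
        raise ValueError(f"unknown topologies: {sorted(bad)}")
    ids = [e.exon_id for e in locus.exons]
    index = {x: i for i, x in enumerate(ids)}
    out: list[Junction] = []
    for d in ids:
        for a in ids:
            if FORWARD in topologies and index[d] < index[a]:
                out.append(Junction(d, a, FORWARD))
            if BACKSPLICE in topologies and index[d] >= index[a]:
                if include_self or d != a:
                    out.append(Junction(d, a, BACKSPLICE))
    return out


def build_probe(locus: LocusModel, junction: Junction, flank: int = 10) -> JunctionProbe:
    """Build the junction probe: F-base donor suffix + F-base acceptor prefix."""
    donor = locus.exon(junction.donor_exon)
    acceptor = locus.exon(junction.acceptor_exon)
    for e in (donor, acceptor):
        if e.length < flank:
            raise ValueError(
                f"exon {e.exon_id!r} is shorter ({e.length}) than the probe flank {flank}"
            )
    return JunctionProbe(
        junction=junction,
        donor_flank=locus.sequence[donor.end - flank : donor.end],
        acceptor_flank=locus.sequence[acceptor.start : acceptor.start + flank],
    )


def isoform_sequence(locus: LocusModel, isoform: IsoformDefinition) -> str:
    """Mature-transcript sequence of an isoform.

    Circular isoforms are returned linearised with the origin at the first
    exon of the path, i.e. the closing back-splice junction sits at the
    string's wrap point; callers treating the product as circular must use
    rotation-invariant matching (see :func:`rotations_equal`).
    """
    return "".join(locus.exon_sequence(x) for x in isoform.exon_path)


def rotations_equal(a: str, b: str) -> bool:
    """True iff the two strings are rotations of one another."""
    return len(a) == len(b) and b in a + a


# ---------------------------------------------------------------------------
# I/O: FASTA sequence + 4-column BED-like exon table
# ---------------------------------------------------------------------------

EXON_TABLE_HEADER = ["exon_id", "start", "end", "annotated"]


def read_exon_table(path: str | Path) -> list[ExonAnnotation]:
    """Read a 4-column TSV (exon_id, start, end, annotated); 0-based half-open."""
    exons = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "exon_id":
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}: line {i + 1}: expected 4 columns")
            exons.append(
                ExonAnnotation(
                    exon_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    annotated=parts[3].lower() in ("1", "true", "yes"),
                )
            )
    return exons


def write_exon_table(exons: list[ExonAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EXON_TABLE_HEADER) + "\n")
        for e in exons:
            fh.write(f"{e.exon_id}\t{e.start}\t{e.end}\t{str(e.annotated).lower()}\n")


def read_locus(fasta: str | Path, exon_table: str | Path, strand: str = "+") -> LocusModel:
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta}: expected exactly one sequence, found {len(records)}")
    return LocusModel(
        sequence=str(records[0].seq).upper(),
        exons=read_exon_table(exon_table),
        strand=strand,
    )


def write_locus(locus: LocusModel, fasta: str | Path, exon_table: str | Path,
                name: str = "locus") -> None:
    SeqIO.write([SeqRecord(Seq(locus.sequence), id=name, description="")],
                str(fasta), "fasta")
    write_exon_table(locus.exons, exon_table)
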