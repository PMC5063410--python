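"""Synthetic stand-in for the cloned ASXL1-like locus.

The study's cloned construct was never deposited, so the package ships a
synthetic locus: a seeded random sequence with five exons laid out like the
region under study — exons 1..4 plus an unannotated cryptic exon ("3*")
inside intron 3. Exon sizes are chosen so that on 2x150 amplicon reads the
5' junctions (donor exon 1) fall inside mate 1 and the 3' junctions (donor
exon 2) inside mate 2, and so that the exon 2+3 circle (140 nt) is shorter
than a read, mirroring the geometry the published assays rely on. All
downstream code treats this locus like any loaded FASTA + exon table.
"""

from __future__ import annotations

import numpy as np

from . import primers
from .locus import (
    CIRCULAR,
    LINEAR,
    IsoformDefinition,
    ExonAnnotation,
    Junction,
    JunctionProbe,
    LocusModel,
    build_probe,
    reverse_complement,
)

#: (exon_id, start, end, annotated): 0-based half-open on a 950 nt locus
EXON_LAYOUT: tuple[tuple[str, int, int, bool], ...] = (
    ("1", 100, 160, True),
    ("2", 300, 400, True),
    ("3", 520, 560, True),
    ("3*", 650, 690, False),
    ("4", 800, 836, True),
)

LOCUS_LENGTH = 950
DEFAULT_SEED = 20160914


def _all_primers() -> list[str]:
    out = list(primers.SC_FORWARD_PRIMERS.values()) + list(primers.RT_PRIMERS.values())
    for seqs in primers.BULK_PRIMER_SET.values():
        out.extend(seqs)
    out += [primers.FORWARD_COMMON_TAG, primers.REVERSE_COMMON_TAG,
            primers.CLONTECH_IIA, primers.NEXTERA_READ2]
    return out


def _is_clean(seq: str, flank: int = 10) -> bool:
    """No primer collisions and all junction probes unique at the given flank."""
    both = seq + "#" + reverse_complement(seq)
    for p in _all_primers():
        if p in both:
            return False
    locus = LocusModel(sequence=seq,
                       exons=[ExonAnnotation(*e) for e in EXON_LAYOUT])
    from .locus import enumerate_junctions  # local to avoid cycle at import

    probes = [build_probe(locus, j, flank) for j in enumerate_junctions(locus)]
    strings = {p.probe for p in probes} | {reverse_complement(p.probe) for p in probes}
    return len(strings) == 2 * len(probes)


def synthetic_locus(seed: int = DEFAULT_SEED) -> LocusModel:
    """Deterministically generate the synthetic locus.

    The sequence is uniform random DNA regenerated (with an incremented
    stream) until no assay primer occurs in it and every junction probe is
    unique — the same well-posedness the real construct satisfies.
    """
    for attempt in range(64):
        rng = np.random.default_rng((seed, attempt))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, LOCUS_LENGTH)])
        if _is_clean(seq):
            return LocusModel(sequence=seq,
                              exons=[ExonAnnotation(*e) for e in EXON_LAYOUT])
    raise RuntimeError("could not generate a collision-free synthetic locus")


#: the isoforms the study detects, keyed by the name used in mixtures
DEFAULT_ISOFORMS: dict[str, IsoformDefinition] = {
    "canonical": IsoformDefinition("canonical", ("1", "2", "3", "4"), LINEAR),
    "skip-1-3*": IsoformDefinition("skip-1-3*", ("1", "3*", "4"), LINEAR),
    "skip-1-4": IsoformDefinition("skip-1-4", ("1", "4"), LINEAR),
    "skip-2-4": IsoformDefinition("skip-2-4", ("1", "2", "4"), LINEAR),
    "skip-2-3*": IsoformDefinition("skip-2-3*", ("1", "2", "3*", "4"), LINEAR),
    "circle-3-2": IsoformDefinition("circle-3-2", ("2", "3"), CIRCULAR),
    "circle-3*-2": IsoformDefinition("circle-3*-2", ("2", "3", "3*"), CIRCULAR),
}


def isoform_channel(isoform: IsoformDefinition) -> str:
    return primers.CIRCULAR if isoform.topology == CIRCULAR else primers.LINEAR


def _probes(locus: LocusModel, pairs: list[tuple[str, str, str]],
            flank: int) -> list[JunctionProbe]:
    return [build_probe(locus, Junction(d, a, t), flank) for d, a, t in pairs]


def five_prime_probes(locus: LocusModel, flank: int = 10) -> list[JunctionProbe]:
    """Probes for the donor-exon-1 junctions visible on mate 1."""
    from .locus import FORWARD

    return _probes(locus, [("1", "2", FORWARD), ("1", "3*", FORWARD),
                           ("1", "4", FORWARD)], flank)


def three_prime_probes(locus: LocusModel, flank: int = 10) -> list[JunctionProbe]:
    """Probes for the donor-exon-2 junctions visible on mate 2."""
    from .locus import FORWARD

    return _probes(locus, [("2", "3", FORWARD), ("2", "4", FORWARD),
                           ("2", "3*", FORWARD)], flank)


def backsplice_probes(locus: LocusModel, flank: int = 10) -> list[JunctionProbe]:
    """Probes for the observed circularisation junctions."""
    from .locus import BACKSPLICE

    return _probes(locus, [("3", "2", BACKSPLICE), ("3*", "2", BACKSPLICE)], flank)
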