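"""Synthetic read-pair generator with ground truth.

Emulates the two targeted libraries of the study:

* **bulk amplicons** — 2x150 paired reads of channel-specific PCR products
  (common tag + primer + spliced template), drawn multinomially from a
  configurable isoform mixture with iid per-base substitution errors;
* **single-cell UMI libraries** — per-cell molecule counts drawn from a
  count distribution, each molecule tagged with a random 8-nt UMI and
  amplified to several read pairs whose read 2 carries the published
  layout (Clontech IIA tag, Nextera read-2 sequence, 4-nt channel filler,
  UMI, channel RT primer).

Two artifact classes the published filters remove are injected with truth
labels: *RT chimeras* (mate 1 from one channel paired with a read-2
architecture of the other) and *rolling-circle* reads (extra read pairs
from a tandem-duplicated circle template, inflating read-based but not
UMI-based circRNA counts).

Every emitted pair has exactly one row in the ground-truth table; per-cell
true molecule counts are the distinct (cell, isoform, UMI) triples among
non-chimeric reads. For a fixed seed the output is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import primers
from .fastq import ReadPair
from .locus import CIRCULAR, IsoformDefinition, LocusModel, isoform_sequence, reverse_complement
from .synthetic_reference import DEFAULT_ISOFORMS, isoform_channel

# ---------------------------------------------------------------------------
# Study conditions: the published junction mixture and per-cell means
# ---------------------------------------------------------------------------

#: fraction of exon1->exon4 amplicon reads skipping straight to the cryptic exon
SKIP_1_3STAR_FRACTION = 0.232
#: fraction skipping exons 2, 3 and the cryptic exon entirely (1-4 product)
SKIP_1_4_FRACTION = 0.057
#: of products with a 1-2 junction, fraction carrying 2-4 on the 3' end
CONDITIONAL_2_4 = 0.129
#: of products with a 1-2 junction, fraction carrying 2-3* on the 3' end
CONDITIONAL_2_3STAR = 0.047

_rest = 1.0 - SKIP_1_3STAR_FRACTION - SKIP_1_4_FRACTION
#: bulk linear-channel isoform mixture at the reported study proportions
BULK_TRUE_MIXTURE: dict[str, float] = {
    "skip-1-3*": SKIP_1_3STAR_FRACTION,
    "skip-1-4": SKIP_1_4_FRACTION,
    "canonical": _rest * (1.0 - CONDITIONAL_2_4 - CONDITIONAL_2_3STAR),
    "skip-2-4": _rest * CONDITIONAL_2_4,
    "skip-2-3*": _rest * CONDITIONAL_2_3STAR,
}

#: reported absolute per-cell molecule means (UMI-based)
LINEAR_MEAN_MOLECULES = 64.0
CIRCULAR_MEAN_MOLECULES = 11.0


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    isoform_mixture: dict[str, float] | None = None      # bulk
    n_reads: int = 0                                     # bulk
    n_cells: int = 0                                     # single-cell
    molecule_means: dict[str, float] | None = None       # sc: isoform -> mean
    molecule_family: str = "poisson"                     # "poisson" | "fixed"
    umi_length: int = 8
    reads_per_molecule: tuple[int, int] = (3, 30)
    substitution_rate: float = 0.002
    chimera_rate: float = 0.0
    rolling_circle_rate: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isoform_mixture is not None:
            total = sum(self.isoform_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"isoform mixture sums to {total}, not 1")
            if any(f < 0 for f in self.isoform_mixture.values()):
                raise ValueError("mixture fractions must be non-negative")
        for name in ("substitution_rate", "chimera_rate", "rolling_circle_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        lo, hi = self.reads_per_molecule
        if lo < 1 or hi < lo:
            raise ValueError("reads_per_molecule must be a (lo, hi) range with lo >= 1")
        if self.molecule_family not in ("poisson", "fixed"):
            raise ValueError(f"unknown molecule_family {self.molecule_family!r}")


def bulk_study_config(n_reads: int = 100_000, seed: int = 0, **overrides) -> SimulationConfig:
    """Bulk configuration at the published mixture proportions."""
    kw = dict(isoform_mixture=dict(BULK_TRUE_MIXTURE), n_reads=n_reads, seed=seed)
    kw.update(overrides)
    return SimulationConfig(**kw)


def single_cell_study_config(n_cells: int = 50, seed: int = 0, **overrides) -> SimulationConfig:
    """Single-cell configuration at the published per-cell molecule means."""
    kw = dict(
        n_cells=n_cells,
        molecule_means={"canonical": LINEAR_MEAN_MOLECULES,
                        "circle-3-2": CIRCULAR_MEAN_MOLECULES},
        chimera_rate=0.05,
        rolling_circle_rate=0.10,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class GroundTruth:
    """Per-read truth rows plus (for single-cell runs) per-cell molecule counts."""

    reads: pd.DataFrame
    cells: pd.DataFrame | None = None


READ_COLUMNS = ["name", "cell_id", "isoform", "channel", "umi", "artifact"]

# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


def _template(locus: LocusModel, isoform: IsoformDefinition, doubled: bool = False) -> str:
    """Mature template; circles are rotated so the back-splice donor leads."""
    if isoform.topology == CIRCULAR:
        path = isoform.exon_path[-1:] + isoform.exon_path[:-1]
        seq = "".join(locus.exon_sequence(x) for x in path)
        return seq * 2 if doubled else seq
    if doubled:
        raise ValueError("rolling-circle templates require a circular isoform")
    return isoform_sequence(locus, isoform)


_BULK_FORWARD = {primers.LINEAR: primers.SHORT_F, primers.CIRCULAR: primers.CIRCLE_F}
_BULK_REVERSE = {primers.LINEAR: primers.SHORT_R, primers.CIRCULAR: primers.CIRCLE_R}


def bulk_amplicon(locus: LocusModel, isoform: IsoformDefinition,
                  doubled: bool = False) -> str:
    """Tagged bulk PCR product: common tag + primer + template + rc(primer+tag)."""
    ch = isoform_channel(isoform)
    return (primers.FORWARD_COMMON_TAG + _BULK_FORWARD[ch]
            + _template(locus, isoform, doubled)
            + reverse_complement(_BULK_REVERSE[ch])
            + reverse_complement(primers.REVERSE_COMMON_TAG))


def sc_read_templates(locus: LocusModel, isoform: IsoformDefinition, umi: str,
                      read_length: int = 150, doubled: bool = False) -> tuple[str, str]:
    """(read 1, read 2) templates for one single-cell molecule.

    Read 1: Nextera read-1 tag + channel forward primer + template.
    Read 2: Clontech IIA + Nextera read-2 + filler + UMI + RT primer + rc(template).
    """
    ch = isoform_channel(isoform)
    t = _template(locus, isoform, doubled)
    full = (primers.FORWARD_COMMON_TAG + primers.SC_FORWARD_PRIMERS[ch] + t
            + reverse_complement(primers.RT_PRIMERS[ch])
            + reverse_complement(umi)
            + reverse_complement(primers.FILLERS[ch])
            + reverse_complement(primers.NEXTERA_READ2)
            + reverse_complement(primers.CLONTECH_IIA))
    return full[:read_length], reverse_complement(full)[:read_length]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Apply iid substitutions; unchanged object when no error lands."""
    if rate <= 0.0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for p, r in zip(pos, rng.integers(0, 3, size=k)):
        chars[p] = _OTHER[chars[p]][r]
    return "".join(chars)


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# Bulk simulation
# ---------------------------------------------------------------------------

def simulate_bulk_amplicons(
    locus: LocusModel,
    config: SimulationConfig,
    isoforms: dict[str, IsoformDefinition] | None = None,
) -> tuple[list[ReadPair], GroundTruth]:
    """Simulate a bulk amplicon library from the configured isoform mixture."""
    if config.isoform_mixture is None or config.n_reads <= 0:
        raise ValueError("bulk simulation needs isoform_mixture and n_reads > 0")
    isoforms = isoforms if isoforms is not None else DEFAULT_ISOFORMS
    unknown = set(config.isoform_mixture) - set(isoforms)
    if unknown:
        raise ValueError(f"mixture references unknown isoforms: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    names = sorted(config.isoform_mixture)
    fracs = np.array([config.isoform_mixture[n] for n in names])
    counts = rng.multinomial(config.n_reads, fracs / fracs.sum())

    L = config.read_length
    pairs: list[ReadPair] = []
    truth_rows: list[tuple] = []
    serial = 0
    for name, n in zip(names, counts):
        iso = isoforms[name]
        ch = isoform_channel(iso)
        amp = bulk_amplicon(locus, iso)
        r1_t, r2_t = amp[:L], reverse_complement(amp)[:L]
        doubled_t = None
        if iso.topology == CIRCULAR and config.rolling_circle_rate > 0:
            amp2 = bulk_amplicon(locus, iso, doubled=True)
            doubled_t = (amp2[:L], reverse_complement(amp2)[:L])
        for _ in range(n):
            artifact = "clean"
            t1, t2 = r1_t, r2_t
            if doubled_t is not None and rng.random() < config.rolling_circle_rate:
                artifact = "rolling_circle"
                t1, t2 = doubled_t
            if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
                # mate 2 taken from a product of the opposite channel
                other = "circle-3-2" if ch == primers.LINEAR else "canonical"
                amp_o = bulk_amplicon(locus, isoforms[other])
                t2 = reverse_complement(amp_o)[:L]
                artifact = "chimera"
            rid = f"bulk:{serial:06d}"
            serial += 1
            pairs.append(ReadPair(
                name=rid,
                seq1=_mutate(t1, rng, config.substitution_rate),
                seq2=_mutate(t2, rng, config.substitution_rate),
            ))
            truth_rows.append((rid, None, name, ch, None, artifact))

    truth = pd.DataFrame(truth_rows, columns=READ_COLUMNS)
    # emit in a seeded shuffle so channel/isoform blocks are interleaved
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    truth = truth.iloc[order].reset_index(drop=True)
    return pairs, GroundTruth(reads=truth)


def simulate_plasmid_amplicons(
    locus: LocusModel, config: SimulationConfig
) -> tuple[list[ReadPair], GroundTruth]:
    """Control library from the unspliced construct: contiguous genomic slices
    around exons 2 and 3 amplified with the plasmid primer pairs."""
    if config.n_reads <= 0:
        raise ValueError("plasmid simulation needs n_reads > 0")
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    slices = {}
    for label, exon_id, (pf, pr) in (
        ("plasmid-e2", "2", (primers.PLASMID_E2_F, primers.PLASMID_E2_R)),
        ("plasmid-e3", "3", (primers.PLASMID_E3_F, primers.PLASMID_E3_R)),
    ):
        e = locus.exon(exon_id)
        t = locus.sequence[max(0, e.start - 50): min(len(locus.sequence), e.end + 50)]
        amp = (primers.FORWARD_COMMON_TAG + pf + t + reverse_complement(pr)
               + reverse_complement(primers.REVERSE_COMMON_TAG))
        slices[label] = (amp[:L], reverse_complement(amp)[:L])
    labels = sorted(slices)
    pairs, rows = [], []
    for i in range(config.n_reads):
        label = labels[int(rng.integers(0, len(labels)))]
        t1, t2 = slices[label]
        rid = f"plasmid:{i:06d}"
        pairs.append(ReadPair(
            name=rid,
            seq1=_mutate(t1, rng, config.substitution_rate),
            seq2=_mutate(t2, rng, config.substitution_rate),
        ))
        rows.append((rid, None, label, primers.PLASMID_CONTROL, None, "clean"))
    return pairs, GroundTruth(reads=pd.DataFrame(rows, columns=READ_COLUMNS))


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------

def simulate_single_cell_reads(
    locus: LocusModel,
    config: SimulationConfig,
    isoforms: dict[str, IsoformDefinition] | None = None,
) -> tuple[list[ReadPair], GroundTruth]:
    """Simulate per-cell UMI-tagged libraries.

    For each cell and isoform, a molecule count is drawn from the configured
    family; each molecule gets a uniform random UMI and ``reads_per_molecule``
    read pairs. Circular molecules additionally emit rolling-circle read
    pairs (binomial in the molecule's read count) and any emitted pair may be
    converted to an RT chimera at ``chimera_rate``.
    """
    if config.n_cells <= 0:
        raise ValueError("single-cell simulation needs n_cells > 0")
    if not config.molecule_means:
        raise ValueError("single-cell simulation needs molecule_means")
    isoforms = isoforms if isoforms is not None else DEFAULT_ISOFORMS
    unknown = set(config.molecule_means) - set(isoforms)
    if unknown:
        raise ValueError(f"molecule_means references unknown isoforms: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.reads_per_molecule
    pairs: list[ReadPair] = []
    rows: list[tuple] = []
    serial = 0

    # pre-build the error-free chimera read-2 for each channel (template from
    # the first configured isoform of that channel, new UMI drawn per event)
    chan_iso: dict[str, IsoformDefinition] = {}
    for name in sorted(config.molecule_means):
        chan_iso.setdefault(isoform_channel(isoforms[name]), isoforms[name])

    def emit(cell: str, iso_name: str, iso: IsoformDefinition, umi: str,
             doubled: bool, base_artifact: str) -> None:
        nonlocal serial
        r1, r2 = sc_read_templates(locus, iso, umi, config.read_length, doubled)
        artifact = base_artifact
        if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
            ch = isoform_channel(iso)
            others = [c for c in chan_iso if c != ch]
            if others:
                o_iso = chan_iso[others[0]]
                _, r2 = sc_read_templates(locus, o_iso,
                                          _random_umi(rng, config.umi_length),
                                          config.read_length)
                artifact = "chimera"
        rid = f"{cell}:{serial:07d}"
        serial += 1
        pairs.append(ReadPair(
            name=rid,
            seq1=_mutate(r1, rng, config.substitution_rate),
            seq2=_mutate(r2, rng, config.substitution_rate),
            cell_id=cell,
        ))
        rows.append((rid, cell, iso_name, isoform_channel(iso), umi, artifact))

    for c in range(config.n_cells):
        cell = f"cell{c:03d}"
        for iso_name in sorted(config.molecule_means):
            iso = isoforms[iso_name]
            mean = config.molecule_means[iso_name]
            if config.molecule_family == "poisson":
                m = int(rng.poisson(mean))
            else:
                m = int(round(mean))
            for _ in range(m):
                umi = _random_umi(rng, config.umi_length)
                r = int(rng.integers(lo, hi + 1))
                for _ in range(r):
                    emit(cell, iso_name, iso, umi, False, "clean")
                if iso.topology == CIRCULAR and config.rolling_circle_rate > 0:
                    extra = rng.binomial(r, config.rolling_circle_rate)
                    for _ in range(extra):
                        emit(cell, iso_name, iso, umi, True, "rolling_circle")

    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    clean = reads[reads["artifact"] != "chimera"]
    observed = (
        clean.drop_duplicates(["cell_id", "isoform", "umi"])
        .groupby(["cell_id", "isoform"], as_index=False)
        .size()
        .rename(columns={"size": "molecules"})
    )
    # full (cell, isoform) grid so zero-molecule cells enter across-cell means
    grid = pd.MultiIndex.from_product(
        [[f"cell{c:03d}" for c in range(config.n_cells)],
         sorted(config.molecule_means)],
        names=["cell_id", "isoform"],
    ).to_frame(index=False)
    grid["channel"] = [isoform_channel(isoforms[i]) for i in grid["isoform"]]
    cells = grid.merge(observed, on=["cell_id", "isoform"], how="left")
    cells["molecules"] = cells["molecules"].fillna(0).astype(int)
    return pairs, GroundTruth(reads=reads, cells=cells)


def expected_distinct_umis(n_molecules: int, umi_length: int) -> float:
    """Birthday-problem expectation: 4^L * (1 - (1 - 4^-L)^m)."""
    space = 4.0 ** umi_length
    return space * (1.0 - (1.0 - 1.0 / space) ** n_molecules)
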