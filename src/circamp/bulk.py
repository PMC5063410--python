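"""Bulk amplicon analysis: demultiplexing, clustering, anchoring, junction
counting and paired-end conditional quantification.

The stages mirror the published bulk workflow: reads are assigned to PCR
channels by exact primer occurrence (grep semantics); assigned reads are
clustered greedily by abundance at 99% identity with a 10-mer prefilter;
clusters with >= 5 reads are anchored to the locus by maximal exact matches
(>= 18 bp, both orientations) whose discontinuities define breakpoints
reported when supported by more than 1% of channel reads; and junctions are
counted directly by matching the 2F-mer junction probes against reads with
at most one mismatch (Hamming, both orientations).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import primers
from .fastq import ReadPair
from .locus import ExonAnnotation, JunctionProbe, LocusModel, reverse_complement

AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# Primer demultiplexing
# ---------------------------------------------------------------------------

def demultiplex_by_primer(
    pairs: list[ReadPair],
    primer_set: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, list[ReadPair]]:
    """Partition read pairs by exact channel-primer occurrence.

    A pair belongs to a channel iff any of the channel's primers occurs as
    an exact substring of either mate. Pairs hitting primers of two
    different channels are flagged ``chimeric``; pairs hitting none are
    ``unassigned``.
    """
    if primer_set is None:
        primer_set = primers.BULK_PRIMER_SET
    if not primer_set or not any(primer_set.values()):
        raise ValueError("empty primer set")
    out: dict[str, list[ReadPair]] = {ch: [] for ch in primer_set}
    out["chimeric"] = []
    out[primers.UNASSIGNED] = []
    for pair in pairs:
        hits = {
            ch
            for ch, seqs in primer_set.items()
            for p in seqs
            if p in pair.seq1 or p in pair.seq2
        }
        if len(hits) == 1:
            out[hits.pop()].append(pair)
        elif len(hits) > 1:
            out["chimeric"].append(pair)
        else:
            out[primers.UNASSIGNED].append(pair)
    return out


# ---------------------------------------------------------------------------
# Greedy abundance-ordered clustering (DNAclust-style)
# ---------------------------------------------------------------------------

@dataclass
class ReadCluster:
    representative: str
    count: int
    member_names: list[str] = field(default_factory=list)


def sequence_identity(a: str, b: str) -> float:
    """1 - editdistance / max(len): the identity used for cluster membership."""
    if a == b:
        return 1.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_reads(
    seqs: list[str],
    names: list[str] | None = None,
    similarity: float = 0.99,
    kmer: int = 10,
) -> list[ReadCluster]:
    """Greedy abundance-ordered clustering at the given identity threshold.

    Unique sequences are sorted by decreasing multiplicity (ties broken
    lexicographically); the most abundant unclustered sequence seeds a
    cluster and absorbs every later unclustered sequence within the
    identity threshold of the seed. The k-mer prefilter skips candidate
    pairs sharing no exact k-mer (a heuristic that cannot reject a pair at
    >= 99% identity over read-length sequences).
    """
    if not 0.0 < similarity <= 1.0:
        raise ValueError("similarity must be in (0, 1]")
    if kmer < 1:
        raise ValueError("kmer must be >= 1")
    if names is None:
        names = [str(i) for i in range(len(seqs))]
    by_seq: dict[str, list[str]] = defaultdict(list)
    for s, n in zip(seqs, names):
        by_seq[s].append(n)
    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), s))
    clustered: set[str] = set()
    clusters: list[ReadCluster] = []
    for i, seed in enumerate(order):
        if seed in clustered:
            continue
        clustered.add(seed)
        members = list(by_seq[seed])
        seed_kmers = _kmers(seed, kmer)
        for other in order[i + 1 :]:
            if other in clustered:
                continue
            if seed_kmers.isdisjoint(_kmers(other, kmer)):
                continue
            if sequence_identity(seed, other) >= similarity:
                clustered.add(other)
                members.extend(by_seq[other])
        clusters.append(ReadCluster(representative=seed, count=len(members),
                                    member_names=members))
    return clusters


def filter_clusters(clusters: list[ReadCluster], min_reads: int = 5) -> list[ReadCluster]:
    """Keep clusters supported by at least ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [c for c in clusters if c.count >= min_reads]


# ---------------------------------------------------------------------------
# Maximal-exact-match anchoring (mummer-style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between an (oriented) query and the locus."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


def _mems(query: str, ref: str, min_len: int, strand: str) -> list[Anchor]:
    """All maximal exact matches of length >= min_len (k-mer seed + extend)."""
    k = min_len
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(ref) - k + 1):
        index[ref[j : j + k]].append(j)
    seen: set[tuple[int, int]] = set()
    out: list[Anchor] = []
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            qs, rs = i, j
            while qs > 0 and rs > 0 and query[qs - 1] == ref[rs - 1]:
                qs -= 1
                rs -= 1
            key = (qs, rs)
            if key in seen:
                continue
            seen.add(key)
            qe, re_ = i + k, j + k
            while qe < len(query) and re_ < len(ref) and query[qe] == ref[re_]:
                qe += 1
                re_ += 1
            out.append(Anchor(qs, qe, rs, re_, strand))
    return sorted(out, key=lambda a: (a.query_start, a.ref_start))


def anchor_align(
    representative: str,
    locus: LocusModel,
    min_anchor: int = 18,
    both_strands: bool = True,
) -> list[Anchor]:
    """Anchor a cluster representative on the locus by maximal exact matches.

    Minus-strand anchors carry query coordinates on the reverse-complemented
    representative, so that within one strand anchors chain left-to-right.
    """
    if min_anchor < 4:
        raise ValueError("min_anchor must be >= 4")
    anchors = _mems(representative, locus.sequence, min_anchor, "+")
    if both_strands:
        anchors += _mems(reverse_complement(representative), locus.sequence,
                         min_anchor, "-")
    return anchors


# ---------------------------------------------------------------------------
# Breakpoint calling
# ---------------------------------------------------------------------------

def _snap(pos: int, boundaries: list[int], tol: int) -> int:
    best = min(boundaries, key=lambda b: abs(b - pos), default=pos)
    return best if abs(best - pos) <= tol else pos


def call_breakpoints(
    clusters: list[ReadCluster],
    locus: LocusModel,
    channel_total: int,
    min_fraction: float = 0.01,
    min_anchor: int = 18,
    min_span: int = 25,
    snap_tol: int = 3,
) -> pd.DataFrame:
    """Call breakpoints from anchor discontinuities of cluster representatives.

    For each cluster the orientation with the larger total anchored length is
    chained by query order; a consecutive anchor pair whose reference gap
    differs from its query gap defines a breakpoint (left = donor-side
    reference end, right = acceptor-side reference start), snapped to the
    nearest exon boundary within ``snap_tol``. Support sums the read counts
    of the clusters exhibiting the breakpoint; breakpoints with fraction
    > ``min_fraction`` of the channel's reads are reported.
    """
    if channel_total <= 0:
        raise ValueError("channel read total must be positive")
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    ends = [e.end for e in locus.exons]
    starts = [e.start for e in locus.exons]
    support: dict[tuple[int, int], int] = defaultdict(int)
    for cl in clusters:
        anchors = anchor_align(cl.representative, locus, min_anchor)
        per_strand = {s: [a for a in anchors if a.strand == s] for s in "+-"}
        chain = max(per_strand.values(), key=lambda v: sum(a.length for a in v))
        if sum(a.length for a in chain) < min_span:
            continue
        chain = sorted(chain, key=lambda a: a.query_start)
        for a, b in zip(chain, chain[1:]):
            qgap = b.query_start - a.query_end
            rgap = b.ref_start - a.ref_end
            if qgap == rgap:
                continue  # collinear (same diagonal): no breakpoint
            left = _snap(a.ref_end, ends, snap_tol)
            right = _snap(b.ref_start, starts, snap_tol)
            support[(left, right)] += cl.count
    rows = [
        {
            "left": left,
            "right": right,
            "support": n,
            "fraction": n / channel_total,
            "topology": "backsplice" if right <= left else "forward",
        }
        for (left, right), n in support.items()
        if n / channel_total > min_fraction
    ]
    return (
        pd.DataFrame(rows, columns=["left", "right", "support", "fraction", "topology"])
        .sort_values(["left", "right"])
        .reset_index(drop=True)
    )


def arc_table(breakpoints: pd.DataFrame) -> list[dict]:
    """Arc records (source, sink, fraction) for circos-style plotting."""
    return [
        {"source": int(r.left), "sink": int(r.right), "fraction": float(r.fraction)}
        for r in breakpoints.itertuples()
    ]


# ---------------------------------------------------------------------------
# Junction counting by probe matching
# ---------------------------------------------------------------------------

class _ProbeMatcher:
    """Minimum-Hamming probe assignment over all read offsets (both strands)."""

    def __init__(self, probes: list[JunctionProbe], max_mismatch: int = 1,
                 search_rc: bool = True) -> None:
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        strings = [p.probe for p in probes]
        if len(set(strings)) != len(strings):
            raise ValueError("duplicate probe strings: probe set is not identifying")
        lengths = {len(s) for s in strings}
        if len(lengths) > 1:
            raise ValueError("probes must share a common flank length")
        self.probes = probes
        self.max_mismatch = max_mismatch
        self.search_rc = search_rc
        self._variants: list[list[tuple[str, np.ndarray]]] = []
        for s in strings:
            var = [(s, np.frombuffer(s.encode(), dtype=np.uint8))]
            if search_rc:
                rc = reverse_complement(s)
                var.append((rc, np.frombuffer(rc.encode(), dtype=np.uint8)))
            self._variants.append(var)

    def distances(self, seq: str) -> list[int]:
        """Minimum Hamming distance of each probe over all offsets of the read."""
        arr: np.ndarray | None = None
        out = []
        for variants in self._variants:
            if any(s in seq for s, _ in variants):
                out.append(0)
                continue
            if arr is None:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            best = len(variants[0][0]) + 1
            for _, parr in variants:
                if len(arr) >= len(parr):
                    w = sliding_window_view(arr, len(parr))
                    best = min(best, int((w != parr).sum(axis=1).min()))
            out.append(best)
        return out

    def assign(self, seq: str) -> tuple[str | None, int | None]:
        """(junction name | 'ambiguous' | None, best distance)."""
        # exact-substring fast path: a unique zero-distance probe wins outright
        exact = [i for i, variants in enumerate(self._variants)
                 if any(s in seq for s, _ in variants)]
        if len(exact) == 1:
            return self.probes[exact[0]].name, 0
        if len(exact) > 1:
            return AMBIGUOUS, 0
        if self.max_mismatch == 0:
            return None, None
        d = self.distances(seq)
        best = min(d)
        if best > self.max_mismatch:
            return None, None
        winners = [i for i, x in enumerate(d) if x == best]
        if len(winners) > 1:
            return AMBIGUOUS, best
        return self.probes[winners[0]].name, best


@dataclass
class JunctionCountResult:
    """Per-read assignments plus the aggregated junction count table."""

    probes: list[JunctionProbe]
    assignments: list[str | None]
    distances: list[int | None]
    max_mismatch: int

    @property
    def ambiguous(self) -> int:
        return sum(1 for a in self.assignments if a == AMBIGUOUS)

    @property
    def unassigned(self) -> int:
        return sum(1 for a in self.assignments if a is None)

    @property
    def assigned(self) -> int:
        return len(self.assignments) - self.ambiguous - self.unassigned

    @property
    def counts(self) -> dict[str, int]:
        out = {p.name: 0 for p in self.probes}
        for a in self.assignments:
            if a is not None and a != AMBIGUOUS:
                out[a] += 1
        return out

    @property
    def table(self) -> pd.DataFrame:
        counts = self.counts
        total = self.assigned
        return pd.DataFrame(
            {
                "junction": list(counts),
                "count": list(counts.values()),
                "fraction": [c / total if total else 0.0 for c in counts.values()],
            }
        )


def count_junctions(
    seqs: list[str],
    probes: list[JunctionProbe],
    max_mismatch: int = 1,
    search_rc: bool = True,
) -> JunctionCountResult:
    """Count reads supporting each junction probe.

    A read supports a junction iff some offset matches the 2F-mer probe (or
    its reverse complement) with Hamming distance <= ``max_mismatch``. Reads
    matching several probes go to the minimum-distance probe; exact ties are
    excluded as ambiguous and reported separately. Fractions are over
    assigned reads.
    """
    matcher = _ProbeMatcher(probes, max_mismatch, search_rc)
    assignments: list[str | None] = []
    distances: list[int | None] = []
    for s in seqs:
        a, d = matcher.assign(s)
        assignments.append(a)
        distances.append(d)
    return JunctionCountResult(probes, assignments, distances, max_mismatch)


# ---------------------------------------------------------------------------
# Paired-end conditional quantification
# ---------------------------------------------------------------------------

@dataclass
class ConditionalResult:
    """Distribution of mate-2 junctions conditional on a mate-1 junction."""

    five_junction: str
    n_pairs: int               # pairs whose mate 1 supports the 5' junction
    counts: dict[str, int]     # mate-2 junction -> pairs
    unresolved: int            # mate 2 supports no probe
    ambiguous: int

    @property
    def resolved(self) -> int:
        return sum(self.counts.values())

    @property
    def table(self) -> pd.DataFrame:
        res = self.resolved
        return pd.DataFrame(
            {
                "junction": list(self.counts),
                "count": list(self.counts.values()),
                "conditional_fraction": [
                    c / res if res else 0.0 for c in self.counts.values()
                ],
            }
        )


def paired_3prime_quantification(
    pairs: list[ReadPair],
    five_probes: list[JunctionProbe],
    three_probes: list[JunctionProbe],
    five_junction: str,
    max_mismatch: int = 1,
) -> ConditionalResult:
    """For pairs whose mate 1 supports ``five_junction``, tabulate the mate-2
    junction distribution over ``three_probes``.

    Conditional fractions are over resolved mate-2 reads; unresolved and
    ambiguous bins are reported so that bins sum to the pair total.
    """
    if five_junction not in {p.name for p in five_probes}:
        raise ValueError(f"5' junction {five_junction!r} absent from the probe set")
    m5 = _ProbeMatcher(five_probes, max_mismatch)
    m3 = _ProbeMatcher(three_probes, max_mismatch)
    counts = {p.name: 0 for p in three_probes}
    n_pairs = unresolved = ambiguous = 0
    for pair in pairs:
        a5, _ = m5.assign(pair.seq1)
        if a5 != five_junction:
            continue
        n_pairs += 1
        a3, _ = m3.assign(pair.seq2)
        if a3 is None:
            unresolved += 1
        elif a3 == AMBIGUOUS:
            ambiguous += 1
        else:
            counts[a3] += 1
    return ConditionalResult(five_junction, n_pairs, counts, unresolved, ambiguous)
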