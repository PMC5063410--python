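"""Independent brute-force oracles used to validate the pipeline operations.

These deliberately avoid the implementation's code paths: junction counting
uses a full sliding-window Hamming scan with no exact-match shortcut,
clustering recomputes edit distances with Biopython's aligner instead of
edlib and applies no k-mer prefilter, and anchoring scans every (query,
reference) start pair.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(s: str) -> np.ndarray:
    return np.array([_ENC[c] for c in s], dtype=np.int8)


def min_hamming(seq: str, probe: str) -> int:
    """Minimum Hamming distance of the probe over all offsets of seq."""
    if len(seq) < len(probe):
        return len(probe) + 1
    s = _encode(seq)
    p = _encode(probe)
    windows = np.lib.stride_tricks.sliding_window_view(s, len(p))
    return int((windows != p).sum(axis=1).min())


def naive_assignments(seqs, probes, max_mismatch=1):
    """Per-read min-distance probe assignment by exhaustive Hamming scan."""
    out = []
    probe_strings = [(p.name, p.probe, str(Seq(p.probe).reverse_complement()))
                     for p in probes]
    for seq in seqs:
        dists = [min(min_hamming(seq, fwd), min_hamming(seq, rc))
                 for _, fwd, rc in probe_strings]
        best = min(dists)
        if best > max_mismatch:
            out.append(None)
            continue
        winners = [name for (name, _, _), d in zip(probe_strings, dists)
                   if d == best]
        out.append(winners[0] if len(winners) == 1 else "ambiguous")
    return out


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 0
    a.mismatch_score = -1
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


def edit_distance(a: str, b: str, aligner=None) -> int:
    aligner = aligner or _aligner()
    return int(-aligner.score(a, b))


def greedy_cluster(seqs, names, similarity=0.99):
    """O(n^2) abundance-ordered greedy clustering without any prefilter.

    Returns a list of (representative, sorted member-name tuple).
    """
    aligner = _aligner()
    by_seq: dict[str, list[str]] = {}
    for s, n in zip(seqs, names):
        by_seq.setdefault(s, []).append(n)
    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), s))
    clustered: set[str] = set()
    clusters = []
    for i, seed in enumerate(order):
        if seed in clustered:
            continue
        clustered.add(seed)
        members = list(by_seq[seed])
        for other in order[i + 1:]:
            if other in clustered:
                continue
            ident = 1.0 - edit_distance(seed, other, aligner) / max(len(seed), len(other))
            if ident >= similarity:
                clustered.add(other)
                members.extend(by_seq[other])
        clusters.append((seed, tuple(sorted(members))))
    return clusters


def naive_mems(query: str, ref: str, min_len: int):
    """All maximal exact matches of length >= min_len by O(n*m) scanning.

    Returns (query_start, query_end, ref_start, ref_end) tuples, plus-strand
    only; callers handle orientation.
    """
    out = []
    for i in range(len(query)):
        for j in range(len(ref)):
            if query[i] != ref[j]:
                continue
            if i > 0 and j > 0 and query[i - 1] == ref[j - 1]:
                continue  # not left-maximal
            k = 0
            while i + k < len(query) and j + k < len(ref) and query[i + k] == ref[j + k]:
                k += 1
            if k >= min_len:
                out.append((i, i + k, j, j + k))
    return sorted(out)
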