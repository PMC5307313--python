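"""Raw paired amplicon reads → per-PCR denoised unique sequences.

The cascade mirrors the standard tag-multiplexed amplicon workflow:

1. merge each mate pair by best ungapped overlap, taking the higher-quality
   base at overlap disagreements;
2. drop merged reads whose overlap alignment score is below a threshold
   (default 40; score = matches − mismatches over the overlap, floored at 0);
3. demultiplex on exactly matching 9-nt tags and primers with at most two
   mismatches, trimming tags and primers;
4. dereplicate identical inserts into unique sequences with per-PCR counts;
5. remove sequences shorter than 80 bp or with a dataset-wide count < 1,000;
6. denoise per PCR with a single-variant graph: a sequence one substitution
   or one indel away from a more abundant one (count ratio < 0.5) is treated
   as a PCR/sequencing error ("internal") and discarded.

All thresholds follow strict inequalities: values exactly at a threshold are
kept.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import mismatches_with_n, revcomp
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

MIN_OVERLAP = 10

__all__ = [
    "TaggedReadPair",
    "MergedRead",
    "UniqueSequence",
    "merge_one",
    "merge_pairs",
    "filter_quality",
    "demultiplex",
    "dereplicate",
    "filter_length_count",
    "denoise",
]


@dataclass
class TaggedReadPair:
    read_id: str
    seq1: str
    qual1: list  # Phred scores, same length as seq1
    seq2: str
    qual2: list


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    alignment_score: float
    pcr_id: str | None = None


@dataclass
class UniqueSequence:
    sequence: str
    per_pcr_counts: dict = field(default_factory=dict)
    status: str | None = None  # head / internal / singleton, set by denoise()

    @property
    def total_count(self) -> int:
        return sum(self.per_pcr_counts.values())


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------


def merge_one(seq1: str, qual1, seq2: str, qual2) -> tuple[str, float]:
    """Merge one pair by scanning every overlap offset of mate1 vs revcomp(mate2).

    Returns ``(merged_sequence, alignment_score)``. The offset maximising
    matches − mismatches over the overlap wins (ties: smallest offset); at
    disagreeing overlap positions the base with the higher Phred quality is
    kept (ties favour mate1). Pairs admitting no overlap of at least
    ``MIN_OVERLAP`` nt are returned as mate1 with score 0.
    """
    r2 = revcomp(seq2)
    q2 = list(qual2)[::-1]
    L1, L2 = len(seq1), len(r2)
    best_score, best_k = None, None
    for k in range(-(L2 - MIN_OVERLAP), L1 - MIN_OVERLAP + 1):
        a1, b1 = max(0, k), min(L1, k + L2)
        if b1 - a1 < MIN_OVERLAP:
            continue
        matches = sum(1 for i in range(a1, b1) if seq1[i] == r2[i - k])
        score = 2 * matches - (b1 - a1)
        if best_score is None or score > best_score:
            best_score, best_k = score, k
    if best_score is None:
        return seq1, 0.0
    k = best_k
    lo, hi = min(0, k), max(L1, k + L2)
    out = []
    for pos in range(lo, hi):
        in1 = 0 <= pos < L1
        in2 = 0 <= pos - k < L2
        if in1 and in2:
            if seq1[pos] == r2[pos - k] or qual1[pos] >= q2[pos - k]:
                out.append(seq1[pos])
            else:
                out.append(r2[pos - k])
        elif in1:
            out.append(seq1[pos])
        else:
            out.append(r2[pos - k])
    return "".join(out), float(max(best_score, 0))


def merge_pairs(pairs) -> list:
    """Merge a stream of :class:`TaggedReadPair`; malformed pairs are logged and skipped.

    Pairs whose mates share one common length are processed in a vectorised
    batch (the common case for fixed-length sequencer output); stragglers fall
    back to :func:`merge_one`.
    """
    pairs = list(pairs)
    good: list[TaggedReadPair] = []
    for p in pairs:
        if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
            logger.warning("rejecting %s: sequence/quality length mismatch", p.read_id)
            continue
        good.append(p)
    by_shape: dict[tuple[int, int], list[TaggedReadPair]] = defaultdict(list)
    for p in good:
        by_shape[(len(p.seq1), len(p.seq2))].append(p)
    merged: dict[str, MergedRead] = {}
    for (L1, L2), group in by_shape.items():
        if len(group) >= 32 and L1 >= MIN_OVERLAP and L2 >= MIN_OVERLAP:
            for p, (seq, score) in zip(group, _merge_batch(group, L1, L2)):
                merged[p.read_id] = MergedRead(p.read_id, seq, score)
        else:
            for p in group:
                seq, score = merge_one(p.seq1, p.qual1, p.seq2, p.qual2)
                merged[p.read_id] = MergedRead(p.read_id, seq, score)
    return [merged[p.read_id] for p in good]


def _merge_batch(group, L1: int, L2: int) -> list:
    """Vectorised equivalent of :func:`merge_one` for same-shape pairs."""
    n = len(group)
    A = np.frombuffer("".join(p.seq1 for p in group).encode(), np.uint8).reshape(n, L1)
    B_fwd = np.frombuffer("".join(revcomp(p.seq2) for p in group).encode(), np.uint8).reshape(
        n, L2
    )
    Q1 = np.array([p.qual1 for p in group], dtype=np.int16)
    Q2 = np.array([p.qual2 for p in group], dtype=np.int16)[:, ::-1]

    offsets = range(-(L2 - MIN_OVERLAP), L1 - MIN_OVERLAP + 1)
    best_score = np.full(n, -(10**9), dtype=np.int32)
    best_k = np.zeros(n, dtype=np.int32)
    for k in offsets:
        a1, b1 = max(0, k), min(L1, k + L2)
        ov = b1 - a1
        if ov < MIN_OVERLAP:
            continue
        matches = (A[:, a1:b1] == B_fwd[:, a1 - k : b1 - k]).sum(axis=1)
        score = 2 * matches.astype(np.int32) - ov
        better = score > best_score
        best_score[better] = score[better]
        best_k[better] = k

    results: list[tuple[str, float] | None] = [None] * n
    for k in np.unique(best_k):
        idx = np.nonzero(best_k == k)[0]
        k = int(k)
        lo, hi = min(0, k), max(L1, k + L2)
        width = hi - lo
        sub_a = np.zeros((idx.size, width), dtype=np.uint8)
        sub_q1 = np.full((idx.size, width), -1, dtype=np.int16)
        sub_b = np.zeros((idx.size, width), dtype=np.uint8)
        sub_q2 = np.full((idx.size, width), -1, dtype=np.int16)
        sub_a[:, -lo : -lo + L1] = A[idx]
        sub_q1[:, -lo : -lo + L1] = Q1[idx]
        sub_b[:, k - lo : k - lo + L2] = B_fwd[idx]
        sub_q2[:, k - lo : k - lo + L2] = Q2[idx]
        take_a = (sub_q1 >= sub_q2) | (sub_a == sub_b)
        cons = np.where((sub_a == 0) | (~take_a & (sub_b != 0)), sub_b, sub_a)
        scores = np.maximum(best_score[idx], 0).astype(float)
        for row, i in enumerate(idx):
            results[i] = (cons[row].tobytes().decode("ascii"), float(scores[row]))
    return results  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------


def filter_quality(merged, min_score: float = 40) -> list:
    """Keep merged reads with alignment_score >= min_score (strict '<' removal)."""
    merged = list(merged)
    kept = [m for m in merged if m.alignment_score >= min_score]
    logger.info("filter_quality: %d -> %d reads", len(merged), len(kept))
    return kept


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def demultiplex(
    merged,
    tag_scheme,
    fwd_primer: str,
    rev_primer: str,
    max_primer_mismatch: int = 2,
    tag_len: int = 9,
) -> tuple[list, list]:
    """Assign merged reads to PCRs by exact tags and near-exact primers.

    A read is assigned when, in either orientation, its two flanking 9-nt tags
    exactly match a registered tag pair and both primer sites align with at
    most ``max_primer_mismatch`` mismatches (any N counts as a mismatch; an N
    inside a tag defeats the exact match). Tags and primers are trimmed from
    the retained insert. Returns ``(assigned, unassigned)``.
    """
    tag_to_pcr = tag_scheme.tag_to_pcr
    seen: dict[tuple[str, str], str] = {}
    for pair, pcr in tag_to_pcr.items():
        if pair in seen and seen[pair] != pcr:
            raise ConfigurationError(f"tag pair {pair} maps to two PCRs")
        seen[pair] = pcr

    lf, lr = len(fwd_primer), len(rev_primer)
    rc_rev = revcomp(rev_primer)
    assigned, unassigned = [], []
    for m in merged:
        hit = None
        for seq in (m.sequence, revcomp(m.sequence)):
            if len(seq) < 2 * tag_len + lf + lr + 1:
                continue
            t1 = seq[:tag_len]
            t2 = revcomp(seq[-tag_len:])
            pcr = tag_to_pcr.get((t1, t2))
            if pcr is None or "N" in t1 or "N" in t2:
                continue
            if mismatches_with_n(seq[tag_len : tag_len + lf], fwd_primer) > max_primer_mismatch:
                continue
            if (
                mismatches_with_n(seq[-tag_len - lr : -tag_len], rc_rev)
                > max_primer_mismatch
            ):
                continue
            hit = (pcr, seq[tag_len + lf : -tag_len - lr])
            break
        if hit is None:
            unassigned.append(m)
        else:
            assigned.append(MergedRead(m.read_id, hit[1], m.alignment_score, pcr_id=hit[0]))
    logger.info("demultiplex: %d assigned, %d unassigned", len(assigned), len(unassigned))
    return assigned, unassigned


# ---------------------------------------------------------------------------
# dereplication and count/length filters
# ---------------------------------------------------------------------------


def dereplicate(assigned) -> list:
    """Collapse identical inserts into :class:`UniqueSequence` with per-PCR tallies."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for m in assigned:
        counts[m.sequence][m.pcr_id] += 1
    out = [UniqueSequence(seq, dict(c)) for seq, c in counts.items()]
    out.sort(key=lambda u: (-u.total_count, u.sequence))
    return out


def filter_length_count(uniques, min_len: int = 80, min_total: int = 1000) -> list:
    """Keep sequences of length >= min_len and dataset-wide count >= min_total."""
    uniques = list(uniques)
    kept = [u for u in uniques if len(u.sequence) >= min_len and u.total_count >= min_total]
    logger.info("filter_length_count: %d -> %d unique sequences", len(uniques), len(kept))
    return kept


# ---------------------------------------------------------------------------
# single-variant graph denoising
# ---------------------------------------------------------------------------


def _edit_distance_one(a: str, b: str) -> bool:
    if abs(len(a) - len(b)) > 1 or a == b:
        return False
    return edlib.align(a, b, task="distance", k=1)["editDistance"] == 1


_STATUS_PREFERENCE = {"head": 0, "singleton": 1, "internal": 2}


def denoise(uniques, ratio_threshold: float = 0.5, merge_variants: bool = False) -> list:
    """Classify unique sequences as head/internal/singleton per PCR; keep non-variants.

    Within each PCR a directed edge u→v exists when u and v differ by exactly
    one substitution or one indel and ``count(v)/count(u) < ratio_threshold``;
    a v with an incoming edge is a variant ("internal") in that PCR, a
    sequence with outgoing edges only is a "head", an isolated sequence a
    "singleton". Per-PCR statuses are aggregated by majority vote over the
    PCRs where the sequence occurs (ties resolve conservatively:
    head > singleton > internal). Sequences whose aggregate status is
    "internal" are discarded; by default their counts are dropped, with
    ``merge_variants=True`` they are added to the most abundant adjacent
    parent in each PCR.
    """
    uniques = sorted(uniques, key=lambda u: (-u.total_count, u.sequence))
    n = len(uniques)
    pcrs = sorted({p for u in uniques for p in u.per_pcr_counts})
    edges = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and _edit_distance_one(uniques[i].sequence, uniques[j].sequence)
    ]

    votes: list[Counter] = [Counter() for _ in range(n)]
    parent_in_pcr: dict[tuple[int, str], int] = {}
    for pcr in pcrs:
        cnt = [u.per_pcr_counts.get(pcr, 0) for u in uniques]
        has_in = [False] * n
        has_out = [False] * n
        for i, j in edges:
            if cnt[i] > 0 and cnt[j] > 0 and cnt[j] / cnt[i] < ratio_threshold:
                has_in[j] = True
                has_out[i] = True
                key = (j, pcr)
                if key not in parent_in_pcr or cnt[parent_in_pcr[key]] < cnt[i]:
                    parent_in_pcr[key] = i
        for i in range(n):
            if cnt[i] == 0:
                continue
            if has_in[i]:
                votes[i]["internal"] += 1
            elif has_out[i]:
                votes[i]["head"] += 1
            else:
                votes[i]["singleton"] += 1

    kept: list[UniqueSequence] = []
    discarded_reads = 0
    merged_counts = {i: dict(u.per_pcr_counts) for i, u in enumerate(uniques)}
    internal = set()
    for i, u in enumerate(uniques):
        best = max(votes[i].items(), key=lambda kv: (kv[1], -_STATUS_PREFERENCE[kv[0]]))
        u.status = best[0]
        if u.status == "internal":
            internal.add(i)
    for i in sorted(internal):
        u = uniques[i]
        discarded_reads += u.total_count
        if merge_variants:
            for pcr, c in u.per_pcr_counts.items():
                parent = parent_in_pcr.get((i, pcr))
                if parent is not None:
                    merged_counts[parent][pcr] = merged_counts[parent].get(pcr, 0) + c
    for i, u in enumerate(uniques):
        if i in internal:
            continue
        if merge_variants:
            u = UniqueSequence(u.sequence, merged_counts[i], status=u.status)
        kept.append(u)
    logger.info(
        "denoise: kept %d of %d sequences (%d variant reads discarded)",
        len(kept),
        n,
        discarded_reads,
    )
    return kept
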