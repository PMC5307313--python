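"""Taxonomic assignment of denoised amplicons and per-sample prey filtering.

The assignment stage works against a reference amplicon database cut out of
source sequences by in-silico PCR. Each query gets a best-identity hit set
(global alignment identity, ties within 1e-9), a provisional lowest common
ancestor (LCA), and is then refined against a list of locally occurring
species:

1. identity >= 98% to exactly one local species → that species;
2. identity >= 98% to several species → the single local one if unique, else
   the lowest taxon containing all local members of the tie set;
3. maximum identity in [94%, 98%) → the lowest taxon containing the local
   species among the top hits; a single non-local top hit is replaced by its
   closest local congener when one exists, otherwise by the lowest containing
   taxon with local members;
4. maximum identity < 94% → discarded.

Afterwards, per-sample counts are cleaned of predator/human reads, of
sequences below 0.1% of the sample or 50 reads, and of anything not
exceeding its worst negative-control count; finally sequences within 2%
divergence are collapsed into discrete prey taxa (single linkage, labelled by
the most abundant member).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, seq_to_array
from .errors import TaxonLookupError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceRecord",
    "Taxonomy",
    "LocalSpeciesList",
    "TaxonAssignment",
    "in_silico_pcr",
    "identity",
    "assign_lca",
    "refine_assignment",
    "per_sample_filter",
    "collapse_taxa",
    "identify_predator",
]

RANKS = ("species", "genus", "family", "order", "class_name")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference amplicon (insert only) with its lineage."""

    record_id: str
    sequence: str
    lineage: dict
    source_length: int = 0

    @property
    def species(self) -> str:
        return self.lineage["species"]


@dataclass
class LocalSpeciesList:
    """Species known to occur in the study area, with an optional regional tier."""

    species: set
    tier: dict = field(default_factory=dict)  # species -> "reserve" | "regional"

    def __contains__(self, name: str) -> bool:
        return name in self.species


@dataclass
class TaxonAssignment:
    query_id: str
    taxon: str | None
    rank: str | None
    max_identity: float
    best_species: set
    rule_applied: object = None  # 1 | 2 | 3 | "discarded_low_identity"
    substituted: bool = False  # rule-3 local-congener replacement
    reason: str | None = None  # machine-readable discard reason


class Taxonomy:
    """Rank-complete lineage table with LCA queries.

    Built from rows carrying species→genus→family→order→class names (e.g. a
    reference taxonomy TSV). Any named taxon at any rank can be looked up;
    the LCA of a species set is the lowest rank at which all lineages agree
    (falling back to the pseudo-root ``Vertebrata``).
    """

    ROOT = ("Vertebrata", "root")

    def __init__(self, rows) -> None:
        self._lineage: dict[str, dict] = {}
        self._rank_of: dict[str, str] = {}
        for row in rows:
            lin = {r: row[r] for r in RANKS}
            self._lineage[lin["species"]] = lin
            for r in RANKS:
                name = lin[r]
                if not name:
                    continue
                if self._rank_of.get(name, r) != r:
                    raise ValidationError(f"taxon {name!r} appears at two ranks")
                self._rank_of[name] = r

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Taxonomy":
        return cls(frame.to_dict("records"))

    def __contains__(self, name: str) -> bool:
        return name in self._rank_of or name == self.ROOT[0]

    def rank_of(self, name: str) -> str:
        if name == self.ROOT[0]:
            return self.ROOT[1]
        try:
            return self._rank_of[name]
        except KeyError:
            raise TaxonLookupError(name) from None

    def lineage_of_species(self, species: str) -> dict:
        try:
            return self._lineage[species]
        except KeyError:
            raise TaxonLookupError(species) from None

    def species_under(self, name: str) -> set:
        """All species whose lineage passes through ``name``."""
        if name == self.ROOT[0]:
            return set(self._lineage)
        rank = self.rank_of(name)
        return {s for s, lin in self._lineage.items() if lin[rank] == name}

    def lca(self, species_names) -> tuple[str, str]:
        """Lowest taxon (name, rank) containing every species in the set."""
        names = list(species_names)
        if not names:
            raise ValidationError("LCA of an empty species set")
        lineages = [self.lineage_of_species(s) for s in names]
        for rank in RANKS:
            values = {lin[rank] for lin in lineages}
            if len(values) == 1:
                return values.pop(), rank
        return self.ROOT

    def rank_depth(self, rank: str) -> int:
        if rank == self.ROOT[1]:
            return len(RANKS)
        return RANKS.index(rank)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _site_mismatch_profile(seq: np.ndarray, primer: np.ndarray) -> np.ndarray:
    """Mismatch count of `primer` at every start position of `seq` (vectorised)."""
    n, m = seq.size, primer.size
    if n < m:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    return (windows != primer[None, :]).sum(axis=1)


def in_silico_pcr(
    sources,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 3,
    insert_len_range: tuple[int, int] = (50, 150),
) -> list:
    """Extract amplicon inserts from source records by primer-site scanning.

    ``sources`` is an iterable of objects with ``record_id``, ``sequence`` and
    ``lineage`` (e.g. :class:`scatdiet.simdata.SourceRecord`). Every pair of
    sites where the forward primer and the reverse-complemented reverse primer
    each match with at most ``max_mismatch`` mismatches, and the enclosed
    insert length falls inside ``insert_len_range``, yields one
    :class:`ReferenceRecord` holding the insert only. Records without any
    amplifiable site pair are skipped with a log message.
    """
    fwd = seq_to_array(fwd_primer)
    rc_rev = seq_to_array(revcomp(rev_primer))
    lo, hi = insert_len_range
    out: list[ReferenceRecord] = []
    for src in sources:
        seq = seq_to_array(src.sequence)
        f_hits = np.nonzero(_site_mismatch_profile(seq, fwd) <= max_mismatch)[0]
        r_hits = np.nonzero(_site_mismatch_profile(seq, rc_rev) <= max_mismatch)[0]
        n_before = len(out)
        for i in f_hits:
            start = int(i) + fwd.size
            for j in r_hits:
                ins_len = int(j) - start
                if lo <= ins_len <= hi:
                    suffix = "" if len(f_hits) * len(r_hits) == 1 else f"_{len(out) - n_before + 1}"
                    out.append(
                        ReferenceRecord(
                            record_id=f"{src.record_id}{suffix}",
                            sequence=src.sequence[start : int(j)],
                            lineage=dict(src.lineage),
                            source_length=len(src.sequence),
                        )
                    )
        if len(out) == n_before:
            logger.info("in_silico_pcr: no amplifiable site in %s", src.record_id)
    return out


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------


def identity(query: str, reference: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps included).

    Needleman–Wunsch with match +1, mismatch 0 and linear gap −1; among
    co-optimal moves the traceback prefers diagonal, then up, then left, which
    fixes the column count deterministically. Symmetric in its arguments.
    """
    if not query or not reference:
        raise ValidationError("identity of an empty sequence is undefined")
    a, b = query, reference
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    score[0, :] = -np.arange(m + 1)
    score[:, 0] = -np.arange(n + 1)
    eq = (seq_to_array(a)[:, None] == seq_to_array(b)[None, :]).astype(np.int32)
    cols = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + eq[i - 1]
        up = score[i - 1, 1:] - 1
        best = np.maximum(diag, up)
        # left gaps form a running max with unit decay:
        # score[i][j] = max_k<=j candidate[k] - (j - k)
        cand = np.concatenate(([score[i, 0]], best + cols[1:]))
        score[i] = np.maximum.accumulate(cand) - cols
    # traceback (diag > up > left on ties)
    i, j, matches, columns = n, m, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + eq[i - 1, j - 1]:
            matches += int(eq[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return matches / columns


# ---------------------------------------------------------------------------
# LCA assignment and local refinement
# ---------------------------------------------------------------------------

TIE_TOL = 1e-9


def assign_lca(query_id: str, query: str, records, taxonomy: Taxonomy) -> TaxonAssignment:
    """Best-identity hit set and its LCA as the provisional assignment."""
    records = list(records)
    if not records:
        raise ValidationError("reference database is empty")
    by_species: dict[str, float] = {}
    for rec in records:
        ident = identity(query, rec.sequence)
        sp = rec.species
        if ident > by_species.get(sp, -1.0):
            by_species[sp] = ident
    max_ident = max(by_species.values())
    best = {sp for sp, ident in by_species.items() if ident >= max_ident - TIE_TOL}
    taxon, rank = taxonomy.lca(best)
    return TaxonAssignment(
        query_id=query_id,
        taxon=taxon,
        rank=rank,
        max_identity=max_ident,
        best_species=best,
    )


def _closest_local_congener(
    species: str, local: LocalSpeciesList, taxonomy: Taxonomy
) -> str | None:
    genus = taxonomy.lineage_of_species(species)["genus"]
    congeners = sorted(
        s for s in taxonomy.species_under(genus) if s in local and s != species
    )
    return congeners[0] if congeners else None


def _lowest_containing_local(
    species_set, local: LocalSpeciesList, taxonomy: Taxonomy
) -> tuple[str, str]:
    local_members = {s for s in species_set if s in local}
    if local_members:
        return taxonomy.lca(local_members)
    return taxonomy.lca(species_set)


def refine_assignment(
    assignment: TaxonAssignment,
    local: LocalSpeciesList,
    taxonomy: Taxonomy,
    species_threshold: float = 0.98,
    min_identity: float = 0.94,
) -> TaxonAssignment:
    """Apply the three local-occurrence refinement rules (see module docstring)."""
    for sp in assignment.best_species:
        if sp not in taxonomy:
            raise TaxonLookupError(sp)
    a = assignment
    m = a.max_identity
    best = a.best_species

    if m < min_identity:
        a.taxon, a.rank = None, None
        a.rule_applied = "discarded_low_identity"
        a.reason = f"max identity {m:.4f} < {min_identity:.2f}"
        return a

    if m >= species_threshold:
        local_best = sorted(s for s in best if s in local)
        if len(best) == 1:
            sp = next(iter(best))
            if sp in local:
                a.taxon, a.rank, a.rule_applied = sp, "species", 1
                return a
            # single confident hit outside the local fauna: resolved like the
            # low-identity non-local case, flagged as a substitution
            congener = _closest_local_congener(sp, local, taxonomy)
            if congener is not None:
                a.taxon, a.rank, a.rule_applied, a.substituted = congener, "species", 2, True
                return a
            a.taxon, a.rank = _walk_up_to_local(sp, local, taxonomy)
            a.rule_applied = 2
            return a
        if len(local_best) == 1:
            a.taxon, a.rank, a.rule_applied = local_best[0], "species", 2
            return a
        a.taxon, a.rank = _lowest_containing_local(best, local, taxonomy)
        a.rule_applied = 2
        return a

    # 0.94 <= m < 0.98
    local_best = sorted(s for s in best if s in local)
    if local_best:
        a.taxon, a.rank = taxonomy.lca(local_best)
        a.rule_applied = 3
        return a
    if len(best) == 1:
        sp = next(iter(best))
        congener = _closest_local_congener(sp, local, taxonomy)
        if congener is not None:
            a.taxon, a.rank, a.rule_applied, a.substituted = congener, "species", 3, True
            return a
        a.taxon, a.rank = _walk_up_to_local(sp, local, taxonomy)
        a.rule_applied = 3
        return a
    a.taxon, a.rank = _lowest_containing_local(best, local, taxonomy)
    a.rule_applied = 3
    return a


def _walk_up_to_local(species: str, local: LocalSpeciesList, taxonomy: Taxonomy):
    """Lowest ancestor of ``species`` that contains at least one local species."""
    lin = taxonomy.lineage_of_species(species)
    for rank in RANKS[1:]:
        name = lin[rank]
        if not name:
            continue
        if any(s in local for s in taxonomy.species_under(name)):
            return name, rank
    return Taxonomy.ROOT


# ---------------------------------------------------------------------------
# per-sample filtering
# ---------------------------------------------------------------------------


@dataclass
class SampleFilterResult:
    counts: pd.DataFrame  # sequences × samples after zeroing
    removed: pd.DataFrame  # long form: sample_id, sequence_id, reads, reason
    no_food_samples: list


def per_sample_filter(
    counts: pd.DataFrame,
    negative_counts: pd.DataFrame | None,
    assignments: dict,
    predator_of: dict,
    human_taxa: set = frozenset({"Homo sapiens"}),
    min_frac: float = 0.001,
    min_reads: int = 50,
) -> SampleFilterResult:
    """Zero out contaminant-like counts within each sample.

    ``counts`` is sequences × samples; ``negative_counts`` sequences ×
    negative-control PCRs (same index). ``assignments`` maps sequence id →
    final taxon name (None for discarded). Removal conditions, applied per
    sample: (a) the sequence is assigned to the sample's predator or to a
    human taxon (removed regardless of count); (b) count < ``min_frac`` of
    the sample's food-read total; (c) count < ``min_reads``; (d) count does
    not exceed the sequence's maximum count across the negative controls.
    Samples left without reads are flagged "no food detected" and excluded
    from diet denominators downstream.
    """
    filtered = counts.copy()
    removed_rows = []
    neg_max = (
        negative_counts.reindex(counts.index).fillna(0).max(axis=1)
        if negative_counts is not None and negative_counts.shape[1] > 0
        else pd.Series(0, index=counts.index)
    )
    for sample in counts.columns:
        col = counts[sample]
        predator = predator_of.get(sample)
        is_nonfood = col.index.map(
            lambda s: assignments.get(s) is not None
            and (assignments.get(s) == predator or assignments.get(s) in human_taxa)
        ).to_numpy(dtype=bool)
        food_total = int(col[~is_nonfood].sum())
        for seq_id in col.index[(col > 0)]:
            c = int(col[seq_id])
            reason = None
            if is_nonfood[col.index.get_loc(seq_id)]:
                reason = "predator_or_human"
            elif c < min_reads:
                reason = "below_min_reads"
            elif food_total > 0 and c < min_frac * food_total:
                reason = "below_min_frac"
            elif c <= neg_max[seq_id] and neg_max[seq_id] > 0:
                reason = "negative_control"
            if reason:
                filtered.loc[seq_id, sample] = 0
                removed_rows.append(
                    {"sample_id": sample, "sequence_id": seq_id, "reads": c, "reason": reason}
                )
    no_food = [s for s in filtered.columns if filtered[s].sum() == 0]
    for s in no_food:
        logger.warning("sample %s: no food detected after filtering", s)
    removed = pd.DataFrame(
        removed_rows, columns=["sample_id", "sequence_id", "reads", "reason"]
    )
    return SampleFilterResult(counts=filtered, removed=removed, no_food_samples=no_food)


# ---------------------------------------------------------------------------
# 2% divergence collapse
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class CollapsedTaxon:
    taxon: str
    rank: str
    order: str | None
    member_ids: list
    label_sequence_id: str


def collapse_taxa(
    counts: pd.DataFrame,
    assignments: dict,
    taxonomy: Taxonomy | None = None,
    divergence: float = 0.02,
) -> tuple[pd.DataFrame, list]:
    """Single-linkage collapse of sequences within ``divergence`` into taxa.

    Sequences (index of ``counts``, which must be the actual insert strings or
    resolvable through ``assignments`` keyed by the same ids) joining with
    identity >= 1 − divergence form one discrete taxon, labelled by the
    assignment of the cluster's most abundant member. Clusters mixing
    assignments from different orders are split by assigned order with a
    warning. Returns (taxa × samples presence/count table, cluster metadata).
    Collapsing an already collapsed table is a no-op.
    """
    seq_ids = list(counts.index)
    n = len(seq_ids)
    uf = _UnionFind(n)
    threshold = 1.0 - divergence
    for i in range(n):
        for j in range(i + 1, n):
            if identity(seq_ids[i], seq_ids[j]) >= threshold - 1e-12:
                uf.union(i, j)
    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    def order_of(taxon: str | None) -> str | None:
        if taxon is None or taxonomy is None or taxon not in taxonomy:
            return None
        rank = taxonomy.rank_of(taxon)
        if rank == "order":
            return taxon
        if rank == "species":
            return taxonomy.lineage_of_species(taxon)["order"]
        for sp in taxonomy.species_under(taxon):
            return taxonomy.lineage_of_species(sp)["order"]
        return None

    taxa_meta: list[CollapsedTaxon] = []
    rows = {}
    for members in clusters.values():
        by_order: dict[object, list] = {}
        orders = {order_of(assignments.get(seq_ids[i])) for i in members}
        if len(orders) > 1:
            logger.warning(
                "collapse_taxa: cluster spans orders %s; splitting by assignment", orders
            )
            for i in members:
                by_order.setdefault(order_of(assignments.get(seq_ids[i])), []).append(i)
        else:
            by_order[next(iter(orders))] = members
        for order_name, group in by_order.items():
            totals = counts.iloc[group].sum(axis=1)
            label_idx = group[int(np.argmax(totals.to_numpy()))]
            label_id = seq_ids[label_idx]
            taxon = assignments.get(label_id)
            if taxon is None:
                continue
            rank = taxonomy.rank_of(taxon) if taxonomy and taxon in taxonomy else "unknown"
            agg = counts.iloc[group].sum(axis=0)
            rows[taxon] = rows[taxon] + agg if taxon in rows else agg
            taxa_meta.append(
                CollapsedTaxon(
                    taxon=taxon,
                    rank=rank,
                    order=order_name,
                    member_ids=[seq_ids[i] for i in group],
                    label_sequence_id=label_id,
                )
            )
    table = pd.DataFrame(rows).T
    table.index.name = "taxon"
    return table, taxa_meta


# ---------------------------------------------------------------------------
# predator identification (16S diagnostic fragment)
# ---------------------------------------------------------------------------


def identify_predator(
    consensus: str, predator_refs: dict, min_identity: float = 0.98
) -> str:
    """Assign the faecal sample's predator from its dominant 16S consensus.

    The best-identity reference at or above ``min_identity`` wins; below the
    threshold the sample stays "unknown"; two references tied within 1e-9 give
    "ambiguous" (logged).
    """
    scores = {sp: identity(consensus, ref) for sp, ref in predator_refs.items()}
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    best_sp, best = ranked[0]
    if best < min_identity:
        return "unknown"
    if len(ranked) > 1 and ranked[1][1] >= best - TIE_TOL:
        logger.warning("predator identification tie: %s", ranked[:2])
        return "ambiguous"
    return best_sp
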