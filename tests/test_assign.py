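"""Reference building, identity/LCA assignment, refinement rules and filters."""

import pandas as pd
import pytest

from scatdiet import assign as am
from scatdiet import simdata
from scatdiet._util import revcomp
from scatdiet.errors import ValidationError
from conftest import random_dna

FWD, REV = simdata.FWD_PRIMER, simdata.REV_PRIMER


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


class FakeSource:
    def __init__(self, record_id, sequence, lineage=None):
        self.record_id = record_id
        self.sequence = sequence
        self.lineage = lineage or {"species": record_id}


def oracle_scan(seq, fwd, rc_rev, max_mm, lo, hi):
    """Naive position-by-position primer-site scan."""
    hits = []
    for i in range(len(seq) - len(fwd) + 1):
        if sum(a != b for a, b in zip(seq[i : i + len(fwd)], fwd)) <= max_mm:
            for j in range(i + len(fwd), len(seq) - len(rc_rev) + 1):
                if sum(a != b for a, b in zip(seq[j : j + len(rc_rev)], rc_rev)) <= max_mm:
                    ins = j - (i + len(fwd))
                    if lo <= ins <= hi:
                        hits.append(seq[i + len(fwd) : j])
    return hits


class TestInSilicoPcr:
    def test_exact_sites_yield_insert(self, rng):
        insert = random_dna(rng, 98)
        src = FakeSource("R1", "TTTTT" + FWD + insert + revcomp(REV) + "GGGGG")
        recs = am.in_silico_pcr([src], FWD, REV)
        assert len(recs) == 1 and recs[0].sequence == insert

    def test_four_mismatches_reject(self, rng):
        insert = random_dna(rng, 98)
        fwd = list(FWD)
        for i in range(4):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        src = FakeSource("R1", "".join(fwd) + insert + revcomp(REV))
        assert am.in_silico_pcr([src], FWD, REV, max_mismatch=3) == []

    def test_insert_length_bounds(self, rng):
        for length, expect in [(49, 0), (50, 1), (150, 1), (151, 0)]:
            src = FakeSource("R", FWD + random_dna(rng, length) + revcomp(REV))
            assert len(am.in_silico_pcr([src], FWD, REV)) == expect

    def test_randomised_templates_match_scanning_oracle(self, rng):
        rc_rev = revcomp(REV)
        for _ in range(20):
            # embed noisy primer sites in random backbone
            parts = [random_dna(rng, 20)]
            for _ in range(int(rng.integers(1, 3))):
                f = list(FWD)
                for _ in range(int(rng.integers(0, 5))):
                    f[int(rng.integers(len(f)))] = "ACGT"[rng.integers(4)]
                parts += ["".join(f), random_dna(rng, int(rng.integers(40, 160)))]
                r = list(rc_rev)
                for _ in range(int(rng.integers(0, 5))):
                    r[int(rng.integers(len(r)))] = "ACGT"[rng.integers(4)]
                parts += ["".join(r), random_dna(rng, 15)]
            seq = "".join(parts)
            got = [rec.sequence for rec in am.in_silico_pcr([FakeSource("R", seq)], FWD, REV)]
            assert sorted(got) == sorted(oracle_scan(seq, FWD, rc_rev, 3, 50, 150))


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------


def oracle_identity(a, b):
    """Memoised recursive Needleman–Wunsch with the same scoring/tie rules."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def score(i, j):
        if i == 0:
            return -j
        if j == 0:
            return -i
        return max(
            score(i - 1, j - 1) + (a[i - 1] == b[j - 1]),
            score(i - 1, j) - 1,
            score(i, j - 1) - 1,
        )

    i, j, matches, cols = len(a), len(b), 0, 0
    while i or j:
        if i and j and score(i, j) == score(i - 1, j - 1) + (a[i - 1] == b[j - 1]):
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i and score(i, j) == score(i - 1, j) - 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches / cols


class TestIdentity:
    def test_identical_and_single_substitution(self, rng):
        s = random_dna(rng, 100)
        assert am.identity(s, s) == 1.0
        t = list(s)
        t[50] = "A" if s[50] != "A" else "C"
        assert am.identity(s, "".join(t)) == pytest.approx(0.99)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a, b = random_dna(rng, 40), random_dna(rng, int(rng.integers(30, 50)))
            x = am.identity(a, b)
            assert 0.0 <= x <= 1.0
            assert x == pytest.approx(am.identity(b, a))

    def test_matches_dp_oracle_short_pairs(self, rng):
        for _ in range(100):
            a = random_dna(rng, int(rng.integers(5, 31)))
            b = random_dna(rng, int(rng.integers(5, 31)))
            assert am.identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            am.identity("", "ACGT")


# ---------------------------------------------------------------------------
# LCA assignment + refinement
# ---------------------------------------------------------------------------


def make_refs(taxonomy, seqs):
    recs = []
    for i, (species, seq) in enumerate(seqs.items()):
        lin = taxonomy.lineage_of_species(species)
        recs.append(am.ReferenceRecord(f"R{i}", seq, dict(lin)))
    return recs


def perturb(seq, n, rng):
    s = list(seq)
    pos = rng.choice(len(s), size=n, replace=False)
    for p in pos:
        s[p] = next(c for c in "ACGT" if c != s[p])
    return "".join(s)


class TestAssignLca:
    def test_single_best_species(self, taxonomy, rng):
        base = random_dna(rng, 100)
        refs = make_refs(
            taxonomy,
            {"Niviventer confucianus": base, "Apodemus draco": perturb(base, 20, rng)},
        )
        asg = am.assign_lca("q", perturb(base, 1, rng), refs, taxonomy)
        assert asg.rank == "species" and asg.taxon == "Niviventer confucianus"
        assert asg.max_identity == pytest.approx(0.99)

    def test_tie_within_genus_gives_genus(self, taxonomy, rng):
        base = random_dna(rng, 100)
        refs = make_refs(
            taxonomy,
            {"Niviventer confucianus": base, "Niviventer excelsior": base},
        )
        asg = am.assign_lca("q", base, refs, taxonomy)
        assert (asg.taxon, asg.rank) == ("Niviventer", "genus")

    def test_tie_across_orders_gives_class(self, taxonomy, rng):
        base = random_dna(rng, 100)
        refs = make_refs(
            taxonomy, {"Niviventer confucianus": base, "Ochotona curzoniae": base}
        )
        asg = am.assign_lca("q", base, refs, taxonomy)
        assert (asg.taxon, asg.rank) == ("Mammalia", "class_name")


class TestRefinement:
    def local(self, *names):
        return am.LocalSpeciesList(species=set(names))

    def asg(self, ident, *best):
        return am.TaxonAssignment("q", None, None, ident, set(best))

    def test_rule1_single_local_species(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.99, "Niviventer confucianus"),
            self.local("Niviventer confucianus"),
            taxonomy,
        )
        assert (a.taxon, a.rank, a.rule_applied) == ("Niviventer confucianus", "species", 1)

    def test_rule2_tie_resolved_by_unique_local(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.99, "Niviventer confucianus", "Niviventer excelsior"),
            self.local("Niviventer excelsior", "Apodemus draco"),
            taxonomy,
        )
        assert (a.taxon, a.rank, a.rule_applied) == ("Niviventer excelsior", "species", 2)

    def test_rule2_multiple_locals_lca(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.99, "Niviventer confucianus", "Niviventer excelsior"),
            self.local("Niviventer confucianus", "Niviventer excelsior"),
            taxonomy,
        )
        assert (a.taxon, a.rank, a.rule_applied) == ("Niviventer", "genus", 2)

    def test_rule3_local_top_hits_lca(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.96, "Ochotona curzoniae"),
            self.local("Ochotona curzoniae"),
            taxonomy,
        )
        assert (a.taxon, a.rank, a.rule_applied) == ("Ochotona curzoniae", "species", 3)

    def test_rule3_nonlocal_top_hit_substituted_by_congener(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.96, "Ochotona curzoniae"),
            self.local("Ochotona thibetana"),
            taxonomy,
        )
        assert (a.taxon, a.rule_applied, a.substituted) == ("Ochotona thibetana", 3, True)

    def test_rule3_no_congener_walks_up_to_local_taxon(self, taxonomy):
        # stoat at 94%: no local Mustela, nearest containing taxon with a
        # local member is the family
        a = am.refine_assignment(
            self.asg(0.94, "Mustela erminea"),
            self.local("Tragopan temminckii", "Hirundo rustica"),
            taxonomy,
        )
        assert a.rule_applied == 3
        assert a.rank in ("family", "order", "class_name", "root")
        assert a.taxon in ("Mustelidae", "Carnivora", "Mammalia", "Vertebrata")

    def test_below_094_discarded(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.93, "Mustela erminea"), self.local("Mustela erminea"), taxonomy
        )
        assert a.rule_applied == "discarded_low_identity"
        assert a.taxon is None and a.reason is not None

    def test_boundary_098_is_species_rule(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.98, "Gallus gallus"), self.local("Gallus gallus"), taxonomy
        )
        assert a.rule_applied == 1

    def test_boundary_094_is_rule3(self, taxonomy):
        a = am.refine_assignment(
            self.asg(0.94, "Gallus gallus"), self.local("Gallus gallus"), taxonomy
        )
        assert a.rule_applied == 3

    def test_refined_rank_never_below_lca_unless_flagged(self, taxonomy, rng):
        species = [r[0] for r in __import__("conftest").TAXONOMY_ROWS]
        for _ in range(50):
            k = int(rng.integers(1, 4))
            best = set(rng.choice(species, size=k, replace=False))
            ident = float(rng.uniform(0.90, 1.0))
            local = set(rng.choice(species, size=int(rng.integers(1, 6)), replace=False))
            provisional = am.TaxonAssignment("q", *taxonomy.lca(best), ident, set(best))
            prov_depth = taxonomy.rank_depth(provisional.rank)
            a = am.refine_assignment(
                am.TaxonAssignment("q", None, None, ident, set(best)),
                am.LocalSpeciesList(species=local),
                taxonomy,
            )
            if a.rule_applied == "discarded_low_identity":
                continue
            if taxonomy.rank_depth(a.rank) < prov_depth:
                # only local knowledge may sharpen the rank, and that path is
                # species-level via rules 2/3
                assert a.rank == "species"
                assert a.substituted or a.taxon in local


# ---------------------------------------------------------------------------
# per-sample filter
# ---------------------------------------------------------------------------


class TestPerSampleFilter:
    def build(self, counts, neg=None, assignments=None, predator="Prionailurus bengalensis"):
        df = pd.DataFrame(counts)
        negdf = pd.DataFrame(neg, index=df.index) if neg is not None else None
        assignments = assignments or {s: f"T{s}" for s in df.index}
        return am.per_sample_filter(
            df, negdf, assignments, {c: predator for c in df.columns}
        )

    def test_low_count_removed_at_49(self):
        res = self.build({"S1": pd.Series({"a": 49, "b": 9951})})
        assert res.counts.loc["a", "S1"] == 0
        assert res.counts.loc["b", "S1"] == 9951
        assert set(res.removed.reason) == {"below_min_reads"}

    def test_50_reads_kept(self):
        res = self.build({"S1": pd.Series({"a": 50, "b": 9950})})
        assert res.counts.loc["a", "S1"] == 50

    def test_below_point1_percent_removed(self):
        # 60 reads clear the 50-read floor but are <0.1% of a 100k sample
        res = self.build({"S1": pd.Series({"a": 60, "b": 99940})})
        assert res.counts.loc["a", "S1"] == 0
        assert "below_min_frac" in set(res.removed.reason)

    def test_negative_control_dominates(self):
        res = self.build(
            {"S1": pd.Series({"a": 200, "b": 9800})},
            neg={"NC1": pd.Series({"a": 250, "b": 0})},
        )
        assert res.counts.loc["a", "S1"] == 0
        assert "negative_control" in set(res.removed.reason)

    def test_predator_removed_regardless_of_count(self):
        res = self.build(
            {"S1": pd.Series({"cat": 3000, "b": 7000})},
            assignments={"cat": "Prionailurus bengalensis", "b": "Tb"},
        )
        assert res.counts.loc["cat", "S1"] == 0
        assert res.counts.loc["b", "S1"] == 7000

    def test_human_removed_and_empty_sample_flagged(self):
        res = self.build(
            {"S1": pd.Series({"h": 9000})}, assignments={"h": "Homo sapiens"}
        )
        assert res.no_food_samples == ["S1"]


# ---------------------------------------------------------------------------
# 2% collapse
# ---------------------------------------------------------------------------


def oracle_single_linkage(seqs, threshold):
    """Union-find oracle over all pairs."""
    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if am.identity(seqs[i], seqs[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), set()).add(seqs[i])
    return {frozenset(g) for g in groups.values()}


class TestCollapse:
    def table(self, seqs, counts):
        return pd.DataFrame({"S1": counts}, index=seqs)

    def test_one_substitution_same_species_one_taxon(self, taxonomy, rng):
        a = random_dna(rng, 100)
        b = perturb(a, 1, rng)
        tbl, meta = am.collapse_taxa(
            self.table([a, b], [900, 100]),
            {a: "Gallus gallus", b: "Gallus gallus"},
            taxonomy,
        )
        assert list(tbl.index) == ["Gallus gallus"]
        assert tbl.loc["Gallus gallus", "S1"] == 1000

    def test_five_percent_divergence_two_taxa(self, taxonomy, rng):
        a = random_dna(rng, 100)
        b = perturb(a, 5, rng)
        tbl, _ = am.collapse_taxa(
            self.table([a, b], [900, 100]),
            {a: "Gallus gallus", b: "Tragopan temminckii"},
            taxonomy,
        )
        assert len(tbl) == 2

    def test_chain_joins_by_single_linkage(self, taxonomy, rng):
        a = random_dna(rng, 100)
        b = perturb(a, 1, rng)
        c = perturb(b, 1, rng)  # a~c at ~0.98 or less, still one cluster via b
        tbl, meta = am.collapse_taxa(
            self.table([a, b, c], [500, 400, 300]),
            {s: "Gallus gallus" for s in (a, b, c)},
            taxonomy,
        )
        assert len(tbl) == 1
        assert oracle_single_linkage([a, b, c], 0.98) == {frozenset({a, b, c})}

    def test_random_instances_match_union_find_oracle(self, taxonomy, rng):
        for _ in range(5):
            base = random_dna(rng, 100)
            seqs = list({perturb(base, int(rng.integers(0, 7)), rng) for _ in range(6)})
            tbl, meta = am.collapse_taxa(
                self.table(seqs, list(rng.integers(100, 1000, len(seqs)))),
                {s: "Gallus gallus" for s in seqs},
                taxonomy,
            )
            expected = oracle_single_linkage(seqs, 0.98)
            got = {frozenset(tm.member_ids) for tm in meta}
            assert got == expected

    def test_label_from_most_abundant_member(self, taxonomy, rng):
        a = random_dna(rng, 100)
        b = perturb(a, 1, rng)
        tbl, _ = am.collapse_taxa(
            self.table([a, b], [100, 900]),
            {a: "Gallus gallus", b: "Tragopan temminckii"},
            taxonomy,
        )
        assert list(tbl.index) == ["Tragopan temminckii"]

    def test_idempotent(self, taxonomy, rng):
        seqs = [random_dna(rng, 100) for _ in range(4)]
        tbl, meta = am.collapse_taxa(
            self.table(seqs, [400, 300, 200, 100]),
            {s: sp for s, sp in zip(seqs, ["Gallus gallus", "Tragopan temminckii",
                                           "Apodemus draco", "Ochotona curzoniae"])},
            taxonomy,
        )
        # re-collapse using the cluster label sequences
        label_seqs = [tm.label_sequence_id for tm in meta]
        tbl2, _ = am.collapse_taxa(
            pd.DataFrame({"S1": tbl["S1"].to_numpy()}, index=label_seqs),
            {tm.label_sequence_id: tm.taxon for tm in meta},
            taxonomy,
        )
        assert sorted(tbl2.index) == sorted(tbl.index)
        assert tbl2["S1"].sum() == tbl["S1"].sum()


# ---------------------------------------------------------------------------
# predator identification
# ---------------------------------------------------------------------------


class TestIdentifyPredator:
    def test_exact_match(self):
        refs = simdata.PREDATOR_16S
        lpc = refs["Prionailurus bengalensis"]
        assert am.identify_predator(lpc, refs) == "Prionailurus bengalensis"

    def test_below_threshold_unknown(self, rng):
        refs = simdata.PREDATOR_16S
        lpc = refs["Prionailurus bengalensis"]
        # 2 substitutions in 60 nt → ~0.967 identity
        assert am.identify_predator(perturb(lpc, 2, rng), refs) == "unknown"

    def test_divergent_fragment_matches_other_felid(self):
        refs = simdata.PREDATOR_16S
        agc = refs["Catopuma temminckii"]
        n_diff = sum(a != b for a, b in zip(*refs.values()))
        assert n_diff == 15
        assert am.identify_predator(agc, refs) == "Catopuma temminckii"

    def test_tie_is_ambiguous(self):
        refs = {"A": "ACGTACGTAC", "B": "ACGTACGTAC"}
        assert am.identify_predator("ACGTACGTAC", refs) == "ambiguous"
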