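"""Synthetic faecal-metabarcoding data: reference databases, tag schemes and reads.

The generator emulates a tag-multiplexed paired-end amplicon run on faecal
DNA: each PCR carries a unique 9-nt tag (``CC`` + 7 variable nucleotides,
pairwise Hamming distance >= 3) on both primers; inserts are ~100 bp
vertebrate barcode fragments; both 100-nt mates overlap across the insert.
Noise knobs cover uniform per-base substitution error, tag jumps (a read
emitted under another PCR's tag pair), incomplete suppression of the
predator's own template by a blocking oligonucleotide, low-level human
contamination, and template-free negative-control PCRs that receive only
contaminant reads. Ground truth (per-sample diet profiles and per-read
origins) is returned alongside so recovery can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import DNA, revcomp
from .errors import (
    DuplicateSpeciesError,
    SimulationError,
    TagCapacityError,
    ValidationError,
)
from .reads import TaggedReadPair

__all__ = [
    "FWD_PRIMER",
    "REV_PRIMER",
    "PREDATOR_16S",
    "LINEAGE_RANKS",
    "TaxonRef",
    "SourceRecord",
    "ReferenceDB",
    "TagScheme",
    "SimConfig",
    "DietProfile",
    "SimulatedRun",
    "generate_reference_db",
    "generate_tag_scheme",
    "simulate_run",
    "random_taxa_pool",
    "table1_taxa_pool",
    "write_fastq",
]

# 12SV5 vertebrate barcode primers (~100 bp insert).
FWD_PRIMER = "TTAGATACCCCACTATGC"
REV_PRIMER = "TAGAACAGGCTCCTCTAG"

LINEAGE_RANKS = ("species", "genus", "family", "order", "class_name")

HIGH_Q = 40
ERROR_Q = 10
READ_LEN = 100

# Short diagnostic fragments of the predator-identification mitochondrial
# marker for the two felids; they differ at exactly 15 positions, mirroring
# the real diagnostic divergence between the two species' sequences.
PREDATOR_16S = {
    "Prionailurus bengalensis": (
        "ACCGCTTAGCCATCAAGGTCTTGGCATAACGGACTTCCAATGACCAACTAGCTGTCCAAG"
    ),
    "Catopuma temminckii": (
        "ACCACATCACAAACACGGTCTTGGCCTAACGACCTTACAATGACCAACTCACTGTCAACG"
    ),
}


@dataclass(frozen=True)
class TaxonRef:
    """One pool member: species name, full lineage and (optionally) a source sequence."""

    species: str
    lineage: dict
    sequence: str | None = None


@dataclass(frozen=True)
class SourceRecord:
    record_id: str
    species: str
    lineage: dict
    sequence: str  # full source sequence, primer sites included


@dataclass
class ReferenceDB:
    """Reference source sequences plus their taxonomy table."""

    records: list

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {"record_id": r.record_id, **{rank: r.lineage.get(rank, "") for rank in LINEAGE_RANKS}}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.record_id} {r.species}\n{r.sequence}\n")

    def write_taxonomy(self, path) -> None:
        self.taxonomy_frame().to_csv(path, sep="\t", index=False)

    def record_for(self, species: str) -> SourceRecord:
        for r in self.records:
            if r.species == species:
                return r
        raise KeyError(species)


# ---------------------------------------------------------------------------
# reference database generation
# ---------------------------------------------------------------------------


def _check_lineage_tree(records) -> None:
    """Every taxon name must have a single parent at the next rank up."""
    parent_of: dict[tuple[str, str], str] = {}
    for r in records:
        for child_rank, parent_rank in zip(LINEAGE_RANKS[:-1], LINEAGE_RANKS[1:]):
            child = r.lineage.get(child_rank)
            parent = r.lineage.get(parent_rank)
            if not child or not parent:
                raise ValidationError(
                    f"{r.species}: lineage must fill ranks {LINEAGE_RANKS}"
                )
            key = (child_rank, child)
            if key in parent_of and parent_of[key] != parent:
                raise ValidationError(
                    f"rank conflict: {child_rank} {child!r} maps to both "
                    f"{parent_of[key]!r} and {parent!r}"
                )
            parent_of[key] = parent


def generate_reference_db(
    taxa_pool,
    flank_primers: tuple[str, str] = (FWD_PRIMER, REV_PRIMER),
    seed: int = 0,
    insert_len_range: tuple[int, int] = (90, 105),
    flank_len: int = 15,
) -> ReferenceDB:
    """Build a reference database for a taxon pool, inventing sequences as needed.

    Pool members without a sequence receive a random insert (length drawn from
    ``insert_len_range``, inside the 60–120 nt band typical of the barcode)
    framed by the primer sites and random flanks; members with a sequence are
    stored verbatim. Deterministic given ``seed``. Duplicate species names and
    inconsistent lineages are rejected.
    """
    pool = list(taxa_pool)
    if not pool:
        raise ValidationError("taxa_pool must be nonempty")
    names = [t.species for t in pool]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise DuplicateSpeciesError(f"duplicate species in pool: {dup}")
    lo, hi = insert_len_range
    if not 60 <= lo <= hi <= 120:
        raise ValidationError("insert_len_range must lie within [60, 120]")
    fwd, rev = flank_primers
    rng = np.random.default_rng(seed)
    records = []
    for i, t in enumerate(pool):
        lineage = dict(t.lineage)
        lineage.setdefault("species", t.species)
        if t.sequence is not None:
            seq = t.sequence
        else:
            ins_len = int(rng.integers(lo, hi + 1))
            insert = "".join(rng.choice(list(DNA), ins_len))
            flank5 = "".join(rng.choice(list(DNA), flank_len))
            flank3 = "".join(rng.choice(list(DNA), flank_len))
            seq = flank5 + fwd + insert + revcomp(rev) + flank3
        records.append(SourceRecord(f"REF{i + 1:04d}", t.species, lineage, seq))
    _check_lineage_tree(records)
    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# tag scheme
# ---------------------------------------------------------------------------


@dataclass
class TagScheme:
    """PCR tags (``CC`` + 7 variable nt, pairwise distance >= 3) and their PCR map."""

    tags: list
    tag_to_pcr: dict  # (fwd_tag, rev_tag) -> pcr_id

    def validate(self) -> None:
        for t in self.tags:
            if len(t) != 9 or not t.startswith("CC") or any(b not in DNA for b in t[2:]):
                raise ValidationError(f"bad tag {t!r}")
        arr = np.array([[ord(c) for c in t] for t in self.tags], dtype=np.uint8)
        for i in range(len(self.tags)):
            d = (arr[i] != arr[i + 1 :]).sum(axis=1)
            if (d < 3).any():
                j = i + 1 + int(np.argmax(d < 3))
                raise ValidationError(
                    f"tags {self.tags[i]} and {self.tags[j]} are closer than distance 3"
                )
        if len(set(self.tag_to_pcr.values())) != len(self.tag_to_pcr):
            raise ValidationError("two tag pairs map to one PCR id")

    @property
    def pcr_ids(self) -> list:
        return list(self.tag_to_pcr.values())

    def pair_for(self, pcr_id: str) -> tuple[str, str]:
        for pair, pcr in self.tag_to_pcr.items():
            if pcr == pcr_id:
                return pair
        raise KeyError(pcr_id)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"forward_tag": f, "reverse_tag": r, "pcr_id": p}
                for (f, r), p in self.tag_to_pcr.items()
            ]
        )


def generate_tag_scheme(n_pcrs: int, seed: int = 0, pcr_ids=None) -> TagScheme:
    """Greedily pick ``n_pcrs`` distance-3 tags from the shuffled CCNNNNNNN space.

    Each PCR uses the same tag on the forward and reverse primer, so a
    tag-jump chimera (mixed pair) matches no registered PCR. Raises
    :class:`TagCapacityError` when the code space is exhausted.
    """
    if n_pcrs < 1:
        raise ValidationError("n_pcrs must be >= 1")
    if pcr_ids is None:
        pcr_ids = [f"PCR{i + 1:03d}" for i in range(n_pcrs)]
    if len(pcr_ids) != n_pcrs:
        raise ValidationError("pcr_ids length must equal n_pcrs")
    rng = np.random.default_rng(seed)
    candidates = np.array(list(itertools.product(range(4), repeat=7)), dtype=np.uint8)
    rng.shuffle(candidates, axis=0)
    accepted: list[np.ndarray] = []
    for cand in candidates:
        if len(accepted) == n_pcrs:
            break
        if accepted:
            dists = (np.stack(accepted) != cand).sum(axis=1)
            if (dists < 3).any():
                continue
        accepted.append(cand)
    if len(accepted) < n_pcrs:
        raise TagCapacityError(
            f"only {len(accepted)} distance-3 tags available, {n_pcrs} requested"
        )
    tags = ["CC" + "".join(DNA[b] for b in row) for row in accepted]
    scheme = TagScheme(tags=tags, tag_to_pcr={(t, t): p for t, p in zip(tags, pcr_ids)})
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# run simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of one synthetic sequencing run.

    Noise defaults are realistic for a modern short-read run: 1e-3 per-base
    substitution error, 1% tag jumps, 90% blocking of the predator template
    (which makes up ``predator_prior_share`` of amplifiable DNA before
    blocking), and 0.1% human contamination. ``min_prey_fraction`` floors each
    true prey's within-sample proportion so that a true item is sequenced well
    above the per-sample detection threshold at the default depth.
    """

    taxa_pool: list
    n_samples: int = 20
    predator_species: str = "Prionailurus bengalensis"
    taxa_per_sample_range: tuple[int, int] = (1, 7)
    abundance_skew: float = 1.0
    per_base_error_rate: float = 0.001
    tag_jump_rate: float = 0.01
    blocking_efficiency: float = 0.9
    contaminant_rate: float = 0.001
    reads_per_sample: int = 1500
    n_negative_controls: int = 7
    seed: int = 0
    predator_prior_share: float = 0.6
    min_prey_fraction: float = 0.08
    contaminant_species: str = "Homo sapiens"

    def __post_init__(self) -> None:
        for name in (
            "per_base_error_rate",
            "tag_jump_rate",
            "blocking_efficiency",
            "contaminant_rate",
            "predator_prior_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_sample <= 0 or self.n_samples <= 0:
            raise ValidationError("reads_per_sample and n_samples must be positive")
        lo, hi = self.taxa_per_sample_range
        if not 1 <= lo <= hi <= len(self.taxa_pool):
            raise ValidationError(
                "taxa_per_sample_range must lie within [1, len(taxa_pool)]"
            )
        if self.abundance_skew <= 0:
            raise ValidationError("abundance_skew must be positive")
        if self.min_prey_fraction * hi >= 1.0:
            raise ValidationError("min_prey_fraction too large for taxa_per_sample_range")


@dataclass
class DietProfile:
    """Ground-truth prey mixture of one sample."""

    sample_id: str
    true_taxa: list
    true_proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.true_proportions, dtype=float)
        if len(self.true_taxa) != p.size:
            raise ValidationError("one proportion per true taxon")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("true_proportions must sum to 1")
        self.true_proportions = p


@dataclass
class SimulatedRun:
    """Everything one synthetic run produced, ground truth included."""

    config: SimConfig
    tag_scheme: TagScheme
    reference_db: ReferenceDB
    reads: list  # TaggedReadPair
    profiles: list  # DietProfile
    metadata: pd.DataFrame
    truth: pd.DataFrame  # read_id, origin_pcr, emitted_pcr, taxon
    sample_ids: list
    control_ids: list

    @property
    def local_species(self) -> set:
        return {r.species for r in self.reference_db.records}

    def write(self, out_dir) -> dict:
        """Write FASTQ/FASTA/TSV outputs; returns the path map."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "r1": os.path.join(out_dir, "reads_R1.fastq"),
            "r2": os.path.join(out_dir, "reads_R2.fastq"),
            "reference": os.path.join(out_dir, "reference.fasta"),
            "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
            "tags": os.path.join(out_dir, "tag_map.tsv"),
            "metadata": os.path.join(out_dir, "metadata.tsv"),
            "truth": os.path.join(out_dir, "truth.tsv"),
        }
        write_fastq(paths["r1"], ((p.read_id, p.seq1, p.qual1) for p in self.reads))
        write_fastq(paths["r2"], ((p.read_id, p.seq2, p.qual2) for p in self.reads))
        self.reference_db.write_fasta(paths["reference"])
        self.reference_db.write_taxonomy(paths["taxonomy"])
        self.tag_scheme.frame().to_csv(paths["tags"], sep="\t", index=False)
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def write_fastq(path, records) -> None:
    """Write (id, seq, phred array) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            qstr = "".join(chr(int(q) + 33) for q in qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


PREDATOR_LINEAGES = {
    "Prionailurus bengalensis": {
        "species": "Prionailurus bengalensis",
        "genus": "Prionailurus",
        "family": "Felidae",
        "order": "Carnivora",
        "class_name": "Mammalia",
    },
    "Catopuma temminckii": {
        "species": "Catopuma temminckii",
        "genus": "Catopuma",
        "family": "Felidae",
        "order": "Carnivora",
        "class_name": "Mammalia",
    },
}

HUMAN_LINEAGE = {
    "species": "Homo sapiens",
    "genus": "Homo",
    "family": "Hominidae",
    "order": "Primates",
    "class_name": "Mammalia",
}


def _locate_insert(record: SourceRecord, fwd: str, rev: str) -> str:
    """Insert between the exact primer sites of a source record, or error."""
    i = record.sequence.find(fwd)
    if i < 0:
        raise SimulationError(f"record {record.record_id} lacks the forward primer site")
    j = record.sequence.find(revcomp(rev), i + len(fwd))
    if j < 0:
        raise SimulationError(f"record {record.record_id} lacks the reverse primer site")
    return record.sequence[i + len(fwd) : j]


def _mutate(seq: str, rng, rate: float) -> tuple[str, np.ndarray]:
    """Substitute bases at ``rate``; Phred 40 everywhere except 10 at error sites."""
    qual = np.full(len(seq), HIGH_Q, dtype=np.uint8)
    if rate <= 0:
        return seq, qual
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, qual
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        alternatives = [b for b in DNA if b != s[p]]
        s[p] = alternatives[rng.integers(3)]
        qual[p] = ERROR_Q
    return "".join(s), qual


def simulate_run(
    config: SimConfig,
    tag_scheme: TagScheme | None = None,
    reference_db: ReferenceDB | None = None,
) -> SimulatedRun:
    """Simulate one tagged paired-end run with ground truth.

    The reference database (built from the prey pool plus the predator and a
    human contaminant record when not supplied) provides the amplified
    templates. Per sample the read mixture is: prey proportions drawn from a
    floored symmetric Dirichlet, predator template at
    ``predator_prior_share × (1 − blocking_efficiency)`` of its pre-blocking
    share, and human contamination at ``contaminant_rate``. Negative controls
    receive only a Poisson-thin spray of contaminant reads. A
    ``tag_jump_rate`` fraction of reads is emitted under another random PCR's
    tag pair; per-read truth records both origins.
    """
    rng = np.random.default_rng(config.seed)
    pool_names = [t.species for t in config.taxa_pool]

    if reference_db is None:
        extra = []
        if config.predator_species not in pool_names:
            lin = PREDATOR_LINEAGES.get(
                config.predator_species,
                {
                    "species": config.predator_species,
                    "genus": config.predator_species.split()[0],
                    "family": "Felidae",
                    "order": "Carnivora",
                    "class_name": "Mammalia",
                },
            )
            extra.append(TaxonRef(config.predator_species, lin))
        if config.contaminant_species not in pool_names:
            extra.append(TaxonRef(config.contaminant_species, HUMAN_LINEAGE))
        reference_db = generate_reference_db(
            list(config.taxa_pool) + extra, seed=config.seed
        )

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    control_ids = [f"NC{i + 1:02d}" for i in range(config.n_negative_controls)]
    if tag_scheme is None:
        tag_scheme = generate_tag_scheme(
            len(sample_ids) + len(control_ids),
            seed=config.seed,
            pcr_ids=sample_ids + control_ids,
        )
    else:
        missing = set(sample_ids + control_ids) - set(tag_scheme.pcr_ids)
        if missing:
            raise ValidationError(f"tag scheme lacks PCRs for {sorted(missing)}")

    inserts = {
        r.species: _locate_insert(r, FWD_PRIMER, REV_PRIMER) for r in reference_db.records
    }
    tag_of = {pcr: tag_scheme.pair_for(pcr)[0] for pcr in tag_scheme.pcr_ids}
    all_pcrs = sample_ids + control_ids

    profiles: list[DietProfile] = []
    meta_rows = []
    reads: list[TaggedReadPair] = []
    truth_rows = []
    read_no = 0

    def emit(origin_pcr: str, taxon: str, count: int) -> None:
        nonlocal read_no
        insert = inserts[taxon]
        for _ in range(count):
            emitted = origin_pcr
            if config.tag_jump_rate > 0 and rng.random() < config.tag_jump_rate:
                others = [p for p in all_pcrs if p != origin_pcr]
                emitted = others[rng.integers(len(others))]
            tag = tag_of[emitted]
            amplicon = (
                tag + FWD_PRIMER + insert + revcomp(REV_PRIMER) + revcomp(tag)
            )
            m1 = amplicon[:READ_LEN]
            m2 = revcomp(amplicon)[:READ_LEN]
            s1, q1 = _mutate(m1, rng, config.per_base_error_rate)
            s2, q2 = _mutate(m2, rng, config.per_base_error_rate)
            read_no += 1
            rid = f"read{read_no:07d}"
            reads.append(TaggedReadPair(rid, s1, q1, s2, q2))
            truth_rows.append(
                {"read_id": rid, "origin_pcr": origin_pcr, "emitted_pcr": emitted, "taxon": taxon}
            )

    lo, hi = config.taxa_per_sample_range
    floor = config.min_prey_fraction
    for sid in sample_ids:
        k = int(rng.integers(lo, hi + 1))
        chosen_idx = rng.choice(len(pool_names), size=k, replace=False)
        chosen = [pool_names[i] for i in sorted(chosen_idx)]
        raw = rng.dirichlet(np.full(k, config.abundance_skew))
        props = floor + (1.0 - k * floor) * raw
        profiles.append(DietProfile(sid, chosen, props / props.sum()))

        w_pred = config.predator_prior_share * (1.0 - config.blocking_efficiency)
        w_prey = 1.0 - config.predator_prior_share
        base = np.concatenate([props * w_prey, [w_pred]])
        base = base / base.sum()
        mix = np.concatenate(
            [base * (1.0 - config.contaminant_rate), [config.contaminant_rate]]
        )
        taxa = chosen + [config.predator_species, config.contaminant_species]
        counts = rng.multinomial(config.reads_per_sample, mix)
        for taxon, c in zip(taxa, counts):
            if c > 0:
                emit(sid, taxon, int(c))

        meta_rows.append(
            {
                "sample_id": sid,
                "predator": config.predator_species,
                "season": ("spring", "autumn")[int(rng.integers(2))],
                "altitude_m": float(np.round(rng.uniform(1250, 3200), 0)),
                "latitude": float(np.round(32.5 + rng.uniform(-0.1, 0.1), 5)),
                "longitude": float(np.round(104.6 + rng.uniform(-0.1, 0.1), 5)),
            }
        )

    contaminant_pool = pool_names + [config.contaminant_species]
    for cid in control_ids:
        n_cont = int(rng.poisson(config.contaminant_rate * config.reads_per_sample))
        for _ in range(n_cont):
            taxon = contaminant_pool[rng.integers(len(contaminant_pool))]
            emit(cid, taxon, 1)

    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin_pcr", "emitted_pcr", "taxon"])
    metadata = pd.DataFrame(meta_rows)
    return SimulatedRun(
        config=config,
        tag_scheme=tag_scheme,
        reference_db=reference_db,
        reads=reads,
        profiles=profiles,
        metadata=metadata,
        truth=truth,
        sample_ids=sample_ids,
        control_ids=control_ids,
    )


# ---------------------------------------------------------------------------
# convenience pools
# ---------------------------------------------------------------------------

_ORDER_CYCLE = [
    ("Rodentia", "Muridae", "Mammalia"),
    ("Galliformes", "Phasianidae", "Aves"),
    ("Soricomorpha", "Soricidae", "Mammalia"),
    ("Passeriformes", "Turdidae", "Aves"),
    ("Artiodactyla", "Bovidae", "Mammalia"),
]


def random_taxa_pool(n_taxa: int, seed: int = 0) -> list:
    """Synthetic prey pool with simple but consistent lineages."""
    pool = []
    for i in range(n_taxa):
        order, family, klass = _ORDER_CYCLE[i % len(_ORDER_CYCLE)]
        genus = f"Genus{i + 1:02d}"
        species = f"Genus{i + 1:02d} preyi"
        pool.append(
            TaxonRef(
                species,
                {
                    "species": species,
                    "genus": genus,
                    "family": family,
                    "order": order,
                    "class_name": klass,
                },
            )
        )
    return pool


def table1_taxa_pool() -> list:
    """A 40-taxon pool with the lineages of the packaged occurrence fixture.

    Rows identified above species rank get placeholder leaf names so the pool
    is usable as simulation ground truth; lineage ranks above the identified
    rank are kept, the ones below are filled with per-row placeholders.
    """
    from .pipeline import load_table1_fixture

    counts, meta = load_table1_fixture()
    pool = []
    for taxon, row in meta.iterrows():
        genus = row["genus"] or f"{taxon.split()[0]}_gen"
        family = row["family"] or f"{genus}_fam"
        species = taxon if row["rank"] == "species" else f"{taxon} sp."
        pool.append(
            TaxonRef(
                species,
                {
                    "species": species,
                    "genus": genus,
                    "family": family,
                    "order": row["order"],
                    "class_name": row["class_name"],
                },
            )
        )
    return pool
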