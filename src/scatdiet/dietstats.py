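"""Dietary composition and niche statistics for occurrence (presence/absence) data.

The quantities follow the standard usage in carnivore diet studies:

* ``%FC`` — percent frequency of occurrence: the fraction of faecal samples
  that contain a food taxon, ``N_i / N`` where ``N`` counts samples containing
  at least one food item.
* ``%TX`` — proportion of occurrence: a taxon's occurrence count divided by the
  summed occurrences of all taxa; the ``%TX`` vector lies on the simplex and is
  the resource-use profile ``p`` used by all niche indices below.
* Levins' niche breadth ``B = 1 / Σ p_i²`` and its standardised form
  ``B_A = (B − 1)/(n − 1)`` on ``[0, 1]``.
* Shannon diversity ``H = −Σ p_i ln p_i`` and Pielou evenness ``J = H / ln n``.
* Pianka's niche overlap ``O_jk = Σ p_ij p_ik / sqrt(Σ p_ij² Σ p_ik²)``,
  with a label-permutation significance test.
* Wilson score intervals for binomial proportions, the exact Wilcoxon
  signed-rank test and Fisher's exact test for general R×C tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .errors import EnumerationBudgetError, TaxonLookupError, ValidationError

__all__ = [
    "OccurrenceMatrix",
    "DietSummary",
    "NicheStats",
    "OverlapResult",
    "WilcoxonResult",
    "FisherResult",
    "ALTITUDE_CLASSES",
    "AltitudeClasses",
    "percent_fc",
    "percent_tx",
    "levins_ba",
    "shannon_pielou",
    "niche_stats",
    "pianka_overlap",
    "pianka_overlap_test",
    "wilson_interval",
    "wilcoxon_signed_rank",
    "fisher_exact_rxc",
    "stratify",
    "season_from_month",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OccurrenceMatrix:
    """Samples × taxa presence matrix plus sample and taxon metadata.

    ``matrix`` holds 0/1 entries with sample ids as the index and taxon names
    as columns. Samples without any food taxon are dropped on construction
    (they do not enter diet denominators); their ids are kept in
    ``empty_samples``.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    taxon_meta: pd.DataFrame | None = None
    empty_samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("occurrence matrix entries must be 0/1")
        keep = self.matrix.sum(axis=1) > 0
        if not keep.all():
            self.empty_samples = list(self.matrix.index[~keep])
            self.matrix = self.matrix.loc[keep]
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.loc[self.matrix.index]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def counts(self) -> pd.Series:
        """Per-taxon occurrence counts N_i."""
        return self.matrix.sum(axis=0)

    def taxon_order(self, taxon: str) -> str:
        if self.taxon_meta is None or taxon not in self.taxon_meta.index:
            raise TaxonLookupError(taxon)
        return self.taxon_meta.loc[taxon, "order"]

    def subset(self, sample_ids) -> "OccurrenceMatrix":
        sub = self.matrix.loc[sample_ids]
        meta = self.sample_meta.loc[sample_ids] if self.sample_meta is not None else None
        return OccurrenceMatrix(sub, meta, self.taxon_meta)


@dataclass
class NicheStats:
    """Niche breadth/diversity indices for one resource-use profile."""

    B: float
    B_A: float | None
    H: float
    J: float | None
    n: int


@dataclass
class DietSummary:
    """Per-taxon and per-order composition of one group of samples."""

    label: str
    n_samples: int
    counts: pd.Series
    fc: pd.Series
    tx: pd.Series
    order_tx: pd.Series
    order_fc: pd.Series | None = None
    niche: NicheStats | None = None

    @property
    def n_taxa(self) -> int:
        return int((self.counts > 0).sum())


@dataclass
class OverlapResult:
    o_jk: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    groups: tuple


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    z: float | None
    p_value: float
    n: int  # pairs after zero-difference removal
    mode: str


@dataclass
class FisherResult:
    p_value: float
    method: str
    n_tables: int


# ---------------------------------------------------------------------------
# composition: %FC and %TX
# ---------------------------------------------------------------------------


def _counts_and_n(data, n_samples=None) -> tuple[pd.Series, int]:
    if isinstance(data, OccurrenceMatrix):
        return data.counts, data.n_samples
    counts = pd.Series(data).astype(float)
    if n_samples is None:
        raise ValidationError("n_samples is required when passing raw counts")
    return counts, int(n_samples)


def percent_fc(data, key: str, n_samples: int | None = None, taxon_meta=None) -> float:
    """Frequency of occurrence ``N_i / N`` of a taxon or a prey order.

    ``data`` may be an :class:`OccurrenceMatrix` or a Series of per-taxon
    occurrence counts (then ``n_samples`` is required). Order-level %FC counts
    the samples containing at least one taxon of the order, so it needs the
    per-sample matrix; from bare counts only taxon-level %FC is available.
    """
    if isinstance(data, OccurrenceMatrix):
        om = data
        if key in om.matrix.columns:
            return float(om.matrix[key].sum() / om.n_samples)
        if om.taxon_meta is not None and (om.taxon_meta["order"] == key).any():
            members = om.taxon_meta.index[om.taxon_meta["order"] == key]
            members = [t for t in members if t in om.matrix.columns]
            present = (om.matrix[members].sum(axis=1) > 0).sum()
            return float(present / om.n_samples)
        raise TaxonLookupError(key)
    counts, n = _counts_and_n(data, n_samples)
    if key in counts.index:
        return float(counts[key] / n)
    if taxon_meta is not None and (taxon_meta["order"] == key).any():
        raise ValidationError(
            "order-level %FC needs the per-sample matrix, not bare counts"
        )
    raise TaxonLookupError(key)


def percent_tx(data, level: str = "taxon", n_samples=None, taxon_meta=None) -> pd.Series:
    """Proportion-of-occurrence simplex vector at taxon or order level."""
    if isinstance(data, OccurrenceMatrix):
        counts = data.counts
        taxon_meta = data.taxon_meta if taxon_meta is None else taxon_meta
    else:
        counts = pd.Series(data).astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("cannot compute %TX of an empty occurrence table")
    if level == "taxon":
        return counts / total
    if level == "order":
        if taxon_meta is None:
            raise ValidationError("order-level %TX requires taxon metadata")
        orders = taxon_meta.loc[counts.index, "order"]
        return counts.groupby(orders).sum() / total
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# niche breadth, diversity, evenness
# ---------------------------------------------------------------------------


def _profile(counts) -> np.ndarray:
    c = pd.Series(counts).astype(float)
    c = c[c > 0]
    if c.empty:
        raise ValidationError("all-zero occurrence counts")
    return (c / c.sum()).to_numpy()


def levins_ba(counts) -> NicheStats:
    """Levins' niche breadth ``B`` and standardised ``B_A`` from counts.

    ``B_A`` needs at least two resource taxa; with ``n = 1`` the index is
    undefined and an error is raised.
    """
    p = _profile(counts)
    n = p.size
    B = 1.0 / float(np.sum(p * p))
    if n < 2:
        raise ValidationError("B_A is undefined for a single resource taxon")
    return NicheStats(B=B, B_A=(B - 1.0) / (n - 1.0), H=math.nan, J=None, n=n)


def shannon_pielou(counts) -> NicheStats:
    """Shannon diversity (natural log) and Pielou evenness from counts."""
    p = _profile(counts)
    n = p.size
    H = float(-np.sum(p * np.log(p)))
    J = H / math.log(n) if n >= 2 else None
    return NicheStats(B=math.nan, B_A=None, H=H, J=J, n=n)


def niche_stats(counts) -> NicheStats:
    """All four niche indices (B, B_A, H, J) for one profile."""
    lev = levins_ba(counts)
    sh = shannon_pielou(counts)
    return NicheStats(B=lev.B, B_A=lev.B_A, H=sh.H, J=sh.J, n=lev.n)


# ---------------------------------------------------------------------------
# Pianka overlap
# ---------------------------------------------------------------------------


def pianka_overlap(profile_j, profile_k) -> float:
    """Pianka's overlap of two resource-use profiles on a shared taxon universe."""
    pj = np.asarray(profile_j, dtype=float)
    pk = np.asarray(profile_k, dtype=float)
    if pj.shape != pk.shape:
        raise ValidationError("profiles must share one taxon universe")
    denom = math.sqrt(float(np.sum(pj * pj)) * float(np.sum(pk * pk)))
    if denom == 0:
        raise ValidationError("zero-norm resource profile")
    return float(np.sum(pj * pk) / denom)


def pianka_overlap_test(
    om: OccurrenceMatrix,
    by: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> OverlapResult:
    """Observed Pianka overlap between two sample groups plus a permutation p.

    The null shuffles the group labels across samples, recomputes the two %TX
    profiles, and counts permutations with overlap at least as large as
    observed; the p-value uses the ``(k + 1)/(n_perm + 1)`` correction.
    """
    if om.sample_meta is None or by not in om.sample_meta.columns:
        raise ValidationError(f"sample metadata lacks a {by!r} column")
    labels = om.sample_meta[by].to_numpy()
    groups = tuple(pd.unique(labels))
    if len(groups) != 2:
        raise ValidationError("overlap test requires exactly two groups")
    mat = om.matrix.to_numpy(dtype=float)

    def _overlap(lab) -> float:
        cj = mat[lab == groups[0]].sum(axis=0)
        ck = mat[lab == groups[1]].sum(axis=0)
        return pianka_overlap(cj / cj.sum(), ck / ck.sum())

    observed = _overlap(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _overlap(perm) >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return OverlapResult(observed, p, n_perm, seed, groups)


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clamped to [0, 1]."""
    if not 0 <= successes <= n or n < 1:
        raise ValidationError("need 0 <= successes <= n with n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(x, y, mode: str = "exact") -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; tied absolute differences get midranks. In
    ``exact`` mode the null distribution of W+ (sum of positive ranks) is built
    over all 2^m sign assignments; the two-sided p-value is
    ``P(|W+ − R/2| ≥ |w − R/2|)`` where ``R`` is the total rank sum (the
    distribution is symmetric about ``R/2`` under the null even with midranks).
    ``normal`` mode uses the tie-corrected Z approximation with a 0.5
    continuity correction toward the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    m = d.size
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(statistic=0.0, z=0.0, p_value=1.0, n=0, mode=mode)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # = m(m+1)/2

    if mode == "exact":
        # DP over the distribution of W+ using doubled ranks (midranks may be
        # half-integral). counts[s] = number of sign assignments with 2*W+ = s.
        r2 = np.rint(2 * ranks).astype(int)
        counts = np.zeros(int(r2.sum()) + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        support = np.arange(counts.size)  # values of 2*W+; centred at `total`
        dev = abs(2 * w_plus - total)
        tail = counts[np.abs(support - total) >= dev - 1e-9]
        p = float(tail.sum() / counts.sum())
        return WilcoxonResult(statistic=w_plus, z=None, p_value=min(p, 1.0), n=m, mode=mode)

    if mode == "normal":
        mu = m * (m + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - float(
            np.sum(tie_counts**3 - tie_counts)
        ) / 48.0
        if sigma2 <= 0:
            return WilcoxonResult(statistic=w_plus, z=0.0, p_value=1.0, n=m, mode=mode)
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(sigma2) if diff != 0 else 0.0
        p = 2.0 * float(stats.norm.sf(abs(z)))
        return WilcoxonResult(statistic=w_plus, z=float(z), p_value=min(p, 1.0), n=m, mode=mode)

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Fisher's exact test for R×C tables
# ---------------------------------------------------------------------------

_TIE_REL_TOL = 1e-12


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - float(gammaln(table + 1).sum())


def fisher_exact_rxc(
    table,
    method: str = "exact",
    max_tables: int = 5_000_000,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> FisherResult:
    """Fisher's exact test on an R×C contingency table of non-negative ints.

    ``exact`` enumerates every table with the observed margins (network
    recursion with margin-bound pruning) and sums the probabilities of tables
    no more probable than the observed one (relative tie tolerance 1e-12).
    When the enumeration would exceed ``max_tables`` an
    :class:`EnumerationBudgetError` suggests ``method="montecarlo"``, which
    samples tables with fixed margins (Patefield's algorithm via
    ``scipy.stats.random_table``) and applies the ``(k+1)/(n+1)`` estimator.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("table must be a 2-D array of non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValidationError("all margins must be positive")
    n = int(obs.sum())
    log_margin_const = float(
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    log_p_obs = _log_table_prob(obs, log_margin_const)
    log_cut = log_p_obs + math.log1p(_TIE_REL_TOL)

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols, seed=rng)
        samples = dist.rvs(n_mc, method="patefield").astype(int)
        logps = log_margin_const - gammaln(samples + 1).sum(axis=(1, 2))
        hits = int(np.sum(logps <= log_cut))
        return FisherResult(p_value=(hits + 1) / (n_mc + 1), method="montecarlo", n_tables=n_mc)

    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    r, c = obs.shape
    total_logp = 0.0
    tables_seen = 0

    def recurse(row_idx: int, col_rem: np.ndarray, partial_loggamma: float) -> None:
        nonlocal total_logp, tables_seen
        if row_idx == r - 1:
            tables_seen += 1
            if tables_seen > max_tables:
                raise EnumerationBudgetError(
                    "exact enumeration exceeds max_tables; use method='montecarlo'"
                )
            logp = (
                log_margin_const
                - partial_loggamma
                - float(gammaln(col_rem + 1).sum())
            )
            if logp <= log_cut:
                total_logp += math.exp(logp)
            return
        # enumerate row row_idx cell by cell
        row_total = int(rows[row_idx])

        def fill(col_idx: int, remaining: int, col_rem_inner: np.ndarray, lg: float) -> None:
            if col_idx == c - 1:
                last = remaining
                if last <= col_rem_inner[col_idx]:
                    nxt = col_rem_inner.copy()
                    nxt[col_idx] -= last
                    recurse(row_idx + 1, nxt, lg + float(gammaln(last + 1)))
                return
            # remaining must fit into the columns still open
            later_cap = int(col_rem_inner[col_idx + 1 :].sum())
            lo = max(0, remaining - later_cap)
            hi = min(remaining, int(col_rem_inner[col_idx]))
            for v in range(lo, hi + 1):
                nxt = col_rem_inner.copy()
                nxt[col_idx] -= v
                fill(col_idx + 1, remaining - v, nxt, lg + float(gammaln(v + 1)))

        fill(0, row_total, col_rem, partial_loggamma)

    recurse(0, cols.astype(int).copy(), 0.0)
    return FisherResult(p_value=min(total_logp, 1.0), method="exact", n_tables=tables_seen)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AltitudeClasses:
    """Left-closed altitude bins: [min,1500), [1500,2000), [2000,2500), [2500,max]."""

    edges: tuple = (1500.0, 2000.0, 2500.0)
    labels: tuple = ("low", "lower-middle", "higher-middle", "high")

    def classify(self, altitude_m: float) -> str:
        if altitude_m is None or (isinstance(altitude_m, float) and math.isnan(altitude_m)):
            raise ValidationError("missing altitude")
        idx = int(np.searchsorted(self.edges, altitude_m, side="right"))
        return self.labels[idx]


ALTITUDE_CLASSES = AltitudeClasses()

_SEASON_BY_MONTH = {3: "spring", 4: "spring", 5: "spring", 9: "autumn", 10: "autumn", 11: "autumn"}


def season_from_month(month: int) -> str | None:
    """Spring = March–May, autumn = September–November, else None (excluded)."""
    return _SEASON_BY_MONTH.get(int(month))


def summarize(om: OccurrenceMatrix, label: str = "all") -> DietSummary:
    """Composition summary (counts, %FC, %TX, order aggregates, niche indices)."""
    counts = om.counts
    fc = counts / om.n_samples
    tx = percent_tx(om, "taxon")
    order_tx = percent_tx(om, "order") if om.taxon_meta is not None else pd.Series(dtype=float)
    order_fc = None
    if om.taxon_meta is not None:
        orders = om.taxon_meta.loc[counts.index, "order"]
        order_fc = pd.Series(
            {
                o: (om.matrix[counts.index[orders == o]].sum(axis=1) > 0).mean()
                for o in orders.unique()
            }
        )
    niche = niche_stats(counts) if (counts > 0).sum() >= 2 else None
    return DietSummary(
        label=label,
        n_samples=om.n_samples,
        counts=counts,
        fc=fc,
        tx=tx,
        order_tx=order_tx,
        order_fc=order_fc,
        niche=niche,
    )


def summarize_counts(counts, n_samples: int, taxon_meta=None, label: str = "all") -> DietSummary:
    """Summary from bare occurrence counts (no per-sample matrix available)."""
    counts = pd.Series(counts).astype(int)
    fc = counts / n_samples
    tx = percent_tx(counts)
    order_tx = (
        percent_tx(counts, "order", taxon_meta=taxon_meta)
        if taxon_meta is not None
        else pd.Series(dtype=float)
    )
    niche = niche_stats(counts) if (counts > 0).sum() >= 2 else None
    return DietSummary(
        label=label,
        n_samples=n_samples,
        counts=counts,
        fc=fc,
        tx=tx,
        order_tx=order_tx,
        order_fc=None,
        niche=niche,
    )


def stratify(om: OccurrenceMatrix, by: str) -> dict:
    """Split samples by season, altitude_class or predator; one summary each.

    Samples with unusable metadata (missing altitude, months outside the
    spring/autumn windows) are excluded with a warning. Empty strata produce
    no summary rather than an error.
    """
    if om.sample_meta is None:
        raise ValidationError("stratification requires sample metadata")
    meta = om.sample_meta
    if by == "altitude_class":
        if "altitude_m" not in meta.columns:
            raise ValidationError("metadata lacks altitude_m")
        usable = meta["altitude_m"].notna()
        if not usable.all():
            warnings.warn(
                f"excluding {int((~usable).sum())} samples without altitude", stacklevel=2
            )
        key = meta.loc[usable, "altitude_m"].map(ALTITUDE_CLASSES.classify)
    elif by == "season":
        if "season" in meta.columns:
            key = meta["season"]
        elif "month" in meta.columns:
            key = meta["month"].map(lambda mo: season_from_month(mo))
            if key.isna().any():
                warnings.warn(
                    f"excluding {int(key.isna().sum())} samples outside spring/autumn",
                    stacklevel=2,
                )
            key = key.dropna()
        else:
            raise ValidationError("metadata lacks season/month")
    elif by == "predator":
        if "predator" not in meta.columns:
            raise ValidationError("metadata lacks predator")
        key = meta["predator"]
    else:
        raise ValueError(f"unknown stratification key {by!r}")

    out: dict[str, DietSummary] = {}
    for value in pd.unique(key):
        ids = key.index[key == value]
        if len(ids) == 0:
            continue
        out[str(value)] = summarize(om.subset(ids), label=str(value))
    return out
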