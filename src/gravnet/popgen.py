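"""Genetic distances, gene-flow response, pairwise F_ST and hierarchical AMOVA.

The central container is :class:`GenotypeMatrix`: biallelic diploid dosages
(0/1/2 copies of the alternate allele) for individuals x loci, with a
missing mask and a population label per individual.

Statistics follow the locus-by-locus AMOVA family: per-locus nested
analysis of variance on alleles (population / individual-within-population /
allele-within-individual strata), with variance components summed over loci
before forming F-statistics (ratio of sums, not mean of ratios).  Under this
decomposition the identity (1 - F_IT) = (1 - F_IS)(1 - F_ST) holds exactly.
F'_ST standardizes F_ST by its maximum attainable value, obtained by
recoding every population's alleles as population-private and recomputing.

Missing genotypes are handled listwise per locus (an individual missing at a
locus contributes no alleles there); the Euclidean genetic distance instead
uses pairwise-complete loci with a sqrt(L / L_complete) rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "DistanceMatrix",
    "AmovaResult",
    "euclidean_genetic_distance",
    "gene_flow",
    "pairwise_fst",
    "weir_cockerham_fst",
    "fst_permutation_test",
    "amova",
]

MISSING = -1  # dosage sentinel


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with missing mask and population labels.

    ``dosages`` is an ``(n_individuals, n_loci)`` integer array with values
    in {0, 1, 2} and :data:`MISSING` (-1) for missing calls.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    population_labels: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be individuals x loci")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosages must be 0/1/2 or missing (-1): biallelic encoding only")
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if len(self.population_labels) != self.dosages.shape[0]:
            raise ValueError("population_labels length mismatch")
        if not all(self.population_labels):
            raise ValueError("population labels must be non-empty")
        if (self.dosages == MISSING).all(axis=0).any():
            raise ValueError("a locus is entirely missing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, pops) -> "GenotypeMatrix":
        keep = np.array([p in set(pops) for p in self.population_labels])
        dos = self.dosages[keep]
        # drop loci that became entirely missing in the subset
        locus_keep = ~(dos == MISSING).all(axis=0)
        return GenotypeMatrix(
            dos[:, locus_keep],
            [i for i, k in zip(self.individual_ids, keep) if k],
            [p for p, k in zip(self.population_labels, keep) if k],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, index=self.individual_ids)
        df.insert(0, "population", self.population_labels)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        pops = df["population"].tolist()
        dos = df.drop(columns=["population"]).to_numpy(dtype=int)
        return cls(dos, [str(i) for i in df.index], [str(p) for p in pops])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix with a metric tag.

    ``gene_flow`` matrices hold similarities in [0, 1] (1 = identical);
    the two distance tags hold non-negative distances with a zero diagonal.
    """

    values: np.ndarray
    ids: list[str]
    metric_tag: str  # euclidean_genotype | gene_flow | geographic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


def euclidean_genetic_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between dosage vectors.

    Uses pairwise-complete loci and rescales each pair by
    sqrt(L / L_complete(i, j)) so that distances remain comparable across
    different amounts of missingness.  A pair sharing zero complete loci is
    an error.
    """
    if g.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    D = g.dosages.astype(float)
    M = (~g.missing_mask).astype(float)
    Dz = np.where(g.missing_mask, 0.0, D)
    sq = Dz ** 2
    # sum over loci complete in both i and j of (g_i - g_j)^2
    cross = Dz @ Dz.T
    si = sq @ M.T          # sum_j-complete g_i^2
    sj = M @ sq.T          # sum_i-complete g_j^2
    d2 = si + sj - 2 * cross
    lc = M @ M.T
    if (lc[~np.eye(len(lc), dtype=bool)] == 0).any():
        raise ValueError("a pair of individuals shares zero complete loci")
    with np.errstate(invalid="ignore"):
        d = np.sqrt(np.maximum(d2, 0.0) * (g.n_loci / np.maximum(lc, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(g.individual_ids), "euclidean_genotype")


def gene_flow(dist: DistanceMatrix) -> DistanceMatrix:
    """Gene flow = 1 - distance scaled by its observed maximum.

    Bounded in [0, 1], 1 on the diagonal, monotone decreasing in distance.
    """
    if dist.metric_tag != "euclidean_genotype":
        raise ValueError("gene_flow expects a euclidean_genotype matrix")
    dmax = np.nanmax(dist.values)
    if dmax == 0:
        warnings.warn("all distances are zero; gene flow set to 1 everywhere")
        flow = np.ones_like(dist.values)
    else:
        flow = 1.0 - dist.values / dmax
    return DistanceMatrix(flow, list(dist.ids), "gene_flow")


# ---------------------------------------------------------------------------
# AMOVA machinery
# ---------------------------------------------------------------------------


def _locus_components(dosages: np.ndarray, pop_idx: np.ndarray, n_pops: int):
    """Nested ANOVA sums of squares / df for one locus, vectorized over loci.

    ``dosages``: (n_ind, n_loci) with MISSING; ``pop_idx``: population index
    per individual.  Returns per-locus arrays
    (ss_wi, ss_ai, ss_ap, df_wi, df_ai, df_ap, n_c) where n_c is the
    variance-component coefficient for the population stratum in allele
    counts.
    """
    present = dosages != MISSING
    d = np.where(present, dosages, 0).astype(float)

    # per-pop allele sums and sizes (alleles = 2 per present individual)
    n_ind, n_loci = dosages.shape
    pop_onehot = np.zeros((n_pops, n_ind))
    pop_onehot[pop_idx, np.arange(n_ind)] = 1.0
    m_p = 2.0 * (pop_onehot @ present)              # alleles per pop per locus
    s_p = pop_onehot @ d                            # allele-count sums per pop
    M = m_p.sum(axis=0)                             # total alleles per locus
    S = s_p.sum(axis=0)

    het = (dosages == 1)
    # within-individual SS: alleles {0,1}; heterozygote contributes 0.5
    ss_wi = 0.5 * het.sum(axis=0).astype(float)

    # within-population SS on alleles: sum a^2 - (sum a)^2 / m
    # for 0/1 alleles sum a^2 = sum a
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_wp = s_p - np.where(m_p > 0, s_p ** 2 / np.where(m_p > 0, m_p, 1), 0.0)
    ss_wp = np.where(m_p > 0, ss_wp, 0.0)
    ss_ai = ss_wp.sum(axis=0) - ss_wi

    ss_total = S - np.where(M > 0, S ** 2 / np.where(M > 0, M, 1), 0.0)
    ss_ap = ss_total - ss_wp.sum(axis=0)

    n_present = present.sum(axis=0).astype(float)
    pops_present = (m_p > 0).sum(axis=0).astype(float)
    df_wi = n_present
    df_ai = n_present - pops_present
    df_ap = pops_present - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = np.where(df_ap > 0, (M - (m_p ** 2).sum(axis=0) / np.where(M > 0, M, 1)) / np.where(df_ap > 0, df_ap, 1), np.nan)
    return ss_wi, ss_ai, ss_ap, df_wi, df_ai, df_ap, n_c


def _variance_components(dosages, pop_idx, n_pops):
    """Summed-over-loci variance components (sigma2_within, sigma2_among_ind, sigma2_among_pop)."""
    ss_wi, ss_ai, ss_ap, df_wi, df_ai, df_ap, n_c = _locus_components(dosages, pop_idx, n_pops)
    usable = (df_ai > 0) & (df_ap > 0) & np.isfinite(n_c) & (n_c > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_wi = ss_wi / np.where(df_wi > 0, df_wi, 1)
        ms_ai = ss_ai / np.where(df_ai > 0, df_ai, 1)
        ms_ap = ss_ap / np.where(df_ap > 0, df_ap, 1)
    sig_w = ms_wi
    sig_i = (ms_ai - ms_wi) / 2.0
    sig_p = np.where(usable, (ms_ap - ms_ai) / np.where(usable, n_c, 1), 0.0)
    w = usable.astype(float)
    return (np.sum(sig_w * w), np.sum(sig_i * w), np.sum(sig_p * w))


def _private_allele_components(dosages, pop_idx, n_pops):
    """Variance components after recoding each population's alleles as private.

    With population-private alleles, allele distance is the 0/1 indicator of
    inequality; the within-individual stratum is unchanged (heterozygote
    alleles still differ) while between-population allele pairs always
    differ.  Sums of squares follow the distance-based AMOVA identity
    SS(group) = (1/m) * sum_{i<j in group} d2_ij computed from allele counts.
    """
    present = dosages != MISSING
    n_ind, n_loci = dosages.shape
    het = (dosages == 1)
    ss_wi = 0.5 * het.sum(axis=0).astype(float)

    pop_onehot = np.zeros((n_pops, n_ind))
    pop_onehot[pop_idx, np.arange(n_ind)] = 1.0
    m_p = 2.0 * (pop_onehot @ present)
    d = np.where(present, dosages, 0).astype(float)
    s_p = pop_onehot @ d                          # count of allele "1" per pop
    M = m_p.sum(axis=0)

    # within-pop: alleles take two possible original values (0/1) but are
    # private to the pop, so within-pop pair distances are as before
    with np.errstate(divide="ignore", invalid="ignore"):
        pairs_diff_wp = s_p * (m_p - s_p)          # unordered unequal pairs
        ss_wp = np.where(m_p > 0, pairs_diff_wp / np.where(m_p > 0, m_p, 1), 0.0)
    ss_ai = ss_wp.sum(axis=0) - ss_wi

    # total: every between-pop pair differs (private alleles)
    same_pairs = (s_p * (s_p - 1) / 2 + (m_p - s_p) * (m_p - s_p - 1) / 2).sum(axis=0)
    total_pairs = M * (M - 1) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_total = (total_pairs - same_pairs) / np.where(M > 0, M, 1)
    ss_ap = ss_total - ss_wp.sum(axis=0)

    n_present = present.sum(axis=0).astype(float)
    pops_present = (m_p > 0).sum(axis=0).astype(float)
    df_wi = n_present
    df_ai = n_present - pops_present
    df_ap = pops_present - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = np.where(df_ap > 0, (M - (m_p ** 2).sum(axis=0) / np.where(M > 0, M, 1)) / np.where(df_ap > 0, df_ap, 1), np.nan)
    usable = (df_ai > 0) & (df_ap > 0) & np.isfinite(n_c) & (n_c > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_wi = ss_wi / np.where(df_wi > 0, df_wi, 1)
        ms_ai = ss_ai / np.where(df_ai > 0, df_ai, 1)
        ms_ap = ss_ap / np.where(df_ap > 0, df_ap, 1)
    sig_w = ms_wi
    sig_i = (ms_ai - ms_wi) / 2.0
    sig_p = np.where(usable, (ms_ap - ms_ai) / np.where(usable, n_c, 1), 0.0)
    w = usable.astype(float)
    return (np.sum(sig_w * w), np.sum(sig_i * w), np.sum(sig_p * w))


def _pop_indices(g: GenotypeMatrix, pops=None):
    if pops is None:
        pops = g.populations
    lookup = {p: i for i, p in enumerate(pops)}
    keep = np.array([p in lookup for p in g.population_labels])
    idx = np.array([lookup[p] for p, k in zip(g.population_labels, keep) if k])
    return g.dosages[keep], idx, list(pops)


def pairwise_fst(g: GenotypeMatrix, pops: tuple[str, str]) -> float:
    """AMOVA-based theta for two populations (ratio of summed components).

    May be slightly negative under panmixia; no clamping is applied.  A pair
    monomorphic across all loci returns 0 with a warning.
    """
    a, b = pops
    dos, idx, _ = _pop_indices(g, [a, b])
    if (idx == 0).sum() < 2 or (idx == 1).sum() < 2:
        raise ValueError("both populations need >= 2 individuals")
    sw, si, sp = _variance_components(dos, idx, 2)
    total = sw + si + sp
    if total == 0:
        warnings.warn("monomorphic population pair; F_ST reported as 0")
        return 0.0
    return float(sp / total)


def weir_cockerham_fst(g: GenotypeMatrix, pops: tuple[str, str]) -> float:
    """Weir & Cockerham (1984) theta, ratio-of-sums over loci (cross-check variant)."""
    a, b = pops
    dos, idx, _ = _pop_indices(g, [a, b])
    present = dos != MISSING
    r = 2
    # per-locus sample sizes and allele freqs per pop
    n_per = np.stack([(present & (idx == k)[:, None]).sum(axis=0) for k in range(r)]).astype(float)
    s_per = np.stack([np.where(present & (idx == k)[:, None], dos, 0).sum(axis=0) for k in range(r)]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_per = s_per / (2 * np.where(n_per > 0, n_per, 1))
    h_per = np.stack([((dos == 1) & (idx == k)[:, None]).sum(axis=0) for k in range(r)]).astype(float)
    ok = (n_per > 0).all(axis=0)
    n_per = n_per[:, ok]; p_per = p_per[:, ok]; h_per = h_per[:, ok]
    nbar = n_per.mean(axis=0)
    n_c = (r * nbar - (n_per ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_per * p_per).sum(axis=0) / (r * nbar)
    s2 = (n_per * (p_per - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (h_per / n_per * n_per).sum(axis=0) / (r * nbar)
    a_comp = nbar / n_c * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b_comp = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c_comp = hbar / 2
    num_sum = np.nansum(a_comp)
    den_sum = np.nansum(a_comp + b_comp + c_comp)
    if den_sum == 0:
        warnings.warn("monomorphic population pair; F_ST reported as 0")
        return 0.0
    return float(num_sum / den_sum)


def _perm_rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-based child stream: one seed, one stream id per test."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def fst_permutation_test(
    g: GenotypeMatrix,
    pops: tuple[str, str],
    n_perm: int = 9999,
    seed: int = 0,
    stream: int = 0,
) -> float:
    """Permutation p-value for pairwise F_ST.

    Individuals are shuffled between the two populations holding sizes
    fixed; p = (1 + #{perm F_ST >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = pops
    dos, idx, _ = _pop_indices(g, [a, b])
    if (idx == 0).sum() < 2 or (idx == 1).sum() < 2:
        raise ValueError("both populations need >= 2 individuals")

    def theta(ix):
        sw, si, sp = _variance_components(dos, ix, 2)
        tot = sw + si + sp
        return 0.0 if tot == 0 else sp / tot

    obs = theta(idx)
    rng = _perm_rng(seed, stream)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        if theta(perm) >= obs:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class AmovaResult:
    """Three-level AMOVA output (the machine analogue of a genodive table)."""

    components: dict[str, float]          # raw variance components
    components_floored: dict[str, float]  # negatives floored at 0
    percent: dict[str, float]             # % of total, from floored components
    f_it: float
    f_is: float
    f_st: float
    f_st_prime: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            ("Within individual", "-", self.percent["within_individual"], "F_IT", self.f_it,
             self.p_values.get("f_it", np.nan), np.nan),
            ("Among individual", "Population", self.percent["among_individual"], "F_IS", self.f_is,
             self.p_values.get("f_is", np.nan), np.nan),
            ("Among population", "-", self.percent["among_population"], "F_ST", self.f_st,
             self.p_values.get("f_st", np.nan), self.f_st_prime),
        ]
        return pd.DataFrame(rows, columns=["source", "nested_in", "pct_var", "f_stat", "f_value", "p_value", "f_prime"])


def amova(g: GenotypeMatrix, n_perm: int = 9999, seed: int = 0) -> AmovaResult:
    """Three-level hierarchical AMOVA with permutation tests.

    Strata: within individual, among individuals within populations, among
    populations.  F_ST is tested by permuting individuals among populations;
    F_IS by permuting the heterozygous/homozygous allele arrangement within
    populations (alleles among individuals within populations).  Populations
    with a single individual are excluded from the F_IS stratum with a
    warning.  All-zero variance yields F-statistics of 0 by convention.
    """
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    sizes = {p: sum(1 for q in g.population_labels if q == p) for p in pops}
    singles = [p for p, n in sizes.items() if n < 2]
    if singles:
        warnings.warn(f"populations with a single individual excluded: {singles}")
        g = g.subset([p for p in pops if sizes[p] >= 2])
        pops = g.populations
    dos, idx, pops = _pop_indices(g, pops)

    sw, si, sp = _variance_components(dos, idx, len(pops))
    total = sw + si + sp
    if total == 0:
        f_it = f_is = f_st = 0.0
        fprime = 0.0
    else:
        f_st = sp / total
        f_is = si / (si + sw) if (si + sw) != 0 else 0.0
        f_it = (sp + si) / total
        _, _, sp_max = _private_allele_components(dos, idx, len(pops))
        tot_max = sw + si + sp_max
        fst_max = sp_max / tot_max if tot_max > 0 else 0.0
        fprime = f_st / fst_max if fst_max > 0 else 0.0

    floored = {"within_individual": max(sw, 0.0), "among_individual": max(si, 0.0), "among_population": max(sp, 0.0)}
    tot_fl = sum(floored.values())
    if tot_fl > 0:
        percent = {k: 100.0 * v / tot_fl for k, v in floored.items()}
    else:
        percent = {k: 0.0 for k in floored}
        percent["within_individual"] = 100.0  # degenerate: all mass reported within

    p_values: dict[str, float] = {}
    if n_perm >= 1 and total > 0:
        rng_st = _perm_rng(seed, 1)
        count = 0
        for _ in range(n_perm):
            perm = rng_st.permutation(idx)
            sw_p, si_p, sp_p = _variance_components(dos, perm, len(pops))
            tot_p = sw_p + si_p + sp_p
            stat = sp_p / tot_p if tot_p != 0 else 0.0
            if stat >= f_st:
                count += 1
        p_values["f_st"] = (1 + count) / (n_perm + 1)

        # F_IS: randomize allele arrangement among individuals within pops by
        # re-pairing each population's alleles at each locus
        rng_is = _perm_rng(seed, 2)
        count = 0
        present = dos != MISSING
        for _ in range(n_perm):
            dos_p = dos.copy()
            for k in range(len(pops)):
                rows = np.where(idx == k)[0]
                sub = dos[rows]
                subp = present[rows]
                s = np.where(subp, sub, 0).sum(axis=0)
                for j in range(dos.shape[1]):
                    r = rows[subp[:, j]]
                    if len(r) < 2:
                        continue
                    alleles = np.repeat([0, 1], [int(2 * len(r) - s[j]), int(s[j])])
                    rng_is.shuffle(alleles)
                    dos_p[r, j] = alleles[0::2] + alleles[1::2]
            sw_p, si_p, _ = _variance_components(dos_p, idx, len(pops))
            stat = si_p / (si_p + sw_p) if (si_p + sw_p) != 0 else 0.0
            if stat >= f_is:
                count += 1
        p_values["f_is"] = (1 + count) / (n_perm + 1)

    return AmovaResult(
        components={"within_individual": sw, "among_individual": si, "among_population": sp},
        components_floored=floored,
        percent=percent,
        f_it=float(f_it),
        f_is=float(f_is),
        f_st=float(f_st),
        f_st_prime=float(fprime),
        p_values=p_values,
        n_permutations=n_perm,
    )
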