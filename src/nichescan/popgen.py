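"""Dominant-marker population genetics: null-allele frequency estimation,
heterozygosities, and per-locus / global / pairwise F_ST.

Dominant markers (AFLP bands) hide the heterozygote: only band-absent
individuals expose the recessive ("null") homozygote, so the null-allele
frequency q must be inferred from the q^2 frequency of band-absent
phenotypes.  We use the Bayesian posterior mean under a uniform prior on
q, which has the closed form B(x+1, n-x+1) / B(x+1/2, n-x+1) for x
band-absent individuals out of n.  All downstream diversity and
differentiation statistics are Nei-type gene-diversity measures computed
on these estimated frequencies: per-locus F_ST = (H_T - H_S) / H_T with
H_S the mean within-site 2pq and H_T from the mean allele frequency.
The global summary is a symmetrically trimmed mean of per-locus values
(default: drop the top and bottom 30%), the convention the dominant-
marker outlier-scan literature uses to stabilise the neutral target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .mantel import DistanceMatrix

#: minimum individuals per site for inclusion in pairwise comparisons;
#: below this the frequency estimate is dominated by the prior
DEFAULT_MIN_N = 4

#: default symmetric trim fraction for the global F_ST mean
DEFAULT_TRIM = 0.30


# ---------------------------------------------------------------------------
# marker matrix container
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Binary band presence/absence per individual x locus.

    ``bands`` holds 0/1 values with one row per individual; every
    individual is assigned to exactly one site and one species.
    """

    bands: np.ndarray
    individual_ids: list
    site_ids: np.ndarray
    locus_ids: list
    species_id: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.bands)
        if b.ndim != 2 or b.size == 0:
            raise ValueError("bands must be a non-empty 2-D matrix")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("band values must be 0 or 1")
        if len(self.individual_ids) != b.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if len(self.site_ids) != b.shape[0]:
            raise ValueError("site_ids length mismatch")
        if len(self.locus_ids) != b.shape[1]:
            raise ValueError("locus_ids length mismatch")
        self.bands = b.astype(np.int8)
        self.site_ids = np.asarray(self.site_ids)

    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    @property
    def sites(self) -> list:
        seen: dict = {}
        for s in self.site_ids:
            seen.setdefault(s, None)
        return list(seen)

    def subset_loci(self, loci: Sequence) -> "MarkerMatrix":
        idx = [self.locus_ids.index(l) for l in loci]
        return MarkerMatrix(self.bands[:, idx], self.individual_ids,
                            self.site_ids, [self.locus_ids[i] for i in idx],
                            self.species_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.bands, columns=self.locus_ids)
        df.insert(0, "individual_id", self.individual_ids)
        df.insert(1, "site_id", self.site_ids)
        df.insert(2, "species_id", self.species_id)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMatrix":
        meta = ["individual_id", "site_id", "species_id"]
        loci = [c for c in df.columns if c not in meta]
        species = df["species_id"].iloc[0] if "species_id" in df else ""
        return cls(df[loci].to_numpy(), list(df["individual_id"]),
                   df["site_id"].to_numpy(), loci, species)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Bayesian null-allele frequency estimation
# ---------------------------------------------------------------------------

def estimate_null_allele_freq(n, x_absent):
    """Posterior mean of the null (band-absent) allele frequency q.

    Model: x band-absent individuals out of n, with phenotype probability
    q^2 under Hardy-Weinberg, likelihood (q^2)^x (1-q^2)^(n-x), uniform
    prior on q.  The posterior mean is the Beta-function ratio
    B(x+1, n-x+1) / B(x+1/2, n-x+1), evaluated in log space for
    stability at large n.  The estimate is strictly inside (0, 1) and
    increases monotonically with x at fixed n.
    """
    n = np.asarray(n, dtype=float)
    x = np.asarray(x_absent, dtype=float)
    if np.any(n < 1):
        raise ValueError("sample size must be at least 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("band-absent count must lie in [0, n]")
    out = np.exp(betaln(x + 1.0, n - x + 1.0) - betaln(x + 0.5, n - x + 1.0))
    return out if out.ndim else float(out)


def null_allele_posterior_moments(n, x_absent):
    """Posterior mean and variance of q under the uniform-prior model.

    The posterior variance doubles as an estimate of the sampling
    variance of the frequency estimate, used to debias among-site
    variance in the F_ST estimator.
    """
    n = np.asarray(n, dtype=float)
    x = np.asarray(x_absent, dtype=float)
    if np.any(n < 1):
        raise ValueError("sample size must be at least 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("band-absent count must lie in [0, n]")
    log_norm = betaln(x + 0.5, n - x + 1.0)
    m1 = np.exp(betaln(x + 1.0, n - x + 1.0) - log_norm)
    m2 = np.exp(betaln(x + 1.5, n - x + 1.0) - log_norm)
    return m1, m2 - m1**2


def site_frequency_table(matrix: MarkerMatrix) -> pd.DataFrame:
    """Per-site sample sizes, band-absent counts, and q estimates.

    Returns a long-format frame with columns site_id, locus_id, n,
    x_absent, q_hat — one row per site x locus.
    """
    sites = matrix.sites
    rows = []
    for s in sites:
        mask = matrix.site_ids == s
        n = int(mask.sum())
        x_abs = (matrix.bands[mask] == 0).sum(axis=0)
        q = estimate_null_allele_freq(np.full(matrix.n_loci, n), x_abs)
        for j, locus in enumerate(matrix.locus_ids):
            rows.append((s, locus, n, int(x_abs[j]), float(q[j])))
    return pd.DataFrame(rows, columns=["site_id", "locus_id", "n", "x_absent", "q_hat"])


def _site_q_matrix(matrix: MarkerMatrix):
    """(sites, n_per_site, q_hat, q_var) arrays for internal use.

    q_hat and q_var are (n_sites, n_loci) posterior means/variances.
    """
    sites = matrix.sites
    n_sites = len(sites)
    ns = np.empty(n_sites, dtype=int)
    q = np.empty((n_sites, matrix.n_loci))
    v = np.empty((n_sites, matrix.n_loci))
    for i, s in enumerate(sites):
        mask = matrix.site_ids == s
        ns[i] = mask.sum()
        x_abs = (matrix.bands[mask] == 0).sum(axis=0)
        q[i], v[i] = null_allele_posterior_moments(np.full(matrix.n_loci, ns[i]), x_abs)
    return sites, ns, q, v


# ---------------------------------------------------------------------------
# heterozygosity and F_ST
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Expected heterozygosity totals: H_T pooled over sites, H_W the
    mean within-site value, for a named locus subset."""

    h_t: float
    h_w: float
    scope: str
    per_locus_ht: np.ndarray = field(repr=False, default=None)
    per_locus_hw: np.ndarray = field(repr=False, default=None)


@dataclass
class FstResult:
    """Per-locus and global Nei-type F_ST over sites."""

    locus_ids: list
    per_locus_fst: np.ndarray
    per_locus_he: np.ndarray
    global_fst: float
    global_fst_untrimmed: float
    trim_fraction: float
    #: unclamped estimates (negatives kept); used for rank comparisons
    per_locus_fst_raw: Optional[np.ndarray] = None
    locus_subset: str = "all"
    excluded_loci: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.locus_ids,
            "he": self.per_locus_he,
            "fst": self.per_locus_fst,
        })


def diversity_summary(
    matrix: MarkerMatrix,
    locus_subset: Optional[Sequence] = None,
    scope: str = "all",
) -> DiversitySummary:
    """H_T and H_W from Bayesian-estimated allele frequencies.

    H_T estimates frequencies from the pooled sample across all sites;
    H_W estimates them per site, averages 2pq over sites, then over
    loci.  Expected heterozygosity of a biallelic dominant locus is
    2*p*q with p = 1 - q the band-presence allele frequency.
    """
    if locus_subset is not None:
        if len(locus_subset) == 0:
            raise ValueError("empty locus subset")
        matrix = matrix.subset_loci(locus_subset)

    n_tot = matrix.n_individuals
    x_pooled = (matrix.bands == 0).sum(axis=0)
    q_pool = estimate_null_allele_freq(np.full(matrix.n_loci, n_tot), x_pooled)
    ht_per_locus = 2.0 * q_pool * (1.0 - q_pool)

    _, _, q_site, _ = _site_q_matrix(matrix)
    hw_per_locus = (2.0 * q_site * (1.0 - q_site)).mean(axis=0)

    return DiversitySummary(
        h_t=float(ht_per_locus.mean()),
        h_w=float(hw_per_locus.mean()),
        scope=scope,
        per_locus_ht=ht_per_locus,
        per_locus_hw=hw_per_locus,
    )


def fst_from_frequencies(
    q: np.ndarray,
    sampling_var: Optional[np.ndarray] = None,
    clamp: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (F_ST, H_e) from a sites x loci matrix of null-allele
    frequencies.

    F_ST is Nei's G_ST: H_S is the mean within-site 2pq, H_T is 2pq at
    the across-site mean frequency, so the numerator H_T - H_S equals
    twice the among-site variance of q.  When per-estimate sampling
    variances are supplied their mean is subtracted from the among-site
    variance first, removing the upward bias that finite per-site
    samples (~18 individuals) otherwise inject.  Negative estimates are
    clamped to zero; loci with H_T = 0 return NaN and are excluded from
    means.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] < 2:
        raise ValueError("need frequencies for at least 2 sites")
    q_bar = q.mean(axis=0)
    h_t = 2.0 * q_bar * (1.0 - q_bar)
    var_among = (q**2).mean(axis=0) - q_bar**2
    if sampling_var is not None:
        var_among = var_among - np.asarray(sampling_var, dtype=float).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = 2.0 * var_among / h_t
    if clamp:
        fst = np.clip(fst, 0.0, 1.0)
    fst = np.where(h_t > 0, fst, np.nan)
    return fst, h_t


def fst_per_locus(
    matrix: MarkerMatrix,
    locus_subset: Optional[Sequence] = None,
    trim_fraction: float = DEFAULT_TRIM,
    scope: str = "all",
    bias_correction: bool = True,
) -> FstResult:
    """Per-locus F_ST over all sites plus trimmed/untrimmed global means.

    The global mean symmetrically discards the highest and lowest
    ``trim_fraction`` of per-locus values (default 30% each side)
    before averaging, matching the calibration convention used when
    targeting a neutral mean for outlier scans.
    """
    if locus_subset is not None:
        if len(locus_subset) == 0:
            raise ValueError("empty locus subset")
        matrix = matrix.subset_loci(locus_subset)
    _, _, q, v = _site_q_matrix(matrix)
    raw, he = fst_from_frequencies(q, v if bias_correction else None, clamp=False)
    fst = np.where(np.isnan(raw), np.nan, np.clip(raw, 0.0, 1.0))
    valid = ~np.isnan(fst)
    excluded = [l for l, v in zip(matrix.locus_ids, valid) if not v]
    if excluded:
        warnings.warn(f"{len(excluded)} locus/loci with H_T = 0 excluded from the mean",
                      stacklevel=2)
    vals = fst[valid]
    if vals.size == 0:
        raise ValueError("no polymorphic loci: global F_ST undefined")
    return FstResult(
        locus_ids=list(matrix.locus_ids),
        per_locus_fst=fst,
        per_locus_he=he,
        global_fst=float(stats.trim_mean(vals, trim_fraction)),
        global_fst_untrimmed=float(vals.mean()),
        trim_fraction=trim_fraction,
        per_locus_fst_raw=raw,
        locus_subset=scope,
        excluded_loci=excluded,
    )


def pairwise_fst(
    matrix: MarkerMatrix,
    locus_subset: Optional[Sequence] = None,
    min_n: int = DEFAULT_MIN_N,
    bias_correction: bool = True,
) -> DistanceMatrix:
    """Mean per-locus two-site G_ST for every site pair.

    Sites with fewer than ``min_n`` individuals are dropped (with a
    warning).  Per-locus values are clamped at zero before averaging;
    loci monomorphic in a pair contribute nothing to that pair's mean.
    """
    if locus_subset is not None:
        if len(locus_subset) == 0:
            raise ValueError("empty locus subset")
        matrix = matrix.subset_loci(locus_subset)
    sites, ns, q, v = _site_q_matrix(matrix)
    keep = ns >= min_n
    if not keep.all():
        dropped = [s for s, k in zip(sites, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} site(s) below min_n={min_n}: {dropped}",
                      stacklevel=2)
        sites = [s for s, k in zip(sites, keep) if k]
        q = q[keep]
        v = v[keep]
    n_sites = len(sites)
    if n_sites < 2:
        raise ValueError("need at least 2 sites with sufficient sample size")
    out = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            fst, _ = fst_from_frequencies(q[[i, j]],
                                           v[[i, j]] if bias_correction else None)
            vals = fst[~np.isnan(fst)]
            out[i, j] = out[j, i] = float(vals.mean()) if vals.size else 0.0
    return DistanceMatrix(sites, out, "genetic")


# ---------------------------------------------------------------------------
# AFLP replicate error rate
# ---------------------------------------------------------------------------

def replicate_error_rate(pairs: Sequence[tuple]) -> float:
    """Genotyping repeatability from replicate fingerprint pairs.

    Each pair holds two equal-length 0/1 band vectors scored for the
    same individual in independent runs.  The error rate is the total
    number of mismatched fragment calls divided by the total number of
    scored fragments, expressed as a percentage.
    """
    if len(pairs) == 0:
        raise ValueError("no replicate pairs supplied")
    mismatches = 0
    scored = 0
    for a, b in pairs:
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("replicate fingerprints differ in locus count")
        mismatches += int((a != b).sum())
        scored += a.size
    return 100.0 * mismatches / scored
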