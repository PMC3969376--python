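"""Outlier-locus detection for dominant markers.

Two complementary scans, combined by an intersection rule:

1. A simulated-null scan in the Fdist/Dfdist tradition: tens of
   thousands of loci are simulated under a symmetrical-island neutral
   model (Balding–Nichols per-deme frequencies), phenotyped at the
   observed per-site sample sizes, and pushed through exactly the same
   frequency-estimation and F_ST machinery as the real data.  The
   Balding–Nichols F is calibrated by bisection so the realized
   trimmed-mean F_ST of the cloud matches the observed target.  Each
   empirical locus gets a one-tailed p-value against the simulated loci
   in its heterozygosity neighbourhood (nearest-k window), followed by
   Benjamini–Hochberg FDR control.

2. A hierarchical Bayesian scan in the BayeScan tradition: the logit of
   the locus-by-population F_ST is decomposed into a locus effect
   alpha_i (selection) and a population effect beta_j (drift/migration),
   per-deme frequencies are Balding–Nichols given that F_ST, and the
   dominant-phenotype likelihood is binomial in q^2.  A spike-and-slab
   prior on alpha_i (prior inclusion odds 1:10) turns selection into a
   model indicator sampled by Metropolis-within-Gibbs with jump moves;
   the per-locus posterior inclusion probability is the evidence for
   selection.  Split-chain R-hat on the population effects flags
   non-convergence.

Loci flagged by both methods are classified ``outlier``; by neither,
``neutral``; by exactly one, ``ambiguous`` and excluded downstream.
Linkage disequilibrium among outliers is tested per site pair-wise with
a permutation chi-square on the 2x2 phenotype table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln as _betaln

from .popgen import (
    MarkerMatrix,
    FstResult,
    fst_from_frequencies,
    null_allele_posterior_moments,
)

_LOGIT_CAP = 10.0  # cap on |alpha + beta| keeping Beta parameters finite


# ---------------------------------------------------------------------------
# Dfdist-style simulated neutral null
# ---------------------------------------------------------------------------

@dataclass
class NullCloud:
    """Simulated neutral (heterozygosity, F_ST) cloud.

    ``calibration_fst`` is the Balding–Nichols F that makes the
    realized trimmed-mean F_ST of the cloud match ``target_mean_fst``
    at the observed sample sizes.
    """

    he: np.ndarray
    fst: np.ndarray
    target_mean_fst: float
    calibration_fst: float
    realized_mean_fst: float
    n_simulated: int
    sample_sizes: np.ndarray
    trim_fraction: float = 0.30
    freq_range: tuple = (0.05, 0.95)
    #: unclamped per-locus estimates for rank comparisons
    fst_raw: Optional[np.ndarray] = None
    #: True when ancestral frequencies were resampled from the data
    empirical_ancestral: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"he": self.he, "fst": self.fst,
                             "fst_raw": (self.fst_raw if self.fst_raw is not None
                                         else self.fst)})

    def to_tsv(self, path) -> None:
        """Cache the cloud as delimited text with a calibration header."""
        header = ("# null_cloud"
                  f" target_mean_fst={self.target_mean_fst}"
                  f" calibration_fst={self.calibration_fst}"
                  f" realized_mean_fst={self.realized_mean_fst}"
                  f" trim_fraction={self.trim_fraction}"
                  f" freq_range={self.freq_range[0]},{self.freq_range[1]}"
                  f" empirical_ancestral={self.empirical_ancestral}"
                  f" sample_sizes={','.join(map(str, np.asarray(self.sample_sizes)))}\n")
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NullCloud":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh, sep="\t")
        meta = dict(item.split("=") for item in header.split()[2:])
        lo, hi = (float(v) for v in meta["freq_range"].split(","))
        return cls(
            he=df["he"].to_numpy(), fst=df["fst"].to_numpy(),
            fst_raw=df["fst_raw"].to_numpy(),
            target_mean_fst=float(meta["target_mean_fst"]),
            calibration_fst=float(meta["calibration_fst"]),
            realized_mean_fst=float(meta["realized_mean_fst"]),
            n_simulated=len(df),
            sample_sizes=np.array([int(v) for v in meta["sample_sizes"].split(",")]),
            trim_fraction=float(meta["trim_fraction"]),
            freq_range=(lo, hi),
            empirical_ancestral=meta.get("empirical_ancestral", "False") == "True",
        )


def _simulate_batch(
    bn_fst: float,
    n_loci: int,
    sample_sizes: np.ndarray,
    rng: np.random.Generator,
    freq_range: tuple = (0.05, 0.95),
    bias_correction: bool = True,
    ancestral_freqs: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(he, fst) for n_loci neutral loci at Balding–Nichols F=bn_fst,
    estimated exactly as on real data.

    Ancestral band-allele frequencies are resampled from
    ``ancestral_freqs`` when given (conditioning the null on the data's
    frequency spectrum, as Dfdist-style scans do), else drawn uniform
    over ``freq_range``."""
    S = len(sample_sizes)
    if ancestral_freqs is not None:
        p0 = rng.choice(ancestral_freqs, size=n_loci, replace=True)
    else:
        p0 = rng.uniform(freq_range[0], freq_range[1], size=n_loci)
    if bn_fst <= 0:
        p = np.tile(p0, (S, 1))
    else:
        c = (1.0 - bn_fst) / bn_fst
        p = rng.beta(np.tile(p0 * c, (S, 1)), np.tile((1.0 - p0) * c, (S, 1)))
    q = 1.0 - p
    ns = np.asarray(sample_sizes, dtype=int)[:, None]
    x = rng.binomial(ns, q**2)
    q_hat, q_var = null_allele_posterior_moments(np.broadcast_to(ns, x.shape), x)
    raw, he = fst_from_frequencies(q_hat, q_var if bias_correction else None,
                                   clamp=False)
    fst = np.clip(raw, 0.0, 1.0)
    keep = ~np.isnan(raw)
    return he[keep], fst[keep], raw[keep]


def simulate_null_fst(
    target_mean_fst: float,
    sample_sizes: Sequence[int],
    n_simulated: int = 50_000,
    seed: Optional[int] = None,
    trim_fraction: float = 0.30,
    freq_range: tuple = (0.05, 0.95),
    pilot_size: int = 4000,
    max_iter: int = 40,
    bias_correction: bool = True,
    ancestral_freqs: Optional[np.ndarray] = None,
) -> NullCloud:
    """Neutral null cloud calibrated to an observed trimmed-mean F_ST.

    Bisection on the Balding–Nichols F uses common random numbers for
    the pilot batches, so the realized-vs-F curve is monotone and the
    bracket is reliable.  Raises if the target cannot be bracketed.
    Passing the data's pooled per-locus band-allele frequencies as
    ``ancestral_freqs`` conditions the null on the observed frequency
    spectrum — without it, high-heterozygosity panels are compared
    against a broader spectrum and the scan turns conservative.
    """
    if ancestral_freqs is not None:
        ancestral_freqs = np.clip(np.asarray(ancestral_freqs, dtype=float),
                                  0.01, 0.99)
    if not 0 < target_mean_fst < 0.5:
        raise ValueError("target_mean_fst must lie in (0, 0.5)")
    if n_simulated < 1000:
        raise ValueError("n_simulated must be at least 1000")
    sample_sizes = np.asarray(sample_sizes, dtype=int)
    if sample_sizes.size < 2:
        raise ValueError("need sample sizes for at least 2 sites")
    base_seed = 0 if seed is None else int(seed)

    def realized(F: float) -> float:
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, 12345]))
        _, fst, _ = _simulate_batch(F, pilot_size, sample_sizes, rng,
                                    freq_range, bias_correction,
                                    ancestral_freqs)
        return float(stats.trim_mean(fst, trim_fraction))

    lo, hi = 1e-6, 0.6
    r_lo, r_hi = realized(lo), realized(hi)
    if not (r_lo <= target_mean_fst <= r_hi):
        raise RuntimeError(
            f"calibration failed to bracket target {target_mean_fst}: "
            f"realized range [{r_lo:.4f}, {r_hi:.4f}] at F in [{lo}, {hi}] "
            f"with sample sizes {sample_sizes.tolist()}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = realized(mid)
        if abs(r_mid - target_mean_fst) < 1e-4:
            lo = hi = mid
            break
        if r_mid < target_mean_fst:
            lo = mid
        else:
            hi = mid
    bn_fst = 0.5 * (lo + hi)

    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 67890]))
    he, fst, raw = _simulate_batch(bn_fst, n_simulated, sample_sizes, rng,
                                   freq_range, bias_correction,
                                   ancestral_freqs)
    return NullCloud(
        he=he,
        fst=fst,
        fst_raw=raw,
        empirical_ancestral=ancestral_freqs is not None,
        target_mean_fst=target_mean_fst,
        calibration_fst=float(bn_fst),
        realized_mean_fst=float(stats.trim_mean(fst, trim_fraction)),
        n_simulated=int(he.size),
        sample_sizes=sample_sizes,
        trim_fraction=trim_fraction,
        freq_range=freq_range,
    )


def pooled_band_frequencies(matrix: MarkerMatrix) -> np.ndarray:
    """Per-locus pooled band-allele frequency estimates (1 - q_hat),
    the natural ancestral-spectrum input for ``simulate_null_fst``."""
    x = (matrix.bands == 0).sum(axis=0)
    q, _ = null_allele_posterior_moments(np.full(matrix.n_loci,
                                                 matrix.n_individuals), x)
    return 1.0 - q


def dfdist_scan(
    observed: FstResult,
    cloud: NullCloud,
    alpha: float = 0.05,
    fdr_q: float = 0.10,
    window_k: int = 2000,
) -> pd.DataFrame:
    """Empirical one-tailed p per locus against the conditional null.

    For each observed locus the null set is the ``window_k`` simulated
    loci nearest in heterozygosity; the high-tail p is the +1/(k+1)
    proportion of those with F_ST at least as large.  Benjamini–
    Hochberg is applied to the high-tail p-values at ``fdr_q``; the raw
    flag marks p < alpha.  The low (balancing) tail is reported too.
    """
    from statsmodels.stats.multitest import multipletests

    order = np.argsort(cloud.he)
    he_sorted = cloud.he[order]
    cloud_fst = cloud.fst_raw if cloud.fst_raw is not None else cloud.fst
    fst_sorted = cloud_fst[order]
    m = he_sorted.size
    k = min(window_k, m)

    he_lo, he_hi = he_sorted[0], he_sorted[-1]
    obs_fst = (observed.per_locus_fst_raw
               if observed.per_locus_fst_raw is not None
               else observed.per_locus_fst)
    p_high = np.empty(len(observed.locus_ids))
    p_low = np.empty_like(p_high)
    out_of_range = np.zeros(len(observed.locus_ids), dtype=bool)
    for i, (he, fst) in enumerate(zip(observed.per_locus_he, obs_fst)):
        if np.isnan(fst):
            p_high[i] = p_low[i] = np.nan
            continue
        if he < he_lo or he > he_hi:
            out_of_range[i] = True
        pos = np.searchsorted(he_sorted, he)
        start = int(np.clip(pos - k // 2, 0, m - k))
        window = fst_sorted[start:start + k]
        p_high[i] = (np.sum(window >= fst - 1e-12) + 1.0) / (k + 1.0)
        p_low[i] = (np.sum(window <= fst + 1e-12) + 1.0) / (k + 1.0)

    valid = ~np.isnan(p_high)
    fdr_flag = np.zeros_like(valid)
    if valid.any():
        fdr_flag[valid] = multipletests(p_high[valid], alpha=fdr_q,
                                        method="fdr_bh")[0]
    return pd.DataFrame({
        "locus_id": observed.locus_ids,
        "he": observed.per_locus_he,
        "fst": observed.per_locus_fst,
        "dfdist_p": p_high,
        "dfdist_p_low": p_low,
        "dfdist_raw_flag": p_high < alpha,
        "dfdist_fdr_flag": fdr_flag,
        "he_out_of_range": out_of_range,
    })


# ---------------------------------------------------------------------------
# BayeScan-style hierarchical Bayesian scan
# ---------------------------------------------------------------------------

@dataclass
class BayesScanState:
    """Posterior summaries of the spike-and-slab locus-effect model."""

    locus_ids: list
    posterior_prob_selection: np.ndarray
    alpha_mean: np.ndarray
    beta_mean: np.ndarray
    rhat_beta: np.ndarray
    converged: bool
    n_iter: int
    burn_in: int
    thin: int
    prior_inclusion: float
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.locus_ids,
            "bayes_posterior": self.posterior_prob_selection,
            "alpha_mean": self.alpha_mean,
        })


def _bn_logpdf(p, mu, f):
    """Balding–Nichols Beta log-density of deme frequencies p given
    ancestral mean mu and differentiation f."""
    c = (1.0 - f) / f
    a = mu * c
    b = (1.0 - mu) * c
    return (a - 1.0) * np.log(p) + (b - 1.0) * np.log1p(-p) - _betaln(a, b)


def _phenotype_loglik(p, x, n):
    """Binomial log-likelihood of band-absent counts given band-allele
    frequency p (the binomial coefficient is constant and dropped)."""
    q = 1.0 - p
    return 2.0 * x * np.log(q) + (n - x) * np.log1p(-(q * q))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_LOGIT_CAP, _LOGIT_CAP)))


def _split_rhat(samples: np.ndarray) -> np.ndarray:
    """Split-chain R-hat per column of a (draws, params) array."""
    n = samples.shape[0] // 2 * 2
    halves = np.stack([samples[: n // 2], samples[n // 2: n]])
    m, half_n = halves.shape[0], halves.shape[1]
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    b = half_n * means.var(axis=0, ddof=1)
    var_plus = (half_n - 1) / half_n * w + b / half_n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)


def bayescan_lite(
    matrix: MarkerMatrix,
    n_iter: int = 6000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: Optional[int] = None,
    prior_inclusion: float = 1.0 / 11.0,
    slab_sd: float = 2.0,
    beta_prior_mean: float = -1.0,
    beta_prior_sd: float = 1.8,
    prior_only: bool = False,
) -> BayesScanState:
    """Posterior probability of selection per locus.

    Metropolis-within-Gibbs over per-deme frequencies, ancestral
    frequencies, population effects beta_j, and the spike-and-slab
    locus effects (gamma_i, alpha_i).  Model-indicator jumps draw the
    candidate alpha from the slab prior, so prior and proposal cancel
    and the acceptance ratio is the likelihood ratio times the prior
    inclusion odds.  ``prior_only=True`` drops the data term — the
    posterior inclusion must then recover the prior, which is the
    standard correctness check for the jump move.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if matrix.n_loci < 20:
        raise ValueError("need at least 20 loci to separate locus and population effects")
    sites = matrix.sites
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")

    L, S = matrix.n_loci, len(sites)
    x = np.empty((L, S))
    n = np.empty(S)
    for j, s in enumerate(sites):
        mask = matrix.site_ids == s
        n[j] = mask.sum()
        x[:, j] = (matrix.bands[mask] == 0).sum(axis=0)

    rng = np.random.default_rng(seed)

    # initial values from marginal estimates
    q_pool, _ = null_allele_posterior_moments(np.full(L, n.sum()), x.sum(axis=1))
    mu = np.clip(1.0 - q_pool, 0.02, 0.98)          # ancestral band-allele freq
    q_site, q_var = null_allele_posterior_moments(np.broadcast_to(n, (L, S)), x)
    p = np.clip(1.0 - q_site, 1e-4, 1 - 1e-4)       # per-deme band-allele freq
    fst0, _ = fst_from_frequencies(q_site.T, q_var.T)
    fst_init = float(np.clip(np.nanmean(fst0), 0.005, 0.4))
    beta = np.full(S, np.log(fst_init / (1.0 - fst_init)))
    alpha = np.zeros(L)
    gamma = np.zeros(L, dtype=bool)

    def data_ll(p_):
        if prior_only:
            return np.zeros_like(p_)
        return _phenotype_loglik(p_, x, n)

    f = _sigmoid(alpha[:, None] * gamma[:, None] + beta[None, :])
    ll = data_ll(p)
    lp = _bn_logpdf(p, mu[:, None], f)

    inv_2slab = 0.5 / slab_sd**2
    inv_2beta = 0.5 / beta_prior_sd**2
    log_prior_odds = np.log(prior_inclusion / (1.0 - prior_inclusion))

    keep_gamma = []
    keep_alpha = []
    keep_beta = []

    logit = lambda v: np.log(v) - np.log1p(-v)

    for it in range(n_iter):
        # --- per-deme frequencies (logit random walk) ----------------
        prop_logit = logit(p) + rng.normal(0, 0.6, size=(L, S))
        p_new = _sigmoid(prop_logit)
        ll_new = data_ll(p_new)
        lp_new = _bn_logpdf(p_new, mu[:, None], f)
        delta = (ll_new + lp_new + np.log(p_new * (1 - p_new))) - (
            ll + lp + np.log(p * (1 - p)))
        acc = np.log(rng.random((L, S))) < delta
        p = np.where(acc, p_new, p)
        ll = np.where(acc, ll_new, ll)
        lp = np.where(acc, lp_new, lp)

        # --- ancestral frequencies mu (logit random walk) ------------
        mu_new = _sigmoid(logit(mu) + rng.normal(0, 0.3, size=L))
        lp_mu_new = _bn_logpdf(p, mu_new[:, None], f)
        delta = (lp_mu_new.sum(axis=1) + np.log(mu_new * (1 - mu_new))) - (
            lp.sum(axis=1) + np.log(mu * (1 - mu)))
        acc = np.log(rng.random(L)) < delta
        mu = np.where(acc, mu_new, mu)
        lp = np.where(acc[:, None], lp_mu_new, lp)

        # --- population effects beta_j (two passes aid mixing) -------
        for scale in (0.25, 0.1):
            beta_new = beta + rng.normal(0, scale, size=S)
            f_new = _sigmoid(alpha[:, None] * gamma[:, None] + beta_new[None, :])
            lp_b_new = _bn_logpdf(p, mu[:, None], f_new)
            delta = (lp_b_new.sum(axis=0) - lp.sum(axis=0)
                     - inv_2beta * ((beta_new - beta_prior_mean) ** 2
                                    - (beta - beta_prior_mean) ** 2))
            acc = np.log(rng.random(S)) < delta
            beta = np.where(acc, beta_new, beta)
            lp = np.where(acc[None, :], lp_b_new, lp)
        f = _sigmoid(alpha[:, None] * gamma[:, None] + beta[None, :])

        # --- slab alpha_i for included loci --------------------------
        if gamma.any():
            alpha_new = np.where(gamma, alpha + rng.normal(0, 0.5, size=L), alpha)
            f_new = _sigmoid(alpha_new[:, None] * gamma[:, None] + beta[None, :])
            lp_a_new = _bn_logpdf(p, mu[:, None], f_new)
            delta = (lp_a_new.sum(axis=1) - lp.sum(axis=1)
                     - inv_2slab * (alpha_new**2 - alpha**2))
            acc = gamma & (np.log(rng.random(L)) < delta)
            alpha = np.where(acc, alpha_new, alpha)
            lp = np.where(acc[:, None], lp_a_new, lp)
            f = _sigmoid(alpha[:, None] * gamma[:, None] + beta[None, :])

        # --- spike/slab jump: toggle gamma_i -------------------------
        alpha_cand = np.where(gamma, 0.0, rng.normal(0, slab_sd, size=L))
        gamma_cand = ~gamma
        f_new = _sigmoid(alpha_cand[:, None] * gamma_cand[:, None] + beta[None, :])
        lp_g_new = _bn_logpdf(p, mu[:, None], f_new)
        delta = lp_g_new.sum(axis=1) - lp.sum(axis=1) + np.where(
            gamma_cand, log_prior_odds, -log_prior_odds)
        acc = np.log(rng.random(L)) < delta
        gamma = np.where(acc, gamma_cand, gamma)
        alpha = np.where(acc, alpha_cand, alpha)
        lp = np.where(acc[:, None], lp_g_new, lp)
        f = _sigmoid(alpha[:, None] * gamma[:, None] + beta[None, :])

        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_gamma.append(gamma.copy())
            keep_alpha.append(np.where(gamma, alpha, 0.0))
            keep_beta.append(beta.copy())

    g = np.asarray(keep_gamma)
    a = np.asarray(keep_alpha)
    b = np.asarray(keep_beta)
    rhat = _split_rhat(b)
    converged = bool(np.all(rhat < 1.1))
    if not converged:
        warnings.warn(
            f"population-effect chains not converged (max R-hat {np.nanmax(rhat):.3f})",
            stacklevel=2,
        )
    return BayesScanState(
        locus_ids=list(matrix.locus_ids),
        posterior_prob_selection=g.mean(axis=0),
        alpha_mean=a.mean(axis=0),
        beta_mean=b.mean(axis=0),
        rhat_beta=rhat,
        converged=converged,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        prior_inclusion=prior_inclusion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classification and LD
# ---------------------------------------------------------------------------

def classify_loci(
    dfdist_table: pd.DataFrame,
    bayes: BayesScanState,
    posterior_threshold: float = 0.95,
    use_fdr_flag: bool = True,
) -> pd.DataFrame:
    """Both-methods intersection rule.

    outlier = flagged by both scans; neutral = flagged by neither;
    ambiguous = exactly one (excluded from every downstream analysis).
    Direction is directional (high-F_ST tail / alpha > 0) or balancing.
    """
    if list(dfdist_table["locus_id"]) != list(bayes.locus_ids):
        raise ValueError("locus sets of the two scans do not match")
    df = dfdist_table.copy()
    df["bayes_posterior"] = bayes.posterior_prob_selection
    df["bayes_flag"] = df["bayes_posterior"] > posterior_threshold
    dfdist_flag = df["dfdist_fdr_flag"] if use_fdr_flag else df["dfdist_raw_flag"]
    df["dfdist_flag"] = dfdist_flag.fillna(False).astype(bool)

    both = df["dfdist_flag"] & df["bayes_flag"]
    neither = ~df["dfdist_flag"] & ~df["bayes_flag"]
    df["class"] = np.where(both, "outlier", np.where(neither, "neutral", "ambiguous"))
    df["direction"] = np.where(bayes.alpha_mean >= 0, "directional", "balancing")
    return df


def _chi2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """2x2 chi-square of association between two binary vectors."""
    n = a.size
    n11 = float(np.sum(a & b))
    r1 = float(a.sum())
    c1 = float(b.sum())
    num = n * (n11 * n - r1 * c1) ** 2
    den = r1 * (n - r1) * c1 * (n - c1)
    return num / den if den > 0 else np.nan


def ld_permutation_test(
    matrix: MarkerMatrix,
    locus_pairs: Sequence[tuple],
    n_perm: int = 1000,
    dememorization: int = 1000,
    min_n: int = 4,
    seed: Optional[int] = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Site-stratified pairwise LD test between outlier loci.

    Within each site the association of the two band-phenotype columns
    is the 2x2 chi-square; the null permutes one column within the site
    ``n_perm`` times after ``dememorization`` warm-up shuffles of the
    generator state.  Returns the per-(pair, site) table and the
    fraction of combinations significant at ``alpha``.  Sites where
    either column is monomorphic are skipped for that pair.
    """
    rng = np.random.default_rng(seed)
    for _ in range(dememorization):
        rng.random()
    sites = matrix.sites
    locus_index = {l: i for i, l in enumerate(matrix.locus_ids)}
    rows = []
    for l1, l2 in locus_pairs:
        i1, i2 = locus_index[l1], locus_index[l2]
        for s in sites:
            mask = matrix.site_ids == s
            if mask.sum() < min_n:
                continue
            a = matrix.bands[mask, i1].astype(bool)
            b = matrix.bands[mask, i2].astype(bool)
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue  # monomorphic column: association undefined
            obs = _chi2_stat(a, b)
            perms = np.array([rng.permutation(b.size) for _ in range(n_perm)])
            b_perm = b[perms]                       # (n_perm, n_ind)
            n_ind = a.size
            n11 = (b_perm & a[None, :]).sum(axis=1).astype(float)
            r1, c1 = float(a.sum()), float(b.sum())
            num = n_ind * (n11 * n_ind - r1 * c1) ** 2
            den = r1 * (n_ind - r1) * c1 * (n_ind - c1)
            stat_perm = num / den
            pval = (np.sum(stat_perm >= obs - 1e-12) + 1.0) / (n_perm + 1.0)
            rows.append({"locus_1": l1, "locus_2": l2, "site_id": s,
                         "chi2": obs, "p": pval})
    table = pd.DataFrame(rows)
    frac = float((table["p"] <= alpha).mean()) if len(table) else np.nan
    return table, frac
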