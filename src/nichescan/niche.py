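"""Environmental-variable pruning, presence derivation from survey
counts, and the ecological specialization index S.

S for a species and variable is the ratio of the variable's standard
deviation across all study sites (sigma_g) to its standard deviation at
the sites where the species is present (sigma_s): S = sigma_g/sigma_s.
A randomly chosen set of sites has S ~ 1; S > 1 means the species
occupies a narrow slice of the available gradient, i.e. that variable
limits its distribution.  Significance comes from a randomization null:
random site subsets of the same size, one-tailed for large S.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def prune_variables(
    sites: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    r_threshold: float = 0.7,
) -> tuple[list, pd.DataFrame]:
    """Greedy elimination of mutually correlated variables.

    While any retained pair has |Pearson r| above the threshold, the
    member of the worst pair with the larger mean |r| to all other
    retained variables is dropped (ties broken by variable-name order,
    dropping the later name).  At least one variable is always kept.
    Returns the retained list and a report of (dropped, partner, r).
    """
    meta = {"site_id", "x_km", "y_km"}
    if variables is None:
        variables = [c for c in sites.columns if c not in meta]
    variables = list(variables)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites with complete data")
    data = sites[variables].dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 sites with complete data")

    retained = list(variables)
    dropped_rows = []
    while len(retained) > 1:
        corr = data[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= r_threshold:
            break
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        # mean |r| of each member of the worst pair to all other variables
        mean_i = corr[i].sum() / (len(retained) - 1)
        mean_j = corr[j].sum() / (len(retained) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j, key=lambda k: retained[k])
        keep = j if drop == i else i
        dropped_rows.append((retained[drop], retained[keep], float(corr[i, j])))
        retained.pop(drop)
    report = pd.DataFrame(dropped_rows, columns=["dropped", "partner", "r"])
    return retained, report


def derive_presence(
    counts: pd.DataFrame,
    min_count: int = 2,
    seasons: Sequence[str] = ("july", "november"),
) -> pd.DataFrame:
    """Presence/absence from per-season survey counts.

    A species is present at a site iff its count reaches ``min_count``
    in at least one season.  Expected columns: species_id, site_id,
    season, count (long format).  Missing seasons count as zero, with a
    warning.
    """
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.equal(np.mod(counts["count"], 1), 0).all():
        raise ValueError("counts must be integers")
    wide = counts.pivot_table(index=["species_id", "site_id"], columns="season",
                              values="count", aggfunc="sum")
    missing = [s for s in seasons if s not in wide.columns]
    if missing:
        warnings.warn(f"season(s) {missing} absent from counts; treated as zero",
                      stacklevel=2)
        for s in missing:
            wide[s] = 0
    na_cells = int(wide[list(seasons)].isna().sum().sum())
    if na_cells:
        warnings.warn(f"{na_cells} missing season count(s) treated as zero", stacklevel=2)
    wide = wide[list(seasons)].fillna(0)
    present = (wide >= min_count).any(axis=1).astype(int)
    out = present.reset_index().rename(columns={0: "present"})
    return out


def specialization_index(
    sites: pd.DataFrame,
    presence: pd.DataFrame,
    variable: str,
    species: str,
    n_rand: int = 999,
    seed: Optional[int] = None,
) -> Optional[dict]:
    """One row of the specialization table: S and its randomization p.

    Both standard deviations use the sample (n-1) convention.  If the
    variable is constant at the occupied sites, S is reported as +inf
    with the minimum attainable p; if it is constant across all sites
    the variable is uninformative and None is returned.
    """
    if variable not in sites.columns:
        raise KeyError(f"variable {variable!r} not in site table")
    occ = presence[(presence["species_id"] == species) & (presence["present"] == 1)]
    occ_ids = set(occ["site_id"])
    mask = sites["site_id"].isin(occ_ids).to_numpy()
    n_occ = int(mask.sum())
    if n_occ < 3:
        raise ValueError(f"species {species!r} occupies {n_occ} sites; need >= 3")

    x = sites[variable].to_numpy(dtype=float)
    sigma_g = x.std(ddof=1)
    if sigma_g == 0:
        return None  # uninformative variable
    sigma_s = x[mask].std(ddof=1)

    rng = np.random.default_rng(seed)
    n_sites = len(x)
    rand_sd = np.empty(n_rand)
    for i in range(n_rand):
        idx = rng.choice(n_sites, size=n_occ, replace=False)
        rand_sd[i] = x[idx].std(ddof=1)
    with np.errstate(divide="ignore"):
        rand_s = np.where(rand_sd > 0, sigma_g / rand_sd, np.inf)

    if sigma_s == 0:
        s_obs = np.inf
        p = 1.0 / (n_rand + 1.0)
    else:
        s_obs = sigma_g / sigma_s
        p = (float(np.sum(rand_s >= s_obs)) + 1.0) / (n_rand + 1.0)
    return {
        "species_id": species,
        "variable": variable,
        "sigma_g": float(sigma_g),
        "sigma_s": float(sigma_s),
        "S": float(s_obs),
        "p_rand": float(p),
        "n_occupied": n_occ,
    }


def specialization_table(
    sites: pd.DataFrame,
    presence: pd.DataFrame,
    variables: Sequence[str],
    species_list: Optional[Sequence[str]] = None,
    n_rand: int = 999,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """S for every species x variable combination."""
    if species_list is None:
        species_list = sorted(presence["species_id"].unique())
    rows = []
    for si, species in enumerate(species_list):
        for vi, variable in enumerate(variables):
            sub_seed = None if seed is None else int(seed) + 7919 * si + vi
            row = specialization_index(sites, presence, variable, species,
                                       n_rand=n_rand, seed=sub_seed)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows)
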