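"""Cross-species concordance between niche limitation and adaptive
divergence, combined with Fisher's method.

For each species the variable with the highest specialization index S
is compared with the variable showing the highest partial Mantel
correlation r_p between genetic distance at outlier loci and
environmental distance.  Under random matching among V variables the
probability of agreement is 1/V; a species whose top variables match
contributes p = 1/V to Fisher's combined test, a non-matching species
contributes p = 1.  Fisher's statistic is chi2 = -2 * sum(ln p) on
2k degrees of freedom; with even df the upper tail has the closed form
exp(-x/2) * sum_{j<k} (x/2)^j / j!.  Discrete per-species p-values make
the combination conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd


@dataclass
class ConcordanceResult:
    per_species: list          # match records (dicts)
    fisher_chi2: float
    df: int
    combined_p: float

    def to_dict(self) -> dict:
        return {
            "per_species": self.per_species,
            "fisher_chi2": self.fisher_chi2,
            "df": self.df,
            "combined_p": self.combined_p,
        }


def _argmax_variables(table: pd.DataFrame, value_col: str) -> list:
    """All variables attaining the maximum of value_col (ties kept)."""
    vmax = table[value_col].max()
    return sorted(table.loc[table[value_col] == vmax, "variable"])


def top_variable_match(
    s_table: pd.DataFrame,
    mantel_table: pd.DataFrame,
    species: str,
) -> dict:
    """Does the top-S variable coincide with the top-r_p variable?

    Ties are kept: all tied maximisers are reported, and a match is
    counted if the two sets intersect (flagged as tied).  The
    per-species null probability of a match under random ranking is
    1/V over the V variables tested for that species.
    """
    s_sub = s_table[s_table["species_id"] == species]
    m_sub = mantel_table[mantel_table["species_id"] == species]
    if s_sub.empty or m_sub.empty:
        raise ValueError(f"no rows for species {species!r}")
    common = sorted(set(s_sub["variable"]) & set(m_sub["variable"]))
    if not common:
        raise ValueError(f"species {species!r}: no shared variables between tables")
    s_sub = s_sub[s_sub["variable"].isin(common)]
    m_sub = m_sub[m_sub["variable"].isin(common)]

    top_s = _argmax_variables(s_sub, "S")
    top_rp = _argmax_variables(m_sub, "r_p")
    match = len(set(top_s) & set(top_rp)) > 0
    n_vars = len(common)
    return {
        "species_id": species,
        "top_S_variable": top_s if len(top_s) > 1 else top_s[0],
        "top_rp_variable": top_rp if len(top_rp) > 1 else top_rp[0],
        "tied": len(top_s) > 1 or len(top_rp) > 1,
        "match": bool(match),
        "n_variables": n_vars,
        "null_p": 1.0 / n_vars if match else 1.0,
    }


def fisher_combined(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns (chi2, df, combined_p) with chi2 = -2 sum(ln p), df = 2k,
    and the upper-tail probability from the closed form for even df.
    p = 0 is rejected: under the +1/(n+1) permutation convention no
    input test can produce it.
    """
    ps = list(p_values)
    if len(ps) == 0:
        raise ValueError("need at least one p-value")
    for p in ps:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    k = len(ps)
    df = 2 * k
    half = chi2 / 2.0
    # upper-tail chi-square with even df: exp(-x/2) * sum_{j<k} (x/2)^j / j!
    term = 1.0
    total = 1.0
    for j in range(1, k):
        term *= half / j
        total += term
    combined_p = math.exp(-half) * total
    combined_p = min(1.0, max(combined_p, 0.0))
    return chi2, df, combined_p


def concordance_report(
    s_table: pd.DataFrame,
    mantel_table: pd.DataFrame,
    species_list: Sequence[str] | None = None,
) -> ConcordanceResult:
    """Per-species top-variable matches plus Fisher's combined test."""
    if species_list is None:
        species_list = sorted(set(s_table["species_id"]) & set(mantel_table["species_id"]))
    records = [top_variable_match(s_table, mantel_table, sp) for sp in species_list]
    chi2, df, p = fisher_combined([r["null_p"] for r in records])
    return ConcordanceResult(per_species=records, fisher_chi2=chi2, df=df, combined_p=p)
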