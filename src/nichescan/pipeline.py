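"""End-to-end orchestration: generate/load → estimate → scan → classify
→ correlate → niche → concordance, with reproducible seeding, logging,
and a report in Markdown + JSON.

The run report mirrors the summaries a field study of this design
prints: a per-species scan summary (sites, individuals, loci, outlier
counts by method and by the intersection rule, with integer-rounded
percentages), a diversity summary (F_ST / H_T / H_W by all / neutral /
outlier subsets), a long table of specialization index S and partial
Mantel r_p per environmental variable, and the cross-species
concordance with Fisher's combined probability.  Every artifact is
stamped with the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import niche as nh
from . import outliers as ol
from . import popgen as pg
from . import synthetic as syn
from .mantel import mantel_suite

log = logging.getLogger("nichescan")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    # input: directory with sites.csv/presence.csv/markers_*.tsv/truth.json,
    # or None to generate the default synthetic scenario
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    scenario_scale: float = 1.0

    # estimator settings
    trim_fraction: float = 0.30
    min_n: int = 4
    bias_correction: bool = True

    # outlier-scan settings
    n_simulated: int = 50_000
    alpha: float = 0.05
    fdr_q: float = 0.10
    window_k: int = 2000
    posterior_threshold: float = 0.95
    use_fdr_flag: bool = True
    mcmc_iter: int = 6000
    mcmc_burn_in: int = 2000
    mcmc_thin: int = 5

    # LD settings
    ld_n_perm: int = 1000
    ld_alpha: float = 0.01

    # matrix-test settings
    n_rand: int = 3000
    mantel_flag_threshold: float = 0.001

    # niche settings
    r_threshold: float = 0.7
    min_count: int = 2
    n_rand_s: int = 999
    prune: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q", "posterior_threshold",
                     "mantel_flag_threshold", "r_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        for name in ("n_simulated", "n_rand", "n_rand_s", "mcmc_iter",
                     "ld_n_perm", "min_n", "min_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _pct(count: int, total: int) -> str:
    """Integer-rounded percentage string, half rounded up."""
    return f"{int(np.floor(100.0 * count / total + 0.5))}%"


@dataclass
class RunReport:
    config: PipelineConfig
    scan_summary: pd.DataFrame
    diversity_summary: pd.DataFrame
    niche_mantel_table: pd.DataFrame
    s_table: pd.DataFrame
    mantel_table: pd.DataFrame
    concordance: conc.ConcordanceResult
    classifications: dict
    ld_fraction: dict
    confusion: Optional[pd.DataFrame] = None
    failed_stage: Optional[str] = None

    def to_markdown(self) -> str:
        cfg = self.config
        lines = [
            "# nichescan run report",
            f"config sha256: {cfg.digest()}  seed: {cfg.seed}",
            "",
            "## Outlier scan summary",
            self.scan_summary.to_markdown(index=False),
            "",
            "## Genetic structure and diversity",
            self.diversity_summary.to_markdown(index=False),
            "",
            "## Specialization and divergence per variable",
            self.niche_mantel_table.to_markdown(index=False),
            "",
            "## Concordance",
            "```json",
            json.dumps(self.concordance.to_dict(), indent=1),
            "```",
        ]
        if self.confusion is not None:
            lines += ["", "## Truth-vs-called confusion (synthetic input)",
                      self.confusion.to_markdown(index=False)]
        return "\n".join(lines)

    def to_json(self) -> dict:
        out = {
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "scan_summary": self.scan_summary.to_dict("records"),
            "diversity_summary": self.diversity_summary.to_dict("records"),
            "niche_mantel_table": self.niche_mantel_table.to_dict("records"),
            "concordance": self.concordance.to_dict(),
            "ld_fraction": self.ld_fraction,
            "failed_stage": self.failed_stage,
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict("records")
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(self.to_markdown())
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json(), fh, indent=1, default=str)
        header = (f"# nichescan config={self.config.digest()} "
                  f"seed={self.config.seed}\n")
        for name, df in [("scan_summary", self.scan_summary),
                         ("diversity_summary", self.diversity_summary),
                         ("specialization_mantel", self.niche_mantel_table),
                         ("mantel", self.mantel_table),
                         ("specialization", self.s_table)]:
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        for sp, cls_df in self.classifications.items():
            with open(out / f"classification_{sp}.tsv", "w") as fh:
                fh.write(header)
                cls_df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage for every species and assemble the report."""
    t0 = time.time()
    stage = "load"
    try:
        if config.input_dir:
            data = syn.SyntheticDataset.read(config.input_dir)
        else:
            scenario = syn.default_scenario(seed=config.seed,
                                            scale=config.scenario_scale)
            data = syn.generate_dataset(scenario)
        log.info("stage load done in %.1fs", time.time() - t0)

        variables = [c for c in data.sites.columns
                     if c not in ("site_id", "x_km", "y_km")]
        if config.prune:
            stage = "prune"
            variables, prune_report = nh.prune_variables(
                data.sites, variables, r_threshold=config.r_threshold)
            log.info("pruned to %d variables", len(variables))

        scan_rows, div_rows, mantel_frames, s_frames = [], [], [], []
        classifications, ld_fraction, confusion_rows = {}, {}, []

        for si, (sp, matrix) in enumerate(sorted(data.matrices.items())):
            sp_seed = int(config.seed) + 1009 * (si + 1)
            t_sp = time.time()

            stage = f"estimate:{sp}"
            fst_all = pg.fst_per_locus(matrix, trim_fraction=config.trim_fraction,
                                       bias_correction=config.bias_correction)

            stage = f"null_cloud:{sp}"
            ns = [int((matrix.site_ids == s).sum()) for s in matrix.sites]
            target = max(fst_all.global_fst, 1e-3)
            cloud = ol.simulate_null_fst(
                target, ns, n_simulated=config.n_simulated, seed=sp_seed,
                trim_fraction=config.trim_fraction,
                bias_correction=config.bias_correction,
                ancestral_freqs=ol.pooled_band_frequencies(matrix))

            stage = f"dfdist:{sp}"
            dfd = ol.dfdist_scan(fst_all, cloud, alpha=config.alpha,
                                 fdr_q=config.fdr_q, window_k=config.window_k)

            stage = f"bayescan:{sp}"
            bayes = ol.bayescan_lite(matrix, n_iter=config.mcmc_iter,
                                     burn_in=config.mcmc_burn_in,
                                     thin=config.mcmc_thin, seed=sp_seed)

            stage = f"classify:{sp}"
            cls = ol.classify_loci(dfd, bayes,
                                   posterior_threshold=config.posterior_threshold,
                                   use_fdr_flag=config.use_fdr_flag)
            classifications[sp] = cls
            outliers = list(cls.loc[cls["class"] == "outlier", "locus_id"])
            neutral = list(cls.loc[cls["class"] == "neutral", "locus_id"])
            n_amb = int((cls["class"] == "ambiguous").sum())
            assert len(outliers) + len(neutral) + n_amb == matrix.n_loci

            n_sites_sp = len(matrix.sites)
            scan_rows.append({
                "species": sp,
                "sites": n_sites_sp,
                "n": matrix.n_individuals,
                "total_loci": matrix.n_loci,
                "bayescan": int((cls["bayes_flag"]).sum()),
                "dfdist": int((cls["dfdist_flag"]).sum()),
                "both": len(outliers),
                "both_pct": _pct(len(outliers), matrix.n_loci),
                "neutral": len(neutral),
                "ambiguous": n_amb,
            })

            if sp in data.truth:
                truth_sel = set(data.truth[sp]["selected_loci"])
                called = set(outliers)
                tp = len(called & truth_sel)
                confusion_rows.append({
                    "species": sp,
                    "planted": len(truth_sel),
                    "called": len(called),
                    "true_positive": tp,
                    "false_positive": len(called - truth_sel),
                    "false_negative": len(truth_sel - called),
                })

            stage = f"ld:{sp}"
            if len(outliers) >= 2:
                pairs = [(a, b) for i, a in enumerate(outliers)
                         for b in outliers[i + 1:]]
                _, frac = ol.ld_permutation_test(
                    matrix, pairs, n_perm=config.ld_n_perm,
                    min_n=config.min_n, seed=sp_seed, alpha=config.ld_alpha)
                ld_fraction[sp] = frac

            stage = f"diversity:{sp}"
            for scope, subset in [("all", None), ("neutral", neutral),
                                  ("outlier", outliers)]:
                if subset is not None and len(subset) == 0:
                    continue
                div = pg.diversity_summary(matrix, subset, scope=scope)
                fst_s = pg.fst_per_locus(matrix, subset,
                                         trim_fraction=config.trim_fraction,
                                         bias_correction=config.bias_correction)
                div_rows.append({"species": sp, "scope": scope,
                                 "fst": round(fst_s.global_fst, 4),
                                 "h_t": round(div.h_t, 4),
                                 "h_w": round(div.h_w, 4)})

            stage = f"mantel:{sp}"
            if len(outliers) >= 1:
                genetic = pg.pairwise_fst(matrix, outliers, min_n=config.min_n,
                                          bias_correction=config.bias_correction)
                mtab = mantel_suite(
                    genetic, data.sites, variables, n_rand=config.n_rand,
                    seed=sp_seed, flag_threshold=config.mantel_flag_threshold,
                    species_id=sp)
                mantel_frames.append(mtab)

            stage = f"niche:{sp}"
            stab = nh.specialization_table(
                data.sites, data.presence, variables, [sp],
                n_rand=config.n_rand_s, seed=sp_seed)
            s_frames.append(stab)
            log.info("species %s done in %.1fs", sp, time.time() - t_sp)

        stage = "concordance"
        s_table = pd.concat(s_frames, ignore_index=True) if s_frames else pd.DataFrame()
        mantel_table = (pd.concat(mantel_frames, ignore_index=True)
                        if mantel_frames else pd.DataFrame())
        combined = s_table.merge(
            mantel_table[["species_id", "variable", "r", "r_p", "p_partial",
                          "significant"]],
            on=["species_id", "variable"], how="left")
        result = conc.concordance_report(s_table, mantel_table)

        report = RunReport(
            config=config,
            scan_summary=pd.DataFrame(scan_rows),
            diversity_summary=pd.DataFrame(div_rows),
            niche_mantel_table=combined,
            s_table=s_table,
            mantel_table=mantel_table,
            concordance=result,
            classifications=classifications,
            ld_fraction=ld_fraction,
            confusion=pd.DataFrame(confusion_rows) if confusion_rows else None,
        )
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        raise
    if config.out_dir:
        report.write(config.out_dir)
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report
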