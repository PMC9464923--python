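"""End-to-end pipeline: simulate/ingest → QC → Q-Q → cond/conjFDR → loci → mixture.

Every stage's seed is derived deterministically from one global seed and the
stage name, so re-running a configuration reproduces every output
bit-identically and single stages can be re-run in isolation. A manifest
records per-stage parameters, output paths and SHA-256 hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._utils import derive_seed
from .condfdr import CondFdr
from .exceptions import ConfigurationError
from .ld import LdReference
from .loci import KnownCatalog, annotate_novelty, clump_loci, loci_table
from .mixture import (BivariateCausalMixture, UnivariateCausalMixture,
                      compare_models_aic, summarize_overlap)
from .preprocess import DEFAULT_EXCLUSIONS, ExclusionRegion, apply_genomic_control, exclude_regions
from .qq import conditional_qq, random_prune
from .simulate import SimulationConfig, simulate
from .sumstats import harmonize, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    outdir: str = "pleioscan_run"
    seed: int = 0
    # either a simulation...
    simulation: SimulationConfig | None = None
    # ...or input files
    sumstats_a: str | None = None
    sumstats_b: str | None = None
    ld_file: str | None = None
    catalog_file: str | None = None
    exclusion_regions: tuple[ExclusionRegion, ...] = DEFAULT_EXCLUSIONS
    pruning_iterations: int = 100
    fdr_threshold: float = 0.05
    qq_strata: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001)
    run_qq: bool = True
    run_mixture: bool = True

    def __post_init__(self):
        if not (0.0 <= self.fdr_threshold <= 1.0):
            raise ConfigurationError(f"fdr_threshold must be in [0, 1]: {self.fdr_threshold}")
        if self.pruning_iterations < 1:
            raise ConfigurationError("pruning_iterations must be >= 1")
        if self.simulation is None and not (self.sumstats_a and self.sumstats_b and self.ld_file):
            raise ConfigurationError(
                "provide either a simulation config or sumstats_a/sumstats_b/ld_file")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        regions = raw.pop("exclusion_regions", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim else None,
            exclusion_regions=tuple(
                ExclusionRegion.parse(r) for r in regions
            ) if regions is not None else DEFAULT_EXCLUSIONS,
            **raw,
        )
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["simulation"] = dataclasses.asdict(self.simulation) if self.simulation else None
        raw["exclusion_regions"] = [
            f"{r.chrom}:{r.start}-{r.end}" for r in self.exclusion_regions
        ]
        raw["qq_strata"] = list(self.qq_strata)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    report: dict = {}
    truth = None

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    # ---------------- input ----------------
    if config.simulation is not None:
        sim_cfg = config.simulation
        if sim_cfg.seed == 0:
            sim_cfg = sim_cfg.with_(seed=derive_seed(config.seed, "simulate"))
        sim = simulate(sim_cfg)
        sim.write(outdir)
        stats_a, stats_b, ld, truth = sim.stats1, sim.stats2, sim.ld, sim.truth
        record("simulate", dataclasses.asdict(sim_cfg),
               [outdir / f for f in ("trait1.sumstats.tsv", "trait2.sumstats.tsv",
                                     "ld_blocks.tsv", "truth.tsv")])
    else:
        stats_a = read_sumstats(config.sumstats_a)
        stats_b = read_sumstats(config.sumstats_b)
        ld = LdReference.read(config.ld_file)
        record("ingest", {"sumstats_a": config.sumstats_a, "sumstats_b": config.sumstats_b,
                          "ld_file": config.ld_file}, [])

    # ---------------- QC ----------------
    pair = harmonize(stats_a, stats_b)
    report["n_shared_snps"] = len(pair)
    pair = exclude_regions(pair, config.exclusion_regions)
    report["n_after_exclusion"] = len(pair)
    pair, gc_a, gc_b = apply_genomic_control(pair)
    report["lambda_gc"] = {pair.trait_a: gc_a.lambda_gc, pair.trait_b: gc_b.lambda_gc}
    report["lambda_gc_raw"] = {pair.trait_a: gc_a.lambda_raw, pair.trait_b: gc_b.lambda_raw}
    qc_path = outdir / "harmonized_qc.tsv"
    pair.df.to_csv(qc_path, sep="\t", index=False)
    record("preprocess", {"regions": [f"{r.chrom}:{r.start}-{r.end}"
                                      for r in config.exclusion_regions]}, [qc_path])

    # ---------------- conditional Q-Q ----------------
    if config.run_qq:
        qq_paths = []
        for primary in ("a", "b"):
            strata = conditional_qq(pair, ld, primary, config.qq_strata,
                                    config.pruning_iterations,
                                    derive_seed(config.seed, f"qq-{primary}"))
            path = outdir / f"qq_{primary}.tsv"
            strata.to_frame().to_csv(path, sep="\t", index=False)
            qq_paths.append(path)
        record("qq", {"strata": list(config.qq_strata),
                      "iterations": config.pruning_iterations}, qq_paths)

    # ---------------- condFDR / conjFDR ----------------
    fdr = CondFdr(pair, ld).fit(iterations=config.pruning_iterations,
                                seed=derive_seed(config.seed, "condfdr"),
                                threshold=config.fdr_threshold)
    fdr_path = outdir / "fdr_per_snp.tsv"
    fdr.assignment.write(fdr_path)
    grid_path_ab = outdir / "fdr_grid_ab.tsv"
    grid_path_ba = outdir / "fdr_grid_ba.tsv"
    fdr.grid_ab.to_frame().to_csv(grid_path_ab, sep="\t")
    fdr.grid_ba.to_frame().to_csv(grid_path_ba, sep="\t")
    report["n_sig_condfdr_ab"] = int(fdr.assignment.df["sig_condfdr_ab"].sum())
    report["n_sig_condfdr_ba"] = int(fdr.assignment.df["sig_condfdr_ba"].sum())
    report["n_sig_conjfdr"] = int(fdr.assignment.df["sig_conjfdr"].sum())
    record("condfdr", {"iterations": config.pruning_iterations,
                       "threshold": config.fdr_threshold},
           [fdr_path, grid_path_ab, grid_path_ba])

    # ---------------- loci ----------------
    loci_paths = []
    for statistic in ("condfdr", "conjfdr"):
        loci = clump_loci(fdr.assignment, ld, statistic, config.fdr_threshold)
        if config.catalog_file:
            catalog = KnownCatalog.read(config.catalog_file)
            original_p = pair.df.set_index("snp")["p_a"]
            annotate_novelty(loci, original_p, catalog, ld, config.fdr_threshold)
        table = loci_table(loci)
        path = outdir / f"loci_{statistic}.tsv"
        table.to_csv(path, sep="\t", index=False)
        loci_paths.append(path)
        report[f"n_loci_{statistic}"] = len(loci)
        report[f"n_concordant_{statistic}"] = sum(l.direction == "concordant" for l in loci)
    record("loci", {"threshold": config.fdr_threshold}, loci_paths)

    # truth-based evaluation when simulating
    if truth is not None:
        comp = truth.set_index("snp")["component"]
        adf = fdr.assignment.df
        called = adf.loc[adf["sig_condfdr_ab"], "snp"]
        if len(called):
            false = comp.loc[called].isin(["null", "c2"])
            report["fdp_condfdr_ab"] = float(false.mean())
        else:
            report["fdp_condfdr_ab"] = 0.0
        report["n_called_condfdr_ab"] = int(len(called))

    # ---------------- mixture model ----------------
    if config.run_mixture:
        prune_seed = derive_seed(config.seed, "mixture-prune")
        subset = random_prune(pair, ld, iterations=1, seed=prune_seed)[0]
        sub = pair.df.set_index("snp").loc[subset]
        n_a = float(np.median(sub["n_a"]))
        n_b = float(np.median(sub["n_b"]))
        fit_a = UnivariateCausalMixture(sub["z_a"].to_numpy(), n_a).fit(
            seed=derive_seed(config.seed, "uni-a"))
        fit_b = UnivariateCausalMixture(sub["z_b"].to_numpy(), n_b).fit(
            seed=derive_seed(config.seed, "uni-b"))
        biv = BivariateCausalMixture(sub["z_a"].to_numpy(), sub["z_b"].to_numpy(), fit_a, fit_b)
        full = biv.fit(seed=derive_seed(config.seed, "biv"))
        constrained = biv.fit_constrained_null()
        m_total = len(pair)
        summary = summarize_overlap(full.params, m_total, n_a, n_b)
        summary.aic_delta = compare_models_aic(full, constrained)
        mix_report = {
            "pi1": full.params.pi1, "pi2": full.params.pi2, "pi12": full.params.pi12,
            "rho12": full.params.rho12, "sigma01": full.params.sigma01,
            "sigma02": full.params.sigma02,
            "shared": summary.shared, "specific1": summary.specific1,
            "specific2": summary.specific2, "dice": summary.dice, "rg": summary.rg,
            "n90_1": summary.n90_1, "n90_2": summary.n90_2,
            "aic_delta": summary.aic_delta,
        }
        mix_path = outdir / "mixture.json"
        with open(mix_path, "w") as fh:
            json.dump(mix_report, fh, indent=2, sort_keys=True)
        report["mixture"] = mix_report
        record("mixture", {"pruned_snps": len(sub)}, [mix_path])

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", report_path)
    return report
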