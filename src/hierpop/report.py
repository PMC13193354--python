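"""Configuration-driven pipeline: simulate/load -> filter -> statistics -> hierarchy.

Every run is fully determined by its :class:`RunConfig` (seed mandatory); all
output files are deterministic byte-for-byte under a fixed seed.  Wall-clock
timings go only to the run log, never into data outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differentiation import amova, differentiation_stats, pairwise_differentiation
from .diversity import diversity_table
from .equilibrium import hwe_table, ld_table
from .hierarchy import decompose, order_summary
from .io_genotypes import GenotypeMatrix, filter_missing, read_csv, read_genepop, write_csv, write_genepop
from .simulate import SURVEY_LOCATION_PLAN, assemble_locations, simulate_hierarchy, survey_config

ALL_STAGES = ["filter", "diversity", "hwe", "ld", "diff", "amova", "hierarchy", "summary", "report"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``input_genepop``, ``input_csv`` or ``simulate`` must supply
    the data.  ``stages`` lists the stages to run (default: all).
    """

    seed: int
    out_dir: str
    input_genepop: str | None = None
    input_csv: str | None = None
    simulate: bool = False
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    max_missing_loci: int | None = None
    n_perm: int = 999
    B: int = 2000
    n_replicates: int = 10
    k_ranges: dict | None = None
    n_min: int = 15
    alpha: float = 0.05
    bootstrap: int = 49
    max_order: int = 3

    def validate(self) -> None:
        sources = [self.input_genepop is not None, self.input_csv is not None, self.simulate]
        if sum(sources) != 1:
            raise ValueError("config must name exactly one input: a GenePop file, "
                             "a CSV file, or simulate: true")
        for p in (self.input_genepop, self.input_csv):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # where outputs land is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_input(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.input_genepop:
        return read_genepop(Path(cfg.input_genepop).read_text(encoding="utf-8"))
    if cfg.input_csv:
        return read_csv(Path(cfg.input_csv).read_text(encoding="utf-8"))
    sim_cfg = survey_config(seed=cfg.seed)
    gm, truth = simulate_hierarchy(sim_cfg)
    gm = assemble_locations(gm, truth, SURVEY_LOCATION_PLAN, seed=cfg.seed + 1)
    return gm


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage error writes a FAILED marker naming the stage (partial outputs are
    kept) and re-raises.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    stage = "load"

    def save_df(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)

    try:
        t0 = time.perf_counter()
        gm = _load_input(cfg)
        log_lines.append(f"load: n={gm.n_individuals} loci={gm.n_loci} "
                         f"({time.perf_counter() - t0:.2f}s)")
        (out / "genotypes.csv").write_text(write_csv(gm), encoding="utf-8")
        (out / "genotypes.gen").write_text(write_genepop(gm, digits=2), encoding="utf-8")

        removed: list[str] = []
        if "filter" in cfg.stages and cfg.max_missing_loci is not None:
            stage = "filter"
            gm, removed = filter_missing(gm, cfg.max_missing_loci)
            log_lines.append(f"filter: removed {len(removed)} individuals")
            (out / "removed_individuals.json").write_text(json.dumps(removed), encoding="utf-8")

        rng = np.random.default_rng(cfg.seed)
        report_parts: dict[str, pd.DataFrame] = {}

        if "diversity" in cfg.stages:
            stage = "diversity"
            t0 = time.perf_counter()
            div = diversity_table(gm)
            save_df(div, "diversity.csv")
            report_parts["diversity"] = div
            log_lines.append(f"diversity: {time.perf_counter() - t0:.2f}s")

        if "hwe" in cfg.stages:
            stage = "hwe"
            t0 = time.perf_counter()
            hwe = hwe_table(gm, B=cfg.B, seed=int(rng.integers(2**31 - 1)), alpha=cfg.alpha)
            save_df(hwe, "hwe.csv")
            report_parts["hwe"] = hwe
            log_lines.append(f"hwe: {time.perf_counter() - t0:.2f}s")

        if "ld" in cfg.stages:
            stage = "ld"
            t0 = time.perf_counter()
            ld = ld_table(gm, B=min(cfg.n_perm, 499), seed=int(rng.integers(2**31 - 1)),
                          alpha=cfg.alpha)
            save_df(ld, "ld.csv")
            log_lines.append(f"ld: {time.perf_counter() - t0:.2f}s")

        if "diff" in cfg.stages:
            stage = "diff"
            t0 = time.perf_counter()
            recs = differentiation_stats(gm, n_perm=cfg.n_perm,
                                         seed=int(rng.integers(2**31 - 1)))
            diff_rows = []
            for name, r in recs.items():
                diff_rows.append({
                    "statistic": name, "value": r.value, "jackknife_SE": r.jackknife_se,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "perm_p": r.perm_p,
                    "K": r.K, "H_S": r.H_S, "H_T": r.H_T,
                })
            diff = pd.DataFrame(diff_rows)
            save_df(diff, "differentiation.csv")
            pw = pairwise_differentiation(gm, n_perm=min(cfg.n_perm, 199),
                                          seed=int(rng.integers(2**31 - 1)))
            save_df(pw, "pairwise_differentiation.csv")
            report_parts["diff"] = diff
            report_parts["pairwise"] = pw
            log_lines.append(f"diff: {time.perf_counter() - t0:.2f}s")

        if "amova" in cfg.stages:
            stage = "amova"
            t0 = time.perf_counter()
            am = amova(gm, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1)))
            (out / "amova.json").write_text(json.dumps(asdict(am), indent=2), encoding="utf-8")
            report_parts["amova"] = pd.DataFrame([asdict(am)])
            log_lines.append(f"amova: {time.perf_counter() - t0:.2f}s")

        tree = None
        if "hierarchy" in cfg.stages:
            stage = "hierarchy"
            t0 = time.perf_counter()
            tree = decompose(gm, max_order=cfg.max_order, k_ranges=cfg.k_ranges,
                             n_min=cfg.n_min, alpha=cfg.alpha,
                             n_replicates=cfg.n_replicates, bootstrap=cfg.bootstrap,
                             seed=int(rng.integers(2**31 - 1)))
            (out / "tree.json").write_text(tree.to_json(), encoding="utf-8")
            save_df(tree.to_frame(), "assignments.csv")
            log_lines.append(f"hierarchy: {time.perf_counter() - t0:.2f}s")

        if "summary" in cfg.stages and tree is not None:
            stage = "summary"
            t0 = time.perf_counter()
            summ = order_summary(tree, gm, hwe_B=min(cfg.B, 2000),
                                 seed=int(rng.integers(2**31 - 1)), alpha=cfg.alpha)
            save_df(summ, "order_summary.csv")
            report_parts["summary"] = summ
            log_lines.append(f"summary: {time.perf_counter() - t0:.2f}s")

        if "report" in cfg.stages:
            stage = "report"
            md = ["# hierpop run report", "",
                  f"- seed: {cfg.seed}",
                  f"- config hash: {cfg.config_hash()}",
                  f"- individuals: {gm.n_individuals}, loci: {gm.n_loci}",
                  f"- removed by missing-data filter: {len(removed)}", ""]
            for title, key in [("Diversity (per group, over loci)", "diversity"),
                               ("HWE tests", "hwe"),
                               ("Multi-locus differentiation", "diff"),
                               ("Pairwise differentiation", "pairwise"),
                               ("AMOVA", "amova"),
                               ("Order-wise trends", "summary")]:
                if key in report_parts:
                    df = report_parts[key]
                    if key == "diversity":
                        df = df[df["locus"] == "over loci"]
                    md += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
            (out / "report.md").write_text("\n".join(md), encoding="utf-8")

        cfg_dict = asdict(cfg)
        cfg_dict.pop("out_dir", None)
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg_dict,
            "config_hash": cfg.config_hash(),
            "stages_run": list(cfg.stages),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str),
                                           encoding="utf-8")
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n", encoding="utf-8")
        raise
    return out
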