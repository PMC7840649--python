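"""End-to-end orchestration: simulate -> impute -> prepare -> search -> effects.

Every stage is a pure function of its inputs plus the run seed, and the
run manifest records the configuration snapshot, seed, per-stage timings,
and SHA-256 checksums of every file written — so a run is reproducible
and auditable from the manifest alone.

Scheme selection happens once per outcome, on the across-imputation
average of the adjusted outcomes (a stable point estimate of each
student-wave value); the selected scheme is then refit to every imputed
dataset and the per-imputation fits are pooled (Rubin's rules for rank
means and Wald contrasts, D2 for the model chi-square). This keeps model
selection out of the pooling step, which Rubin's rules do not cover.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import GROUPS, ITEM_COUNTS, N_WAVES, WAVE_LABELS
from .effects import MeanGrid, printed_grid, round_half_up, summarize
from .imputation import impute
from .mean_structure import PooledMeanModel, fit_constrained, pool_fits, rmsea, srmr
from .constraint_search import GapRule, search
from .outcome_prep import (
    DEFAULT_WINSOR_Z,
    item_columns,
    prepare_outcome_grid,
)
from .trial_synth import (
    COVARIATE_COLS,
    DEFAULT_ZERO_POINTS,
    SimConfig,
    config_from_dict,
    config_to_dict,
    generate_trial,
)


@dataclass
class PipelineConfig:
    """Everything a full evaluation run needs besides the seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    outcomes: tuple = tuple(ITEM_COUNTS)
    m: int = 10  # completed datasets; production analyses use more
    k_aux: int = 4  # auxiliary principal components
    alpha: float = 0.05
    gap_threshold: float = 2.0
    gap_mode: str = "greedy"  # one guarded merge per attempt
    attempt_cap: int = 60
    winsor_z: float | None = DEFAULT_WINSOR_Z
    zero_points: dict = field(default_factory=lambda: dict(DEFAULT_ZERO_POINTS))
    write_imputations: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = config_from_dict(d["sim"]) if "sim" in d else SimConfig()
        kwargs = {k: v for k, v in d.items() if k != "sim"}
        if "outcomes" in kwargs:
            kwargs["outcomes"] = tuple(kwargs["outcomes"])
        return cls(sim=sim, **kwargs)

    def to_dict(self) -> dict:
        return {
            "sim": config_to_dict(self.sim),
            "outcomes": list(self.outcomes),
            "m": self.m, "k_aux": self.k_aux, "alpha": self.alpha,
            "gap_threshold": self.gap_threshold, "gap_mode": self.gap_mode,
            "attempt_cap": self.attempt_cap,
            "winsor_z": self.winsor_z, "zero_points": dict(self.zero_points),
            "write_imputations": self.write_imputations,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record(self, path: Path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "version": self.version,
             "timings": self.timings, "outputs": self.outputs},
            indent=2, sort_keys=True))


def grid_from_pooled(outcome: str, pooled: PooledMeanModel,
                     n_per_group: np.ndarray) -> MeanGrid:
    return MeanGrid(outcome=outcome,
                    means=pooled.rank_means[pooled.scheme.ranks - 1],
                    n=n_per_group)


def report_tables(outcome: str, pooled: PooledMeanModel, grid: MeanGrid,
                  srmr_value: float, summary) -> str:
    """Plain-text report: fit rows, rank/Wald block, and the 8 x 6 mean grid."""
    lines = [f"=== {outcome} ==="]
    rm = rmsea(pooled.chisq_mean, pooled.df, int(grid.n.sum()), len(GROUPS))
    lines.append("Model results (unconstrained / constrained / difference):")
    lines.append("  chisq     df  RMSEA  SRMR")
    lines.append(f"  {0.0:7.2f} {0:4d}  {0.0:.2f}   {0.0:.2f}   (unconstrained)")
    lines.append(f"  {pooled.chisq_mean:7.2f} {pooled.df:4d}  {rm:.2f}   "
                 f"{srmr_value:.2f}   (constrained)")
    lines.append(f"  {pooled.chisq_mean:7.2f} {pooled.df:4d}  "
                 f"p = {pooled.pooled_chisq_p:.3f}   (difference)")
    lines.append("Ranks and adjacent Wald separations:")
    order = np.argsort(pooled.rank_means)
    for i, idx in enumerate(order):
        line = f"  rank {i + 1}: mean = {pooled.rank_means[idx]:6.2f}"
        if i + 1 < len(order):
            w = pooled.wald(int(order[i]) + 1, int(order[i + 1]) + 1)
            line += f"   {i + 1} v {i + 2}: z = {w.statistic:6.2f}, p = {w.p:.3f}"
        lines.append(line)
    lines.append("Model-estimated means:")
    hdr = "  group                n  " + "  ".join(f"{w:>8s}" for w in WAVE_LABELS)
    lines.append(hdr)
    for gi, g in enumerate(GROUPS):
        cells = "  ".join(f"{grid.means[gi, t]:8.2f}" for t in range(N_WAVES))
        lines.append(f"  {g[0]}-{g[1]}-C{g[2]:<12d} {grid.n[gi]:5d}  {cells}")
    r = summary.rounded()
    lines.append(
        f"Effects: avg diff {r['avg_diff']:.2f} POMS "
        f"(range {r['diff_range'][0]:.2f}-{r['diff_range'][1]:.2f}); "
        f"avg RRR {r['avg_rrr']:.0f}% (range {r['rrr_range'][0]:.0f}-"
        f"{r['rrr_range'][1]:.0f}%); spring-8th avg RRR "
        f"{r['final_wave_avg_rrr']:.0f}%")
    return "\n".join(lines)


def run_evaluation(config: PipelineConfig, outdir: str | Path,
                   seed: int = 0) -> RunManifest:
    """Run the full evaluation and write tables, reports, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=seed, version=__version__)

    t0 = time.perf_counter()
    sim = SimConfig(**{**config.sim.__dict__, "seed": seed})
    table = generate_trial(sim)
    table_path = outdir / "trial_table.csv"
    table.to_csv(table_path, index=False)
    manifest.record(table_path)
    manifest.timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cols = [c for o in config.outcomes
            for c in item_columns(o, ITEM_COUNTS[o])]
    stack = impute(table, m=config.m, k=config.k_aux, seed=seed + 1,
                   columns=cols)
    if config.write_imputations:
        impdir = outdir / "imputations"
        impdir.mkdir(exist_ok=True)
        for i, d in enumerate(stack.datasets):
            p = impdir / f"imputation_{i:03d}.csv"
            d.to_csv(p, index=False)
            manifest.record(p)
        mpath = impdir / "stack_manifest.json"
        mpath.write_text(json.dumps({"m": stack.m, "k": stack.n_aux_components,
                                     "seed": stack.seed,
                                     "columns": list(stack.imputed_columns)}))
        manifest.record(mpath)
    manifest.timings["impute"] = time.perf_counter() - t0

    results = {}
    report_chunks = []
    for outcome in config.outcomes:
        t0 = time.perf_counter()
        n_items = ITEM_COUNTS[outcome]
        grids = [prepare_outcome_grid(d, outcome, n_items,
                                      list(COVARIATE_COLS), config.zero_points,
                                      winsor_z=config.winsor_z)
                 for d in stack.datasets]

        # model selection on all m grids jointly (pooled test statistics)
        trace = search(grids, alpha=config.alpha,
                       gap_rule=GapRule(threshold=config.gap_threshold,
                                        mode=config.gap_mode),
                       attempt_cap=config.attempt_cap)
        scheme = trace.final_scheme

        fits = [fit_constrained(g, scheme) for g in grids]
        pooled = pool_fits(fits)
        srmr_value = float(np.mean([srmr(f, g) for f, g in zip(fits, grids)]))
        grid = grid_from_pooled(outcome, pooled, grids[0].n_per_group())
        summary = summarize(grid)
        results[outcome] = {
            "scheme_ranks": pooled.scheme.ranks.tolist(),
            "rank_means": pooled.rank_means.tolist(),
            "chisq_mean": pooled.chisq_mean,
            "df": pooled.df,
            "pooled_chisq_p": pooled.pooled_chisq_p,
            "rmsea": rmsea(pooled.chisq_mean, pooled.df, int(grid.n.sum()),
                           len(GROUPS)),
            "srmr": srmr_value,
            "n_attempts": trace.n_attempts,
            "baseline_level": trace.baseline_level,
            "effects": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in summary.rounded().items()},
        }
        gpath = outdir / f"means_{outcome}.csv"
        grid.write_csv(gpath)
        manifest.record(gpath)
        report_chunks.append(report_tables(outcome, pooled, grid, srmr_value,
                                           summary))
        manifest.timings[f"analyze_{outcome}"] = time.perf_counter() - t0

    rpath = outdir / "results.json"
    rpath.write_text(json.dumps(results, indent=2, sort_keys=True))
    manifest.record(rpath)
    tpath = outdir / "report.txt"
    tpath.write_text("\n\n".join(report_chunks) + "\n")
    manifest.record(tpath)
    manifest.save(outdir / "manifest.json")
    return manifest


def effects_only_report(outcomes=tuple(ITEM_COUNTS)) -> dict:
    """Effect summaries straight from the packaged printed mean grids."""
    out = {}
    for o in outcomes:
        s = summarize(printed_grid(o))
        out[o] = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in s.rounded().items()}
    return out
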