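"""Orchestration of the full comparative analysis.

A run takes a caste trait table and an ultrametric chronogram, matches taxa,
and for each configured caste pair: drops taxa missing either trait (per-pair,
not globally), prunes the tree, log10-transforms, computes contrasts of both
traits on the identical pruned tree, fits a through-origin major-axis line and
tests isometry (b0 = 1). Optionally the same analysis is repeated with a genus
excluded, to measure that clade's leverage on the allometry. A second entry
point reconstructs ancestral SSDi states and exports a painted tree.

Outputs are deterministic: re-running with the same config and seed writes
byte-identical CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import MAFit, ma_fit, ma_slope_test, _verdict, studentized_residuals
from .ancestral import AncestralMap, ml_ancestral_states, paint_tree
from .contrasts import compute_contrasts
from .dimorphism import DEFAULT_THRESHOLD, ssdi_table
from .phylo_io import (
    PhyloTree,
    check_ultrametric,
    load_tree,
    match_taxa,
    prune_to_taxa,
    read_trait_table,
    resolve_polytomies,
)

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = (("male", "queen"), ("male", "worker"), ("queen", "worker"))


@dataclass
class RunConfig:
    traits: str | pd.DataFrame = None
    tree: str | PhyloTree = None
    dialect: str | None = None
    convention: str = "queen_over_male"
    threshold: float = DEFAULT_THRESHOLD
    log10: bool = True
    pairs: tuple = DEFAULT_PAIRS
    exclude_genus: str | None = None
    through_origin: bool = True
    b0: float = 1.0
    ultrametric_tol: float = 1e-6
    force: bool = False
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        allowed = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pairs" in raw:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        return cls(**raw)


@dataclass
class PairResult:
    fit: MAFit
    taxa: list[str]
    contrasts: pd.DataFrame
    max_abs_studentized_residual: float
    outliers: list[int]


@dataclass
class RenschResults:
    runs: dict  # run name ("full", "excluded") -> {pair label: PairResult}
    ssdi: pd.DataFrame
    config: RunConfig
    log: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for run, pairs in self.runs.items():
            out[run] = {lbl: pr.fit.to_dict() for lbl, pr in pairs.items()}
        return out


def _load_inputs(config: RunConfig) -> tuple[PhyloTree, pd.DataFrame]:
    table = (
        config.traits
        if isinstance(config.traits, pd.DataFrame)
        else read_trait_table(config.traits)
    )
    tree = config.tree if isinstance(config.tree, PhyloTree) else load_tree(config.tree, config.dialect)
    flag, dev = check_ultrametric(tree, rel_tol=config.ultrametric_tol)
    if not flag:
        msg = f"tree is not ultrametric (max relative deviation {dev:.3g})"
        if config.force:
            logger.warning("%s; continuing (force=True)", msg)
        else:
            raise ValueError(msg + "; pass force=True to proceed anyway")
    if not tree.is_binary:
        tree = resolve_polytomies(tree, seed=config.seed)
    return tree, table


def _caste_column(caste: str) -> str:
    if caste not in ("worker", "male", "queen"):
        raise ValueError(f"caste must be worker/male/queen, got {caste!r}")
    return f"{caste}_mm"


def _pair_analysis(tree: PhyloTree, table: pd.DataFrame, y: str, x: str, config: RunConfig) -> PairResult:
    cols = [_caste_column(x), _caste_column(y)]
    sub = table.dropna(subset=cols)
    if len(sub) < 3:
        raise ValueError(f"pair {y}~{x}: only {len(sub)} taxa with both traits (need >= 3)")
    pruned, aligned = match_taxa(tree, sub)
    cs_x = compute_contrasts(pruned, aligned[cols[0]], log10_flag=config.log10, trait=x)
    cs_y = compute_contrasts(pruned, aligned[cols[1]], log10_flag=config.log10, trait=y)
    fit = ma_fit(cs_x.contrasts, cs_y.contrasts, through_origin=config.through_origin, pair=(y, x))
    ma_slope_test(fit, b0=config.b0)
    fit.verdict = _verdict(fit)
    tstud = studentized_residuals(fit)
    frame = pd.DataFrame(
        {
            "node_id": cs_x.node_ids,
            f"contrast_{x}": cs_x.contrasts,
            f"contrast_{y}": cs_y.contrasts,
            "sd": cs_x.sds,
            "studentized_residual": tstud,
        }
    )
    return PairResult(
        fit=fit,
        taxa=list(aligned.index),
        contrasts=frame,
        max_abs_studentized_residual=float(np.max(np.abs(tstud))),
        outliers=[int(i) for i in cs_x.node_ids[np.abs(tstud) > 3]],
    )


def run_rensch_pipeline(config: RunConfig) -> RenschResults:
    """Per-pair contrasts + MA isometry tests; optionally repeated with a
    genus excluded. Returns a RenschResults (and writes outputs if
    ``config.outdir`` is set)."""
    tree, table = _load_inputs(config)
    ssdi = ssdi_table(table, convention=config.convention, threshold=config.threshold)

    runs: dict[str, dict[str, PairResult]] = {}
    variants = {"full": table}
    if config.exclude_genus:
        if "genus" in table.columns:
            mask = table["genus"].str.lower() != config.exclude_genus.lower()
        else:
            mask = ~table.index.str.lower().str.startswith(config.exclude_genus.lower() + " ")
        variants["excluded"] = table[mask]
    for name, tbl in variants.items():
        runs[name] = {}
        for y, x in config.pairs:
            pr = _pair_analysis(tree, tbl, y, x, config)
            runs[name][f"{y}~{x}"] = pr
            logger.info(
                "%s %s~%s: n=%d slope=%.4f r2=%.4f p=%.4g (%s)",
                name, y, x, pr.fit.n_pairs, pr.fit.slope, pr.fit.r2, pr.fit.p, pr.fit.verdict,
            )
    results = RenschResults(runs=runs, ssdi=ssdi, config=config, log=_run_log(config, runs))
    if config.outdir:
        _write_outputs(results, Path(config.outdir))
    return results


def run_ssd_reconstruction(config: RunConfig):
    """SSDi table -> ML ancestral states -> node CSV + painted tree.

    Returns the AncestralMap; files are written when ``config.outdir`` is set.
    """
    tree, table = _load_inputs(config)
    eligible = table.dropna(subset=["queen_mm", "male_mm"])
    pruned, aligned = match_taxa(tree, eligible)
    ssdi = ssdi_table(aligned, convention=config.convention, threshold=config.threshold)
    anc = ml_ancestral_states(pruned, ssdi["ssdi"], trait=f"SSDi ({config.convention})")
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        anc.node_frame().to_csv(out / "ancestral_states.csv", index=False, float_format="%.10g")
        fig = paint_tree(anc)
        fig.savefig(out / "painted_tree.svg")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return anc


def _run_log(config: RunConfig, runs) -> dict:
    cfg = asdict(config)
    for key in ("traits", "tree"):
        if not isinstance(cfg[key], (str, type(None))):
            cfg[key] = f"<in-memory {type(cfg[key]).__name__}>"
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "taxa": {name: {lbl: pr.taxa for lbl, pr in pairs.items()} for name, pairs in runs.items()},
    }


def _write_outputs(results: RenschResults, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results.ssdi.reset_index().to_csv(outdir / "ssdi.csv", index=False, float_format="%.10g")
    with open(outdir / "ssdi_summary.json", "w") as fh:
        json.dump(
            {"counts": results.ssdi.attrs.get("counts", {}), "convention": results.ssdi.attrs.get("convention")},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    for run, pairs in results.runs.items():
        for lbl, pr in pairs.items():
            safe = lbl.replace("~", "_on_")
            pr.contrasts.to_csv(outdir / f"contrasts_{run}_{safe}.csv", index=False, float_format="%.10g")
    with open(outdir / "rensch_results.json", "w") as fh:
        json.dump(results.summary(), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(results.log, fh, indent=2, sort_keys=True)
        fh.write("\n")
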