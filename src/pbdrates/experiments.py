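"""Reduced-scale experiment drivers.

Each driver writes a ``manifest.json`` (inputs, seeds, version) plus TSV
tables into an output directory; rerunning a driver from its manifest
reproduces the tables byte-for-byte.  The three experiments mirror the main
simulation studies of the equivalent-rates analysis:

- ``compare``: tree statistics (SR, gamma, stairs2) under PBD vs. the two
  equivalent BD models, varying each PBD parameter over five values;
- ``dr``: median DR tip rate on PBD and equivalent-constant-BD trees against
  the equivalent constant birth rate;
- ``truncation``: constant-BD fits of PBD trees sliced at regularly spaced
  ages, against the equivalent constant rates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fit import truncation_sweep
from .params import PBDParams, SimulationConfig, TREE_SIM_DEFAULTS
from .rates import PiecewiseConstantRates, equivalent_constant_rates
from .simulate import run_comparison_experiment, simulate_bd_batch, simulate_pbd_batch
from .stats import batch_stats, dr_statistic, summarize_stats

#: Multiplicative factor grids per varied parameter (five values each, the
#: default in the middle).  Amplitudes are asymmetric where the larger
#: factors would make the process explode over 15 Myr.
COMPARISON_FACTORS: dict[str, list[float]] = {
    "lambda1": [1 / 3, 1 / 2, 1.0, 1.25, 1.5],
    "lambda2": [1 / 4, 1 / 2, 1.0, 2.0, 4.0],
    "lambda3": [1 / 4, 1 / 2, 1.0, 2.0, 3.0],
    "mu1": [1 / 4, 1 / 2, 1.0, 2.0, 4.0],
    "mu2": [1 / 4, 1 / 2, 1.0, 2.0, 4.0],
}

EXPERIMENTS = ("compare", "dr", "truncation")


@dataclass
class ExperimentManifest:
    """Everything needed to reproduce an experiment's tables."""

    experiment: str
    params: dict
    T: float
    n_grid: int
    seed: int
    n_reps: int
    extra: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def save(self, path: Path) -> None:
        d = asdict(self)
        d["timestamp"] = d["timestamp"] or datetime.now(timezone.utc).isoformat()
        path.write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def load(cls, path: Path) -> "ExperimentManifest":
        d = json.loads(Path(path).read_text())
        d.pop("version", None)
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def _config(manifest: ExperimentManifest, seed: int) -> SimulationConfig:
    return SimulationConfig(T=manifest.T, n_grid=manifest.n_grid, seed=seed)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_compare(manifest: ExperimentManifest, outdir: Path) -> Path:
    """Tree-statistic comparison across 25 parameter combinations x 3 models."""
    outdir.mkdir(parents=True, exist_ok=True)
    base = PBDParams.from_dict(manifest.params)
    rows = []
    combo = 0
    for pname, factors in COMPARISON_FACTORS.items():
        for fac in factors:
            d = base.as_dict()
            d[pname] = d[pname] * fac
            params = PBDParams.from_dict(d)
            cfg = _config(manifest, manifest.seed + combo)
            batches = run_comparison_experiment(params, cfg, manifest.n_reps)
            for model, batch in batches.items():
                summ = summarize_stats(batch_stats(batch))
                for _, r in summ.iterrows():
                    rows.append(
                        {
                            "varied": pname,
                            "factor": fac,
                            "value": d[pname],
                            "model": model,
                            **r.to_dict(),
                        }
                    )
            combo += 1
    table = pd.DataFrame(rows)
    _write(table, outdir / "comparison_stats.tsv")
    manifest.save(outdir / "manifest.json")
    return outdir / "comparison_stats.tsv"


def run_dr(manifest: ExperimentManifest, outdir: Path) -> Path:
    """Median DR tip rate vs. the equivalent constant birth rate."""
    outdir.mkdir(parents=True, exist_ok=True)
    params = PBDParams.from_dict(manifest.params)
    cfg = _config(manifest, manifest.seed)
    const = equivalent_constant_rates(params)
    pbd = simulate_pbd_batch(params, cfg, manifest.n_reps)
    bd = simulate_bd_batch(
        PiecewiseConstantRates.constant(const.lambda_tilde, const.mu_tilde, cfg.T),
        cfg,
        manifest.n_reps,
    )
    rows = []
    for model, batch in (("PBD", pbd), ("BD", bd)):
        for i, tree in enumerate(batch.trees):
            dr = dr_statistic(tree)[1] if tree is not None and tree.n_tips >= 2 else np.nan
            rows.append(
                {
                    "model": model,
                    "replicate": i,
                    "n_tips": tree.n_tips if tree is not None else 0,
                    "dr_median": dr,
                    "lambda_tilde": const.lambda_tilde,
                }
            )
    table = pd.DataFrame(rows)
    _write(table, outdir / "dr_vs_lambda.tsv")
    manifest.save(outdir / "manifest.json")
    return outdir / "dr_vs_lambda.tsv"


def run_truncation(manifest: ExperimentManifest, outdir: Path) -> Path:
    """BD estimates on sliced PBD trees over a regular grid of slice ages."""
    outdir.mkdir(parents=True, exist_ok=True)
    params = PBDParams.from_dict(manifest.params)
    cfg = _config(manifest, manifest.seed)
    taus = manifest.extra.get("taus")
    if taus is None:
        taus = np.linspace(0.0, 4.0, 17).tolist()
    batch = simulate_pbd_batch(params, cfg, manifest.n_reps)
    table = truncation_sweep(batch, taus, origin_age=cfg.T)
    const = equivalent_constant_rates(params)
    table["lambda_tilde"] = const.lambda_tilde
    table["mu_tilde"] = const.mu_tilde
    _write(table, outdir / "truncation_estimates.tsv")
    manifest.save(outdir / "manifest.json")
    return outdir / "truncation_estimates.tsv"


_RUNNERS = {"compare": run_compare, "dr": run_dr, "truncation": run_truncation}


def run_experiment(
    name: str,
    outdir,
    params: PBDParams | None = None,
    T: float = 15.0,
    n_grid: int = 200,
    seed: int = 0,
    n_reps: int = 200,
    **extra,
) -> Path:
    """Run a named experiment at (reduced) default scale into ``outdir``."""
    if name not in _RUNNERS:
        raise ValueError(f"unknown experiment {name!r}; valid names: {', '.join(EXPERIMENTS)}")
    params = params or TREE_SIM_DEFAULTS
    manifest = ExperimentManifest(
        experiment=name,
        params=params.as_dict(),
        T=T,
        n_grid=n_grid,
        seed=seed,
        n_reps=n_reps,
        extra=extra,
    )
    return _RUNNERS[name](manifest, Path(outdir))


def rerun_from_manifest(manifest_path, outdir) -> Path:
    """Re-execute an experiment from its manifest (byte-identical tables)."""
    manifest = ExperimentManifest.load(Path(manifest_path))
    return _RUNNERS[manifest.experiment](manifest, Path(outdir))
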