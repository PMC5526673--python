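"""Configuration schema, output writers and provenance management.

Runs are declared in a YAML document with four sections — ``model``
(population size, selection strength, response probability, noise, seed),
``response`` (family + parameters), ``initial`` (family + parameters) and
``run`` (time horizon, recording schedule, cutoff, replicates) — validated
strictly: unknown keys are rejected by name, constraint violations carry
the offending field.  ``parse_config(write_config(cfg))`` round-trips
losslessly.

Outputs are plain columnar text: a scalar-trajectory CSV (time, mean,
variance, cluster_count), a long-format histogram or atom-table CSV, and a
JSON manifest echoing the full configuration, derived seeds and library
versions, from which any run can be reproduced exactly.
"""

from __future__ import annotations

import datetime
import json
import sys
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .gillespie import EnsembleSummary, Trajectory
from .meanfield import MeanFieldTrajectory
from .model import (
    InitialDistribution,
    ModelParams,
    NoiseSettings,
    ResponseFunction,
    response_from_config,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "parse_config",
    "write_config",
    "write_outputs",
]

_FMT = "%.12g"  # all numeric output at 12 significant digits


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


class _Strict(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class NoiseConfig(_Strict):
    sigma_inherit: float = Field(0.0, ge=0.0)
    sigma_perceive: float = Field(0.0, ge=0.0)
    sigma_respond: float = Field(0.0, ge=0.0)


class ModelSection(_Strict):
    N: int = Field(..., ge=2)
    s: float = Field(..., ge=0.0, lt=1.0)
    lam: float = Field(..., ge=0.0, le=1.0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 0


class ResponseSection(_Strict):
    family: Literal["linear", "sinusoidal", "hill_bistable", "pitchfork", "table"]
    kappa: Optional[float] = None
    coefficient: Optional[float] = None
    threshold: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    xs: Optional[list[float]] = None
    ys: Optional[list[float]] = None

    def build(self) -> ResponseFunction:
        params = {k: v for k, v in self.model_dump().items()
                  if k != "family" and v is not None}
        try:
            return response_from_config(self.family, **params)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"response: {exc}") from exc


class InitialSection(_Strict):
    family: Literal["uniform", "atoms", "truncated_gaussian", "table"] = "uniform"
    lo: Optional[float] = None
    hi: Optional[float] = None
    locations: Optional[list[float]] = None
    weights: Optional[list[float]] = None
    mu: Optional[float] = None
    sigma: Optional[float] = None
    xs: Optional[list[float]] = None
    ps: Optional[list[float]] = None

    def build(self) -> InitialDistribution:
        params = {k: v for k, v in self.model_dump().items()
                  if k != "family" and v is not None}
        try:
            return InitialDistribution(self.family, **params)
        except (TypeError, KeyError, ValueError) as exc:
            raise ConfigError(f"initial: {exc}") from exc


class RunSection(_Strict):
    t_max: float = Field(100.0, gt=0.0)
    record_every: float = Field(1.0, gt=0.0)
    t_cutoff: float = Field(1e4, gt=0.0)
    M: int = Field(1, ge=1)
    bins: int = Field(50, ge=2)
    gap: float = Field(0.05, gt=0.0, lt=1.0)


class OutputSection(_Strict):
    directory: Optional[str] = None
    force: bool = False


class RunConfig(_Strict):
    """Fully validated declaration of a simulation or mean-field run."""

    model: ModelSection
    response: ResponseSection = Field(default_factory=lambda: ResponseSection(family="linear"))
    initial: InitialSection = Field(default_factory=InitialSection)
    run: RunSection = Field(default_factory=RunSection)
    output: OutputSection = Field(default_factory=OutputSection)

    def model_params(self) -> ModelParams:
        n = self.model.noise
        return ModelParams(N=self.model.N, s=self.model.s, lam=self.model.lam,
                           noise=NoiseSettings(n.sigma_inherit, n.sigma_perceive,
                                               n.sigma_respond),
                           seed=self.model.seed)

    def response_function(self) -> ResponseFunction:
        return self.response.build()

    def initial_distribution(self) -> InitialDistribution:
        return self.initial.build()


def parse_config(source: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML run configuration (path or literal text)."""
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and Path(source).is_file()):
        text = Path(source).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from exc
    if raw is None:
        raise ConfigError(
            "empty configuration; required sections: model (with N, s, lam)")
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping of sections")
    try:
        cfg = RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "<root>"
            msgs.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(msgs)) from exc
    # eagerly build the declared objects so family-specific constraint
    # violations (e.g. kappa > 1/pi) are reported at parse time
    cfg.response_function()
    cfg.initial_distribution()
    return cfg


def write_config(cfg: RunConfig) -> str:
    """Serialize a configuration back to YAML (lossless round trip)."""
    data = cfg.model_dump(exclude_none=True)
    return yaml.safe_dump(data, sort_keys=False)


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _prepare_dir(outdir: Union[str, Path], force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists():
        if not outdir.is_dir():
            raise IOError(f"output path {outdir} exists and is not a directory")
        if any(outdir.iterdir()) and not force:
            raise IOError(
                f"output directory {outdir} is not empty; pass force=True / --force "
                "to overwrite")
    else:
        outdir.mkdir(parents=True)
    return outdir


def _scalar_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame({
        "time": traj.times,
        "mean": traj.means,
        "variance": traj.variances,
        "cluster_count": traj.cluster_counts,
    })


def _histogram_frame(traj: Trajectory) -> pd.DataFrame:
    edges = np.linspace(0.0, 1.0, traj.bins + 1)
    rows = []
    for k, t in enumerate(traj.times):
        for b in range(traj.bins):
            rows.append((t, edges[b], edges[b + 1], traj.histograms[k, b]))
    return pd.DataFrame(rows, columns=["time", "bin_left", "bin_right", "count"])


def _atom_frame(traj: MeanFieldTrajectory) -> pd.DataFrame:
    rows = []
    for t, m in zip(traj.times, traj.measures):
        for loc, w in zip(m.locations, m.weights):
            rows.append((t, loc, w))
    return pd.DataFrame(rows, columns=["time", "location", "weight"])


def _manifest(cfg: Optional[RunConfig], extra: dict) -> dict:
    man = {
        "package": "quorumsim",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    if cfg is not None:
        man["config"] = cfg.model_dump(exclude_none=True)
    man.update(extra)
    return man


def write_outputs(result: Union[Trajectory, MeanFieldTrajectory, EnsembleSummary],
                  outdir: Union[str, Path], *, config: Optional[RunConfig] = None,
                  force: bool = False) -> list[Path]:
    """Write a result bundle as columnar text plus a JSON manifest.

    Trajectories produce ``scalars.csv`` + ``histograms.csv`` (stochastic)
    or ``scalars.csv`` + ``atoms.csv`` (mean-field); ensembles produce
    per-replicate scalar files plus pooled files.  Refuses to write into a
    non-empty directory unless ``force``.
    """
    outdir = _prepare_dir(outdir, force)
    written: list[Path] = []
    extra: dict = {}

    def _save(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format=_FMT)
        written.append(path)

    if isinstance(result, Trajectory):
        _save(_scalar_frame(result), "scalars.csv")
        _save(_histogram_frame(result), "histograms.csv")
        extra["seed"] = result.seed
    elif isinstance(result, MeanFieldTrajectory):
        _save(pd.DataFrame({
            "time": result.times,
            "mean": result.means,
            "variance": result.variances,
            "mean_fitness": result.mean_fitnesses,
        }), "scalars.csv")
        _save(_atom_frame(result), "atoms.csv")
    elif isinstance(result, EnsembleSummary):
        if result.trajectories:
            for m, traj in enumerate(result.trajectories):
                _save(_scalar_frame(traj), f"replicate_{m:03d}.csv")
        _save(pd.DataFrame({
            "time": result.times,
            "mean": result.mean_of_means,
            "variance": result.mean_of_variances,
        }), "pooled_scalars.csv")
        edges = np.linspace(0.0, 1.0, result.pooled_histograms.shape[1] + 1)
        rows = [(t, edges[b], edges[b + 1], result.pooled_histograms[k, b])
                for k, t in enumerate(result.times)
                for b in range(result.pooled_histograms.shape[1])]
        _save(pd.DataFrame(rows, columns=["time", "bin_left", "bin_right", "count"]),
              "pooled_histograms.csv")
        extra["replicate_seeds"] = result.seeds
        extra["M"] = result.M
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(_manifest(config, extra), indent=2))
    written.append(manifest_path)
    return written
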