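"""Experiment dispatch, output serialization, and run manifests."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .dynamics import impulse_response
from .lattice import distance_shells
from .perturbation import attenuation_profile, range_vs_input, tangent_propagate
from .spectral import FrontNotReached, dispersion, front_speed
from .hopf1d import rate_table

__all__ = ["RunManifest", "run_experiment", "ExperimentError"]

FLOAT_FMT = "%.12g"


class ExperimentError(RuntimeError):
    pass


@dataclass
class RunManifest:
    """Reproducibility record for one experiment run."""

    experiment: str
    config_hash: str
    code_version: str
    seed: int
    outputs: list[str] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(self.to_json())
        return path


def _write_table(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_experiment(config: RunConfig, log=lambda msg: None) -> RunManifest:
    """Run the named experiment, writing all outputs under config.out.

    Every output file is listed in the manifest; partial failures are
    recorded per stage and re-raised as :class:`ExperimentError` at the
    end so the caller can exit nonzero.
    """
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.lattice_spec()
    manifest = RunManifest(
        experiment=config.experiment,
        config_hash=config.hash(),
        code_version=__version__,
        seed=config.seed,
        started=time.time(),
    )

    def emit(name: str, writer) -> None:
        t0 = time.time()
        path = out_dir / name
        try:
            writer(path)
        except Exception as err:  # record and continue; fail at the end
            manifest.failures.append(f"{name}: {err}")
            log(f"stage {name} FAILED: {err}")
        else:
            manifest.outputs.append(name)
            manifest.stages.append({"name": name, "seconds": round(time.time() - t0, 3)})
            log(f"wrote {path} ({time.time() - t0:.2f} s)")

    config_path = out_dir / "config.yaml"
    config.serialize(config_path)
    manifest.outputs.append("config.yaml")

    if config.experiment == "dispersion":
        table = dispersion(spec)
        emit("dispersion.tsv", lambda p: _write_table(table.to_dataframe(), p))

    elif config.experiment == "hopf1d":
        emit("hopf_rates.tsv", lambda p: _write_table(
            rate_table(config.f_grid, omega0=config.omega0), p))

    elif config.experiment == "impulse":
        shells = distance_shells(spec)
        T = config.t_final if config.t_final is not None else spec.n / (2.0 * 2.0 * spec.g) * 0.9
        traj = impulse_response(
            spec, T=T, dt=config.dt_resolved, save_stride=config.save_stride
        )
        emit("impulse_trajectory.npz", traj.save)

        def write_profile(p):
            site_max = np.abs(traj.states).max(axis=0)
            rows = [(float(r), float(site_max[shells.shells[int(r)]].mean()))
                    for r in shells.radii]
            import pandas as pd
            _write_table(pd.DataFrame(rows, columns=["r", "M"]), p)

        emit("impulse_profile.tsv", write_profile)

        def write_speed(p):
            try:
                fs = front_speed(traj, shells)
            except FrontNotReached as err:
                raise ExperimentError(str(err)) from err
            p.write_text(
                f"speed\t{fs.speed:.6g}\nr2\t{fs.r2:.6g}\n"
                f"slope\t{fs.slope:.6g}\nintercept\t{fs.intercept:.6g}\n"
            )

        emit("front_speed.tsv", write_speed)
        if config.plot:
            emit("impulse_raster.png", lambda p: _plot_raster(traj, spec, p))

    elif config.experiment == "attenuation":
        table, profiles = range_vs_input(
            spec,
            config.eta_grid,
            n_realizations=config.realizations,
            master_seed=config.seed,
            dt=config.dt_resolved,
            T=config.t_final,
            burn_in=config.burn_in,
            window_frac=config.window_frac,
            keep_profiles=True,
        )
        for eta, prof in profiles.items():
            emit(f"profile_eta_{eta:g}.tsv", lambda p, pr=prof: _write_table(pr.to_dataframe(), p))
        emit("attenuation_summary.tsv", lambda p: _write_table(table, p))
        if config.plot:
            emit("attenuation.png", lambda p: _plot_attenuation(table, profiles, p))
        bad = table[table["error"] != ""]
        for _, row in bad.iterrows():
            manifest.failures.append(f"eta={row['eta']}: {row['error']}")

    manifest.finished = time.time()
    manifest.write(out_dir)
    if manifest.failures:
        raise ExperimentError(
            "experiment completed with failures: " + "; ".join(manifest.failures)
        )
    return manifest


def _plot_raster(traj, spec, path) -> None:
    from .plotting import raster_plot

    raster_plot(traj, spec, path)


def _plot_attenuation(table, profiles, path) -> None:
    from .plotting import attenuation_plot

    attenuation_plot(table, profiles, path)
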