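"""Deterministic toy-artifact generation for tests and demos.

Everything is produced at run time from a seed; outputs are plain text
and byte-identical across runs with the same seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import preset_config, write_burst_table
from .dipole_dynamics import sample_uniform_sphere, simulate_dipoles_batch
from .fret_core import kappa_squared_vec
from .photon_engine import run_experiment
from .shift_analysis import TwoStateSpec, two_state_reference

__all__ = ["generate_fixtures"]

FIXTURE_FILES = ("burst_table_50.tsv", "kappa2_path.tsv", "two_state_table.tsv")


def _kappa2_path_fixture(path: Path, seed: int) -> None:
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 4.0, 201)
    mu0 = sample_uniform_sphere(2, rng)
    mus = simulate_dipoles_batch(0.5, mu0, t, seed=rng)  # (n_t, 2, 3)
    r_hat = np.array([0.0, 0.0, 1.0])
    k2 = kappa_squared_vec(mus[:, 0, :], mus[:, 1, :], r_hat)
    with open(path, "w") as fh:
        fh.write(f"# smfretsim fixture kappa2_path seed={seed}\n")
        fh.write("time_ns\tkappa2\n")
        for ti, ki in zip(t, k2):
            fh.write(f"{ti:.10g}\t{ki:.10g}\n")


def generate_fixtures(outdir, seed: int = 0) -> list[Path]:
    """Write the bundled small test inputs into ``outdir``.

    Emits a 50-burst table (reduced iso-spring experiment), a short
    kappa^2 path, and a 30-burst two-state reference table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cfg = preset_config(
        "iso_spring",
        overrides={"n_bursts": 50, "seed": seed, "burst": {"n_excitations": 100}},
    )
    table = run_experiment(
        cfg.experiment_model(),
        cfg.kappa2_mode,
        cfg.n_bursts,
        cfg.physical_params(),
        cfg.burst_config(),
        seed=cfg.seed,
    )
    p = outdir / "burst_table_50.tsv"
    write_burst_table(table, p, meta={"fixture": "burst_table_50", "seed": seed})
    written.append(p)

    p = outdir / "kappa2_path.tsv"
    _kappa2_path_fixture(p, seed)
    written.append(p)

    ts = two_state_reference(
        TwoStateSpec(E1=0.3, E2=0.8, lam=0.01),
        n_bursts=30,
        seed=seed,
    )
    p = outdir / "two_state_table.tsv"
    write_burst_table(ts, p, meta={"fixture": "two_state_table", "seed": seed})
    written.append(p)
    return written
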