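"""Readers/writers, run configuration and seeded fixture generation.

Formats are deliberately plain: trajectories are ``t,x,y[,z]`` CSV files
with a JSON metadata sidecar (kind, γ, seed, r_max, ℓ₀); MSD curves are
``t,msd,n_tracks`` CSV; correlation curves are ``tau,G`` CSV; run
configurations round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import fcs, subpop
from .fractal import GeneratorMask, standard_carpet_mask, full_mask, FractalSupport
from .msd import MSDCurve, ensemble_msd, log_grid
from .walks import InverseGammaWaitingTimes, Trajectory, ctrw_ensemble

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "read_trajectories",
    "write_msd",
    "read_msd",
    "write_correlation",
    "read_correlation",
    "load_config",
    "save_config",
    "config_hash",
    "setup_logging",
    "make_fixtures",
]

log = logging.getLogger("lctrw")

_AXES = ("x", "y", "z")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    cols = {"t": traj.times}
    for i in range(traj.dim):
        cols[_AXES[i]] = traj.positions[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "kind": traj.kind,
        "gamma": traj.gamma,
        "seed": traj.seed,
        "r_max": traj.r_max,
        "ell0": 1.0,
        "dim": traj.dim,
        "support": None
        if traj.support is None
        else {
            "nu": traj.support.nu,
            "k_max": traj.support.k_max,
            "mask": traj.support.generator.to_text(),
        },
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def _validate(df: pd.DataFrame, kind: str, path: Path) -> None:
    # CSV line numbers are 1-based with the header on line 1; a bad
    # difference at index i implicates data row i+1, i.e. line i+3
    dt = np.diff(df["t"].to_numpy())
    bad = np.where(dt <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path}: non-increasing time at row {int(bad[0]) + 3}"
        )
    pos = df[[c for c in df.columns if c != "t"]].to_numpy()
    step = np.abs(np.diff(pos, axis=0)).sum(axis=1)
    bad = np.where((step != 0) & (step != 1))[0]
    if len(bad):
        raise ValueError(
            f"{path}: non-unit lattice step at row {int(bad[0]) + 3}"
        )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV (with optional sidecar), validating the format."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[0] != "t" or cols[1:] not in (["x", "y"], ["x", "y", "z"]):
        raise ValueError(f"{path}: expected header t,x,y[,z], got {cols}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if "dim" in meta and meta["dim"] != len(cols) - 1:
        raise ValueError(
            f"{path}: sidecar dim {meta['dim']} != {len(cols) - 1} columns"
        )
    kind = meta.get("kind", "ctrw")
    _validate(df, kind, path)
    support = None
    if meta.get("support"):
        gen = GeneratorMask.from_text(meta["support"]["mask"])
        support = FractalSupport(gen, meta["support"]["k_max"])
    return Trajectory(
        times=df["t"].to_numpy(),
        positions=df[cols[1:]].to_numpy(dtype=np.int64),
        kind=kind,
        gamma=meta.get("gamma", 1.0),
        seed=meta.get("seed"),
        r_max=meta.get("r_max"),
        support=support,
    )


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read every ``*.csv`` trajectory in a directory (or a single file)."""
    path = Path(path)
    files = [path] if path.is_file() else sorted(path.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no trajectory CSV files under {path}")
    return [read_trajectory(f) for f in files]


def write_msd(curve: MSDCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"t": curve.abscissa, "msd": curve.values, "n_tracks": curve.n_tracks}
    ).to_csv(path, index=False)


def read_msd(path: str | Path) -> MSDCurve:
    df = pd.read_csv(path)
    return MSDCurve(
        df["t"].to_numpy(),
        df["msd"].to_numpy(),
        n_tracks=int(df["n_tracks"].iloc[0]) if "n_tracks" in df else 1,
    )


def write_correlation(curve: fcs.CorrelationCurve, path: str | Path) -> None:
    pd.DataFrame({"tau": curve.lags, "G": curve.G}).to_csv(path, index=False)


def read_correlation(path: str | Path) -> fcs.CorrelationCurve:
    df = pd.read_csv(path)
    return fcs.CorrelationCurve(df["tau"].to_numpy(), df["G"].to_numpy())


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration dict (provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(level: str = "INFO", seed=None, cfg: Optional[dict] = None) -> None:
    """Configure the package logger and record run provenance."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    import numpy
    import scipy

    from . import __version__

    log.info(
        "lctrw %s (numpy %s, scipy %s) seed=%s config=%s",
        __version__,
        numpy.__version__,
        scipy.__version__,
        seed,
        config_hash(cfg or {}),
    )


# ---------------------------------------------------------------------------
# Seeded fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("ideal_powerlaw_family", "ctrw_tracks", "fcs_curve", "carpet_mask")


def make_fixtures(kind: str, out_dir: str | Path, seed: int = 0, **params) -> list[Path]:
    """Generate deterministic synthetic inputs used by the test suite.

    Kinds
    -----
    ideal_powerlaw_family
        Noise-free power-law MSD curves (default: the γ̃ = 0.689 reference
        family with bounds [0.243, 0.799]); one CSV per track.
    ctrw_tracks
        CTRW trajectories on the full lattice (default γ = 0.5, 500 tracks).
    fcs_curve
        A noiseless anomalous-diffusion correlation curve.
    carpet_mask
        The standard 3×3 carpet generator (or a full mask) as text.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "ideal_powerlaw_family":
        fam = subpop.build_family(
            params.get("gamma_min", 0.243),
            params.get("gamma_max", 0.799),
            params.get("l_max", 32),
            grid=params.get("grid"),
            prefactor_rule=params.get("prefactor_rule", "unit"),
        )
        for i, (g, vals) in enumerate(zip(fam.exponents, fam.curves), start=1):
            p = out_dir / f"track_{i:03d}.csv"
            pd.DataFrame({"t": fam.grid, "msd": vals, "n_tracks": 1}).to_csv(
                p, index=False
            )
            written.append(p)
        meta = out_dir / "family.json"
        meta.write_text(
            json.dumps(
                {
                    "gamma_min": fam.gamma_min,
                    "gamma_max": fam.gamma_max,
                    "l_max": fam.l_max,
                    "exponents": list(map(float, fam.exponents)),
                },
                indent=1,
            )
        )
        written.append(meta)
    elif kind == "ctrw_tracks":
        gamma = params.get("gamma", 0.5)
        n_tracks = params.get("n_tracks", 500)
        n_steps = params.get("n_steps", 400)
        dim = params.get("dim", 2)
        support = FractalSupport(full_mask(3, dim), k_max=params.get("k_max", 5))
        start = (support.side // 2,) * dim
        trajs = ctrw_ensemble(
            support,
            InverseGammaWaitingTimes(gamma),
            n_steps,
            n_tracks,
            start,
            seed=seed,
        )
        for i, tr in enumerate(trajs, start=1):
            p = out_dir / f"ctrw_{i:04d}.csv"
            write_trajectory(tr, p)
            written.append(p)
    elif kind == "fcs_curve":
        p = fcs.FCSParams(
            N=params.get("N", 0.5),
            tau_D=params.get("tau_D", 1e-3),
            gamma=params.get("gamma", 0.7),
            s=params.get("s", 5.0),
            dim=params.get("dim", 3),
        )
        lags = log_grid(params.get("tau_lo", 1e-6), params.get("tau_hi", 1.0), 10)
        curve = fcs.CorrelationCurve(lags, fcs.correlation_model(lags, p))
        out = out_dir / "fcs_curve.csv"
        write_correlation(curve, out)
        written.append(out)
    elif kind == "carpet_mask":
        mask = (
            full_mask(params.get("nu", 3), params.get("dim", 2))
            if params.get("full")
            else standard_carpet_mask()
        )
        out = out_dir / "mask.txt"
        out.write_text(mask.to_text())
        written.append(out)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return written
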