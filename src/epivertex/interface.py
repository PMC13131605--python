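"""Run orchestration: configuration, the main simulation loop, experiment
drivers, fixture generation, and snapshot serialization.

A run is reproducible bit-for-bit from (config, seed) at the deterministic
settings (D_t = 0): a single seeded generator is threaded through every
stochastic choice (thermal noise, growing-cell selection, fate conversion).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tissue_geometry as tg
from . import mechanics as mech
from . import proliferation as prol
from . import stratification as strat

log = logging.getLogger("epivertex")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    experiment: str = "division_sweep"   # growth_orientation | division_sweep | droplet
    stage: str = "E14"
    n_basal: int = 36
    n_suprabasal_layers: int = 1
    theta: float = 0.0
    phi: float = 0.0
    t_div: float = 100.0
    protocol: str = strat.HOMEOSTATIC
    duration: float = 400.0
    t_retess: float = 1.0
    t_pop: float | None = None           # default: t_div / 2
    alpha: float | None = None           # default: 1 / t_div (doubling per interval)
    jitter: float = 0.2
    seed: int = 0
    D_t: float | None = None             # override mechanics default
    out_dir: str | None = None

    def echo(self) -> dict:
        return dataclasses.asdict(self)


class Simulation:
    """Langevin dynamics + cadence re-tessellation + division/stratification.

    The per-step order is: advance the growing cell's target volume, one
    Euler-Maruyama step, then (on cadence steps) rebuild the tessellation from
    centroids and run stratification detection, then the homeostasis check,
    then a scheduled division.  At most one cell divides per step.
    """

    def __init__(self, tess, params, rng, division: prol.DivisionSpec | None = None,
                 protocol: str = strat.HOMEOSTATIC, t_retess: float = 1.0,
                 t_pop: float | None = None, alpha: float | None = None,
                 record: bool = True, post_rebuild_iters: int = 30):
        self.tess = tess
        self.params = params
        self.rng = rng
        self.division = division
        self.post_rebuild_iters = post_rebuild_iters
        self.alpha = alpha if alpha is not None else (
            1.0 / division.t_div if division else 0.0)
        dt = params.dt
        self.n_retess = max(1, int(round(t_retess / dt)))
        self.scheduler = prol.DivisionScheduler(division.t_div, dt) if division else None
        t_pop = t_pop if t_pop is not None else (
            division.t_div / 2 if division else 50.0)
        self.n_pop = max(1, int(round(t_pop / dt)))
        self.log = strat.EventLog(
            protocol=protocol, t_pop=t_pop,
            n_basal_ref=int((tess.cell_type == tg.BASAL).sum()))
        self.record = record
        self._traj: list = []
        self.step_count = 0
        self.time = 0.0
        self.recent_daughters: dict[int, float] = {}
        if self.division or self.alpha > 0:
            prol.ensure_growing_cell(self.tess, self.rng, self.alpha)
        if record:
            self._snapshot()

    # -- recording -----------------------------------------------------------

    def _snapshot(self):
        _, _, cen = self.tess.geometry()
        self._traj.append((self.time, self.tess.cell_ids.copy(),
                           cen.copy(), self.tess.cell_type.copy()))

    def trajectories(self) -> pd.DataFrame:
        frames = []
        for t, ids, cen, types in self._traj:
            frames.append(pd.DataFrame({
                "time": t, "cell": ids, "x": cen[:, 0], "y": cen[:, 1],
                "z": cen[:, 2], "type": types}))
        if not frames:
            return pd.DataFrame(columns=["time", "cell", "x", "y", "z", "type"])
        df = pd.concat(frames, ignore_index=True)
        # a division step snapshots both at the rebuild and after the split;
        # keep the post-division state for that time
        return df.drop_duplicates(["time", "cell"], keep="last",
                                  ignore_index=True)

    # -- the loop ------------------------------------------------------------

    def _rebuild(self):
        self.tess = tg.retessellate(self.tess)
        # brief relaxation removes the artificial strain of snapping vertices
        # to raw Voronoi positions before dynamics resume
        mech.minimize(self.tess, self.params, max_iter=self.post_rebuild_iters)
        interface = strat.compute_bs_interface(self.tess)
        horizon = self.division.t_div if self.division else np.inf
        recent = {c for c, t0 in self.recent_daughters.items()
                  if self.time - t0 <= horizon}
        stratified = strat.detect_homotypic(
            self.tess, self.params, interface, self.log, self.time,
            recent_daughters=recent)
        for _ in stratified:
            strat.ghost_convert_top(self.tess, exclude=set(stratified))
        if stratified and (self.division or self.alpha > 0):
            prol.ensure_growing_cell(self.tess, self.rng, self.alpha)

    def run(self, duration: float):
        dt = self.params.dt
        nsteps = int(round(duration / dt))
        for _ in range(nsteps):
            self.step_count += 1
            self.time = self.step_count * dt
            prol.grow_step(self.tess, dt, self.params)
            mech.langevin_step(self.tess, self.params, self.rng)
            if self.step_count % self.n_retess == 0:
                self._rebuild()
                if self.record:
                    self._snapshot()
            if self.log.protocol == strat.HOMEOSTATIC and \
                    self.step_count % self.n_pop == 0:
                cid = strat.homeostatic_check(self.tess, self.params, self.log,
                                              self.rng, self.time)
                if cid is not None:
                    strat.ghost_convert_top(self.tess, exclude={cid})
                    if self.division or self.alpha > 0:
                        prol.ensure_growing_cell(self.tess, self.rng, self.alpha)
            if self.scheduler and self.scheduler.due(self.step_count):
                self._divide()
        return self

    def _divide(self):
        gid = prol.ensure_growing_cell(self.tess, self.rng, self.alpha)
        self.tess, event = prol.divide_cell(self.tess, gid, self.division,
                                            self.params)
        event.t0 = self.time
        self.log.divisions.append(event)
        self.log.N_div += 1
        self.recent_daughters[event.d1] = self.time
        self.recent_daughters[event.d2] = self.time
        prol.ensure_growing_cell(self.tess, self.rng, self.alpha)
        if self.record:
            self._snapshot()


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def run_division_experiment(stage: str, theta: float, t_div: float,
                            duration: float, n_basal: int = 36,
                            n_suprabasal_layers: int = 1,
                            protocol: str = strat.HOMEOSTATIC,
                            seed: int = 0, D_t: float | None = None,
                            t_pop: float | None = None,
                            record: bool = True) -> Simulation:
    """Layered-tissue run with scheduled oriented divisions."""
    rng = np.random.default_rng(seed)
    params = mech.stage_to_params(stage)
    if D_t is not None:
        params.D_t = D_t
    tess = tg.build_initial_tissue(n_basal, n_suprabasal_layers, seed=seed,
                                   s0_by_type=params.s0)
    mech.minimize(tess, params, tol=0.05, max_iter=200)
    spec = prol.DivisionSpec(theta=theta, t_div=t_div)
    sim = Simulation(tess, params, rng, division=spec, protocol=protocol,
                     t_pop=t_pop, record=record)
    sim.run(duration)
    return sim


def run_growth_orientation(stage: str, n_episodes: int = 8, t_grow: float = 40.0,
                           n_basal: int = 25, seed: int = 0,
                           sample_every: float = 1.0,
                           sample_after: float = 0.5) -> np.ndarray:
    """Long-axis orientation samples of isotropically growing basal cells.

    A random basal cell grows its target volume toward doubling over t_grow;
    the angle between its longest principal axis and the basal plane is
    sampled during the later part of each growth episode (when the cell is
    appreciably enlarged, i.e. just prior to when it would divide).  At the
    end of an episode the cell's targets are reset and a new cell is drawn,
    isolating growth geometry from division and stratification dynamics.
    """
    rng = np.random.default_rng(seed)
    params = mech.stage_to_params(stage)
    tess = tg.build_initial_tissue(n_basal, 1, seed=seed, s0_by_type=params.s0)
    mech.minimize(tess, params, tol=0.05, max_iter=200)
    alpha = 1.0 / t_grow
    dt = params.dt
    n_retess = int(round(1.0 / dt))
    n_sample = int(round(sample_every / dt))
    samples = []
    step = 0
    for _ in range(n_episodes):
        basal = np.where(tess.cell_type == tg.BASAL)[0]
        tess.alpha[:] = 0.0
        pick = basal[rng.integers(len(basal))]
        gid = int(tess.cell_ids[pick])
        tess.alpha[pick] = alpha
        nsteps = int(round(t_grow / dt))
        for k in range(nsteps):
            step += 1
            prol.grow_step(tess, dt, params)
            mech.langevin_step(tess, params, rng)
            if step % n_retess == 0:
                tess = tg.retessellate(tess)
                mech.minimize(tess, params, max_iter=30)
            if k >= sample_after * nsteps and step % n_sample == 0:
                i = tess.id_to_index.get(gid)
                if i is None or tess.cell_type[i] != tg.BASAL:
                    break  # grower stratified; end episode
                fit = tg.fit_ellipsoid(tess, gid)
                if not fit.degenerate:
                    samples.append(fit.theta_long)
        # reset the episode: restore unit targets on the grower if still present
        i = tess.id_to_index.get(gid)
        if i is not None:
            tess.V0[i] = 1.0
            tess.S0[i] = params.s0[tg.TYPE_NAMES[int(tess.cell_type[i])]]
            tess.alpha[i] = 0.0
            mech.minimize(tess, params, tol=0.1, max_iter=50)
    return np.array(samples)


def run_experiment(config: RunConfig) -> dict:
    """Dispatch a configured experiment; returns a result bundle of tables.

    The full configuration is echoed into the run log (and into the output
    directory when one is given) so every artifact is traceable.
    """
    log.info("run config: %s", json.dumps(config.echo()))
    out = {"config": config.echo()}
    if config.experiment == "growth_orientation":
        samples = run_growth_orientation(config.stage, seed=config.seed,
                                         n_basal=config.n_basal)
        out["theta_samples"] = samples
    elif config.experiment == "division_sweep":
        sim = run_division_experiment(
            config.stage, config.theta, config.t_div, config.duration,
            n_basal=config.n_basal, n_suprabasal_layers=config.n_suprabasal_layers,
            protocol=config.protocol, seed=config.seed, D_t=config.D_t,
            t_pop=config.t_pop)
        out["trajectories"] = sim.trajectories()
        out["events"] = sim.log.events_frame()
        out["divisions"] = sim.log.divisions_frame()
        out["summary"] = {
            "N_homo": sim.log.N_homo, "N_fate": sim.log.N_fate,
            "N_div": sim.log.N_div,
            "yield": strat.stratification_yield(sim.log),
        }
    elif config.experiment == "droplet":
        from . import rheology
        cfg = rheology.DropletConfig()
        trace, fit = rheology.run_droplet(cfg, seed=config.seed)
        out["strain_trace"] = trace.frame()
        out["fit"] = fit
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    if config.out_dir:
        _write_bundle(out, Path(config.out_dir))
    return out


def _write_bundle(out: dict, path: Path):
    path.mkdir(parents=True, exist_ok=True)
    (path / "config.json").write_text(json.dumps(out["config"], indent=2))
    for key, val in out.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(path / f"{key}.csv", index=False)
        elif isinstance(val, np.ndarray):
            np.savetxt(path / f"{key}.txt", val)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Small deterministic inputs for unit tests.

    kinds: tiny_tissue (3x3 basal slab), bilayer (basement+basal+supra+ghost),
    synthetic_separation_trace (Brownian daughter pairs with known D0),
    synthetic_strain_trace (two-exponential recovery with known tau's).
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    if kind == "tiny_tissue":
        return tg.build_initial_tissue(params.get("n_basal", 9),
                                       params.get("n_suprabasal_layers", 1),
                                       jitter=params.get("jitter", 0.2), seed=seed)
    if kind == "bilayer":
        return tg.build_initial_tissue(params.get("n_basal", 16), 1,
                                       jitter=params.get("jitter", 0.15), seed=seed)
    if kind == "synthetic_separation_trace":
        # two independent Brownian walkers per division event
        D0 = params.get("D0", 0.01)
        n_pairs = params.get("n_pairs", 200)
        n_t = params.get("n_t", 101)
        dt = params.get("dt", 1.0)
        t = np.arange(n_t) * dt
        steps = rng.normal(scale=np.sqrt(2 * D0 * dt), size=(n_pairs, 2, n_t - 1, 3))
        pos = np.concatenate([np.zeros((n_pairs, 2, 1, 3)),
                              np.cumsum(steps, axis=2)], axis=2)
        return t, pos  # pos[pair, daughter, time, xyz]
    if kind == "synthetic_strain_trace":
        tau1 = params.get("tau1", 10.0)
        tau2 = params.get("tau2", 68.0)
        A1 = params.get("A1", 0.05)
        A2 = params.get("A2", 0.05)
        noise = params.get("noise", 0.01)
        t = np.arange(0.0, params.get("t_max", 400.0), params.get("dt", 0.5))
        eps = A1 * np.exp(-t / tau1) + A2 * np.exp(-t / tau2)
        eps = eps * (1.0 + noise * rng.standard_normal(len(t)))
        return t, eps
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------

def snapshot_writer(tess: tg.Tessellation, path: str | Path):
    """Write per-cell surface meshes (OFF polygon format) plus a metadata table.

    Produces ``<path>.off`` with all cell faces (each cell's polygon fan) and
    ``<path>_cells.csv`` with id, type, V0, S0, volume, area, centroid.  Ghost
    cells are exported with their distinguishing type label.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol, area, cen = tess.geometry()
    rows = []
    verts_out: list = []
    faces_out: list = []
    for i in range(tess.n_cells):
        base = len(verts_out)
        vmap: dict = {}
        for j in range(tess.cf_offsets[i], tess.cf_offsets[i + 1]):
            f = tess.cf_faces[j]
            side = tess.cf_side[j]
            b0, b1 = tess.face_offsets[f], tess.face_offsets[f + 1]
            poly = []
            krange = range(b0, b1) if side > 0 else range(b1 - 1, b0 - 1, -1)
            for k in krange:  # reversed winding keeps normals outward per cell
                p = tess.verts[tess.face_vidx[k]] + tess.face_shift[k]
                if side < 0:
                    p = p - tess.face_pair_shift[f]
                key = tuple(np.round(p, 9))
                if key not in vmap:
                    vmap[key] = base + len(vmap)
                    verts_out.append(p)
                poly.append(vmap[key])
            faces_out.append((poly, i))
        rows.append({"cell": int(tess.cell_ids[i]),
                     "type": tg.TYPE_NAMES[int(tess.cell_type[i])],
                     "V0": tess.V0[i], "S0": tess.S0[i],
                     "volume": vol[i], "area": area[i],
                     "x": cen[i, 0], "y": cen[i, 1], "z": cen[i, 2]})
    off = path.with_suffix(".off")
    with off.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(verts_out)} {len(faces_out)} 0\n")
        for v in verts_out:
            fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for poly, ci in faces_out:
            fh.write(str(len(poly)) + " " + " ".join(map(str, poly))
                     + f" # cell {int(tess.cell_ids[ci])}\n")
    pd.DataFrame(rows).to_csv(path.parent / (path.stem + "_cells.csv"), index=False)
    return off


def setup_logging(level=logging.INFO):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(level)
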