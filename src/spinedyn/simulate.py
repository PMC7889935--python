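"""Time-stepping orchestration of membrane + actin, PSD/neck remodeling,
the structural-LTP protocol, and trajectory recording.

A simulation couples the deterministic overdamped membrane (``membrane``)
to the stochastic focus dynamics (``actin``).  Per step of ``dt``: a focus
may nucleate; every live focus feels the kernel-weighted local membrane
force, branches/caps/severs accordingly and polymerizes; the membrane moves
under the summed actin and Helfrich forces (with mechanical substeps for
integrator stability); the mesh is maintained; and the eight slow PSD/neck
remodeling events fire independently.  PSD and neck changes are applied
after the actin dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _sstats

from . import _kernels as _kern
from . import actin as ac
from . import membrane as mb


@dataclass
class GeometryParams:
    """Seed-polygon geometry for the initial (resting) spine shape, um."""

    h_psd: float = 0.55
    h_neck: float = 0.0
    psd_width: float = 0.40
    neck_width: float = 0.15
    bulge: float = 0.38
    spacing: float = 0.035


@dataclass
class LTPProtocol:
    """Structural-LTP-like event: at ``t_event`` (s) the nucleation rate is
    multiplied by ``factor`` permanently."""

    t_event: float
    factor: float = 3.0

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("LTP factor must be positive")


@dataclass
class SimConfig:
    mechanical: mb.MechanicalParams = field(default_factory=mb.MechanicalParams)
    actin: ac.ActinRates = field(default_factory=ac.ActinRates)
    kernel: ac.KernelParams = field(default_factory=ac.KernelParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    psd_neck_rate: float = 1.0 / 75.0
    d_mov: float | None = None          # defaults to d_min
    duration: float = 3600.0
    sample_interval: float = 10.0
    seed: int = 0
    feedback: bool = True
    ltp: LTPProtocol | None = None
    n_substeps: int = 200               # mechanical substeps per dt
    check_interval: int = 100           # self-intersection check cadence
    contact_radius: float | None = None  # excluded volume; None -> 2.5*d_min
    force_mode: str = "magnitude"       # local_membrane_force reading
    kernel_center: str = "track"        # "track" contact point or "static"
    max_vertices: int = 900             # contour-size validity bound
    log_events: bool = True

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_interval < self.mechanical.dt:
            raise ValueError("sample_interval must be >= dt")
        # one dt governs both subsystems
        self.actin = replace(self.actin, dt=self.mechanical.dt)
        if self.d_mov is None:
            self.d_mov = self.mechanical.d_min
        if self.contact_radius is None:
            self.contact_radius = 2.5 * self.mechanical.d_min


@dataclass
class Trajectory:
    """Per-step record of a simulation plus sampled shape snapshots."""

    dt: float
    sample_interval: float
    times: np.ndarray                   # per-step, s
    areas: np.ndarray                   # per-step, um^2
    total_B: np.ndarray                 # per-step summed barbed ends
    n_foci: np.ndarray                  # per-step live focus count
    snapshot_times: list
    snapshots: list                     # MembraneMesh at sample times
    event_log: list                     # (time_s, focus_id, event, B_after)

    @property
    def sampled_times(self) -> np.ndarray:
        return np.asarray(self.snapshot_times)

    @property
    def sampled_areas(self) -> np.ndarray:
        idx = np.clip(np.round(self.sampled_times / self.dt).astype(int),
                      0, len(self.areas) - 1)
        return self.areas[idx]

    @property
    def sampled_total_B(self) -> np.ndarray:
        """Mean total barbed-end count within each sampling window (the
        barbed-end series at the granularity of the plotted traces)."""
        k = max(int(round(self.sample_interval / self.dt)), 1)
        out = np.empty(len(self.snapshot_times))
        for i in range(len(out)):
            lo = i * k
            out[i] = self.total_B[lo:lo + k].mean()
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "area_um2": self.areas,
                             "total_B": self.total_B, "n_foci": self.n_foci})

    def event_frame(self):
        import pandas as pd

        return pd.DataFrame(self.event_log,
                            columns=["time_s", "focus_id", "event", "B_after"])


#: fraction of n_substeps run between mesh-maintenance passes
_SUBSTEP_CHUNKS = (0.25, 0.25, 0.25, 0.25)


class SimulationAborted(RuntimeError):
    def __init__(self, message: str, step: int):
        super().__init__(f"{message} (step {step})")
        self.step = step


def psd_neck_update(mesh: mb.MembraneMesh, rate: float, d_mov: float,
                    rng: np.random.Generator, dt: float) -> mb.MembraneMesh:
    """Apply the eight independent Bernoulli(rate*dt) PSD/neck events.

    PSD right/left boundaries elongate (recruit the neighboring free
    vertex, pinning it at h_psd) or shrink (release the boundary vertex);
    the whole PSD shifts up/down by ``d_mov``; the neck elongates or
    shrinks symmetrically (both ends at once) so its centre stays put.  A
    shrink that would empty the pinned set is skipped.
    """
    hits = rng.random(8) < rate * dt
    if not hits.any():
        return mesh
    m = mesh.copy()

    def run_bounds(role):
        """First and last index of the cyclically contiguous pinned run,
        in contour order (first = entry into the run walking the contour)."""
        idx = np.flatnonzero(m.roles == role)
        if idx.size == 0:
            return None, None, idx
        if idx.size == m.n:
            return idx[0], idx[-1], idx
        # entry point: pinned vertex whose predecessor is not pinned
        prev = (idx - 1) % m.n
        entry = idx[~np.isin(prev, idx)]
        first = int(entry[0])
        nxt = (idx + 1) % m.n
        exit_ = idx[~np.isin(nxt, idx)]
        last = int(exit_[0])
        return first, last, idx

    def recruit(vertex_idx, role, height):
        if m.roles[vertex_idx] != mb.FREE:
            return
        m.roles[vertex_idx] = role
        m.vertices[vertex_idx, 1] = height

    # the contour is counter-clockwise with the PSD on top, so walking the
    # contour enters the PSD at its right boundary and leaves at its left
    first, last, idx = run_bounds(mb.PSD)
    if first is not None:
        if hits[0]:                                     # right elongate
            recruit((first - 1) % m.n, mb.PSD, m.h_psd)
        first, last, idx = run_bounds(mb.PSD)
        if hits[1] and idx.size > 1:                    # right shrink
            m.roles[first] = mb.FREE
        first, last, idx = run_bounds(mb.PSD)
        if hits[2]:                                     # left elongate
            recruit((last + 1) % m.n, mb.PSD, m.h_psd)
        first, last, idx = run_bounds(mb.PSD)
        if hits[3] and idx.size > 1:                    # left shrink
            m.roles[last] = mb.FREE
        idx = np.flatnonzero(m.roles == mb.PSD)
        if hits[4]:                                     # PSD up
            m.h_psd += d_mov
            m.vertices[idx, 1] = m.h_psd
        elif hits[5]:                                   # PSD down
            m.h_psd -= d_mov
            m.vertices[idx, 1] = m.h_psd

    first, last, idx = run_bounds(mb.NECK)
    if first is not None:
        if hits[6]:                                     # neck elongate
            recruit((first - 1) % m.n, mb.NECK, m.h_neck)
            recruit((last + 1) % m.n, mb.NECK, m.h_neck)
        first, last, idx = run_bounds(mb.NECK)
        if hits[7] and idx.size > 2:                    # neck shrink
            m.roles[first] = mb.FREE
            m.roles[last] = mb.FREE
    return m


_REST_CACHE: dict = {}


def initial_mesh(config: SimConfig) -> mb.MembraneMesh:
    """Resting shape: the stadium seed polygon relaxed to equilibrium.

    Deterministic in the mechanical and geometry parameters, so the result
    is memoized for the lifetime of the process (replicate runs share it).
    """
    g = config.geometry
    me = config.mechanical
    key = (g.h_psd, g.h_neck, g.psd_width, g.neck_width, g.bulge, g.spacing,
           me.P, me.tau, me.kappa, me.zeta, me.d_min, me.d_max, me.dt)
    if key not in _REST_CACHE:
        seed = mb.stadium_mesh(h_psd=g.h_psd, h_neck=g.h_neck,
                               psd_width=g.psd_width,
                               neck_width=g.neck_width,
                               bulge=g.bulge, spacing=g.spacing)
        _REST_CACHE[key] = mb.relax_to_rest(seed, me)
    return _REST_CACHE[key].copy()


def run_simulation(config: SimConfig,
                   start_mesh: mb.MembraneMesh | None = None) -> Trajectory:
    """Run the coupled membrane/actin simulation and record the trajectory.

    Deterministic under a fixed config seed.  Aborts with
    ``SimulationAborted`` if the contour self-intersects or coordinates
    become non-finite.
    """
    mech = config.mechanical
    rates = config.actin
    kp = config.kernel
    rng = np.random.default_rng(config.seed)
    mesh = (start_mesh.copy() if start_mesh is not None
            else initial_mesh(config))

    n_steps = int(round(config.duration / mech.dt))
    sub = replace(mech, dt=mech.dt / config.n_substeps)
    sample_every = max(int(round(config.sample_interval / mech.dt)), 1)

    times = np.arange(n_steps) * mech.dt
    areas = np.empty(n_steps)
    total_B = np.zeros(n_steps, dtype=np.int64)
    n_foci = np.zeros(n_steps, dtype=np.int32)
    snapshots, snapshot_times, log = [], [], []

    foci: list[ac.Focus] = []
    next_id = 0
    nuc_rates = rates
    ltp_done = False

    for step in range(n_steps):
        t = times[step]
        if (config.ltp is not None and not ltp_done
                and t >= config.ltp.t_event):
            nuc_rates = replace(rates,
                                gamma_f=rates.gamma_f * config.ltp.factor)
            ltp_done = True

        new = ac.maybe_nucleate(mesh, nuc_rates, rng, focus_id=next_id,
                                time=t, offset_scale=kp.sigma)
        if new is not None:
            foci.append(new)
            next_id += 1
            if config.log_events:
                log.append((t, new.id, "nucleate", new.B))

        if foci:
            mem_f = _kern.mem_force(mesh.vertices, mech.P, mech.tau,
                                    mech.kappa)
            survivors = []
            track = config.kernel_center == "track"
            for f in foci:
                F_i = ac.local_membrane_force(
                    f, mesh, mem_f, kp, mode=config.force_mode,
                    X_c=None if track else f.X_n)
                f2, _, counts = ac.step_focus(f, F_i, rates, rng,
                                              feedback=config.feedback)
                if config.log_events:
                    for ev in ("branch", "cap", "uncap", "sever"):
                        if counts[ev]:
                            log.append((t, f2.id, ev, f2.B))
                if f2.extinct:
                    if config.log_events:
                        log.append((t, f2.id, "extinct", 0))
                else:
                    survivors.append(f2)
            foci = survivors

        # fused mechanical substeps (jitted), in chunks with mesh
        # maintenance between them: remeshing keeps the edge lengths inside
        # the integrator's stability envelope, and the excluded-volume pass
        # keeps opposite walls of thin protrusions from passing through
        # each other; the spine is attached to the dendrite at the neck, so
        # the contour cannot dip below that plane
        fx = np.array([f.X_n[0] for f in foci])
        fy = np.array([f.X_n[1] for f in foci])
        fB = np.array([float(f.B) for f in foci])
        touched = 0
        _, el_now = mb._edge_vectors(mesh.vertices)
        e_min = float(el_now.min())
        for chunk in _SUBSTEP_CHUNKS:
            # stability-adaptive substep count: the explicit step must keep
            # zeta*dt_sub*k_max below ~1 with k_max ~ 64*kappa/l_min^3
            k_max = 67.0 * mech.kappa / max(e_min, mech.d_min) ** 3
            need = int(np.ceil(mech.dt * chunk * mech.zeta * k_max)) + 1
            n_sub = min(max(need, 8), max(int(config.n_substeps * chunk), 8))
            remaining = n_sub
            stall = 0
            while remaining > 0:
                if config.kernel_center == "track" and len(foci):
                    centres = np.array([ac.contact_point(f, mesh, kp.reach)
                                        for f in foci])
                    cxa, cya = centres[:, 0], centres[:, 1]
                else:
                    cxa, cya = fx, fy
                status, e_min, e_max, area, done = _kern.run_substeps(
                    mesh.vertices, mesh.free_mask, mech.P, mech.tau,
                    mech.kappa, mech.zeta, sub.dt, remaining, cxa, cya,
                    fx, fy, fB, kp.amplitude, kp.sigma, mesh.h_neck,
                    mech.d_max, mech.d_min)
                if status == 1:
                    raise mb.TimeStepError(
                        f"substep displacement exceeded d_max at step {step}")
                remaining -= done
                stall = stall + 1 if done == 0 else 0
                if stall > 5:
                    raise mb.TimeStepError(
                        f"mesh maintenance stalled at step {step}")
                if status == 2 or e_min < mech.d_min or e_max > mech.d_max:
                    mesh = mb.remesh(mesh, mech)
                    _, el_now = mb._edge_vectors(mesh.vertices)
                    e_min = float(el_now.min())
            moved = _kern.resolve_contacts(mesh.vertices, mesh.free_mask,
                                           config.contact_radius)
            touched += moved
            if moved:
                # contact pushes can themselves create out-of-bound edges
                _, el_now = mb._edge_vectors(mesh.vertices)
                if (el_now.min() < mech.d_min
                        or el_now.max() > mech.d_max):
                    mesh = mb.remesh(mesh, mech)
                    _, el_now = mb._edge_vectors(mesh.vertices)
                e_min = float(el_now.min())

        before = mesh
        mesh = psd_neck_update(mesh, config.psd_neck_rate, config.d_mov,
                               rng, mech.dt)
        if (mesh is not before or touched
                or e_min < mech.d_min or e_max > mech.d_max):
            area = abs(mb.signed_area(mesh))

        areas[step] = area
        total_B[step] = sum(f.B for f in foci)
        n_foci[step] = len(foci)

        if step % sample_every == 0:
            snapshot_times.append(t)
            snapshots.append(mesh.copy())
        if mesh.n > config.max_vertices:
            # tens of micrometres of contour cannot fit a spine's membrane
            # reservoir: the run has left the model's validity envelope
            raise SimulationAborted(
                f"contour grew beyond {config.max_vertices} vertices", step)
        if step % config.check_interval == 0:
            if not np.all(np.isfinite(mesh.vertices)):
                raise SimulationAborted("non-finite coordinates", step)
            if not mesh.is_simple():
                raise SimulationAborted("contour self-intersects", step)

    return Trajectory(dt=mech.dt, sample_interval=config.sample_interval,
                      times=times, areas=areas, total_B=total_B,
                      n_foci=n_foci, snapshot_times=snapshot_times,
                      snapshots=snapshots, event_log=log)


@dataclass
class LTPResult:
    """One replicate of the LTP experiment."""

    seed: int
    times: np.ndarray                   # sampled times, s
    areas: np.ndarray                   # sampled areas, um^2
    doubling_time: float | None         # s after t_event, None if never
    pct_change: float                   # % area change, 5-min means


def area_doubling_time(times: np.ndarray, areas: np.ndarray,
                       t_event: float) -> float | None:
    """First sampled time after ``t_event`` at which the area reaches twice
    its value at ``t_event``; None if it never does."""
    times = np.asarray(times, float)
    areas = np.asarray(areas, float)
    i0 = int(np.argmin(np.abs(times - t_event)))
    ref = areas[i0]
    after = np.flatnonzero((times > t_event) & (areas >= 2.0 * ref))
    if after.size == 0:
        return None
    return float(times[after[0]] - t_event)


def pct_area_change(times: np.ndarray, areas: np.ndarray, t_event: float,
                    window: float = 300.0) -> float:
    """Percent change of the mean area over ``window`` s after vs before
    ``t_event`` (the Fig-style 5-min pre/post time averages)."""
    times = np.asarray(times, float)
    areas = np.asarray(areas, float)
    if t_event - window < times[0] - 1e-9 or t_event + window > times[-1] + 1e-9:
        raise ValueError("t_event +/- window outside the recorded series")
    before = areas[(times >= t_event - window) & (times < t_event)]
    after = areas[(times >= t_event) & (times <= t_event + window)]
    mb_ = float(before.mean())
    return 100.0 * (float(after.mean()) - mb_) / mb_


def ltp_experiment(config: SimConfig, n_replicates: int,
                   window: float = 300.0,
                   start_mesh: mb.MembraneMesh | None = None) -> list[LTPResult]:
    """Run ``n_replicates`` independent LTP simulations (distinct seeds) and
    report per-replicate doubling time and 5-min pre/post area change."""
    if config.ltp is None:
        raise ValueError("config.ltp must be set for the LTP experiment")
    t_event = config.ltp.t_event
    if t_event - window < 0 or t_event + window > config.duration:
        raise ValueError("t_event +/- window outside simulation duration")
    if start_mesh is None:
        start_mesh = initial_mesh(config)
    out = []
    for k in range(n_replicates):
        cfg = replace(config, seed=config.seed + k, log_events=False)
        traj = run_simulation(cfg, start_mesh=start_mesh)
        ts, ar = traj.sampled_times, traj.sampled_areas
        out.append(LTPResult(seed=cfg.seed, times=ts, areas=ar,
                             doubling_time=area_doubling_time(ts, ar, t_event),
                             pct_change=pct_area_change(ts, ar, t_event,
                                                        window)))
    return out


def welch_test(sample_a, sample_b):
    """Two-sided Welch unequal-variance t-test: returns (t, p).

    Two zero-variance samples with equal means give (0.0, 1.0).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = _sstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
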