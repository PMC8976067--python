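"""Synthetic FLIM, time-lapse, isotopologue, and cell-count data with truth.

The FLIM generator emulates two-photon NADH lifetime acquisitions: every
cell pixel draws photon micro-times from a two-component mixture of
exponential decays -- a short "free NADH" lifetime and a long "enzyme-bound
NADH" lifetime -- wrapped modulo the laser period, blurred by a Gaussian
instrument response, and binned into a TCSPC histogram with Poisson photon
statistics.  The per-cell bound photon fraction f_bound is the ground-truth
analogue of the bound/total-NADH ratio (BTNR) the analysis estimates:
because phasors of mixtures combine intensity-linearly, a cell generated at
f_bound sits at normalized distance f_bound along the free-to-bound tie
line.

Defaults reflect the modeled study system: tau_free = 0.4 ns,
tau_bound = 3.4 ns (literature NADH values), 80 MHz repetition (12.5 ns
period), 256 micro-time bins, OxPhos-like cells at f_bound = 0.85 and
glycolytic cells at 0.70 with a classification cutoff of 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metabolomics import convolve_natural_abundance
from .phasor import TCSPCStack

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "TimeSeriesConfig",
    "MetabSimConfig",
    "generate_flim_scene",
    "generate_time_series",
    "generate_isotopologue_table",
    "generate_count_table",
    "generate_reference_stack",
    "decay_bin_probabilities",
]

STATE_OXPHOS = "OxPhos"
STATE_GLYC = "Glycolytic"


@dataclass
class SceneConfig:
    """Parameters of one synthetic FLIM scene.

    ``f_bound`` may be a scalar (all cells identical) or a sequence with one
    entry per cell.  ``shape`` of None auto-sizes the image to fit the cells
    on a jittered grid.  The seed fixes all randomness.
    """

    n_cells: int = 20
    f_bound: float | list[float] = 0.85
    photons_per_cell: float = 1e5
    shape: tuple[int, int] | None = None
    period_ns: float = 12.5
    n_bins: int = 256
    irf_sigma_ns: float = 0.1
    irf_center_ns: float = 0.5
    tau_free_ns: float = 0.4
    tau_bound_ns: float = 3.4
    background_photons: float = 0.05
    hoechst: bool = False
    hoechst_multiplier: float = 10.0
    hoechst_lifetime_ns: float = 1.4
    cell_radius_px: float = 10.0
    state_cutoff: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_ns <= 0:
            raise ValueError("laser period must be positive")
        if self.n_bins < 16:
            raise ValueError("need at least 16 micro-time bins")
        fb = np.atleast_1d(np.asarray(self.f_bound, dtype=float))
        if np.any((fb < 0) | (fb > 1)):
            raise ValueError("f_bound must lie in [0, 1]")
        if fb.size not in (1, self.n_cells):
            raise ValueError("f_bound must be scalar or one value per cell")
        if self.photons_per_cell < 0 or self.background_photons < 0:
            raise ValueError("photon budgets must be nonnegative")
        if self.irf_sigma_ns < 0:
            raise ValueError("IRF width must be nonnegative")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins

    def f_bound_per_cell(self) -> np.ndarray:
        fb = np.atleast_1d(np.asarray(self.f_bound, dtype=float))
        if fb.size == 1:
            fb = np.repeat(fb, self.n_cells)
        return fb


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a generated scene.

    label_mask uses 0 for background and 1..n_cells for cells; state labels
    follow the cutoff rule on f_bound; photon_log records how many photons
    each cell drew from the bound vs free component.
    """

    label_mask: np.ndarray
    nuclear_mask: np.ndarray
    f_bound: np.ndarray
    states: list[str]
    centroids: np.ndarray
    cutoff: float
    photon_log: dict[int, tuple[int, int]] = field(default_factory=dict)
    transitions: list[dict] = field(default_factory=list)
    alive: np.ndarray | None = None

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.label_mask)
        return ids[ids > 0]


@dataclass
class TimeSeriesConfig:
    """Dynamics of a time-lapse experiment.

    Transitions may be scripted (``schedule`` entries of
    (cell_id, frame, direction) with direction "G->O" or "O->G") or drawn
    from Markov rates per hour.  Under the cisplatin model glycolytic cells
    die with ``cisplatin_death_prob`` per frame and the G->O rate is
    multiplied; under phenformin the O->G rate is multiplied.
    """

    n_frames: int = 17
    frame_interval_h: float = 3.0
    schedule: list[tuple[int, int, str]] | None = None
    g2o_rate_per_h: float = 0.0
    o2g_rate_per_h: float = 0.0
    treatment: str | None = None
    cisplatin_death_prob: float = 0.05
    cisplatin_g2o_multiplier: float = 5.0
    phenformin_o2g_multiplier: float = 5.0
    initial_oxphos_fraction: float = 0.2
    initial_states: list[str] | None = None
    f_glycolytic: float = 0.70
    f_oxphos: float = 0.85
    jitter_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.g2o_rate_per_h < 0 or self.o2g_rate_per_h < 0:
            raise ValueError("transition rates must be nonnegative")
        for p in (self.cisplatin_death_prob, self.initial_oxphos_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.treatment not in (None, "cisplatin", "phenformin"):
            raise ValueError("treatment must be None, 'cisplatin' or 'phenformin'")


@dataclass
class MetabSimConfig:
    """Forward model for LC-MS isotopologue tables.

    ``truth`` maps condition -> metabolite -> corrected isotopologue
    distribution (length n_carbons + 1, summing to 1).  Measured signal is
    the truth convolved with the binomial natural-abundance matrix at
    abundance ``p``, scaled per sample and multiplied by log-normal noise.
    """

    truth: dict[str, dict[str, np.ndarray]]
    n_carbons: dict[str, int]
    p: float = 0.0107
    n_replicates: int = 3
    noise_sd: float = 0.05
    sample_scale: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p < 1:
            raise ValueError("natural abundance p must lie in [0, 1)")
        for cond, mets in self.truth.items():
            for met, x in mets.items():
                x = np.asarray(x, dtype=float)
                n = self.n_carbons[met]
                if x.shape != (n + 1,):
                    raise ValueError(f"{met}: distribution must have n+1 entries")
                if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-8:
                    raise ValueError(
                        f"{cond}/{met}: distribution must be nonnegative and sum to 1"
                    )


# ---------------------------------------------------------------------------
# decay model


def decay_bin_probabilities(
    tau_ns: float,
    period_ns: float,
    n_bins: int,
    irf_sigma_ns: float = 0.0,
    irf_center_ns: float = 0.0,
    oversample: int = 16,
) -> np.ndarray:
    """Bin probabilities of a periodically wrapped exponential decay.

    The decay exp(-t/tau) is wrapped modulo the laser period (so the
    single-period phasor equals the analytic 1/(1 + i*omega*tau) exactly),
    circularly convolved with a Gaussian IRF of width ``irf_sigma_ns``
    centered at ``irf_center_ns``, and integrated over the micro-time bins.
    tau = 0 gives a delta decay at the IRF center.
    """
    m = n_bins * oversample
    dt = period_ns / m
    t = (np.arange(m) + 0.5) * dt
    if tau_ns > 0:
        dens = np.exp(-t / tau_ns)
    else:
        dens = np.zeros(m)
        dens[0] = 1.0
    dens /= dens.sum()
    # circular convolution with the (wrapped) IRF kernel
    shift = irf_center_ns % period_ns
    if irf_sigma_ns > 0:
        d = (t - period_ns / 2.0)
        kernel = np.exp(-0.5 * (d / irf_sigma_ns) ** 2)
        kernel /= kernel.sum()
        kernel = np.roll(kernel, int(round((shift + period_ns / 2.0) / dt)) - m // 2)
    else:
        kernel = np.zeros(m)
        kernel[int(shift / dt) % m] = 1.0
    conv = np.fft.irfft(np.fft.rfft(dens) * np.fft.rfft(kernel), n=m)
    conv = np.clip(conv, 0.0, None)
    probs = conv.reshape(n_bins, oversample).sum(axis=1)
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# geometry


def _layout(config: SceneConfig, rng: np.random.Generator):
    """Place cells on a jittered grid; return (shape, centroids, radii)."""
    r = config.cell_radius_px
    n = config.n_cells
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    spacing = 4.5 * r
    margin = 2.4 * r
    shape = config.shape
    if shape is None:
        shape = (
            int(round(2 * margin + (rows - 1) * spacing)),
            int(round(2 * margin + (cols - 1) * spacing)),
        )
    centroids = np.empty((n, 2))
    for i in range(n):
        gy, gx = divmod(i, cols)
        jy, jx = rng.uniform(-0.15 * spacing, 0.15 * spacing, size=2)
        centroids[i] = (margin + gy * spacing + jy, margin + gx * spacing + jx)
    radii = np.column_stack([
        np.full(n, r),
        r * rng.uniform(0.85, 1.15, size=n),
    ])
    return shape, centroids, radii


def _masks(shape, centroids, radii, alive=None):
    """Rasterize elliptical cells and concentric nuclei into label masks."""
    label = np.zeros(shape, dtype=np.uint16)
    nuclear = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, ((cy, cx), (ry, rx)) in enumerate(zip(centroids, radii)):
        if alive is not None and not alive[i]:
            continue
        d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        inside = d2 <= 1.0
        label[inside] = i + 1
        nuclear |= d2 <= 0.16  # nucleus = concentric region at 40% radius
    nuclear &= label > 0
    return label, nuclear


def _render(
    config: SceneConfig,
    f_cells: np.ndarray,
    centroids: np.ndarray,
    radii: np.ndarray,
    alive: np.ndarray,
    rng: np.random.Generator,
) -> tuple[TCSPCStack, np.ndarray, np.ndarray, dict[int, tuple[int, int]]]:
    shape = config.shape if config.shape is not None else _auto_shape(config)
    label, nuclear = _masks(shape, centroids, radii, alive)
    B = config.n_bins
    kw = dict(
        period_ns=config.period_ns,
        n_bins=B,
        irf_sigma_ns=config.irf_sigma_ns,
        irf_center_ns=config.irf_center_ns,
    )
    p_bound = decay_bin_probabilities(config.tau_bound_ns, **kw)
    p_free = decay_bin_probabilities(config.tau_free_ns, **kw)
    counts = np.zeros(shape + (B,), dtype=np.uint16)
    photon_log: dict[int, tuple[int, int]] = {}
    for i in range(len(centroids)):
        if not alive[i]:
            continue
        ys, xs = np.nonzero(label == i + 1)
        if ys.size == 0:
            continue
        per_px = config.photons_per_cell / ys.size
        n_px = rng.poisson(per_px, size=ys.size)
        nb_px = rng.binomial(n_px, f_cells[i])
        nf_px = n_px - nb_px
        if nb_px.sum() > 0:
            counts[ys, xs] += rng.multinomial(nb_px, p_bound).astype(np.uint16)
        if nf_px.sum() > 0:
            counts[ys, xs] += rng.multinomial(nf_px, p_free).astype(np.uint16)
        photon_log[i + 1] = (int(nb_px.sum()), int(nf_px.sum()))
    if config.hoechst:
        p_h = decay_bin_probabilities(config.hoechst_lifetime_ns, **kw)
        ys, xs = np.nonzero(nuclear)
        if ys.size:
            # nuclear dye photons on top of cytoplasmic NADH signal
            cell_area = np.pi * radii[:, 0] * radii[:, 1]
            per_px_cell = config.photons_per_cell / cell_area.mean()
            lam = config.hoechst_multiplier * per_px_cell
            nh = rng.poisson(lam, size=ys.size)
            counts[ys, xs] += rng.multinomial(nh, p_h).astype(np.uint16)
    if config.background_photons > 0:
        n_bg = rng.poisson(config.background_photons * shape[0] * shape[1])
        if n_bg:
            py = rng.integers(0, shape[0], n_bg)
            px = rng.integers(0, shape[1], n_bg)
            pb = rng.integers(0, B, n_bg)
            np.add.at(counts, (py, px, pb), 1)
    stack = TCSPCStack(counts, config.period_ns, config.bin_width_ns)
    return stack, label, nuclear, photon_log


def _auto_shape(config: SceneConfig) -> tuple[int, int]:
    r = config.cell_radius_px
    cols = math.ceil(math.sqrt(config.n_cells))
    rows = math.ceil(config.n_cells / cols)
    spacing, margin = 4.5 * r, 2.4 * r
    return (
        int(round(2 * margin + (rows - 1) * spacing)),
        int(round(2 * margin + (cols - 1) * spacing)),
    )


def _state(f: float, cutoff: float) -> str:
    return STATE_OXPHOS if f > cutoff else STATE_GLYC


def generate_flim_scene(config: SceneConfig) -> tuple[TCSPCStack, SceneTruth]:
    """Generate one synthetic TCSPC scene plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    _, centroids, radii = _layout(config, rng)
    f_cells = config.f_bound_per_cell()
    alive = np.ones(config.n_cells, dtype=bool)
    stack, label, nuclear, photon_log = _render(
        config, f_cells, centroids, radii, alive, rng
    )
    truth = SceneTruth(
        label_mask=label,
        nuclear_mask=nuclear,
        f_bound=f_cells,
        states=[_state(f, config.state_cutoff) for f in f_cells],
        centroids=centroids,
        cutoff=config.state_cutoff,
        photon_log=photon_log,
        alive=alive,
    )
    return stack, truth


def generate_reference_stack(
    config: SceneConfig, lifetime_ns: float, photons: float = 1e6
) -> TCSPCStack:
    """Uniform monoexponential reference acquisition for IRF calibration.

    Simulated with the same period, binning and IRF as the scene config, on
    a small uniform field, so its measured phasor captures the instrumental
    phase/modulation that calibration divides out.
    """
    rng = np.random.default_rng(config.seed + 987654321 % (2**31))
    shape = (32, 32)
    probs = decay_bin_probabilities(
        lifetime_ns,
        config.period_ns,
        config.n_bins,
        config.irf_sigma_ns,
        config.irf_center_ns,
    )
    per_px = photons / (shape[0] * shape[1])
    n_px = rng.poisson(per_px, size=shape[0] * shape[1])
    counts = rng.multinomial(n_px, probs).reshape(shape + (config.n_bins,))
    return TCSPCStack(counts.astype(np.uint32), config.period_ns, config.bin_width_ns)


# ---------------------------------------------------------------------------
# time lapse


def generate_time_series(
    scene: SceneConfig, ts: TimeSeriesConfig, render: bool = True
) -> tuple[list[TCSPCStack], list[SceneTruth]]:
    """Simulate a time-lapse acquisition with metabolic state transitions.

    Cells persist across frames with small centroid jitter; scripted or
    Markov transitions flip each cell's f_bound between the glycolytic and
    OxPhos values; under the cisplatin model glycolytic cells may die
    (drop out of the mask).  Each frame's SceneTruth carries the transition
    events that occurred since the previous frame.

    With ``render=False`` no photon stacks are drawn (the stack list is
    empty) but the truth sequence is identical to a rendered run: state
    dynamics and photon noise use separate random streams.
    """
    rng = np.random.default_rng(ts.seed)
    photon_rng = np.random.default_rng((ts.seed + 1_000_003) % 2**31)
    geo_rng = np.random.default_rng(scene.seed)
    _, base_centroids, radii = _layout(scene, geo_rng)
    n = scene.n_cells

    if ts.initial_states is not None:
        if len(ts.initial_states) != n:
            raise ValueError("initial_states must have one entry per cell")
        states = list(ts.initial_states)
    else:
        ox = rng.random(n) < ts.initial_oxphos_fraction
        states = [STATE_OXPHOS if o else STATE_GLYC for o in ox]
    alive = np.ones(n, dtype=bool)

    g2o = ts.g2o_rate_per_h
    o2g = ts.o2g_rate_per_h
    death_p = 0.0
    if ts.treatment == "cisplatin":
        g2o *= ts.cisplatin_g2o_multiplier
        death_p = ts.cisplatin_death_prob
    elif ts.treatment == "phenformin":
        o2g *= ts.phenformin_o2g_multiplier
    p_g2o = 1.0 - math.exp(-g2o * ts.frame_interval_h)
    p_o2g = 1.0 - math.exp(-o2g * ts.frame_interval_h)

    sched: dict[int, list[tuple[int, str]]] = {}
    if ts.schedule is not None:
        for cell_id, frame, direction in ts.schedule:
            if not 1 <= cell_id <= n:
                raise ValueError(f"schedule references unknown cell {cell_id}")
            if not 0 <= frame < ts.n_frames:
                raise ValueError(f"schedule references unknown frame {frame}")
            sched.setdefault(frame, []).append((cell_id, direction))

    stacks: list[TCSPCStack] = []
    truths: list[SceneTruth] = []
    centroids = base_centroids.copy()
    for frame in range(ts.n_frames):
        events: list[dict] = []
        if frame > 0:
            centroids = base_centroids + rng.normal(0, ts.jitter_px, size=(n, 2))
            for cell_id, direction in sched.get(frame, []):
                i = cell_id - 1
                if not alive[i]:
                    continue
                new = STATE_OXPHOS if direction == "G->O" else STATE_GLYC
                if states[i] != new:
                    events.append(
                        {"cell": cell_id, "frame": frame, "direction": direction}
                    )
                    states[i] = new
            if ts.schedule is None and (p_g2o > 0 or p_o2g > 0):
                u = rng.random(n)
                for i in range(n):
                    if not alive[i]:
                        continue
                    if states[i] == STATE_GLYC and u[i] < p_g2o:
                        states[i] = STATE_OXPHOS
                        events.append(
                            {"cell": i + 1, "frame": frame, "direction": "G->O"}
                        )
                    elif states[i] == STATE_OXPHOS and u[i] < p_o2g:
                        states[i] = STATE_GLYC
                        events.append(
                            {"cell": i + 1, "frame": frame, "direction": "O->G"}
                        )
            if death_p > 0:
                dies = rng.random(n) < death_p
                for i in range(n):
                    if alive[i] and states[i] == STATE_GLYC and dies[i]:
                        alive[i] = False
        f_cells = np.array(
            [ts.f_oxphos if st == STATE_OXPHOS else ts.f_glycolytic for st in states]
        )
        if render:
            stack, label, nuclear, photon_log = _render(
                scene, f_cells, centroids, radii, alive, photon_rng
            )
            stacks.append(stack)
        else:
            shape = scene.shape if scene.shape is not None else _auto_shape(scene)
            label, nuclear = _masks(shape, centroids, radii, alive)
            photon_log = {}
        truths.append(
            SceneTruth(
                label_mask=label,
                nuclear_mask=nuclear,
                f_bound=f_cells,
                states=list(states),
                centroids=centroids.copy(),
                cutoff=scene.state_cutoff,
                photon_log=photon_log,
                transitions=events,
                alive=alive.copy(),
            )
        )
    return stacks, truths


# ---------------------------------------------------------------------------
# metabolomics & counts


def generate_isotopologue_table(
    config: MetabSimConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]]]:
    """Forward-simulate an LC-MS isotopologue table in long format.

    Columns: sample, condition, replicate, metabolite, n_carbons, M, signal.
    The returned truth dict holds the corrected distributions the
    natural-abundance correction should recover.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond, mets in config.truth.items():
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_{rep}"
            for met, x in mets.items():
                n = config.n_carbons[met]
                measured = convolve_natural_abundance(
                    np.asarray(x, dtype=float), config.p
                )
                if config.noise_sd > 0:
                    noise = rng.lognormal(0.0, config.noise_sd, size=n + 1)
                else:
                    noise = np.ones(n + 1)
                sig = measured * config.sample_scale * noise
                for m in range(n + 1):
                    rows.append(
                        (sample, cond, rep, met, n, m, float(sig[m]))
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample", "condition", "replicate",
            "metabolite", "n_carbons", "M", "signal",
        ],
    )
    return table, config.truth


def generate_count_table(
    effects: dict[str, float],
    control_count: float = 3e5,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_name: str = "control",
) -> pd.DataFrame:
    """Cell-count table for synergy analysis: count = control x fraction x noise.

    ``effects`` maps condition name -> survival fraction in (0, 1]; the
    control arm (fraction 1) is added automatically.
    """
    if control_count <= 0:
        raise ValueError("control count must be positive")
    for cond, f in effects.items():
        if not 0 < f <= 1:
            raise ValueError(f"survival fraction for {cond} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    arms = {control_name: 1.0, **effects}
    rows = []
    for cond, frac in arms.items():
        for rep in range(1, n_replicates + 1):
            noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
            rows.append((cond, rep, int(round(control_count * frac * noise))))
    return pd.DataFrame(rows, columns=["condition", "replicate", "count"])
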