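"""End-to-end FLIM analysis pipeline.

Composes the stages: decay stacks -> phasor transform -> calibration ->
Hoechst thresholding -> complex-wavelet filtering -> per-ROI BTNR -> frame
linking -> transition detection -> population timecourse.  Every
intermediate is persisted; a manifest records the configuration hash and
software version so runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .btnr import DEFAULT_CUTOFF, ReferencePair, measure_rois, segment_cells
from .denoise import FilterConfig, complex_wavelet_filter, hoechst_threshold
from .phasor import calibrate, mean_phasor, phasor_transform
from .synthetic import SceneConfig, generate_reference_stack
from .tracking import detect_transitions, link_frames, population_timecourse

log = logging.getLogger("phasortrack")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_flim_pipeline",
    "analyze_scene",
]


def analyze_scene(
    stack,
    mask,
    config: PipelineConfig | None = None,
    frame: int = 0,
):
    """Run the in-memory analysis chain on one stack with a known mask.

    phasor transform -> IRF calibration (against a simulated monoexponential
    reference matched to the stack's timing) -> Hoechst thresholding ->
    complex-wavelet filtering -> per-ROI BTNR measurement.  Returns the list
    of RoiMeasurement.
    """
    config = config or PipelineConfig()
    omega = 2 * np.pi * config.harmonic / stack.period_ns
    img = phasor_transform(stack, config.harmonic)
    if config.calibration_lifetime_ns is not None:
        ref_scene = SceneConfig(
            n_cells=1, period_ns=stack.period_ns, n_bins=stack.n_bins,
            seed=config.seed,
        )
        ref = generate_reference_stack(ref_scene, config.calibration_lifetime_ns)
        measured = mean_phasor(phasor_transform(ref, config.harmonic))
        img = calibrate(img, measured, config.calibration_lifetime_ns, omega)
    fcfg = FilterConfig(
        levels=config.wavelet_levels,
        hoechst_percentile=config.hoechst_percentile,
    )
    if config.apply_hoechst_threshold:
        img = hoechst_threshold(img, fcfg)
    if config.apply_wavelet_filter:
        img = complex_wavelet_filter(img, fcfg)
    refs = ReferencePair.from_lifetimes(
        config.tau_free_ns, config.tau_bound_ns, omega
    )
    return measure_rois(img, mask, refs, config.cutoff, frame=frame)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; round-trips through JSON."""

    stack_paths: list[str] = field(default_factory=list)
    mask_paths: list[str] | None = None
    out_dir: str = "phasortrack_out"
    harmonic: int = 1
    tau_free_ns: float = 0.4
    tau_bound_ns: float = 3.4
    cutoff: float = DEFAULT_CUTOFF
    calibration_lifetime_ns: float | None = 2.0
    wavelet_levels: int = 3
    hoechst_percentile: float = 98.0
    apply_hoechst_threshold: bool = True
    apply_wavelet_filter: bool = True
    gate_px: float = 10.0
    debounce: int = 1
    make_figures: bool = True
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _calibration_point(stacks, cfg: PipelineConfig):
    """Measured phasor of a simulated monoexponential reference acquisition
    matched to the input stack's timing (period / bins / IRF defaults)."""
    ref_scene = SceneConfig(
        n_cells=1,
        period_ns=stacks[0].period_ns,
        n_bins=stacks[0].n_bins,
        seed=cfg.seed,
    )
    ref_stack = generate_reference_stack(ref_scene, cfg.calibration_lifetime_ns)
    return mean_phasor(phasor_transform(ref_stack, cfg.harmonic))


def run_flim_pipeline(config: PipelineConfig) -> Path:
    """Run the full FLIM pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        stacks = [io.read_stack(p) for p in config.stack_paths]
        if not stacks:
            raise ValueError("no input stacks")
        masks = None
        if config.mask_paths:
            masks = [io.read_mask(p) for p in config.mask_paths]
            if len(masks) not in (1, len(stacks)):
                raise ValueError("need one mask, or one per stack")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    omega = 2 * np.pi * config.harmonic / stacks[0].period_ns
    refs = ReferencePair.from_lifetimes(
        config.tau_free_ns, config.tau_bound_ns, omega
    )
    fcfg = FilterConfig(
        levels=config.wavelet_levels,
        hoechst_percentile=config.hoechst_percentile,
    )

    measured_ref = None
    if config.calibration_lifetime_ns is not None:
        stage = "calibration-reference"
        try:
            measured_ref = _calibration_point(stacks, config)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e

    frames = []
    for fi, stack in enumerate(stacks):
        stage = f"phasor-transform[{fi}]"
        try:
            img = phasor_transform(stack, config.harmonic)
            if measured_ref is not None:
                img = calibrate(
                    img, measured_ref, config.calibration_lifetime_ns, omega
                )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e
        stage = f"denoise[{fi}]"
        try:
            if config.apply_hoechst_threshold:
                img = hoechst_threshold(img, fcfg)
            if config.apply_wavelet_filter:
                img = complex_wavelet_filter(img, fcfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e
        io.write_phasor(img, out / f"phasor_{fi:03d}.tif")
        stage = f"measure[{fi}]"
        try:
            if masks is not None:
                mask = masks[fi if len(masks) > 1 else 0]
            else:
                mask = segment_cells(img.intensity)
                io.write_mask(mask, out / f"mask_{fi:03d}.tif")
            ms = measure_rois(img, mask, refs, config.cutoff, frame=fi)
            log.info("stage=%s rois=%d", stage, len(ms))
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, e) from e
        io.write_roi_csv(ms, out / f"rois_{fi:03d}.csv")
        frames.append(ms)

    stage = "track"
    try:
        tracks = link_frames(frames, config.gate_px)
        events = [e for t in tracks for e in detect_transitions(t, config.debounce)]
        course = population_timecourse(tracks)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    import pandas as pd

    pd.DataFrame(
        [
            {
                "track": t.track_id, "frame": m.frame, "btnr": m.btnr,
                "g": m.com.g, "s": m.com.s, "state": m.state,
            }
            for t in tracks
            for m in t.measurements
        ]
    ).to_csv(out / "tracks.csv", index=False)
    pd.DataFrame(
        [
            {
                "track": e.track, "frame_from": e.frame_from,
                "frame_to": e.frame_to, "direction": e.direction,
            }
            for e in events
        ],
        columns=["track", "frame_from", "frame_to", "direction"],
    ).to_csv(out / "events.csv", index=False)
    course.to_csv(out / "timecourse.csv", index=False)

    if config.make_figures:
        stage = "figures"
        try:
            _phasor_figure(out, refs, omega)
        except Exception as e:  # noqa: BLE001
            log.warning("figure stage failed (non-fatal): %s", e)

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "n_frames": len(frames),
        "n_tracks": len(tracks),
        "n_events": len(events),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "config.json").write_text(config.to_json())
    return out


def _phasor_figure(out: Path, refs: ReferencePair, omega: float) -> None:
    """Phasor density plot with the universal semicircle and tie line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = io.read_phasor(out / "phasor_000.tif")
    g = img.g[img.valid]
    s = img.s[img.valid]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist2d(g, s, bins=120, range=[[0, 1], [0, 0.7]], cmap="viridis",
              cmin=1)
    th = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th), "w--", lw=1)
    ax.plot([refs.free.g, refs.bound.g], [refs.free.s, refs.bound.s],
            "r-", lw=1)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_title("phasor density (frame 0)")
    fig.tight_layout()
    fig.savefig(out / "phasor_density.png", dpi=110)
    plt.close(fig)
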