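"""Synthetic study generator: archetype hemodynamics, noise, raw signals.

Generates ground-truth chromophore and blood-flow time courses for three
subject archetypes under each block protocol, then forward-models them into
the raw measurables (dual-wavelength intensities via the MBLL forward model;
noisy g2 autocorrelation frames via the Siegert/diffusion forward model) so
the entire analysis chain can be exercised and verified without any
external data.

Archetypes
----------
* ``healthy`` — canonical responses: cognitive activation raises dHbO2 and
  lowers dHb with near-constant flow; breath hold shows the hypoxia pattern
  (dHbO2 down, dHb up) with a flow dip and a post-release hyperemic peak.
* ``neuron_deficit`` — blunted oxygenation responses to every task and
  task-gated large slow flow oscillations (autoregulatory instability).
* ``vascular_deficit`` — cognitive tasks drive both chromophores down
  (task ischemia, with an HbO2 recovery overshoot); flow responds with a
  sustained rise (VFT) or a drop that recovers quickly (HCT); breath hold
  shows a delayed paradoxical rise of both chromophores.

The response kernel is a saturating exponential toward a task plateau with
an exponential return (optionally to an overshoot level) in recovery —
block-trend shapes, not transient HRFs. Amplitudes are declared fixtures
(see ``ARCHETYPE_TABLE``); they define the study conditions for every test.
Physiological noise is white + 1/f + ~1 Hz cardiac; g2 shot noise is a
lag-independent multiplicative Gaussian surrogate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dcs import (
    DcsOpticalModel,
    FlowSeries,
    G2Frame,
    default_tau_grid,
    g1_semiinfinite,
    write_g2_frames,
    read_g2_frames,
)
from .mbll import (
    ExtinctionTable,
    IntensitySeries,
    MeasurementGeometry,
    OxySeries,
    forward_mbll,
)
from .protocol import ProtocolTimeline, build_timeline

__all__ = [
    "ARCHETYPES",
    "ARCHETYPE_TABLE",
    "DESIGNED_LABELS",
    "OxyResponse",
    "FlowResponse",
    "NoiseSpec",
    "ArchetypeSpec",
    "archetype_spec",
    "generate_oxy_truth",
    "generate_flow_truth",
    "add_physiological_noise",
    "synthesize_g2_frames",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "regenerate_from_manifest",
]

ARCHETYPES = ("healthy", "neuron_deficit", "vascular_deficit")


@dataclass(frozen=True)
class OxyResponse:
    """Chromophore block-response parameters (amplitudes in uM)."""

    a_hbo2: float
    a_hb: float
    tau_rise_s: float = 10.0
    tau_recovery_s: float = 20.0
    overshoot_hbo2: float = 0.0  # recovery asymptote relative to baseline
    overshoot_hb: float = 0.0
    onset_delay_s: float = 0.0


@dataclass(frozen=True)
class FlowResponse:
    """Flow block-response parameters (all amplitudes in rCBF %)."""

    task_delta_pct: float = 0.0
    tau_rise_s: float = 10.0
    tau_recovery_s: float = 20.0
    sustain: bool = False  # hold the task plateau through recovery
    osc_base_pct: float = 0.0  # slow-oscillation amplitude outside the task
    osc_task_pct: float = 0.0  # ... during task + early recovery
    osc_freq_hz: float = 0.1
    vbh_kernel: bool = False
    vbh_nadir_pct: float = 0.0
    vbh_hyperemia_pct: float = 0.0
    vbh_nadir_frac: float = 1.0  # nadir position within the hold (1 = at release)


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological/instrument noise levels (defaults = study conditions)."""

    oxy_white_sd_um: float = 0.10
    oxy_pink_sd_um: float = 0.05
    oxy_cardiac_amp_um: float = 0.10
    flow_white_sd_pct: float = 3.0
    flow_pink_sd_pct: float = 1.0
    flow_cardiac_amp_pct: float = 2.0
    cardiac_hz: float = 1.0
    g2_noise_fraction: float = 0.01


@dataclass(frozen=True)
class ArchetypeSpec:
    """Full generating specification for one archetype."""

    archetype: str
    responses: Mapping[str, tuple[OxyResponse, FlowResponse]]
    baseline_alpha_db: float = 1e-8  # cm^2/s
    beta: float = 0.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        for task, (oxy, flow) in self.responses.items():
            if oxy.tau_rise_s <= 0 or oxy.tau_recovery_s <= 0:
                raise ValueError(f"{task}: time constants must be positive")
        if self.baseline_alpha_db <= 0:
            raise ValueError("baseline_alpha_db must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")


# Fixture amplitudes defining each archetype x task. Declared constants of the
# generator, not reproductions of any measured values.
ARCHETYPE_TABLE: dict[str, dict[str, tuple[OxyResponse, FlowResponse]]] = {
    "healthy": {
        "VFT": (OxyResponse(+0.8, -0.3), FlowResponse(task_delta_pct=0.0)),
        "HCT": (OxyResponse(+0.8, -0.3), FlowResponse(task_delta_pct=3.0)),
        "VBH": (
            OxyResponse(-0.5, +0.3),
            # gradual decline across the hold, sharp post-release hyperemia
            FlowResponse(
                vbh_kernel=True, vbh_nadir_pct=-10.0, vbh_hyperemia_pct=20.0,
                vbh_nadir_frac=1.0,
            ),
        ),
    },
    "neuron_deficit": {
        "VFT": (
            OxyResponse(+0.06, -0.03),
            FlowResponse(osc_base_pct=3.0, osc_task_pct=15.0),
        ),
        "HCT": (
            OxyResponse(+0.06, -0.03),
            FlowResponse(osc_base_pct=3.0, osc_task_pct=15.0),
        ),
        "VBH": (
            OxyResponse(-0.06, -0.04),
            FlowResponse(osc_base_pct=3.0, osc_task_pct=15.0),
        ),
    },
    "vascular_deficit": {
        "VFT": (
            OxyResponse(-0.6, -0.3, overshoot_hbo2=+0.2),
            FlowResponse(task_delta_pct=+10.0, sustain=True),
        ),
        "HCT": (
            OxyResponse(-0.6, -0.3, overshoot_hbo2=+0.2),
            FlowResponse(task_delta_pct=-12.0, tau_recovery_s=5.0),
        ),
        "VBH": (
            OxyResponse(+0.4, +0.3, onset_delay_s=10.0),
            # rapid early dip at hold onset, partial in-hold recovery, hyperemia
            FlowResponse(
                vbh_kernel=True, vbh_nadir_pct=-15.0, vbh_hyperemia_pct=12.0,
                vbh_nadir_frac=0.25,
            ),
        ),
    },
}

# The label pair each archetype x protocol is designed to elicit.
DESIGNED_LABELS: dict[tuple[str, str], tuple[str, str]] = {
    ("healthy", "VFT"): ("typical_activation", "stable"),
    ("healthy", "HCT"): ("typical_activation", "stable"),
    ("healthy", "VBH"): ("hypoxia_typical", "vbh_dip_hyperemia"),
    ("neuron_deficit", "VFT"): ("blunted", "flow_instability"),
    ("neuron_deficit", "HCT"): ("blunted", "flow_instability"),
    ("neuron_deficit", "VBH"): ("blunted", "flow_instability"),
    ("vascular_deficit", "VFT"): ("task_ischemia", "task_increase"),
    ("vascular_deficit", "HCT"): ("task_ischemia", "task_decrease_recover"),
    ("vascular_deficit", "VBH"): ("hypoxia_atypical", "vbh_dip_hyperemia"),
}


def archetype_spec(
    archetype: str, noise: NoiseSpec | None = None, **overrides
) -> ArchetypeSpec:
    """Build the generating spec for a named archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"archetype must be one of {ARCHETYPES}")
    return ArchetypeSpec(
        archetype=archetype,
        responses=ARCHETYPE_TABLE[archetype],
        noise=noise or NoiseSpec(),
        **overrides,
    )


def _block_kernel(
    time: np.ndarray,
    task_start: float,
    task_end: float,
    amplitude: float,
    tau_rise: float,
    tau_rec: float,
    overshoot: float = 0.0,
    onset_delay: float = 0.0,
    sustain: bool = False,
) -> np.ndarray:
    """Saturating-exponential block response; exactly 0 before task onset."""
    x = np.zeros_like(time)
    t0 = task_start + onset_delay
    in_task = (time >= t0) & (time < task_end)
    x[in_task] = amplitude * (1.0 - np.exp(-(time[in_task] - t0) / tau_rise))
    x_end = amplitude * (1.0 - np.exp(-max(task_end - t0, 0.0) / tau_rise))
    post = time >= task_end
    if sustain:
        x[post] = x_end
    else:
        x[post] = overshoot + (x_end - overshoot) * np.exp(
            -(time[post] - task_end) / tau_rec
        )
    return x


def _vbh_flow_kernel(
    time: np.ndarray,
    task_start: float,
    task_end: float,
    nadir_pct: float,
    hyperemia_pct: float,
    nadir_frac: float = 1.0,
    hyperemia_tau_s: float = 6.0,
    release_tau_s: float = 10.0,
) -> np.ndarray:
    """Breath-hold flow shape: onset dip to a nadir, partial rise during the
    hold, post-release hyperemic peak, exponential recovery (in rCBF %)."""
    x = np.zeros_like(time)
    hold = max(task_end - task_start, 1e-9)
    t_n = nadir_frac * hold
    in_task = (time >= task_start) & (time < task_end)
    tp = time[in_task] - task_start
    # skewed hump: unit peak at t_n, partial relaxation afterwards
    x[in_task] = nadir_pct * (tp / t_n) * np.exp(1.0 - tp / t_n)
    x_end = nadir_pct * (hold / t_n) * np.exp(1.0 - hold / t_n)
    post = time >= task_end
    s = time[post] - task_end
    x[post] = x_end * np.exp(-s / release_tau_s) + hyperemia_pct * (
        s / hyperemia_tau_s
    ) * np.exp(1.0 - s / hyperemia_tau_s)
    return x


def _task_window(timeline: ProtocolTimeline) -> tuple[float, float]:
    seg = timeline.segment("task")
    return seg.start_s, seg.end_s


def _time_grid(timeline: ProtocolTimeline, fs: float) -> np.ndarray:
    n = int(round(timeline.total_duration_s * fs))
    return np.arange(n) / fs


def generate_oxy_truth(
    spec: ArchetypeSpec, timeline: ProtocolTimeline, fs: float = 10.0
) -> OxySeries:
    """Noise-free dHbO2/dHb truth on the uniform grid; zero over baseline."""
    oxy, _ = spec.responses[timeline.protocol]
    time = _time_grid(timeline, fs)
    t0, t1 = _task_window(timeline)
    dhbo2 = _block_kernel(
        time, t0, t1, oxy.a_hbo2, oxy.tau_rise_s, oxy.tau_recovery_s,
        oxy.overshoot_hbo2, oxy.onset_delay_s,
    )
    dhb = _block_kernel(
        time, t0, t1, oxy.a_hb, oxy.tau_rise_s, oxy.tau_recovery_s,
        oxy.overshoot_hb, oxy.onset_delay_s,
    )
    return OxySeries(time, dhbo2[:, None], dhb[:, None], ["truth"])


def generate_flow_truth(
    spec: ArchetypeSpec, timeline: ProtocolTimeline, fs: float = 10.0
) -> FlowSeries:
    """Noise-free rCBF/alpha_Db truth; rCBF = 100 over the baseline."""
    _, flow = spec.responses[timeline.protocol]
    time = _time_grid(timeline, fs)
    t0, t1 = _task_window(timeline)
    if flow.vbh_kernel:
        dev = _vbh_flow_kernel(
            time, t0, t1, flow.vbh_nadir_pct, flow.vbh_hyperemia_pct,
            nadir_frac=flow.vbh_nadir_frac,
        )
    else:
        dev = _block_kernel(
            time, t0, t1, flow.task_delta_pct, flow.tau_rise_s,
            flow.tau_recovery_s, sustain=flow.sustain,
        )
    if flow.osc_task_pct or flow.osc_base_pct:
        gate = ((time >= t0) & (time < t1 + 20.0)).astype(float)
        amp = flow.osc_base_pct + (flow.osc_task_pct - flow.osc_base_pct) * gate
        dev = dev + amp * np.sin(2.0 * np.pi * flow.osc_freq_hz * time)
    rcbf_pct = 100.0 + dev
    if np.any(rcbf_pct <= 0):
        raise ValueError("flow truth dropped to nonpositive rCBF; check amplitudes")
    alpha = spec.baseline_alpha_db * rcbf_pct / 100.0
    return FlowSeries(time, alpha, rcbf_pct)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise by spectral synthesis (zero DC)."""
    freqs = np.fft.rfftfreq(n)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def add_physiological_noise(
    values: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    white_sd: float = 0.0,
    pink_sd: float = 0.0,
    cardiac_amp: float = 0.0,
    cardiac_hz: float = 1.0,
) -> np.ndarray:
    """Add white + 1/f + cardiac-sinusoid noise along axis 0.

    Each channel (column) draws independent noise; the cardiac component has
    a seeded random phase per channel. Zero levels return the input values
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    work = values[:, None] if squeeze else values.copy()
    n, n_ch = work.shape
    t = np.arange(n) / fs
    out = work.copy()
    for c in range(n_ch):
        if white_sd > 0:
            out[:, c] += rng.normal(0.0, white_sd, size=n)
        if pink_sd > 0:
            out[:, c] += pink_sd * _pink_noise(n, rng)
        if cardiac_amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out[:, c] += cardiac_amp * np.sin(2.0 * np.pi * cardiac_hz * t + phase)
    return out[:, 0] if squeeze else out


def synthesize_g2_frames(
    flow_truth: FlowSeries,
    model: DcsOpticalModel | None = None,
    beta: float = 0.5,
    tau: np.ndarray | None = None,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    frame_interval_s: float | None = None,
) -> list[G2Frame]:
    """Forward-model a flow series into (optionally noisy) g2 frames.

    One frame per flow sample by default, or one per ``frame_interval_s``.
    Noise is multiplicative Gaussian on g2 of the stated fraction (a
    simplified shot-noise surrogate). Noiseless frames are exactly
    invertible by the fitting routines.
    """
    model = model or DcsOpticalModel()
    tau = default_tau_grid() if tau is None else np.asarray(tau, dtype=float)
    if np.any(flow_truth.alpha_db <= 0):
        raise ValueError("flow truth must be strictly positive")
    if frame_interval_s is None:
        pick = np.arange(flow_truth.time.size)
    else:
        dt = float(flow_truth.time[1] - flow_truth.time[0])
        step = max(1, int(round(frame_interval_s / dt)))
        pick = np.arange(0, flow_truth.time.size, step)
    if noise_fraction and rng is None:
        raise ValueError("noise_fraction > 0 requires an rng")
    frames = []
    for i in pick:
        g1 = g1_semiinfinite(model, float(flow_truth.alpha_db[i]), tau)
        g2 = 1.0 + beta * g1**2
        if noise_fraction:
            g2 = g2 * (1.0 + rng.normal(0.0, noise_fraction, size=g2.shape))
        frames.append(G2Frame(tau, g2, float(flow_truth.time[i])))
    return frames


@dataclass
class SyntheticDataset:
    """Truth + raw measurables + timeline + regeneration manifest."""

    archetype: str
    protocol: str
    seed: int
    timeline: ProtocolTimeline
    oxy_truth: OxySeries
    flow_truth: FlowSeries
    intensity: IntensitySeries
    frames: list[G2Frame]
    params: dict

    @property
    def manifest(self) -> dict:
        return {
            "format_version": 1,
            "archetype": self.archetype,
            "protocol": self.protocol,
            "seed": self.seed,
            "params": self.params,
        }


def generate_dataset(
    archetype: str,
    protocol: str,
    seed: int,
    n_channels: int = 5,
    fs: float = 10.0,
    frame_interval_s: float = 0.5,
    vbh_hold_s: float = 40.0,
    noise: NoiseSpec | None = None,
    optics: DcsOpticalModel | None = None,
    geometry: MeasurementGeometry | None = None,
    extinctions: ExtinctionTable | None = None,
) -> SyntheticDataset:
    """Generate one archetype x protocol dataset, truth through raw signals.

    Identical arguments (including seed) regenerate the dataset bit for bit.
    """
    spec = archetype_spec(archetype, noise=noise)
    optics = optics or DcsOpticalModel()
    geometry = geometry or MeasurementGeometry()
    extinctions = extinctions or ExtinctionTable()
    if protocol == "VBH":
        timeline = build_timeline(
            "VBH",
            events={"breath_start": 30.0, "breath_end": 30.0 + vbh_hold_s},
        )
    else:
        timeline = build_timeline(protocol)
    ns = spec.noise

    oxy_truth = generate_oxy_truth(spec, timeline, fs)
    flow_truth = generate_flow_truth(spec, timeline, fs)

    rng_oxy = np.random.default_rng([seed % 2**31, 1])
    rng_flow = np.random.default_rng([seed % 2**31, 2])
    rng_g2 = np.random.default_rng([seed % 2**31, 3])

    # per-channel chromophore series = shared cortical truth + channel noise
    tiled_o = np.repeat(oxy_truth.dhbo2, n_channels, axis=1)
    tiled_h = np.repeat(oxy_truth.dhb, n_channels, axis=1)
    noisy_o = add_physiological_noise(
        tiled_o, fs, rng_oxy, ns.oxy_white_sd_um, ns.oxy_pink_sd_um,
        ns.oxy_cardiac_amp_um, ns.cardiac_hz,
    )
    noisy_h = add_physiological_noise(
        tiled_h, fs, rng_oxy, ns.oxy_white_sd_um, ns.oxy_pink_sd_um,
        ns.oxy_cardiac_amp_um, ns.cardiac_hz,
    )
    channels = [f"ch{i + 1:02d}" for i in range(n_channels)]
    oxy_noisy = OxySeries(oxy_truth.time.copy(), noisy_o, noisy_h, channels)
    # channel-dependent source-detector coupling
    base_i = {695.0: 1.0, 830.0: 1.2}
    intensity = forward_mbll(oxy_noisy, extinctions, geometry, base_i)

    rcbf_noisy = add_physiological_noise(
        flow_truth.rcbf, fs, rng_flow, ns.flow_white_sd_pct,
        ns.flow_pink_sd_pct, ns.flow_cardiac_amp_pct, ns.cardiac_hz,
    )
    rcbf_noisy = np.clip(rcbf_noisy, 1.0, None)
    alpha_noisy = spec.baseline_alpha_db * rcbf_noisy / 100.0
    flow_noisy = FlowSeries(flow_truth.time.copy(), alpha_noisy, rcbf_noisy)
    frames = synthesize_g2_frames(
        flow_noisy, optics, spec.beta, noise_fraction=ns.g2_noise_fraction,
        rng=rng_g2, frame_interval_s=frame_interval_s,
    )
    params = {
        "n_channels": n_channels,
        "fs": fs,
        "frame_interval_s": frame_interval_s,
        "vbh_hold_s": vbh_hold_s,
        "noise": asdict(ns),
        "optics": optics.to_dict(),
        "geometry": {
            "sd_distance_cm": geometry.sd_distance_cm, "dpf": geometry.dpf
        },
        "beta": spec.beta,
        "baseline_alpha_db": spec.baseline_alpha_db,
    }
    return SyntheticDataset(
        archetype, protocol, seed, timeline, oxy_truth, flow_truth,
        intensity, frames, params,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> Path:
    """Write all CSV/JSON artifacts + a checksummed manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "intensity.csv": lambda p: ds.intensity.to_csv(p),
        "g2_frames.csv": lambda p: write_g2_frames(ds.frames, p),
        "timeline.json": lambda p: ds.timeline.to_json(p),
        "oxy_truth.csv": lambda p: ds.oxy_truth.to_csv(p),
        "flow_truth.csv": lambda p: ds.flow_truth.to_csv(p),
    }
    written: list[Path] = []
    try:
        for name, writer in files.items():
            path = directory / name
            writer(path)
            written.append(path)
        manifest = dict(ds.manifest)
        manifest["checksums"] = {p.name: _sha256(p) for p in written}
        mpath = directory / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return mpath
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def read_dataset(directory: str | Path, verify: bool = True) -> SyntheticDataset:
    """Read a written dataset back; checksum mismatches raise by default."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if verify:
        for name, digest in manifest["checksums"].items():
            actual = _sha256(directory / name)
            if actual != digest:
                raise ValueError(f"checksum mismatch for {name}: file was modified")
    return SyntheticDataset(
        archetype=manifest["archetype"],
        protocol=manifest["protocol"],
        seed=manifest["seed"],
        timeline=ProtocolTimeline.from_json(directory / "timeline.json"),
        oxy_truth=OxySeries.from_csv(directory / "oxy_truth.csv"),
        flow_truth=FlowSeries.from_csv(directory / "flow_truth.csv"),
        intensity=IntensitySeries.from_csv(directory / "intensity.csv"),
        frames=read_g2_frames(directory / "g2_frames.csv"),
        params=manifest["params"],
    )


def regenerate_from_manifest(manifest: Mapping | str | Path) -> SyntheticDataset:
    """Regenerate a dataset from its manifest alone (bit-identical)."""
    if not isinstance(manifest, Mapping):
        manifest = json.loads(Path(manifest).read_text())
    p = manifest["params"]
    return generate_dataset(
        manifest["archetype"],
        manifest["protocol"],
        manifest["seed"],
        n_channels=p["n_channels"],
        fs=p["fs"],
        frame_interval_s=p["frame_interval_s"],
        vbh_hold_s=p["vbh_hold_s"],
        noise=NoiseSpec(**p["noise"]),
        optics=DcsOpticalModel(**p["optics"]),
        geometry=MeasurementGeometry(**p["geometry"]),
    )
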