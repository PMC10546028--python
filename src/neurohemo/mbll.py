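"""Modified Beer–Lambert law (MBLL) chromophore inversion for dual-wavelength fNIRS.

The MBLL relates the change in optical density at wavelength ``lambda`` to the
change in chromophore concentrations along the mean photon path::

    dOD(lambda, t) = -log10( I(lambda, t) / I0(lambda) )
                   = L * [ eps_HbO2(lambda) * dHbO2(t) + eps_Hb(lambda) * dHb(t) ]

with ``L = sd_distance * DPF`` the effective pathlength (cm), ``eps`` the molar
extinction coefficients (cm^-1 mM^-1, base 10) and concentration changes in mM.
With measurements at two wavelengths the 2x2 linear system is solved exactly per
time sample; results are reported in micromolar.

This module provides the inverse model (raw intensities -> dHbO2/dHb) and the
matching forward model used by the synthetic-data generator, so the two are
exact inverses by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXTINCTIONS",
    "ExtinctionTable",
    "MeasurementGeometry",
    "IntensitySeries",
    "OpticalDensitySeries",
    "OxySeries",
    "compute_delta_od",
    "mbll_invert",
    "forward_mbll",
]

# Molar extinction coefficients of hemoglobin, base-10, cm^-1 mM^-1.
# Interpolated to the working wavelengths from the Prahl/OMLC compilation of
# the Gratzer spectra; overridable via ExtinctionTable.from_json.
DEFAULT_EXTINCTIONS: dict[float, tuple[float, float]] = {
    695.0: (0.283, 1.923),  # (eps_HbO2, eps_Hb)
    830.0: (0.974, 0.693),
}


class SingularExtinctionError(ValueError):
    """Extinction matrix is singular or too ill-conditioned to invert."""


@dataclass(frozen=True)
class ExtinctionTable:
    """Wavelength-indexed molar extinction coefficients for HbO2 and Hb.

    Parameters
    ----------
    entries
        Mapping wavelength (nm) -> ``(eps_HbO2, eps_Hb)`` in cm^-1 mM^-1.
    """

    entries: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTIONS)
    )

    def __post_init__(self) -> None:
        for wl, (e_oxy, e_deoxy) in self.entries.items():
            if e_oxy <= 0 or e_deoxy <= 0:
                raise ValueError(
                    f"extinction coefficients must be positive; got "
                    f"({e_oxy}, {e_deoxy}) at {wl} nm"
                )

    def matrix(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Return the 2x2 matrix [[eHbO2(l1), eHb(l1)], [eHbO2(l2), eHb(l2)]]."""
        if len(wavelengths) != 2:
            raise ValueError("MBLL inversion requires exactly two wavelengths")
        rows = []
        for wl in wavelengths:
            try:
                rows.append(self.entries[float(wl)])
            except KeyError:
                raise KeyError(
                    f"no extinction entry for {wl} nm; table has "
                    f"{sorted(self.entries)}"
                ) from None
        return np.asarray(rows, dtype=float)

    def condition_number(self, wavelengths: Sequence[float]) -> float:
        return float(np.linalg.cond(self.matrix(wavelengths)))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExtinctionTable":
        """Load ``{"695": {"eHbO2": x, "eHb": y}, ...}`` (cm^-1 mM^-1)."""
        raw = json.loads(Path(path).read_text())
        entries = {
            float(wl): (float(v["eHbO2"]), float(v["eHb"])) for wl, v in raw.items()
        }
        return cls(entries)

    def to_json(self, path: str | Path) -> None:
        raw = {
            f"{wl:g}": {"eHbO2": e1, "eHb": e2}
            for wl, (e1, e2) in sorted(self.entries.items())
        }
        Path(path).write_text(json.dumps(raw, indent=1))


@dataclass(frozen=True)
class MeasurementGeometry:
    """Source–detector separation and differential pathlength factor (DPF).

    Defaults are the study configuration: 3.0 cm separation, DPF 5, giving an
    effective pathlength of 15 cm at both wavelengths.
    """

    sd_distance_cm: float = 3.0
    dpf: float = 5.0

    def __post_init__(self) -> None:
        if self.sd_distance_cm <= 0:
            raise ValueError("sd_distance_cm must be positive")
        if self.dpf <= 0:
            raise ValueError("dpf must be positive")

    @property
    def pathlength_cm(self) -> float:
        """Effective mean photon pathlength L = sd_distance * DPF."""
        return self.sd_distance_cm * self.dpf


def _check_uniform_time(time: np.ndarray) -> float:
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid must be 1-D with at least two samples")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise ValueError("time grid must be strictly increasing")
    dt = float(steps[0])
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("time grid must be uniform")
    return dt


@dataclass
class IntensitySeries:
    """Raw dual-wavelength intensities on a uniform time grid.

    ``values`` has shape ``(n_times, n_channels, n_wavelengths)`` in arbitrary
    units; intensities must be strictly positive.
    """

    time: np.ndarray
    values: np.ndarray
    channels: list[str]
    wavelengths: list[float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_uniform_time(self.time)
        expected = (self.time.size, len(self.channels), len(self.wavelengths))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (n_times, n_channels, "
                f"n_wavelengths) = {expected}"
            )
        bad = ~(self.values > 0) | ~np.isfinite(self.values)
        if np.any(bad):
            t_idx, ch_idx, wl_idx = np.argwhere(bad)[0]
            raise ValueError(
                "nonpositive/nonfinite intensity at "
                f"t={self.time[t_idx]:g} s, channel={self.channels[ch_idx]}, "
                f"wavelength={self.wavelengths[wl_idx]:g} nm"
            )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def to_frame(self) -> pd.DataFrame:
        """Long format: time_s, channel, wavelength_nm, intensity."""
        n_t, n_ch, n_wl = self.values.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.time, n_ch * n_wl),
                "channel": np.tile(np.repeat(self.channels, n_wl), n_t),
                "wavelength_nm": np.tile(self.wavelengths, n_t * n_ch),
                "intensity": self.values.reshape(-1),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensitySeries":
        df = pd.read_csv(path)
        required = {"time_s", "channel", "wavelength_nm", "intensity"}
        if missing := required - set(df.columns):
            raise ValueError(f"intensity CSV missing columns {sorted(missing)}")
        time = np.sort(df["time_s"].unique())
        channels = sorted(df["channel"].astype(str).unique())
        wavelengths = sorted(df["wavelength_nm"].unique())
        cube = (
            df.assign(channel=df["channel"].astype(str))
            .pivot_table(
                index="time_s",
                columns=["channel", "wavelength_nm"],
                values="intensity",
                sort=True,
            )
            .to_numpy()
            .reshape(time.size, len(channels), len(wavelengths))
        )
        return cls(time, cube, channels, [float(w) for w in wavelengths])


@dataclass
class OpticalDensitySeries:
    """Per-channel, per-wavelength dOD relative to a reference window."""

    time: np.ndarray
    values: np.ndarray  # (n_times, n_channels, n_wavelengths)
    channels: list[str]
    wavelengths: list[float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("optical density values must be finite")


@dataclass
class OxySeries:
    """Chromophore concentration changes (micromolar) per channel."""

    time: np.ndarray
    dhbo2: np.ndarray  # (n_times, n_channels), uM
    dhb: np.ndarray
    channels: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dhbo2 = np.atleast_2d(np.asarray(self.dhbo2, dtype=float))
        self.dhb = np.atleast_2d(np.asarray(self.dhb, dtype=float))
        if self.dhbo2.shape != self.dhb.shape:
            raise ValueError("dHbO2 and dHb must have identical shapes")
        if self.dhbo2.shape != (self.time.size, len(self.channels)):
            raise ValueError(
                f"oxy arrays shape {self.dhbo2.shape} != "
                f"{(self.time.size, len(self.channels))}"
            )
        if not (np.all(np.isfinite(self.dhbo2)) and np.all(np.isfinite(self.dhb))):
            raise ValueError("oxy series must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def to_frame(self) -> pd.DataFrame:
        n_t, n_ch = self.dhbo2.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.time, n_ch),
                "channel": np.tile(self.channels, n_t),
                "dHbO2_uM": self.dhbo2.reshape(-1),
                "dHb_uM": self.dhb.reshape(-1),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OxySeries":
        df = pd.read_csv(path)
        time = np.sort(df["time_s"].unique())
        channels = sorted(df["channel"].astype(str).unique())
        piv_o = df.pivot_table(index="time_s", columns="channel", values="dHbO2_uM")
        piv_d = df.pivot_table(index="time_s", columns="channel", values="dHb_uM")
        return cls(time, piv_o.to_numpy(), piv_d.to_numpy(), channels)


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"reference window ({t0}, {t1}) is empty")
    mask = (time >= t0) & (time < t1)
    if not mask.any():
        raise ValueError(
            f"reference window ({t0}, {t1}) contains no samples of the series "
            f"[{time[0]:g}, {time[-1]:g}] s"
        )
    return mask


def compute_delta_od(
    series: IntensitySeries, reference_window: tuple[float, float]
) -> OpticalDensitySeries:
    """Optical-density change relative to the window-mean baseline intensity.

    dOD(lambda, t) = -log10( I(lambda, t) / mean_{t in window} I(lambda, t) ),
    computed per channel and wavelength. dOD is exactly zero wherever the
    intensity equals its reference mean.
    """
    mask = _window_mask(series.time, reference_window)
    i0 = series.values[mask].mean(axis=0)  # (n_channels, n_wavelengths)
    od = -np.log10(series.values / i0)
    return OpticalDensitySeries(
        series.time.copy(), od, list(series.channels), list(series.wavelengths)
    )


def mbll_invert(
    od: OpticalDensitySeries,
    ext: ExtinctionTable | None = None,
    geom: MeasurementGeometry | None = None,
    cond_threshold: float = 1e6,
) -> OxySeries:
    """Solve the per-sample 2x2 MBLL system for dHbO2 and dHb (micromolar)."""
    ext = ext or ExtinctionTable()
    geom = geom or MeasurementGeometry()
    e = ext.matrix(od.wavelengths)
    cond = float(np.linalg.cond(e))
    if not np.isfinite(cond) or cond > cond_threshold:
        raise SingularExtinctionError(
            f"extinction matrix for wavelengths {od.wavelengths} nm is "
            f"ill-conditioned (cond={cond:.3g} > {cond_threshold:g})"
        )
    # od values (n_t, n_ch, 2);  c_mM = E^-1 od / L
    inv_le = np.linalg.inv(e) / geom.pathlength_cm
    conc_mm = np.einsum("ij,tcj->tci", inv_le, od.values)
    conc_um = conc_mm * 1e3
    return OxySeries(
        od.time.copy(), conc_um[..., 0], conc_um[..., 1], list(od.channels)
    )


def forward_mbll(
    oxy: OxySeries,
    ext: ExtinctionTable | None = None,
    geom: MeasurementGeometry | None = None,
    baseline_intensity: Mapping[float, float] | Sequence[float] | float = 1.0,
    wavelengths: Sequence[float] = (695.0, 830.0),
) -> IntensitySeries:
    """Forward model: concentration changes -> raw dual-wavelength intensities.

    Exact inverse of ``compute_delta_od`` + ``mbll_invert`` (with a reference
    window in which the oxy series is zero). Used by the synthetic generator.
    """
    ext = ext or ExtinctionTable()
    geom = geom or MeasurementGeometry()
    wavelengths = [float(w) for w in wavelengths]
    e = ext.matrix(wavelengths)
    if isinstance(baseline_intensity, Mapping):
        i0 = np.array([float(baseline_intensity[w]) for w in wavelengths])
    else:
        i0 = np.broadcast_to(
            np.asarray(baseline_intensity, dtype=float), (len(wavelengths),)
        ).copy()
    if np.any(i0 <= 0):
        raise ValueError("baseline intensities must be positive")
    conc_mm = np.stack([oxy.dhbo2, oxy.dhb], axis=-1) * 1e-3  # (n_t, n_ch, 2)
    od = geom.pathlength_cm * np.einsum("ij,tcj->tci", e, conc_mm)
    values = i0[None, None, :] * 10.0 ** (-od)
    return IntensitySeries(oxy.time.copy(), values, list(oxy.channels), wavelengths)
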