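"""Hartley stimulus construction and its mapping to the Fourier plane.

The stimulus is a rapid sequence of flashed gratings drawn from the Hartley
basis ``H_{kx,ky}(x, y) = cas(2*pi*(kx*x + ky*y)/n)`` with ``cas(z) = cos(z)
+ sin(z)``.  Each integer index pair ``(kx, ky)`` corresponds to one
orientation / spatial-frequency / spatial-phase combination on the screen;
``(kx, ky)`` and ``(-kx, -ky)`` share orientation and spatial frequency and
differ only in phase, which is why tuning kernels are estimated on a
phase-pooled ("folded") half-plane grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "HartleyCondition",
    "FourierGrid",
    "StimulusSequence",
    "DesignTensor",
    "visual_angle",
    "hartley_image",
    "condition_to_fourier",
    "generate_sequence",
    "build_design",
]


def visual_angle(extent_cm: float, distance_cm: float, truncate: bool = False) -> float:
    """Full visual angle (degrees) subtended by a flat extent at a distance.

    Uses ``2 * arctan(extent / (2 * distance))``.  With ``truncate=True`` the
    angle is truncated to whole degrees, the convention used when quoting
    screen sizes (a 60 cm screen at 20 cm subtends 112 deg).
    """
    if distance_cm <= 0:
        raise ValueError(f"distance_cm must be positive, got {distance_cm}")
    if extent_cm < 0:
        raise ValueError(f"extent_cm must be non-negative, got {extent_cm}")
    deg = math.degrees(2.0 * math.atan2(extent_cm, 2.0 * distance_cm))
    return float(math.trunc(deg)) if truncate else deg


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical stimulus screen and viewing distance.

    Defaults are a 60 x 34 cm monitor viewed at 20 cm, subtending roughly
    112 x 80 degrees of visual angle.
    """

    width_cm: float = 60.0
    height_cm: float = 34.0
    distance_cm: float = 20.0

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def width_deg(self) -> float:
        return visual_angle(self.width_cm, self.distance_cm)

    @property
    def height_deg(self) -> float:
        return visual_angle(self.height_cm, self.distance_cm)


def _orientation_sf(kx: int, ky: int, screen: ScreenGeometry) -> tuple[float, float]:
    """(orientation deg in [0, 180), spatial frequency cpd) of one condition.

    The spatial-frequency vector in cycles/deg is ``(kx / width_deg,
    ky / height_deg)``.  Grating orientation is perpendicular to that wave
    vector, reduced mod 180, with 0 deg = horizontal grating.
    """
    fx = kx / screen.width_deg
    fy = ky / screen.height_deg
    sf = math.hypot(fx, fy)
    if kx == 0 and ky == 0:
        return float("nan"), 0.0
    ori = (math.degrees(math.atan2(fy, fx)) + 90.0) % 180.0
    return ori, sf


@dataclass(frozen=True)
class HartleyCondition:
    """One Hartley basis function, with its derived tuning coordinates."""

    kx: int
    ky: int
    orientation_deg: float
    sf_cpd: float

    @property
    def is_dc(self) -> bool:
        return self.kx == 0 and self.ky == 0

    @classmethod
    def from_indices(cls, kx: int, ky: int, screen: ScreenGeometry) -> "HartleyCondition":
        ori, sf = _orientation_sf(kx, ky, screen)
        return cls(kx=int(kx), ky=int(ky), orientation_deg=ori, sf_cpd=sf)


def condition_to_fourier(cond: HartleyCondition, screen: ScreenGeometry) -> tuple[float, float]:
    """Map a condition to (orientation_deg, sf_cpd); DC maps to (nan, 0)."""
    return _orientation_sf(cond.kx, cond.ky, screen)


def hartley_image(kx: int, ky: int, n_pixels: int) -> np.ndarray:
    """The n x n Hartley basis image cas(2*pi*(kx*x + ky*y)/n).

    Values lie in [-sqrt(2), sqrt(2)]; distinct indices on the n x n torus
    give mutually orthogonal images.
    """
    if n_pixels < 2:
        raise ValueError("n_pixels must be >= 2")
    if abs(kx) >= n_pixels / 2 or abs(ky) >= n_pixels / 2:
        raise ValueError(f"indices ({kx}, {ky}) beyond Nyquist for n={n_pixels}")
    x = np.arange(n_pixels)
    phase = 2.0 * np.pi * (kx * x[None, :] + ky * x[:, None]) / n_pixels
    return np.cos(phase) + np.sin(phase)


class FourierGrid:
    """The lattice of (kx, ky) stimulus indices used as the tuning grid.

    DC is excluded.  When folded, (kx, ky) and (-kx, -ky) share one cell
    (spatial-phase pooling); the representative has ky > 0, or ky == 0 and
    kx > 0.
    """

    def __init__(self, screen: ScreenGeometry, sf_max_cpd: float = 0.15, folded: bool = True):
        if sf_max_cpd <= 0:
            raise ValueError("sf_max_cpd must be positive")
        self.screen = screen
        self.sf_max_cpd = float(sf_max_cpd)
        self.folded = bool(folded)

        kx_max = int(math.floor(sf_max_cpd * screen.width_deg))
        ky_max = int(math.floor(sf_max_cpd * screen.height_deg))
        kxs, kys, oris, sfs = [], [], [], []
        for ky in range(-ky_max, ky_max + 1):
            for kx in range(-kx_max, kx_max + 1):
                if kx == 0 and ky == 0:
                    continue
                ori, sf = _orientation_sf(kx, ky, screen)
                if sf > sf_max_cpd:
                    continue
                if folded and (ky < 0 or (ky == 0 and kx < 0)):
                    continue
                kxs.append(kx)
                kys.append(ky)
                oris.append(ori)
                sfs.append(sf)
        self.kx = np.asarray(kxs, dtype=np.int64)
        self.ky = np.asarray(kys, dtype=np.int64)
        self.orientation_deg = np.asarray(oris)
        self.sf_cpd = np.asarray(sfs)
        self._index = {(int(a), int(b)): i for i, (a, b) in enumerate(zip(self.kx, self.ky))}

    @property
    def n_cells(self) -> int:
        return len(self.kx)

    def __len__(self) -> int:
        return self.n_cells

    def index_of(self, kx: int, ky: int) -> int:
        """Grid-cell index of (kx, ky); folds onto the representative."""
        key = (int(kx), int(ky))
        if key in self._index:
            return self._index[key]
        if self.folded:
            key = (-int(kx), -int(ky))
            if key in self._index:
                return self._index[key]
        raise KeyError(f"({kx}, {ky}) not on the grid")

    def contains(self, kx: int, ky: int) -> bool:
        try:
            self.index_of(kx, ky)
            return True
        except KeyError:
            return False

    def unfold(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetrize a folded kernel to the full plane for display.

        Returns (kx, ky, values) covering both (kx, ky) and (-kx, -ky).
        """
        if not self.folded:
            return self.kx, self.ky, np.asarray(w)
        kx = np.concatenate([self.kx, -self.kx])
        ky = np.concatenate([self.ky, -self.ky])
        vals = np.concatenate([w, w])
        return kx, ky, vals


@dataclass
class StimulusSequence:
    """An ordered Hartley sequence with onsets on the stimulus clock."""

    kx: np.ndarray
    ky: np.ndarray
    onset_times_s: np.ndarray
    update_rate_hz: float
    screen: ScreenGeometry
    sf_max_cpd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.kx = np.asarray(self.kx, dtype=np.int64)
        self.ky = np.asarray(self.ky, dtype=np.int64)
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        if len(self.kx) != len(self.ky) or len(self.kx) != len(self.onset_times_s):
            raise ValueError("kx, ky and onset_times_s must have equal length")
        if len(self.onset_times_s) > 1 and not np.all(np.diff(self.onset_times_s) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kx)

    @property
    def conditions(self) -> list[HartleyCondition]:
        return [HartleyCondition.from_indices(a, b, self.screen) for a, b in zip(self.kx, self.ky)]

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.onset_times_s[-1] + 1.0 / self.update_rate_hz)

    def to_frame(self) -> pd.DataFrame:
        ori_sf = np.array([_orientation_sf(a, b, self.screen) for a, b in zip(self.kx, self.ky)])
        return pd.DataFrame(
            {
                "onset_s": self.onset_times_s,
                "kx": self.kx,
                "ky": self.ky,
                "orientation_deg": ori_sf[:, 0] if len(self) else [],
                "sf_cpd": ori_sf[:, 1] if len(self) else [],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, screen: ScreenGeometry, update_rate_hz: float = 4.0,
                 sf_max_cpd: float = 0.15) -> "StimulusSequence":
        df = pd.read_csv(path)
        return cls(
            kx=df["kx"].to_numpy(),
            ky=df["ky"].to_numpy(),
            onset_times_s=df["onset_s"].to_numpy(),
            update_rate_hz=update_rate_hz,
            screen=screen,
            sf_max_cpd=sf_max_cpd,
        )


def generate_sequence(
    duration_s: float,
    update_rate_hz: float = 4.0,
    sf_max_cpd: float = 0.15,
    screen: ScreenGeometry | None = None,
    seed: int | None = None,
) -> StimulusSequence:
    """Draw a uniform i.i.d. Hartley sequence below the spatial-frequency cap.

    Conditions are drawn from the full (unfolded) index set with DC excluded,
    so symmetric index pairs appear as distinct spatial phases, as on the
    screen.  A 20-min sequence at 4 Hz holds 4,800 conditions.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    screen = screen or ScreenGeometry()
    grid = FourierGrid(screen, sf_max_cpd=sf_max_cpd, folded=False)
    if grid.n_cells == 0:
        raise ValueError("no Hartley conditions satisfy the spatial-frequency cap")
    n = int(round(duration_s * update_rate_hz))
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, grid.n_cells, size=n)
    onsets = np.arange(n) / update_rate_hz
    return StimulusSequence(
        kx=grid.kx[draw],
        ky=grid.ky[draw],
        onset_times_s=onsets,
        update_rate_hz=update_rate_hz,
        screen=screen,
        sf_max_cpd=sf_max_cpd,
        seed=seed,
    )


@dataclass
class DesignTensor:
    """The stimulus realized on the imaging clock.

    ``frame_condition[t]`` is the folded grid-cell index of the condition on
    screen during imaging frame ``t`` (-1 if none, i.e. before the first
    onset or after the last offset).  The one-hot regressor s(wx, wy, t - tau)
    is materialized lazily by :meth:`indicator` for small problems; the
    fitting code consumes ``frame_condition`` directly.
    """

    frame_condition: np.ndarray
    grid: FourierGrid
    n_lags: int
    imaging_rate_hz: float
    frame_times_s: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return len(self.frame_condition)

    def lagged_condition(self, lag: int) -> np.ndarray:
        """Condition index seen ``lag`` frames before each frame (-1 pad)."""
        c = self.frame_condition
        if lag == 0:
            return c
        out = np.full_like(c, -1)
        out[lag:] = c[:-lag]
        return out

    def indicator(self) -> np.ndarray:
        """Dense (n_frames, n_lags, n_cells) one-hot tensor (small use only)."""
        T, L, G = self.n_frames, self.n_lags, self.grid.n_cells
        out = np.zeros((T, L, G))
        for lag in range(L):
            c = self.lagged_condition(lag)
            valid = c >= 0
            out[np.nonzero(valid)[0], lag, c[valid]] = 1.0
        return out


def build_design(
    seq: StimulusSequence,
    imaging_rate_hz: float = 15.5,
    n_lags: int = 8,
    fold_symmetry: bool = True,
    n_frames: int | None = None,
) -> DesignTensor:
    """Assign each imaging frame the Hartley condition on screen at its time."""
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if len(seq) == 0:
        raise ValueError("empty stimulus sequence")
    onsets = seq.onset_times_s
    if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
        raise ValueError("overlapping or non-increasing stimulus onsets")
    if n_frames is None:
        n_frames = int(math.ceil(seq.duration_s * imaging_rate_hz))
    t = np.arange(n_frames) / imaging_rate_hz
    grid = FourierGrid(seq.screen, sf_max_cpd=seq.sf_max_cpd, folded=fold_symmetry)
    # index of the last onset at or before each frame time
    idx = np.searchsorted(onsets, t, side="right") - 1
    frame_condition = np.full(n_frames, -1, dtype=np.int64)
    dt = 1.0 / seq.update_rate_hz
    safe = idx.clip(min=0)
    on_screen = (idx >= 0) & (t < onsets[safe] + dt)
    which = np.nonzero(on_screen)[0]
    cond_cell = np.array(
        [grid.index_of(a, b) for a, b in zip(seq.kx, seq.ky)], dtype=np.int64
    )
    frame_condition[which] = cond_cell[idx[which]]
    return DesignTensor(
        frame_condition=frame_condition,
        grid=grid,
        n_lags=n_lags,
        imaging_rate_hz=imaging_rate_hz,
        frame_times_s=t,
    )
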