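"""Gel-lane densitometry: lane profiles, baseline removal, band quantification.

Mirrors the manual gel-analysis workflow: draw a rectangle around a lane,
collapse it to a 1-D intensity profile along the migration axis, mark the
band boundaries, and report each band's share of the total integrated
signal.  Band windows can also be placed automatically from detected peaks.

Conventions: pixel positions are 0-based; windows are half-open
``[start, stop)``; migration runs along image rows.  For this assay the
supercoiled topology migrates fastest (furthest), relaxed slowest and
linear in between — the window labelling order is configurable because gel
orientation varies between imagers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "LaneProfile",
    "BandWindows",
    "BandPercentages",
    "lane_profile_from_image",
    "read_image",
    "subtract_baseline",
    "quantify_bands",
    "auto_detect_windows",
    "DEFAULT_MIGRATION_ORDER",
]

_SPECIES = ("supercoiled", "relaxed", "linear")

#: species from slowest to fastest migration (increasing position):
#: relaxed trails, linear is intermediate, supercoiled runs furthest
DEFAULT_MIGRATION_ORDER = ("relaxed", "linear", "supercoiled")


@dataclass(frozen=True)
class LaneProfile:
    """1-D intensity profile of one gel lane along the migration axis."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1-D arrays")
        if len(self.positions) < 2:
            raise ValueError("profile needs at least 2 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"position": self.positions, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LaneProfile":
        df = pd.read_csv(path)
        if list(df.columns) != ["position", "intensity"]:
            raise ValueError(
                f"profile CSV must have columns ['position', 'intensity'], got {list(df.columns)}"
            )
        return cls(df["position"].to_numpy(), df["intensity"].to_numpy())


@dataclass(frozen=True)
class BandWindows:
    """Half-open position windows for the three topology bands."""

    supercoiled: tuple[float, float]
    relaxed: tuple[float, float]
    linear: tuple[float, float]

    def __post_init__(self) -> None:
        ivs = [(name, getattr(self, name)) for name in _SPECIES]
        for name, (a, b) in ivs:
            if not b > a:
                raise ValueError(f"{name} window [{a}, {b}) is empty or inverted")
        ivs.sort(key=lambda kv: kv[1][0])
        for (n1, (_, b1)), (n2, (a2, _)) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError(f"windows {n1} and {n2} overlap")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in _SPECIES}


@dataclass(frozen=True)
class BandPercentages:
    """Band shares of total integrated signal; sums to 100 by construction."""

    supercoiled: float
    relaxed: float
    linear: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _SPECIES}

    def as_array(self) -> np.ndarray:
        return np.array([self.supercoiled, self.relaxed, self.linear])


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale gel image (TIFF/PNG) as a 2-D float array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        if img.shape[2] in (3, 4):  # collapse RGB(A) shot of a mono gel
            img = img[..., :3].mean(axis=2)
        else:
            raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    return img


def lane_profile_from_image(
    image: np.ndarray,
    lane_rect: tuple[int, int, int, int],
    *,
    invert: bool = False,
) -> LaneProfile:
    """Collapse a lane rectangle to a migration-axis profile.

    Parameters
    ----------
    image
        2-D grayscale array, rows = migration axis.
    lane_rect
        ``(row_start, row_stop, col_start, col_stop)``, half-open.
    invert
        Set for dark-bands-on-light images (the profile must have bands as
        positive excursions).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a single-channel 2-D array")
    r0, r1, c0, c1 = lane_rect
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError(
            f"lane rectangle {lane_rect} out of bounds or zero-area for image "
            f"shape {image.shape}"
        )
    block = image[r0:r1, c0:c1]
    if invert:
        block = block.max() - block
    profile = block.sum(axis=1)
    return LaneProfile(np.arange(r0, r1, dtype=float), profile)


def subtract_baseline(
    profile: LaneProfile,
    method: str = "rolling_minimum",
    *,
    window: int | None = None,
) -> LaneProfile:
    """Remove the background baseline from a lane profile.

    ``linear_endpoints`` subtracts the straight line through the first and
    last samples.  ``rolling_minimum`` subtracts a morphological opening
    (rolling minimum followed by rolling maximum over the same window),
    which tracks slowly varying backgrounds exactly while ignoring bands
    narrower than the window; choose ``window`` about 3x the widest expected
    band.  The opening is computed on a lightly smoothed copy of the profile
    (boxcar of window/8 samples) so the baseline follows the mean background
    rather than the lower noise envelope.  Output intensities are clipped at
    zero.
    """
    y = profile.intensities
    if method == "linear_endpoints":
        x = profile.positions
        baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    elif method == "rolling_minimum":
        if window is None:
            raise ValueError("rolling_minimum needs an explicit window (samples)")
        if window < 1 or window > len(y):
            raise ValueError(
                f"window must be in [1, {len(y)}] samples, got {window}"
            )
        smoothed = ndimage.uniform_filter1d(y, size=max(window // 8, 1), mode="nearest")
        baseline = ndimage.maximum_filter1d(
            ndimage.minimum_filter1d(smoothed, size=window, mode="nearest"),
            size=window,
            mode="nearest",
        )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return LaneProfile(profile.positions, np.clip(y - baseline, 0.0, None))


def quantify_bands(profile: LaneProfile, windows: BandWindows) -> BandPercentages:
    """Integrate each band window and express it as a share of the total.

    The profile should be baseline-corrected.  Raises on zero total signal
    rather than returning NaN percentages; warns when more than 10% of the
    profile's signal lies outside all three windows (e.g. high-damage
    linear-fragment smears truncated at the window edges).
    """
    integrals = {}
    covered = np.zeros_like(profile.intensities, dtype=bool)
    for name, (a, b) in windows.as_dict().items():
        mask = (profile.positions >= a) & (profile.positions < b)
        integrals[name] = float(profile.intensities[mask].sum())
        covered |= mask
    total = sum(integrals.values())
    if total <= 0.0:
        raise ValueError("zero total band signal in the given windows")
    outside = float(profile.intensities[~covered].sum())
    if outside > 0.10 * (total + outside):
        warnings.warn(
            f"{100 * outside / (total + outside):.1f}% of profile signal lies "
            "outside all band windows; check window placement or smearing",
            stacklevel=2,
        )
    return BandPercentages(
        **{name: 100.0 * v / total for name, v in integrals.items()}
    )


def auto_detect_windows(
    profile: LaneProfile,
    *,
    n_bands: int = 3,
    order: tuple[str, str, str] = DEFAULT_MIGRATION_ORDER,
    min_prominence: float = 0.05,
) -> BandWindows:
    """Place band windows automatically from detected profile peaks.

    Peaks are found on the (baseline-corrected) profile with a prominence
    threshold relative to the profile maximum; the ``n_bands`` most
    prominent peaks are kept and windows are split at the intensity minima
    between adjacent peaks.  Labels follow ``order`` along increasing
    position (default: relaxed slowest, then linear, supercoiled fastest).
    Deterministic for a fixed profile.
    """
    if sorted(order) != sorted(_SPECIES):
        raise ValueError(f"order must be a permutation of {_SPECIES}")
    y = profile.intensities
    if y.max() <= 0:
        raise ValueError("flat profile: no bands to detect")
    peaks, props = signal.find_peaks(y, prominence=min_prominence * y.max())
    if len(peaks) < n_bands:
        raise ValueError(
            f"detected {len(peaks)} peaks but expected {n_bands}; "
            "draw the band windows manually"
        )
    keep = peaks[np.argsort(props["prominences"])[::-1][:n_bands]]
    keep.sort()
    pos = profile.positions
    step = float(np.median(np.diff(pos)))
    edges = [pos[0]]
    for a, b in zip(keep, keep[1:]):
        valley = a + int(np.argmin(y[a : b + 1]))
        edges.append(float(pos[valley]))
    edges.append(float(pos[-1]) + step)  # include the last sample (half-open)
    intervals = {order[i]: (edges[i], edges[i + 1]) for i in range(n_bands)}
    return BandWindows(**intervals)
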