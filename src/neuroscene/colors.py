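"""Scalar-data to RGBA color mapping.

Every drawable that colors itself from data (projected source activity,
connectivity strength, activation overlays, colorbars) goes through one
rule, held in a :class:`ColorSpec`: a colormap given as anchor colors
interpolated linearly in RGB, data limits ``clim = (lo, hi)``, optional
lower/upper thresholds ``vmin``/``vmax`` with dedicated ``under``/``over``
colors, a global ``alpha`` and a ``bad`` color for non-finite values.

Thresholds are exclusive: a value equal to ``vmin`` or ``vmax`` still gets
the colormap; only values strictly beyond a threshold receive the
``under``/``over`` color.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ColorSpec", "map_colors", "colorbar_image", "named_colormap"]

RGBA = tuple[float, float, float, float]

# Anchor tables for the built-in colormaps. "viridis" is a 9-anchor
# piecewise-linear approximation of the familiar perceptually-uniform map;
# exact table fidelity is not a goal here, monotone lightness is.
_NAMED_CMAPS: dict[str, list[RGBA]] = {
    "gray": [(0.0, 0.0, 0.0, 1.0), (1.0, 1.0, 1.0, 1.0)],
    "hot": [
        (0.0, 0.0, 0.0, 1.0),
        (1.0, 0.0, 0.0, 1.0),
        (1.0, 1.0, 0.0, 1.0),
        (1.0, 1.0, 1.0, 1.0),
    ],
    "viridis": [
        (0.267, 0.005, 0.329, 1.0),
        (0.283, 0.141, 0.458, 1.0),
        (0.254, 0.265, 0.530, 1.0),
        (0.207, 0.372, 0.553, 1.0),
        (0.164, 0.471, 0.558, 1.0),
        (0.128, 0.567, 0.551, 1.0),
        (0.135, 0.659, 0.518, 1.0),
        (0.267, 0.749, 0.441, 1.0),
        (0.478, 0.821, 0.318, 1.0),
        (0.741, 0.873, 0.150, 1.0),
        (0.993, 0.906, 0.144, 1.0),
    ],
    "coolwarm": [
        (0.230, 0.299, 0.754, 1.0),
        (0.865, 0.865, 0.865, 1.0),
        (0.706, 0.016, 0.150, 1.0),
    ],
}


def named_colormap(name: str) -> list[RGBA]:
    """Return the anchor list of a built-in colormap.

    Parameters
    ----------
    name : str
        One of ``gray``, ``hot``, ``viridis``, ``coolwarm``.
    """
    try:
        return list(_NAMED_CMAPS[name])
    except KeyError:
        known = ", ".join(sorted(_NAMED_CMAPS))
        raise KeyError(f"unknown colormap {name!r}; known: {known}") from None


def _as_rgba(c: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape == (3,):
        arr = np.append(arr, 1.0)
    if arr.shape != (4,):
        raise ValueError(f"{what} must be RGB or RGBA, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{what} channels must lie in [0, 1], got {arr!r}")
    return arr


@dataclass
class ColorSpec:
    """Full description of a data-to-color conversion.

    Parameters
    ----------
    cmap : str or sequence of RGBA
        Either the name of a built-in colormap or an ordered list of
        anchor colors, interpolated linearly in RGB.
    clim : (float, float)
        Data values mapped to the first and last anchor; ``lo < hi``.
    vmin, vmax : float, optional
        Exclusive lower/upper thresholds. Values strictly below ``vmin``
        get ``under``; strictly above ``vmax`` get ``over``.
    under, over : RGBA
        Colors for thresholded values.
    alpha : float
        Global opacity in [0, 1], multiplied into the alpha channel.
    bad : RGBA
        Color for non-finite input values (default fully transparent).
    """

    cmap: str | Sequence[Sequence[float]] = "viridis"
    clim: tuple[float, float] = (0.0, 1.0)
    vmin: float | None = None
    vmax: float | None = None
    under: Sequence[float] = (0.0, 0.0, 0.0, 1.0)
    over: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
    alpha: float = 1.0
    bad: Sequence[float] = (0.0, 0.0, 0.0, 0.0)

    _anchors: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        anchors = named_colormap(self.cmap) if isinstance(self.cmap, str) else self.cmap
        arr = np.array([_as_rgba(a, "cmap anchor") for a in anchors], dtype=float)
        if len(arr) < 2:
            raise ValueError("cmap needs at least 2 anchor colors")
        self._anchors = arr

        lo, hi = map(float, self.clim)
        if not lo < hi:
            raise ValueError(f"clim requires lo < hi, got ({lo}, {hi})")
        self.clim = (lo, hi)
        if self.vmin is not None and self.vmax is not None:
            if not (lo <= self.vmin <= self.vmax <= hi):
                raise ValueError(
                    f"need lo <= vmin <= vmax <= hi, got lo={lo} vmin={self.vmin} "
                    f"vmax={self.vmax} hi={hi}"
                )
        else:
            for name in ("vmin", "vmax"):
                v = getattr(self, name)
                if v is not None and not lo <= v <= hi:
                    raise ValueError(f"{name}={v} outside clim ({lo}, {hi})")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        self.under = tuple(_as_rgba(self.under, "under"))
        self.over = tuple(_as_rgba(self.over, "over"))
        self.bad = tuple(_as_rgba(self.bad, "bad"))

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Linear-RGB interpolation of the anchors at positions ``t`` in [0, 1]."""
        t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
        xp = np.linspace(0.0, 1.0, len(self._anchors))
        out = np.empty(t.shape + (4,))
        for ch in range(4):
            out[..., ch] = np.interp(t, xp, self._anchors[:, ch])
        return out


def map_colors(values: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Convert a scalar vector to an ``(n, 4)`` RGBA matrix.

    Finite values are normalized by ``clim`` (clamped to [0, 1]) and
    interpolated through the colormap anchors; values strictly beyond
    ``vmin``/``vmax`` receive the ``under``/``over`` color; non-finite
    values receive ``bad``. ``spec.alpha`` scales the alpha channel of
    every output color.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = spec.clim
    finite = np.isfinite(values)

    t = np.zeros_like(values)
    t[finite] = np.clip((values[finite] - lo) / (hi - lo), 0.0, 1.0)
    out = spec.interpolate(t)

    if spec.vmin is not None:
        out[finite & (values < spec.vmin)] = spec.under
    if spec.vmax is not None:
        out[finite & (values > spec.vmax)] = spec.over
    out[~finite] = spec.bad
    out[:, 3] *= spec.alpha
    return out


def colorbar_image(
    spec: ColorSpec, length: int = 256, orientation: str = "vertical"
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a colorbar strip plus its end-tick data values.

    Pixel ``k`` of the strip shows ``map_colors`` of
    ``lo + k/(length-1) * (hi-lo)``. Vertical strips run bottom-to-top:
    row 0 (top) is ``hi``, the last row is ``lo``. Returns the strip as a
    ``(length, 1, 4)`` (vertical) or ``(1, length, 4)`` (horizontal) RGBA
    array and the tick values ``(lo, hi)``.
    """
    if length < 2:
        raise ValueError(f"colorbar length must be >= 2, got {length}")
    if orientation not in ("vertical", "horizontal"):
        raise ValueError(f"orientation must be vertical|horizontal, got {orientation!r}")
    lo, hi = spec.clim
    ramp = np.linspace(lo, hi, length)
    colors = map_colors(ramp, spec)
    if orientation == "vertical":
        strip = colors[::-1][:, np.newaxis, :]
    else:
        strip = colors[np.newaxis, :, :]
    return strip, (lo, hi)
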