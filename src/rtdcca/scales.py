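"""Analysis-scale configuration.

Detrended fluctuation / cross-correlation analysis evaluates a fluctuation
function at a set of window sizes (scales) ``s``.  Because the power law
``F(s) ~ s**alpha`` is fitted after a log-log transformation, scales are
spaced logarithmically; the conventional dialect is dyadic (powers of two),
typically from ``2**3`` up to ``N/4`` or ``N/5``.

The streaming engines additionally need an *analysis window* ``W``: the span
of recent samples an estimate summarizes.  ``W`` must be a whole number of
``s_max``-sized blocks, and every scale must divide ``s_max``, so that window
boundaries at all scales align with block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScaleSet", "dyadic_scales", "preset_for_length", "LENGTH_PRESETS"]


def dyadic_scales(s_min: int, s_max: int) -> tuple[int, ...]:
    """All powers of two from ``s_min`` to ``s_max`` inclusive."""
    if s_min < 2 or s_max < s_min:
        raise ValueError(f"need 2 <= s_min <= s_max, got ({s_min}, {s_max})")
    for s in (s_min, s_max):
        if s & (s - 1):
            raise ValueError(f"scale bound {s} is not a power of 2")
    return tuple(s_min << k for k in range((s_max // s_min).bit_length()))


# Per-length scale settings used throughout the runtime/precision experiments:
# N -> (s_min, s_max, number of scales).
LENGTH_PRESETS: dict[int, tuple[int, int, int]] = {
    2**8: (2**2, 2**6, 5),
    2**9: (2**2, 2**7, 6),
    2**10: (2**2, 2**8, 7),
    2**11: (2**3, 2**9, 7),
    2**12: (2**3, 2**10, 8),
    2**13: (2**3, 2**10, 8),
    2**14: (2**4, 2**11, 8),
    2**15: (2**4, 2**11, 8),
    2**16: (2**4, 2**12, 9),
    2**17: (2**4, 2**12, 9),
}


@dataclass(frozen=True)
class ScaleSet:
    """A strictly increasing set of analysis scales plus the window ``W``.

    Parameters
    ----------
    scales
        Window sizes in samples, strictly increasing.  In the default
        (dyadic) dialect each scale is a power of two, ``s_min >= 4``, and
        every scale divides ``s_max``.
    W
        Analysis-window length in samples for the streaming engines.  Must
        be a positive multiple of ``s_max``.  ``None`` for purely offline
        use, where the signal length plays that role.
    dyadic
        If ``True`` (default) enforce the power-of-two dialect.
    """

    scales: tuple[int, ...]
    W: int | None = None
    dyadic: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        scales = tuple(int(s) for s in self.scales)
        object.__setattr__(self, "scales", scales)
        if not scales:
            raise ValueError("ScaleSet needs at least one scale")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError(f"scales must be strictly increasing: {scales}")
        if scales[0] < 4:
            raise ValueError(f"s_min must be >= 4, got {scales[0]}")
        if self.dyadic and any(s & (s - 1) for s in scales):
            raise ValueError(f"non power-of-2 scale in dyadic dialect: {scales}")
        s_max = scales[-1]
        if any(s_max % s for s in scales):
            raise ValueError(f"every scale must divide s_max={s_max}: {scales}")
        if self.W is not None:
            W = int(self.W)
            object.__setattr__(self, "W", W)
            if W < s_max:
                raise ValueError(f"W={W} smaller than s_max={s_max}")
            if W % s_max:
                raise ValueError(f"W={W} is not a multiple of s_max={s_max}")

    # -- convenience -----------------------------------------------------
    @property
    def s_min(self) -> int:
        return self.scales[0]

    @property
    def s_max(self) -> int:
        return self.scales[-1]

    @property
    def n_s(self) -> int:
        return len(self.scales)

    @property
    def n_blocks(self) -> int:
        """Number of s_max-sized blocks spanned by the analysis window."""
        if self.W is None:
            raise ValueError("ScaleSet has no analysis window W")
        return self.W // self.s_max

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scales, dtype=np.int64)

    def with_window(self, W: int) -> "ScaleSet":
        return ScaleSet(self.scales, W=W, dyadic=self.dyadic)

    @classmethod
    def from_bounds(cls, s_min: int, s_max: int, W: int | None = None) -> "ScaleSet":
        return cls(dyadic_scales(s_min, s_max), W=W)


def preset_for_length(N: int, W: int | None = None) -> ScaleSet:
    """The standard scale setting for a signal of dyadic length ``N``.

    ``W`` defaults to ``N`` itself (the whole-signal analysis window used in
    the precision experiments).
    """
    try:
        s_min, s_max, _ = LENGTH_PRESETS[N]
    except KeyError:
        raise ValueError(
            f"no preset for N={N}; presets cover dyadic lengths 2^8..2^17"
        ) from None
    return ScaleSet.from_bounds(s_min, s_max, W=N if W is None else W)


#: Settings used for the multichannel EEG demonstration: 2-second analysis
#: window at 256 Hz with scales 8..128.
EEG_PRESET = ScaleSet.from_bounds(2**3, 2**7, W=512)
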