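"""R2* mapping from a dual-echo UTE pair.

R2*(x) = (ln I1(x) - ln I2(x)) / (TE2 - TE1), in 1/ms for echo times in ms.
Intensities are floored before the logarithm and negative rates (noise can
make I2 exceed I1) are clamped to zero. The natural logarithm is used; any
other base would simply rescale the bone calibration polynomial, which is
fitted downstream anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume


@dataclass
class EchoPair:
    echo1: Volume
    echo2: Volume
    te1_ms: float
    te2_ms: float

    def __post_init__(self) -> None:
        if not self.echo1.same_grid(self.echo2):
            raise ValueError("echoes are not on one grid")
        if not (self.te2_ms > self.te1_ms > 0):
            raise ValueError("echo times must satisfy te2 > te1 > 0")


def compute_r2star(pair: EchoPair, intensity_floor: float | None = None) -> Volume:
    """R2* volume (1/ms) from the two echoes.

    ``intensity_floor`` defaults to 1e-6 times the global maximum intensity.
    """
    i1 = np.asarray(pair.echo1.data, dtype=np.float64)
    i2 = np.asarray(pair.echo2.data, dtype=np.float64)
    if intensity_floor is None:
        peak = max(float(np.max(i1)), float(np.max(i2)), 0.0)
        intensity_floor = 1e-6 * peak if peak > 0 else 1e-12
    if intensity_floor <= 0:
        raise ValueError("intensity_floor must be positive")
    dte = pair.te2_ms - pair.te1_ms
    r2s = (np.log(np.maximum(i1, intensity_floor))
           - np.log(np.maximum(i2, intensity_floor))) / dte
    return pair.echo1.with_data(np.maximum(r2s, 0.0), units="r2star_per_ms")
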