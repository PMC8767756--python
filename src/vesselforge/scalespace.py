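"""The Z-profile operator.

A filter applied over a set of observation scales yields, at every pixel, a
vector of responses indexed by scale.  The Z-profile condenses that vector
into four per-pixel summary statistics — maximum, mean, population variance,
and interquartile range — so downstream classifiers see a fixed-width
description of how the response evolves across scales.

Conventions fixed here for reproducibility: the variance divides by the
number of scales S (population variance), and quartiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ZProfile:
    """Per-pixel scale-space summary of one filter's responses."""

    z_max: np.ndarray
    z_mean: np.ndarray
    z_var: np.ndarray
    z_interq: np.ndarray
    source_filter: str = ""

    def maps(self) -> list[tuple[str, np.ndarray]]:
        """The four maps in canonical order, with dotted names."""
        f = self.source_filter or "filter"
        return [
            (f + ".z_max", self.z_max),
            (f + ".z_mean", self.z_mean),
            (f + ".z_var", self.z_var),
            (f + ".z_interq", self.z_interq),
        ]


def zprofile(responses: np.ndarray, source_filter: str = "") -> ZProfile:
    """Compute the Z-profile of a (S, H, W) stack of per-scale responses.

    Parameters
    ----------
    responses : ndarray, shape (S, H, W)
        One 2-D response map per scale, S >= 2.
    source_filter : str
        Name recorded on the output (used for feature naming).
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 3 or responses.shape[0] < 2:
        raise ValueError("need a stack of at least two equal-shape response maps")
    q1, q3 = np.percentile(responses, [25, 75], axis=0)
    return ZProfile(
        z_max=responses.max(axis=0),
        z_mean=responses.mean(axis=0),
        z_var=responses.var(axis=0),  # population variance (ddof=0)
        z_interq=q3 - q1,
        source_filter=source_filter,
    )
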