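"""Moving-average-charge baseline and its linear-regression comparator.

A residue's score is the mean of the +1/-1/0 charges inside a
``window``-residue window centered on it; windows are truncated at the
sequence edges (the mean runs over the in-range positions only).  With
free termini a +1 is added at position 1 and a -1 at position N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ResidueClasses, classify_residues


@dataclass(frozen=True)
class ToyModelConfig:
    window: int = 7
    termini: str = "free"
    edge_mode: str = "truncate"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.edge_mode != "truncate":
            raise ValueError("only edge_mode='truncate' is supported")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def moving_average_charge(
    sequence: str | ResidueClasses, config: ToyModelConfig = ToyModelConfig()
) -> np.ndarray:
    """Per-residue mean charge over a centered, edge-truncated window."""
    if isinstance(sequence, ResidueClasses):
        classes = sequence
    else:
        classes = classify_residues(sequence, termini=config.termini)
    charges = classes.charges
    if classes.n_term_site:
        charges[0] += 1.0
    if classes.c_term_site:
        charges[-1] -= 1.0
    n = charges.size
    half = config.window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = charges[lo:hi].mean()
    return out


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of observed profile ``y`` on toy profile ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    # constant y: no variance to explain, report R^2 = 0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=x.size,
    )
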