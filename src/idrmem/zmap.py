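"""Map side-chain tip heights above the phosphate plane to contact probabilities.

The map is a logistic in the tip height ``z_tip`` whose width itself
interpolates smoothly between a lower and an upper length scale, so that
the transition sharpens as the side chain approaches the membrane:

    C(z)  = 1 / (1 + exp[(z - z0) / L(z)])
    L(z)  = L1 - (L1 - L0) / (1 + exp[(z - Lm) / Lw])

All heights are in Angstrom.  Operations accept scalars or arrays and
preserve shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# exp() overflows just above 709; clamping here has no visible effect on C
_EXP_CLAMP = 700.0
# keep outputs strictly inside their open intervals despite float saturation
_EDGE = 1e-15


@dataclass(frozen=True)
class SmoothMapParams:
    """Constants of the height-to-contact map (Angstrom)."""

    z0: float = 6.9
    L1: float = 3.2
    L0: float = 1.2
    Lm: float = 5.0
    Lw: float = 0.5

    def __post_init__(self) -> None:
        if not self.L1 > self.L0 > 0:
            raise ValueError("requires L1 > L0 > 0")
        if self.Lw <= 0:
            raise ValueError("requires Lw > 0")


DEFAULT_ZMAP = SmoothMapParams()


def length_scale(z_tip, params: SmoothMapParams = DEFAULT_ZMAP):
    """Height-dependent width L(z_tip), strictly between L0 and L1."""
    z = np.asarray(z_tip, dtype=float)
    arg = np.clip((z - params.Lm) / params.Lw, -_EXP_CLAMP, _EXP_CLAMP)
    L = params.L1 - (params.L1 - params.L0) / (1.0 + np.exp(arg))
    margin = (params.L1 - params.L0) * _EDGE
    L = np.clip(L, params.L0 + margin, params.L1 - margin)
    return L if L.ndim else float(L)


def contact_from_ztip(z_tip, params: SmoothMapParams = DEFAULT_ZMAP):
    """Contact probability C(z_tip) in (0, 1); overflow-guarded."""
    z = np.asarray(z_tip, dtype=float)
    L = np.asarray(length_scale(z, params))
    arg = np.clip((z - params.z0) / L, -_EXP_CLAMP, _EXP_CLAMP)
    C = 1.0 / (1.0 + np.exp(arg))
    C = np.clip(C, 1e-300, 1.0 - _EDGE)
    return C if C.ndim else float(C)
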