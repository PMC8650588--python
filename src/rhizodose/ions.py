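"""Macronutrient ion set, ordering, and valences.

The whole package works on the fixed, ordered macronutrient set
(NO3, H2PO4, SO4, K, Ca, Mg).  Anions come first, cations second, so a
charge-group split is a simple slice.  Every ``NutrientVector`` in the
codebase is a length-6 ``numpy`` array in this order; the helpers here
convert between dicts and arrays and validate shape/sign.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

#: Ion labels, fixed order used by every array in the package.
IONS: tuple[str, ...] = ("NO3", "H2PO4", "SO4", "K", "Ca", "Mg")

#: Absolute ionic valence |z| per ion (charge equivalents per mole).
VALENCES = np.array([1.0, 1.0, 2.0, 1.0, 2.0, 2.0])

#: Index slices for the two charge groups.
ANIONS = slice(0, 3)
CATIONS = slice(3, 6)

N_IONS = len(IONS)


def nutrient_vector(values, *, allow_negative: bool = False) -> np.ndarray:
    """Coerce ``values`` to a validated length-6 float array in ion order.

    ``values`` may be a mapping keyed by ion label, a scalar (broadcast),
    or any sequence of 6 numbers already in canonical order.
    """
    if isinstance(values, Mapping):
        missing = [ion for ion in IONS if ion not in values]
        if missing:
            raise ValueError(f"missing ions: {missing}")
        arr = np.array([float(values[ion]) for ion in IONS])
    else:
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 0:
            arr = np.full(N_IONS, float(arr))
    if arr.shape != (N_IONS,):
        raise ValueError(f"expected {N_IONS} ion entries, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("nutrient vector entries must be finite")
    if not allow_negative and np.any(arr < 0):
        raise ValueError("nutrient vector entries must be >= 0")
    return arr


def as_dict(vec: np.ndarray) -> dict[str, float]:
    """Array -> {ion: value} in canonical order."""
    vec = np.asarray(vec, dtype=float)
    return {ion: float(v) for ion, v in zip(IONS, vec)}
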