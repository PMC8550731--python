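"""Genetic map functions.

Converts genetic distance (centimorgan) to recombination fraction and back.
Haldane assumes crossovers form a Poisson process (no interference); Kosambi
incorporates positive interference and is the standard choice for vertebrate
intercross maps.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "haldane_r",
    "haldane_d",
    "kosambi_r",
    "kosambi_d",
    "map_function",
    "MAP_FUNCTIONS",
]


def haldane_r(d_cm):
    """Recombination fraction for a distance ``d_cm`` under Haldane: r = (1 - e^(-2d))/2."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def haldane_d(r):
    """Inverse Haldane map: distance in cM for recombination fraction ``r``."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * np.clip(r, 0.0, 0.4999999))


def kosambi_r(d_cm):
    """Recombination fraction under Kosambi: r = tanh(2d)/2."""
    d = np.asarray(d_cm, dtype=float) / 100.0
    return 0.5 * np.tanh(2.0 * d)


def kosambi_d(r):
    """Inverse Kosambi map: distance in cM for recombination fraction ``r``."""
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * np.clip(r, 0.0, 0.4999999)))


MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


def map_function(name: str):
    """Return the r(d) callable for ``name`` ('haldane' or 'kosambi')."""
    try:
        return MAP_FUNCTIONS[name]
    except KeyError:
        raise ValueError(f"unknown map function {name!r}; expected one of {sorted(MAP_FUNCTIONS)}")
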