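"""Spectral similarity metrics.

The workhorse is the weighted dot product

    wdp_{a,b}(s, t) = ( sum_k m_k^a I_k^b J_k^b m_k^a )
                      / ( ||m^a I^b|| * ||m^a J^b|| )

i.e. cosine similarity of the mass- and intensity-weighted vectors
``m_k^a I_k^b``.  Common presets: DP = (a, b) = (1, 0.5) and the Stein
dot product SDP = (3, 0.6), the standard metric for library search.
Mass power ``a >= 1`` emphasises errors at high mass; intensity power
``b < 1`` damps dominant peaks.  Values lie in [0, 1] for non-negative
spectra and are invariant to intensity scaling.

Barcode metrics (weighted precision WP, weighted false-positive rate
WFPR, top-K precision) classify bins of the true spectrum as present or
absent by whether their L1-normalized intensity reaches ``i_min``
(default 1e-4), then ask how much predicted intensity lands in present
bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .spectrum import DegenerateSpectrumError, Spectrum, align

DEFAULT_I_MIN = 0.0001


@dataclass(frozen=True)
class MetricConfig:
    mass_power: float = 3.0
    intensity_power: float = 0.6
    i_min: float = DEFAULT_I_MIN

    def __post_init__(self):
        if self.mass_power < 0 or self.intensity_power <= 0:
            raise ValueError("require mass_power >= 0 and intensity_power > 0")


DP = MetricConfig(mass_power=1.0, intensity_power=0.5)
SDP = MetricConfig(mass_power=3.0, intensity_power=0.6)


def _weighted_vector(bins: np.ndarray, intens: np.ndarray, a: float, b: float, res: float) -> np.ndarray:
    mz = bins * res
    if a == 0:
        mass_w = np.ones_like(mz)  # 0^0 := 1 -> plain cosine on intensities
    else:
        mass_w = mz**a
    return mass_w * intens**b


def weighted_dot_product(
    s1: Spectrum, s2: Spectrum, mass_power: float = 3.0, intensity_power: float = 0.6
) -> float:
    """Weighted cosine similarity of two spectra on their union grid."""
    bins, i1, i2 = align(s1, s2)
    v1 = _weighted_vector(bins, i1, mass_power, intensity_power, s1.resolution)
    v2 = _weighted_vector(bins, i2, mass_power, intensity_power, s1.resolution)
    n1 = np.sqrt(v1 @ v1)
    n2 = np.sqrt(v2 @ v2)
    if n1 <= 0 or n2 <= 0:
        raise DegenerateSpectrumError("weighted spectrum vector is all zero")
    return float(np.clip((v1 @ v2) / (n1 * n2), 0.0, 1.0))


def stein_dot_product(s1: Spectrum, s2: Spectrum) -> float:
    return weighted_dot_product(s1, s2, SDP.mass_power, SDP.intensity_power)


def _present_mask(truth_intens: np.ndarray, i_min: float) -> np.ndarray:
    total = truth_intens.sum()
    if total <= 0:
        return np.zeros(len(truth_intens), dtype=bool)
    return truth_intens / total >= i_min


def weighted_precision(
    pred: Spectrum, truth: Spectrum, i_min: float = DEFAULT_I_MIN
) -> float:
    """Fraction of predicted intensity in bins present in the true spectrum."""
    _, p, t = align(pred, truth)
    total = p.sum()
    if total <= 0:
        raise DegenerateSpectrumError("predicted spectrum has zero intensity")
    present = _present_mask(t, i_min)
    return float(p[present].sum() / total)


def weighted_fpr(pred: Spectrum, truth: Spectrum, i_min: float = DEFAULT_I_MIN) -> float:
    """Fraction of predicted intensity in bins absent from the true spectrum.

    Complement of :func:`weighted_precision`: WP + WFPR = 1 exactly.
    """
    return 1.0 - weighted_precision(pred, truth, i_min)


def top_k_precision(
    pred: Spectrum, truth: Spectrum, k: int, i_min: float = DEFAULT_I_MIN
) -> float:
    """Fraction of the k strongest predicted bins that are truth-present.

    Ties in predicted intensity are broken toward lower m/z.  If the
    prediction has fewer than ``k`` nonzero bins, the fraction is taken
    over the bins available.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    bins, p, t = align(pred, truth)
    nz = p > 0
    if not nz.any():
        raise DegenerateSpectrumError("predicted spectrum has zero intensity")
    order = np.lexsort((bins[nz], -p[nz]))  # intensity desc, then m/z asc
    take = order[: min(k, int(nz.sum()))]
    present = _present_mask(t, i_min)[nz]
    return float(present[take].mean())
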