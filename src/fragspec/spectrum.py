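"""Spectra: binning, normalization, and assembly from fragment distributions.

A :class:`Spectrum` is a sparse histogram over a grid of bins of width
``resolution`` Da, with bin centers at integer multiples of the
resolution (at 1 Da the familiar integer-Dalton bins).  A peak is
assigned to the bin whose center is nearest its mass; a mass exactly
half-way between two centers goes to the higher bin.

The observation model is exact and linear: given a probability
distribution over fragments, the predicted spectrum is the
probability-weighted sum of each fragment formula's binned isotopic peak
distribution, L2-normalized at the end.  Because fragments carry exact
mass peaks, the same distribution can be rendered at any resolution by
simply changing the binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .chem import Molecule
from .formulas import Formula
from .fragments import AtomSubset, subset_formula
from .isotopes import IsotopePeakDistribution, isotope_distribution

#: nudges exact half-way masses into the higher bin and absorbs float fuzz
_TIE_EPS = 1e-9


class DegenerateSpectrumError(ValueError):
    """A spectrum with no positive intensity where one is required."""


@dataclass(frozen=True)
class Spectrum:
    """Sparse binned spectrum: sorted unique bin indices and intensities.

    ``mz`` of bin ``k`` is ``k * resolution``.  ``norm`` records which
    normalization has been applied ("none", "L1" or "L2").
    """

    bin_index: np.ndarray
    intensity: np.ndarray
    resolution: float = 1.0
    norm: str = "none"

    def __post_init__(self):
        bi = np.asarray(self.bin_index, dtype=np.int64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if bi.shape != inten.shape or bi.ndim != 1:
            raise ValueError("bin_index and intensity must be 1-D and aligned")
        if len(bi) > 1 and not np.all(np.diff(bi) > 0):
            order = np.argsort(bi)
            bi, inten = bi[order], inten[order]
            if not np.all(np.diff(bi) > 0):
                raise ValueError("bin indices must be unique")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "bin_index", bi)
        object.__setattr__(self, "intensity", inten)

    @property
    def mz(self) -> np.ndarray:
        return self.bin_index * self.resolution

    def __len__(self) -> int:
        return len(self.bin_index)

    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def l2_norm(self) -> float:
        return float(np.sqrt(np.sum(self.intensity**2)))

    def as_dict(self) -> Dict[int, float]:
        return dict(zip(self.bin_index.tolist(), self.intensity.tolist()))

    def base_peak_bin(self) -> int:
        """Bin index of the maximum-intensity peak (lowest m/z on ties)."""
        if len(self) == 0 or self.intensity.max() <= 0:
            raise DegenerateSpectrumError("spectrum has no positive intensity")
        return int(self.bin_index[int(np.argmax(self.intensity))])


def bin_peaks(
    peaks: Union[IsotopePeakDistribution, Sequence[Tuple[float, float]]],
    resolution: float = 1.0,
) -> Spectrum:
    """Histogram exact peaks onto the bin grid of the given resolution.

    Nearest-center assignment; intensities of peaks sharing a bin are
    summed, so total intensity is conserved exactly.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if isinstance(peaks, IsotopePeakDistribution):
        masses, intens = peaks.masses, peaks.probabilities
    else:
        arr = np.asarray(list(peaks), dtype=np.float64).reshape(-1, 2)
        masses, intens = arr[:, 0], arr[:, 1]
    if len(masses) == 0:
        return Spectrum(np.array([], dtype=np.int64), np.array([]), resolution)
    idx = np.floor(masses / resolution + 0.5 + _TIE_EPS).astype(np.int64)
    uniq, inv = np.unique(idx, return_inverse=True)
    out = np.zeros(len(uniq))
    np.add.at(out, inv, intens)
    return Spectrum(uniq, out, resolution)


def normalize(spec: Spectrum, norm: str = "L2") -> Spectrum:
    """Scale intensities to unit L1 or L2 norm; bin structure unchanged."""
    if norm not in ("L1", "L2"):
        raise ValueError(f"norm must be 'L1' or 'L2', got {norm!r}")
    scale = spec.total_intensity() if norm == "L1" else spec.l2_norm()
    if scale <= 0:
        raise DegenerateSpectrumError("cannot normalize an all-zero spectrum")
    return replace(spec, intensity=spec.intensity / scale, norm=norm)


def rebin(spec: Spectrum, resolution: float) -> Spectrum:
    """Re-histogram a spectrum's bin centers onto a coarser (or equal) grid."""
    out = bin_peaks(list(zip(spec.mz.tolist(), spec.intensity.tolist())), resolution)
    return replace(out, norm=spec.norm if len(out) == len(spec) else "none")


FragmentKey = Union[Formula, AtomSubset]


@dataclass
class FragmentProbabilities:
    """A probability distribution over fragment keys (formulas or subsets)."""

    items: List[Tuple[FragmentKey, float]]

    def __post_init__(self):
        total = sum(p for _, p in self.items)
        if any(p < 0 for _, p in self.items):
            raise ValueError("fragment probabilities must be non-negative")
        if self.items and abs(total - 1.0) > 1e-6:
            raise ValueError(f"fragment probabilities sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.items)

    def keys(self) -> List[FragmentKey]:
        return [k for k, _ in self.items]

    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.items])


def fragment_formula(key: FragmentKey, mol: Optional[Molecule]) -> Formula:
    if isinstance(key, Formula):
        return key
    if mol is None:
        raise ValueError("an AtomSubset key needs the parent molecule")
    return subset_formula(key, mol)


def assemble_spectrum(
    probs: FragmentProbabilities,
    mol: Optional[Molecule] = None,
    resolution: float = 1.0,
    prune_below: float = 1e-6,
    normalization: Optional[str] = "L2",
) -> Spectrum:
    """Render a fragment-probability distribution as a spectrum.

    Each fragment contributes its binned isotopic peak distribution
    weighted by its probability; contributions are summed bin-wise.  With
    ``prune_below=0`` the pre-normalization total intensity equals the
    total fragment probability (1 for a proper distribution, minus any
    mass on the empty formula, which has no observable peaks).  Pass
    ``normalization=None`` to inspect the raw assembly.
    """
    if len(probs) == 0:
        raise DegenerateSpectrumError("empty fragment distribution")
    acc: Dict[int, float] = {}
    iso_cache: Dict[Formula, Spectrum] = {}
    for key, p in probs.items:
        f = fragment_formula(key, mol)
        binned = iso_cache.get(f)
        if binned is None:
            binned = bin_peaks(isotope_distribution(f, prune_below), resolution)
            iso_cache[f] = binned
        for b, inten in zip(binned.bin_index.tolist(), binned.intensity.tolist()):
            acc[b] = acc.get(b, 0.0) + p * inten
    if not acc:
        raise DegenerateSpectrumError("distribution produced no observable peaks")
    bins = np.array(sorted(acc), dtype=np.int64)
    intens = np.array([acc[b] for b in bins])
    spec = Spectrum(bins, intens, resolution)
    if normalization is None:
        return spec
    return normalize(spec, normalization)


def align(s1: Spectrum, s2: Spectrum) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Put two spectra on their union grid; returns (bins, i1, i2)."""
    if abs(s1.resolution - s2.resolution) > 1e-12:
        raise ValueError(
            f"resolution mismatch: {s1.resolution} vs {s2.resolution}"
        )
    bins = np.union1d(s1.bin_index, s2.bin_index)
    i1 = np.zeros(len(bins))
    i2 = np.zeros(len(bins))
    i1[np.searchsorted(bins, s1.bin_index)] = s1.intensity
    i2[np.searchsorted(bins, s2.bin_index)] = s2.intensity
    return bins, i1, i2
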