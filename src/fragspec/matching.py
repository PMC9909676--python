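"""Library matching: ranked lookup of query spectra in an augmented library.

The protocol mirrors routine compound identification: an *augmented
library* holds one spectrum per molecule (experimental for known
compounds, model-predicted for the rest).  For each query spectrum, the
library is first filtered to candidates whose base peak (max-intensity
bin) lies within +-``window`` Da of the query's base peak, candidates
are ranked by decreasing Stein dot product, and the rank of the true
molecule is recorded.  ``recall@K`` is the fraction of queries whose
true molecule ranks in the top K; its complement is the lookup error
rate.  Error bars come from bootstrap subsamples of the query set drawn
without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .metrics import MetricConfig, SDP, weighted_dot_product
from .spectrum import Spectrum


@dataclass
class LibraryRecord:
    molecule_id: str
    spectrum: Spectrum
    provenance: str = "experimental"  # or "predicted"


@dataclass
class AugmentedLibrary:
    records: List[LibraryRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.molecule_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids must be unique")
        if self.records:
            res = self.records[0].spectrum.resolution
            if any(abs(r.spectrum.resolution - res) > 1e-12 for r in self.records):
                raise ValueError("all library spectra must share one resolution")

    def add(self, molecule_id: str, spectrum: Spectrum, provenance: str = "experimental"):
        self.records.append(LibraryRecord(molecule_id, spectrum, provenance))
        self.__post_init__()

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class RankResult:
    """Outcome of one query: 1-based rank of the true molecule, or None if
    the base-peak filter excluded it."""

    molecule_id: str
    rank: Optional[int]
    n_candidates: int

    @property
    def found(self) -> bool:
        return self.rank is not None


def library_match(
    query: Spectrum,
    library: AugmentedLibrary,
    window: float = 5.0,
    metric: MetricConfig = SDP,
) -> List[Tuple[str, float]]:
    """Rank library records against a query spectrum.

    Candidates must have their max-intensity bin within ``window`` Da of
    the query's; survivors are sorted by decreasing weighted dot product
    under ``metric``, with ties broken by molecule id for reproducible
    ranks.  An empty candidate list is a valid result.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    q_peak = query.base_peak_bin() * query.resolution
    scored = []
    for rec in library.records:
        peak = rec.spectrum.base_peak_bin() * rec.spectrum.resolution
        if abs(peak - q_peak) > window:
            continue
        score = weighted_dot_product(
            query, rec.spectrum, metric.mass_power, metric.intensity_power
        )
        scored.append((rec.molecule_id, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def rank_query(
    query: Spectrum,
    true_id: str,
    library: AugmentedLibrary,
    window: float = 5.0,
    metric: MetricConfig = SDP,
) -> RankResult:
    ranked = library_match(query, library, window, metric)
    for pos, (mid, _) in enumerate(ranked, start=1):
        if mid == true_id:
            return RankResult(true_id, pos, len(ranked))
    return RankResult(true_id, None, len(ranked))


def recall_at_k(ranks: Sequence[RankResult], k: int) -> float:
    """Fraction of queries whose true molecule ranked in the top ``k``."""
    if not ranks:
        raise ValueError("empty rank list")
    hits = sum(1 for r in ranks if r.found and r.rank <= k)
    return hits / len(ranks)


def error_rate_at_k(ranks: Sequence[RankResult], k: int) -> float:
    return 1.0 - recall_at_k(ranks, k)


def bootstrap_error(
    ranks: Sequence[RankResult],
    k: int,
    draws: int = 100,
    fraction: float = 0.2,
    seed: int = 0,
) -> Tuple[float, float]:
    """Mean and 1-sigma of the error rate over bootstrap query subsamples.

    Each draw takes ``fraction`` of the queries uniformly at random
    without replacement.  ``fraction=1.0`` reproduces the full-set error
    with zero spread.  Deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    ranks = list(ranks)
    n = len(ranks)
    size = max(1, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    rates = np.empty(draws)
    for d in range(draws):
        idx = rng.choice(n, size=size, replace=False)
        rates[d] = error_rate_at_k([ranks[i] for i in idx], k)
    return float(rates.mean()), float(rates.std())
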