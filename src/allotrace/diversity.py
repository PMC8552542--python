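"""Per-sample diversity statistics.

Three complementary views of repertoire diversity:

* **Clonality** ``C = 1 − H_obs / H_max`` with ``H_max = ln S`` over the
  ``S`` unique clonotypes: 0 for a maximally diverse (uniform) repertoire,
  1 for a monoclonal one.
* **R20**: the fraction of the most frequent clonotypes that together hold
  20% of the repertoire mass; small values indicate immunodominance.
* **Power-law slope**: log–log OLS slope of the bulk clone-size spectrum
  after splitting off the high-frequency ("expanded") component; a steeper
  absolute slope means a greater abundance of distinct low-frequency clones.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import DiversityReport, RepertoireSample

FREQ_TOL = 1e-9


def shannon_entropy(frequencies: np.ndarray) -> float:
    """Shannon entropy H = −Σ f ln f in nats of a normalized frequency vector."""
    f = np.asarray(frequencies, dtype=float)
    f = f[f > 0]
    if f.size == 0:
        raise ValueError("no positive frequencies")
    if abs(f.sum() - 1.0) > FREQ_TOL:
        raise ValueError(f"frequencies sum to {f.sum():.12f}, expected 1")
    return float(-(f * np.log(f)).sum())


def clonality(sample: RepertoireSample) -> float:
    """Normalized clonal dominance C = 1 − H_obs / ln(S), in [0, 1].

    Defined as 1 for a single-clonotype sample (the limit of the formula).
    """
    s = sample.n_clonotypes
    if s == 0:
        raise ValueError("empty sample")
    if s == 1:
        return 1.0
    h_obs = shannon_entropy(sample.frequencies)
    c = 1.0 - h_obs / np.log(s)
    # uniform repertoires can land at -1e-16 by float round-off
    return float(min(1.0, max(0.0, c)))


def r20(sample: RepertoireSample, mass: float = 0.20) -> float:
    """Fraction of top clonotypes jointly holding ``mass`` of the repertoire.

    Clones are ranked by descending frequency with ties broken by clonotype
    key for determinism; R20 = k/S with k the smallest number of top clones
    whose cumulative frequency reaches ``mass``.
    """
    if sample.n_clonotypes == 0:
        raise ValueError("empty sample")
    order = sorted(sample.clonotypes, key=lambda c: (-c.frequency, c.key))
    cum = np.cumsum([c.frequency for c in order])
    k = int(np.searchsorted(cum, mass - FREQ_TOL)) + 1
    k = min(k, len(order))
    return k / sample.n_clonotypes


def clone_size_spectrum(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct clone sizes s and the fraction of clonotypes at each size."""
    sizes, n_at_size = np.unique(np.asarray(counts, dtype=np.int64), return_counts=True)
    return sizes, n_at_size / n_at_size.sum()


def powerlaw_slope(
    sample: RepertoireSample, expanded_threshold: float = 1e-3
) -> tuple[float, float, float]:
    """OLS slope of the log bulk clone-size spectrum, its R², and the cutoff.

    The repertoire is split into a high-frequency and a bulk component at the
    second-smallest distinct frequency among "expanded" clones (frequency ≥
    ``expanded_threshold``); with fewer than two expanded clones every clone
    is bulk.  The spectrum (x = clone count, y = fraction of distinct
    clonotypes at that count) of the bulk is regressed log y on log x.
    """
    freqs = sample.frequencies
    expanded = np.unique(freqs[freqs >= expanded_threshold])
    if expanded.size >= 2:
        cutoff = float(expanded[1])  # second-smallest distinct expanded frequency
    else:
        cutoff = float("inf")
    bulk_counts = sample.counts[freqs < cutoff]
    if bulk_counts.size == 0:
        raise ValueError("no bulk clones below the expanded-component cutoff")
    sizes, frac = clone_size_spectrum(bulk_counts)
    if sizes.size < 3:
        raise ValueError(
            f"clone-size spectrum has only {sizes.size} distinct size(s); "
            "a larger sample is needed for a power-law fit"
        )
    fit = stats.linregress(np.log(sizes), np.log(frac))
    return float(fit.slope), float(fit.rvalue**2), cutoff


def diversity_report(
    sample: RepertoireSample,
    expanded_threshold: float = 1e-3,
    mass: float = 0.20,
) -> DiversityReport:
    """All diversity statistics for one sample.

    The power-law fit is skipped (NaN fields) when the clone-size spectrum is
    degenerate, e.g. for small or uniform toy samples.
    """
    h = shannon_entropy(sample.frequencies) if sample.n_clonotypes > 1 else 0.0
    report = DiversityReport(
        sample_ref=sample.meta,
        n_clonotypes=sample.n_clonotypes,
        shannon_H=h,
        clonality=clonality(sample),
        r20=r20(sample, mass=mass),
    )
    try:
        slope, r2, cutoff = powerlaw_slope(sample, expanded_threshold)
    except ValueError:
        return report
    report.powerlaw_slope = slope
    report.powerlaw_r2 = r2
    report.cutoff_frequency = cutoff
    return report
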