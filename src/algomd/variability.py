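"""Shannon-entropy variability analysis of descriptor tables.

A descriptor's information content over a dataset of N molecules is the
Shannon entropy SE = -sum p_i log2 p_i of its value distribution after
discretization into B bins (p_i = count_i / N over occupied bins).  A
descriptor that places every molecule in its own bin attains the maximum
log2 N bits; a constant descriptor carries 0 bits.  Entropy profiles are
the instrument used to compare descriptor families: the fraction of
descriptors above a bits threshold (reported alongside the threshold as a
percentage of the attainable maximum) summarizes how discriminative a
family is.

Two discretization rules are available: equal-width bins over [min, max]
(default) and equal-count (quantile) bins; with B = N equal-count bins a
descriptor with all-distinct values reaches the log2 N maximum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ResultTable

__all__ = ["EntropyProfile", "shannon_entropy", "entropy_profile", "max_entropy_bits"]


def max_entropy_bits(n: int) -> float:
    """Attainable maximum entropy for a dataset of n molecules: log2 n."""
    if n < 1:
        raise ValueError("dataset size must be >= 1")
    return float(np.log2(n))


def shannon_entropy(
    values,
    bins: int,
    binning: str = "width",
) -> float:
    """Entropy in bits of one descriptor column discretized into ``bins`` bins.

    NA entries are dropped before binning (an all-NA column yields NaN).
    ``binning='width'`` uses equal-width intervals over [min, max]
    (right-closed); ``binning='count'`` uses equal-count (quantile) cuts.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if binning not in ("width", "count"):
        raise ValueError(f"unknown binning rule {binning!r}")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        return float("nan")
    if np.ptp(v) == 0:
        return 0.0
    if binning == "width":
        edges = np.linspace(v.min(), v.max(), bins + 1)
        # right-closed intervals; put the minimum in the first bin
        idx = np.searchsorted(edges, v, side="left") - 1
        idx = np.clip(idx, 0, bins - 1)
        counts = np.bincount(idx, minlength=bins)
    else:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        idx = (ranks * bins) // n
        counts = np.bincount(idx, minlength=bins)
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


@dataclass
class EntropyProfile:
    names: list[str]
    entropies: np.ndarray  # bits, NaN for all-NA columns
    bins: int
    n_molecules: int
    threshold_bits: float | None = None
    dropped_na: dict[str, int] = field(default_factory=dict)

    @property
    def max_entropy(self) -> float:
        return max_entropy_bits(self.n_molecules)

    @property
    def ratios(self) -> np.ndarray:
        """Per-descriptor entropy as a fraction of the log2 N maximum."""
        return self.entropies / self.max_entropy

    @property
    def threshold_pct_of_max(self) -> float | None:
        if self.threshold_bits is None:
            return None
        return 100.0 * self.threshold_bits / self.max_entropy

    @property
    def count_above_threshold(self) -> int:
        if self.threshold_bits is None:
            raise ValueError("no threshold configured")
        finite = self.entropies[np.isfinite(self.entropies)]
        return int((finite > self.threshold_bits).sum())

    @property
    def fraction_above_threshold(self) -> float:
        return self.count_above_threshold / len(self.names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"descriptor": self.names, "entropy_bits": self.entropies,
             "fraction_of_max": self.ratios}
        )

    def summary(self) -> str:
        lines = [
            f"N = {self.n_molecules} molecules, B = {self.bins} bins, "
            f"max entropy = {self.max_entropy:.2f} bits",
        ]
        if self.threshold_bits is not None:
            lines.append(
                f"{self.count_above_threshold}/{len(self.names)} descriptors "
                f"({100 * self.fraction_above_threshold:.0f}%) above "
                f"{self.threshold_bits:.2f} bits "
                f"({self.threshold_pct_of_max:.0f}% of the maximum entropy)"
            )
        return "\n".join(lines)


def entropy_profile(
    table: ResultTable,
    bins: int | None = None,
    binning: str = "width",
    threshold_bits: float | None = None,
) -> EntropyProfile:
    """Per-descriptor entropy profile of a result table.

    ``bins`` defaults to N (one bin per molecule), so log2 N is the
    attainable maximum.  ``threshold_bits`` enables the above-threshold
    count and its percent-of-maximum report.
    """
    if len(table.names) < 1:
        raise ValueError("table has no descriptor columns")
    n = len(table.ids)
    if bins is None:
        bins = n
    dropped = {}
    ents = []
    for col, name in enumerate(table.names):
        column = table.values[:, col]
        n_na = int(np.sum(~np.isfinite(column)))
        if n_na:
            dropped[name] = n_na
        ents.append(shannon_entropy(column, bins, binning))
    return EntropyProfile(
        names=list(table.names),
        entropies=np.array(ents),
        bins=bins,
        n_molecules=n,
        threshold_bits=threshold_bits,
        dropped_na=dropped,
    )


def write_profile(profile: EntropyProfile, path: str | Path) -> None:
    """Write the per-descriptor entropy table plus a trailing summary comment."""
    df = profile.to_dataframe()
    with Path(path).open("w") as fh:
        df.to_csv(fh, index=False, float_format="%.6g")
        for line in profile.summary().splitlines():
            fh.write(f"# {line}\n")
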