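"""Rosenberg's informativeness for assignment (I_n) for biallelic markers.

For K populations with ALT-allele frequencies p_1..p_K and unweighted mean
p_bar, the statistic sums over the two alleles j in {alt, ref}:

    I_n = sum_j ( -p_bar_j ln p_bar_j + (1/K) sum_i p_ij ln p_ij )

with 0 ln 0 = 0. Values are in nats and lie in [0, ln K]; I_n is 0 iff the
compared populations share identical frequencies and reaches ln K only at a
K-way fixed difference. It is invariant to population order and to which
allele is counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .popdata import FrequencyTable

Comparison = tuple[str, ...]


def comparison_name(subset: Sequence[str]) -> str:
    return "|".join(subset)


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with the 0 ln 0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = p * np.log(p)
    return np.where(p > 0, out, 0.0)


def marker_in(freqs: Sequence[float] | np.ndarray) -> float:
    """I_n (nats) for one biallelic marker across K >= 2 populations.

    Parameters
    ----------
    freqs : array of length K
        ALT-allele frequency in each compared population.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need at least two population frequencies")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    return float(_in_rows(p[None, :])[0])


def _in_rows(p: np.ndarray) -> np.ndarray:
    """Vectorized I_n for an (n_markers, K) array of ALT frequencies."""
    K = p.shape[1]
    terms = np.zeros(p.shape[0])
    for allele in (p, 1.0 - p):
        pbar = allele.mean(axis=1)
        terms += -_xlogx(pbar) + _xlogx(allele).sum(axis=1) / K
    # clip tiny negative round-off
    return np.maximum(terms, 0.0)


@dataclass
class InformativenessTable:
    """Markers x comparisons table of I_n values (nats).

    NaN marks a marker with a missing frequency in some compared
    population; such markers are ineligible for panel selection in that
    comparison.
    """

    values: pd.DataFrame  # index marker_id, one column per comparison
    comparisons: list[Comparison]
    markers: pd.DataFrame

    def column(self, comparison: Comparison | str) -> pd.Series:
        name = comparison if isinstance(comparison, str) else comparison_name(comparison)
        if name not in self.values.columns:
            raise KeyError(f"no such comparison: {name}")
        return self.values[name]

    def write_tsv(self, path) -> None:
        self.values.rename_axis("marker_id").to_csv(path, sep="\t", na_rep="NA")


def in_table(
    F: FrequencyTable, comparisons: Sequence[Sequence[str]] | None = None
) -> InformativenessTable:
    """I_n for every marker under each comparison.

    By default every unordered pair of populations in ``F`` is compared
    (6 pairs for 4 populations). A comparison may also be the full
    population set or any subset of size >= 2.
    """
    if comparisons is None:
        comparisons = list(itertools.combinations(F.populations, 2))
    comps: list[Comparison] = [tuple(c) for c in comparisons]
    cols = {}
    for comp in comps:
        if len(comp) < 2:
            raise ValueError(f"comparison {comp} needs >= 2 populations")
        rows = [F.population_index(p) for p in comp]
        sub = F.freqs[rows, :].T  # markers x K
        vals = np.full(sub.shape[0], np.nan)
        ok = ~np.isnan(sub).any(axis=1)
        vals[ok] = _in_rows(sub[ok])
        cols[comparison_name(comp)] = vals
    values = pd.DataFrame(cols, index=F.marker_ids)
    return InformativenessTable(values, comps, F.markers)


def top_rank(
    T: InformativenessTable, comparison: Comparison | str, k: int
) -> list[str]:
    """IDs of the k markers with highest I_n under one comparison.

    Sorted descending by I_n; ties broken by (chromosome, position,
    marker_id) so the ranking is deterministic. Markers with missing I_n
    are ineligible.
    """
    col = T.column(comparison)
    df = T.markers.copy()
    df["in_value"] = col.to_numpy()
    df = df.dropna(subset=["in_value"])
    if k > len(df):
        raise ValueError(f"k={k} exceeds {len(df)} eligible markers")
    df = df.sort_values(
        by=["in_value", "chrom", "pos", "marker_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return df["marker_id"].head(k).tolist()
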