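"""Fixed-size AIM panel selection by genetic-algorithm subset search.

The objective balances two goals: the panel should carry as much
informativeness as possible for every population comparison at once, and it
should be spread across the genome rather than clustered. Formally, for a
candidate subset S of size n,

    fitness(S) = sum_c w_c * ( sum_{m in S} I_n,c(m) ) / Z_c
                 + lambda * coverage(S)

where Z_c is the sum of the n largest I_n values for comparison c over the
whole candidate pool (so each comparison term is at most 1, preventing
high-divergence pairs from drowning the hard, closely related pair), and
coverage(S) is the fraction of fixed-width genome bins containing at least
one candidate that S occupies. Because the informativeness part is additive
over markers, each marker carries a precomputed scalar score and fitness
evaluation is a sum plus a bin count.

The search is a steady-generational GA over fixed-size marker subsets:
tournament selection, uniform set-union crossover with random repair to the
exact panel size, per-slot swap mutation, and elitism (which makes the
best-so-far fitness monotone non-decreasing). An exhaustive optimizer over
all C(n, k) subsets serves as the oracle on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .informativeness import InformativenessTable, comparison_name
from .popdata import AUTOSOMES, FrequencyTable, GenotypeMatrix


@dataclass
class GAConfig:
    population_size: int = 200
    generations: int = 500
    tournament_size: int = 3
    mutation_rate: float = 0.01  # per-slot swap probability
    elitism_count: int = 1

    def __post_init__(self) -> None:
        if min(self.population_size, self.generations, self.tournament_size) < 1:
            raise ValueError("GA counts must be >= 1")
        if self.elitism_count < 0 or not (0 <= self.mutation_rate <= 1):
            raise ValueError("invalid elitism or mutation rate")


@dataclass
class DesignConfig:
    """Panel-design objective and search hyperparameters."""

    panel_size: int = 150
    comparison_weights: Mapping[str, float] | None = None  # default: 1 each
    coverage_weight: float = 1.0  # lambda
    bin_size: int = 20_000_000
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.coverage_weight < 0:
            raise ValueError("coverage_weight must be >= 0")
        if self.comparison_weights and any(
            w < 0 for w in self.comparison_weights.values()
        ):
            raise ValueError("comparison weights must be >= 0")


@dataclass
class Panel:
    """Deployable AIM panel: ordered markers with reference frequencies."""

    markers: pd.DataFrame  # marker_id, chrom, pos, ref, alt
    ref_freqs: FrequencyTable
    fitness: float
    provenance: dict

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def __len__(self) -> int:
        return len(self.markers)

    def write_tsv(self, path) -> None:
        """Panel TSV: marker metadata, reference frequencies, I_n columns."""
        out = self.ref_freqs.to_frame()
        in_cols = self.provenance.get("in_values")
        if in_cols is not None:
            out = out.join(in_cols.add_prefix("In_"), on="marker_id")
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "Panel":
        F = FrequencyTable.read_tsv(path)
        return cls(F.markers.copy(), F, float("nan"), {"source": str(path)})


# ---------------------------------------------------------------------------
# Objective components
# ---------------------------------------------------------------------------

def coverage_score(
    markers: pd.DataFrame,
    genome_map: Mapping[str, int],
    bin_size: int,
    candidate_bins: set[tuple[str, int]] | None = None,
) -> float:
    """Fraction of candidate-containing genome bins occupied by the markers.

    The genome is partitioned into fixed ``bin_size`` windows per
    chromosome. Only bins containing at least one candidate marker count
    toward the denominator (``candidate_bins``; defaults to the bins of
    ``markers`` itself, which then scores 1.0 by construction).
    """
    if len(markers) == 0:
        import warnings

        warnings.warn("empty marker set has zero coverage")
        return 0.0
    for _, row in markers.iterrows():
        if row["chrom"] not in genome_map:
            raise ValueError(f"marker {row['marker_id']} on unmapped chromosome")
        if not (1 <= row["pos"] <= genome_map[row["chrom"]]):
            raise ValueError(f"marker {row['marker_id']} position outside chromosome")
    bins = {
        (c, p // bin_size)
        for c, p in zip(markers["chrom"], markers["pos"].astype(int) - 1)
    }
    if candidate_bins is None:
        candidate_bins = bins
    return len(bins & candidate_bins) / len(candidate_bins)


@dataclass
class _Instance:
    """Preprocessed candidate pool for fast fitness evaluation."""

    marker_ids: np.ndarray
    scores: np.ndarray  # per-marker normalized informativeness score
    bin_ids: np.ndarray  # integer bin per marker
    n_candidate_bins: int
    markers: pd.DataFrame
    cfg: DesignConfig
    in_values: pd.DataFrame

    def fitness_of(self, idx: np.ndarray) -> float:
        cov = len(np.unique(self.bin_ids[idx])) / self.n_candidate_bins
        return float(self.scores[idx].sum() + self.cfg.coverage_weight * cov)


def _prepare(
    T: InformativenessTable, cfg: DesignConfig, genome_map: Mapping[str, int] | None
) -> _Instance:
    mk = T.markers.copy().reset_index(drop=True)
    eligible = mk["chrom"].astype(str).isin(AUTOSOMES).to_numpy()
    eligible &= ~T.values.isna().any(axis=1).to_numpy()
    mk = mk.loc[eligible].reset_index(drop=True)
    vals = T.values[eligible]
    if len(mk) < cfg.panel_size:
        raise ValueError(
            f"only {len(mk)} eligible candidates for panel_size {cfg.panel_size}"
        )
    weights = dict(cfg.comparison_weights or {})
    scores = np.zeros(len(mk))
    for comp in T.comparisons:
        name = comparison_name(comp)
        w = weights.get(name, 1.0)
        col = vals[name].to_numpy()
        top = np.sort(col)[::-1][: cfg.panel_size]
        z = top.sum()
        if z > 0:
            scores += w * col / z
    if genome_map is None:
        genome_map = {
            c: int(g["pos"].max()) for c, g in mk.groupby("chrom", sort=False)
        }
    chrom_code = pd.factorize(mk["chrom"])[0]
    bin_ids = chrom_code * (2**32) + (mk["pos"].astype(int).to_numpy() - 1) // cfg.bin_size
    return _Instance(
        mk["marker_id"].to_numpy(),
        scores,
        bin_ids,
        len(np.unique(bin_ids)),
        mk,
        cfg,
        vals,
    )


def fitness(
    subset: Sequence[str],
    T: InformativenessTable,
    cfg: DesignConfig,
    genome_map: Mapping[str, int] | None = None,
) -> float:
    """Objective value of a marker subset (see module docstring)."""
    inst = _prepare(T, cfg, genome_map)
    lookup = {m: i for i, m in enumerate(inst.marker_ids)}
    missing = [m for m in subset if m not in lookup]
    if missing:
        raise ValueError(f"markers ineligible or unknown: {missing[:5]}")
    if len(subset) != cfg.panel_size:
        raise ValueError(f"subset size {len(subset)} != panel_size {cfg.panel_size}")
    idx = np.array([lookup[m] for m in subset])
    return inst.fitness_of(idx)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def _build_panel(
    inst: _Instance, idx: np.ndarray, F: FrequencyTable, fit: float, prov: dict
) -> Panel:
    order = idx[np.argsort(inst.marker_ids[idx])]
    ids = list(inst.marker_ids[order])
    prov = dict(prov)
    prov["in_values"] = inst.in_values.loc[ids]
    return Panel(
        inst.markers.set_index("marker_id").loc[ids].reset_index(),
        F.subset_markers(ids),
        fit,
        prov,
    )


def ga_optimize(
    F: FrequencyTable,
    T: InformativenessTable,
    cfg: DesignConfig | None = None,
    genome_map: Mapping[str, int] | None = None,
    seed: int = 0,
) -> Panel:
    """Genetic-algorithm search for a high-fitness fixed-size panel.

    Reproducible given ``seed``; with elitism >= 1 the best-ever fitness is
    monotone non-decreasing across generations.
    """
    cfg = cfg if cfg is not None else DesignConfig()
    inst = _prepare(T, cfg, genome_map)
    n, k = len(inst.marker_ids), cfg.panel_size
    rng = np.random.default_rng(seed)
    ga = cfg.ga

    pop = np.stack(
        [rng.choice(n, size=k, replace=False) for _ in range(ga.population_size)]
    )
    # warm start: seed one individual with the greedy score-ranked subset,
    # so with elitism the result never falls below the greedy baseline
    pop[0] = np.argsort(inst.scores)[::-1][:k]
    fits = np.array([inst.fitness_of(ind) for ind in pop])
    best_idx = int(fits.argmax())
    best, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]

    for _ in range(ga.generations):
        new_pop = np.empty_like(pop)
        elite_order = np.argsort(fits)[::-1][: ga.elitism_count]
        new_pop[: ga.elitism_count] = pop[elite_order]
        for i in range(ga.elitism_count, ga.population_size):
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population_size, ga.tournament_size)
                parents.append(pop[contenders[fits[contenders].argmax()]])
            # uniform set-union crossover with random repair to size k
            union = np.union1d(parents[0], parents[1])
            child = rng.choice(union, size=k, replace=False)
            # per-slot swap mutation
            n_mut = rng.binomial(k, ga.mutation_rate)
            if n_mut:
                member = np.zeros(n, dtype=bool)
                member[child] = True
                outside = np.flatnonzero(~member)
                n_mut = min(n_mut, outside.size)
                if n_mut:
                    slots = rng.choice(k, size=n_mut, replace=False)
                    child[slots] = rng.choice(outside, size=n_mut, replace=False)
            new_pop[i] = child
        pop = new_pop
        fits = np.array([inst.fitness_of(ind) for ind in pop])
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    return _build_panel(
        inst,
        best,
        F,
        best_fit,
        {"method": "ga", "seed": seed, "config": cfg, "history": history},
    )


def exhaustive_optimize(
    F: FrequencyTable,
    T: InformativenessTable,
    cfg: DesignConfig | None = None,
    genome_map: Mapping[str, int] | None = None,
    cap: int = 10**6,
) -> Panel:
    """Global optimum by enumerating all C(n, panel_size) subsets.

    Ties are broken toward the lexicographically smallest marker-ID tuple.
    Refuses instances larger than ``cap`` subsets.
    """
    cfg = cfg if cfg is not None else DesignConfig()
    inst = _prepare(T, cfg, genome_map)
    n, k = len(inst.marker_ids), cfg.panel_size
    if comb(n, k) > cap:
        raise ValueError(
            f"C({n},{k}) = {comb(n, k)} exceeds cap {cap}; use ga_optimize"
        )
    order = np.argsort(inst.marker_ids)  # lexicographic enumeration for ties
    best_idx: np.ndarray | None = None
    best_fit = -np.inf
    for combo in itertools.combinations(order, k):
        idx = np.array(combo)
        f = inst.fitness_of(idx)
        if f > best_fit + 1e-15:
            best_idx, best_fit = idx, f
    assert best_idx is not None
    return _build_panel(
        inst, best_idx, F, best_fit, {"method": "exhaustive", "config": cfg}
    )


# ---------------------------------------------------------------------------
# Panel evaluation
# ---------------------------------------------------------------------------

def evaluate_panel(
    panel: Panel,
    G_validation: GenotypeMatrix,
    F_ref: FrequencyTable,
    components: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Per-component correlation of panel-based vs all-marker estimates.

    Ancestry is estimated supervised (reference frequencies fixed) twice:
    from the panel markers alone and from every marker in the validation
    set; the Pearson correlation across individuals is reported per
    component. A component with zero variance in either estimate yields
    NaN.
    """
    from .ancestry import AncestryModel, estimate_q

    comps = list(components) if components is not None else list(F_ref.populations)
    model_all = AncestryModel.from_frequency_table(F_ref, comps)
    q_all = estimate_q(G_validation, model_all, seed=seed)

    panel_ids = [m for m in panel.marker_ids if m in set(G_validation.marker_ids)]
    if not panel_ids:
        raise ValueError("panel markers absent from validation genotypes")
    F_panel = F_ref.subset_markers(panel_ids)
    model_panel = AncestryModel.from_frequency_table(F_panel, comps)
    q_panel = estimate_q(
        G_validation.subset_markers(panel_ids), model_panel, seed=seed
    )

    out = {}
    for c in comps:
        x = q_all.proportions[c].to_numpy()
        y = q_panel.proportions[c].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
            out[c] = np.nan
        else:
            out[c] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="correlation")
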