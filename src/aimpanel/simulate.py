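"""Synthetic cohorts with hierarchical population structure.

Allele frequencies drift along a small population tree under the
Balding-Nichols model: given a parent frequency p and a drift parameter F,
the child frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p and
whose variance is F p(1-p). The default tree mirrors a four-way admixture
setting with two distant continental components and two closely related
sub-continental ones:

    ROOT -- 0.15 --> EUR
    ROOT -- 0.15 --> AFR
    ROOT -- 0.25 --> AMR -- 0.05 --> AYM
                         -- 0.05 --> MAP

so the EUR/AFR pair is easy to separate (pairwise Fst ~ 0.30) while the
AYM/MAP pair is genuinely hard (~0.05) -- the regime a sub-continental AIM
panel exists for. Admixed individuals draw ancestry proportions from a
Dirichlet whose default concentration (2.1, 0.16, 0.72, 1.0) gives mean
proportions (0.53, 0.04, 0.18, 0.25) for (EUR, AFR, AYM, MAP), the profile
of a strongly admixed Latin American cohort. Genotypes are
Binomial(2, sum_k q_k f_km) and calls go missing completely at random at a
configurable rate (default 0.012).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popdata import FrequencyTable, GenotypeMatrix, MARKER_COLUMNS
from .ancestry import QMatrix

# GRCh37 autosome lengths, Mb-rounded.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_000_000, "2": 243_000_000, "3": 198_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 159_000_000, "8": 146_000_000,
    "9": 141_000_000, "10": 136_000_000, "11": 135_000_000, "12": 134_000_000,
    "13": 115_000_000, "14": 107_000_000, "15": 103_000_000, "16": 90_000_000,
    "17": 81_000_000, "18": 78_000_000, "19": 59_000_000, "20": 63_000_000,
    "21": 48_000_000, "22": 51_000_000,
}

# edge list: population -> (parent, drift). "ROOT" is the ancestral pool.
DEFAULT_FST_TREE: dict[str, tuple[str, float]] = {
    "EUR": ("ROOT", 0.15),
    "AFR": ("ROOT", 0.15),
    "AMR": ("ROOT", 0.25),
    "AYM": ("AMR", 0.05),
    "MAP": ("AMR", 0.05),
}

DEFAULT_ALPHA: dict[str, float] = {"EUR": 2.1, "AFR": 0.16, "AYM": 0.72, "MAP": 1.0}


@dataclass
class SimulationConfig:
    """Parameters of the hierarchical admixture simulator.

    Attributes
    ----------
    n_markers : number of candidate biallelic SNPs.
    chromosome_lengths : map chromosome -> length in bp; positions are
        drawn uniformly, markers allocated to chromosomes in proportion to
        length.
    fst_tree : map population -> (parent, drift); parents must appear as
        keys or be "ROOT". Leaves (non-parents) are the admixture
        components.
    ancestral_freq_range : uniform support of the root ALT frequency.
    alpha : Dirichlet concentration per leaf component (insertion order of
        ``fst_tree`` leaves).
    n_admixed, n_reference_per_pop : cohort sizes.
    missing_rate : MCAR genotype missingness.
    """

    n_markers: int = 20_000
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    fst_tree: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_FST_TREE)
    )
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    alpha: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    n_admixed: int = 300
    n_reference_per_pop: int = 30
    missing_rate: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, (parent, drift) in self.fst_tree.items():
            if not (0 <= drift < 1):
                raise ValueError(f"drift for {pop} must be in [0, 1)")
            if parent != "ROOT" and parent not in self.fst_tree:
                raise ValueError(f"unknown parent {parent!r} for {pop}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if any(a <= 0 for a in self.alpha.values()):
            raise ValueError("Dirichlet alpha must be positive")
        lo, hi = self.ancestral_freq_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("invalid ancestral_freq_range")

    @property
    def leaves(self) -> list[str]:
        parents = {parent for parent, _ in self.fst_tree.values()}
        return [p for p in self.fst_tree if p not in parents]

    def alpha_vector(self) -> np.ndarray:
        missing = [p for p in self.leaves if p not in self.alpha]
        if missing:
            raise ValueError(f"alpha missing for leaves: {missing}")
        return np.array([self.alpha[p] for p in self.leaves], dtype=float)


@dataclass
class SimulatedCohort:
    """Ground-truth carrier: genotypes plus the generating Q and F."""

    G: GenotypeMatrix
    true_Q: QMatrix
    true_F: FrequencyTable
    config: SimulationConfig

    @property
    def reference_labels(self) -> dict[str, str]:
        return dict(self.G.labels or {})

    @property
    def admixed_samples(self) -> list[str]:
        labelled = set(self.G.labels or {})
        return [s for s in self.G.samples if s not in labelled]


def _balding_nichols(
    rng: np.random.Generator, parent: np.ndarray, drift: float
) -> np.ndarray:
    if drift == 0:
        return parent.copy()
    out = parent.copy()
    inner = (parent > 0) & (parent < 1)  # a fixed allele stays fixed
    a = parent[inner] * (1.0 - drift) / drift
    b = (1.0 - parent[inner]) * (1.0 - drift) / drift
    out[inner] = rng.beta(a, b)
    return out


def _marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(cfg.n_markers, lengths / lengths.sum())
    rows = []
    i = 0
    for c, n_c, L in zip(chroms, counts, lengths):
        pos = np.sort(rng.integers(1, int(L) + 1, size=n_c))
        for p in pos:
            rows.append((f"snp{i:06d}", c, int(p), "A", "G"))
            i += 1
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def simulate_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[FrequencyTable, np.ndarray]:
    """Leaf-population allele frequencies drifted along the tree.

    Returns the leaf FrequencyTable and the ancestral (root) frequencies.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    lo, hi = cfg.ancestral_freq_range
    root = rng.uniform(lo, hi, size=cfg.n_markers)
    freqs: dict[str, np.ndarray] = {"ROOT": root}
    # fst_tree is insertion-ordered parent-before-child by construction
    for pop, (parent, drift) in cfg.fst_tree.items():
        freqs[pop] = _balding_nichols(rng, freqs[parent], drift)
    leaves = cfg.leaves
    F = np.vstack([freqs[p] for p in leaves])
    return FrequencyTable(F, markers, leaves), root


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Reference + admixed genotypes with known ancestry proportions.

    Reference individuals have indicator ancestry (pure leaf-population
    members); admixed individuals draw q ~ Dirichlet(alpha). Dosages are
    Binomial(2, q . f) and then masked MCAR at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    F_table, _ = simulate_frequencies(cfg, rng)
    leaves = cfg.leaves
    K = len(leaves)

    samples: list[str] = []
    labels: dict[str, str] = {}
    q_rows: list[np.ndarray] = []
    for k, pop in enumerate(leaves):
        for i in range(cfg.n_reference_per_pop):
            sid = f"{pop}_{i:03d}"
            samples.append(sid)
            labels[sid] = pop
            q_rows.append(np.eye(K)[k])
    q_adm = rng.dirichlet(cfg.alpha_vector(), size=cfg.n_admixed)
    for i in range(cfg.n_admixed):
        samples.append(f"ADM_{i:04d}")
        q_rows.append(q_adm[i])
    Q = np.vstack(q_rows) if q_rows else np.empty((0, K))

    A = Q @ F_table.freqs
    dosages = rng.binomial(2, A).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    G = GenotypeMatrix(dosages, F_table.markers, samples, labels)
    true_Q = QMatrix(
        pd.DataFrame(Q, index=samples, columns=leaves),
        loglik=float("nan"),
        iterations=0,
        converged=True,
    )
    return SimulatedCohort(G, true_Q, F_table, cfg)


def empirical_fst(
    F: FrequencyTable | GenotypeMatrix, pops: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Hudson-style Fst from population allele frequencies.

    For each pair, Fst = sum_m (p1-p2)^2 / sum_m [p1(1-p2) + p2(1-p1)]
    (ratio of sums). Symmetric with a zero diagonal. Raises if every
    marker is monomorphic in both populations of a pair.
    """
    if isinstance(F, GenotypeMatrix):
        from .popdata import allele_frequencies

        F = allele_frequencies(F)
    pops = list(pops) if pops is not None else list(F.populations)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            p1 = F.freqs[F.population_index(a)]
            p2 = F.freqs[F.population_index(b)]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            num = np.sum((p1[ok] - p2[ok]) ** 2)
            den = np.sum(p1[ok] * (1 - p2[ok]) + p2[ok] * (1 - p1[ok]))
            if den == 0:
                raise ValueError(f"Fst undefined for {a}/{b}: no polymorphism")
            out.loc[a, b] = out.loc[b, a] = num / den
    return out
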