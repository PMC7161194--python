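"""Admixture-proportion estimation under the binomial likelihood.

The model is the standard one used by ADMIXTURE/FRAPPE/structure: individual
i carries ancestry proportions q_i on the K-simplex, component k has
ALT-allele frequency f_km at marker m, and the observed dosage is
g_im ~ Binomial(2, a_im) with a_im = sum_k q_ik f_km. Estimation here uses
the classic multiplicative EM updates (FRAPPE-style) rather than
block-relaxation quasi-Newton: the likelihood and its fixed points are the
same, and at panel scale (hundreds of markers, thousands of individuals) EM
converges in well under a second.

Two modes are provided:

* supervised (``estimate_q``): component frequencies are fixed at reference
  values; each individual is an independent concave problem.
* joint (``fit_admixture``): Q and F are estimated together; reference
  individuals may be pinned to indicator rows of Q via ``fixed_labels``.

Missing genotypes are simply skipped by the likelihood (MCAR assumption).
Frequencies are clamped to [eps, 1-eps] so that a homozygote never meets a
frequency of exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popdata import FrequencyTable, GenotypeMatrix, PopdataError

EPS = 1e-6


class EMError(RuntimeError):
    pass


@dataclass
class AncestryModel:
    """Fixed component allele frequencies for supervised estimation."""

    freqs: np.ndarray  # K x M, clamped to [EPS, 1-EPS]
    component_names: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.clip(np.asarray(self.freqs, dtype=float), EPS, 1 - EPS)
        if self.freqs.shape != (len(self.component_names), len(self.marker_ids)):
            raise ValueError("frequency shape inconsistent with names/markers")

    @property
    def K(self) -> int:
        return len(self.component_names)

    @classmethod
    def from_frequency_table(
        cls, F: FrequencyTable, components: Sequence[str] | None = None
    ) -> "AncestryModel":
        comps = list(components) if components is not None else list(F.populations)
        rows = [F.population_index(c) for c in comps]
        freqs = F.freqs[rows, :]
        if np.isnan(freqs).any():
            raise ValueError("model frequencies contain missing values")
        return cls(freqs, comps, F.marker_ids)


def pool_components(
    F: FrequencyTable,
    pools: Mapping[str, Sequence[str]],
    counts: Mapping[str, int] | None = None,
) -> FrequencyTable:
    """Merge populations into pooled components by weighted frequency average.

    ``pools`` maps each output component to the populations it absorbs; a
    population not mentioned passes through unchanged. ``counts`` gives the
    per-population sample sizes used as weights (equal weights if omitted).
    Used to collapse the two Amerindian references into one component for
    K=3 estimation.
    """
    absorbed = {p for members in pools.values() for p in members}
    out_names: list[str] = []
    out_rows: list[np.ndarray] = []
    for pop in F.populations:
        if pop in absorbed:
            continue
        out_names.append(pop)
        out_rows.append(F.freqs[F.population_index(pop)])
    for name, members in pools.items():
        w = np.array(
            [float(counts[m]) if counts else 1.0 for m in members], dtype=float
        )
        rows = np.array([F.population_index(m) for m in members])
        out_names.append(name)
        out_rows.append(np.average(F.freqs[rows, :], axis=0, weights=w))
    return FrequencyTable(np.vstack(out_rows), F.markers, out_names)


@dataclass
class QMatrix:
    """Individuals x K ancestry proportions with fit diagnostics."""

    proportions: pd.DataFrame  # index samples, columns component names
    loglik: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        q = self.proportions.to_numpy()
        ok = ~np.isnan(q).any(axis=1)
        if (q[ok] < -1e-12).any():
            raise ValueError("negative ancestry proportion")
        if ok.any() and np.abs(q[ok].sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("ancestry proportions do not sum to 1")

    @property
    def components(self) -> list[str]:
        return list(self.proportions.columns)

    def write_q(self, path) -> None:
        """ADMIXTURE .Q-compatible whitespace-delimited output."""
        self.proportions.to_csv(
            path, sep=" ", header=False, index=False, float_format="%.6f"
        )


@dataclass
class CVResult:
    errors: dict[int, float]
    folds: int
    seed: int

    @property
    def best_k(self) -> int:
        return min(self.errors, key=lambda k: (self.errors[k], k))


# ---------------------------------------------------------------------------
# Likelihood and EM cores
# ---------------------------------------------------------------------------

def loglik(
    q: np.ndarray, g: np.ndarray, F: np.ndarray
) -> float:
    """Binomial log-likelihood (nats) of one individual's dosages.

    The binomial coefficient is omitted (constant in q). Missing markers
    (NaN dosage) are skipped.
    """
    q = np.asarray(q, dtype=float)
    g = np.asarray(g, dtype=float)
    F = np.clip(np.asarray(F, dtype=float), EPS, 1 - EPS)
    ok = ~np.isnan(g)
    a = q @ F[:, ok]
    return float(np.sum(g[ok] * np.log(a) + (2.0 - g[ok]) * np.log1p(-a)))


def _masked(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute W*g (ALT counts) and W*(2-g) (REF counts) with NaN -> 0."""
    W = ~np.isnan(G)
    G0 = np.where(W, G, 0.0)
    return W, W * G0, W * (2.0 - G0)


def _total_loglik(WG: np.ndarray, W2G: np.ndarray, A: np.ndarray) -> float:
    return float(np.sum(WG * np.log(A)) + np.sum(W2G * np.log1p(-A)))


def _em_q_step(
    WG: np.ndarray, W2G: np.ndarray, A: np.ndarray, Q: np.ndarray,
    F: np.ndarray, m_obs: np.ndarray,
) -> np.ndarray:
    """One multiplicative EM update of Q (F held fixed).

    WG/W2G are the masked ALT/REF count matrices and A = Q @ F. The update
    preserves the simplex exactly because the expected allele counts per
    individual sum to 2 * m_obs.
    """
    R = (WG / A) @ F.T + (W2G / (1.0 - A)) @ (1.0 - F).T
    Qn = Q * R / (2.0 * m_obs[:, None])
    with np.errstate(invalid="ignore"):
        return Qn / Qn.sum(axis=1, keepdims=True)  # guard round-off


def _em_f_step(
    WG: np.ndarray, W2G: np.ndarray, A: np.ndarray, Q: np.ndarray, F: np.ndarray
) -> np.ndarray:
    """One multiplicative EM update of F (Q held fixed), A = Q @ F."""
    num = F * (Q.T @ (WG / A))
    den = num + (1.0 - F) * (Q.T @ (W2G / (1.0 - A)))
    with np.errstate(invalid="ignore"):
        Fn = num / den
    Fn = np.where(den > 0, Fn, F)
    return np.clip(Fn, EPS, 1 - EPS)


def _supervised_kernel():
    """Lazily compiled fused EM iteration for the supervised fit.

    One pass over the dosage matrix (missing encoded as -1) computes the
    log-likelihood of the current Q and the multiplicative EM update,
    avoiding the large temporaries of the matrix formulation.
    """
    global _EM_ITER
    if _EM_ITER is not None:
        return _EM_ITER
    import numba

    @numba.njit(cache=True, fastmath=True)
    def em_iter(G, Q, F):  # pragma: no cover - exercised via estimate_q
        n, M = G.shape
        K = F.shape[0]
        Qn = np.zeros_like(Q)
        ll = 0.0
        for i in range(n):
            r = np.zeros(K)
            m_obs = 0.0
            for m in range(M):
                g = G[i, m]
                if g < 0.0:
                    continue
                m_obs += 1.0
                a = 0.0
                for k in range(K):
                    a += Q[i, k] * F[k, m]
                if g == 0.0:
                    ll += 2.0 * np.log1p(-a)
                elif g == 2.0:
                    ll += 2.0 * np.log(a)
                else:
                    ll += np.log(a) + np.log1p(-a)
                c1 = g / a
                c2 = (2.0 - g) / (1.0 - a)
                for k in range(K):
                    r[k] += c1 * F[k, m] + c2 * (1.0 - F[k, m])
            s = 0.0
            for k in range(K):
                Qn[i, k] = Q[i, k] * r[k] / (2.0 * m_obs)
                s += Qn[i, k]
            for k in range(K):
                Qn[i, k] /= s
        return Qn, ll

    _EM_ITER = em_iter
    return em_iter


_EM_ITER = None


def _check_monotone(prev: float, curr: float) -> None:
    if curr < prev - 1e-9 * max(1.0, abs(prev)):
        raise EMError(
            f"log-likelihood decreased from {prev:.10g} to {curr:.10g}; "
            "EM update is broken"
        )


# ---------------------------------------------------------------------------
# Supervised estimation
# ---------------------------------------------------------------------------

def estimate_q(
    G: GenotypeMatrix,
    model: AncestryModel,
    tol: float = 1e-7,
    max_iter: int = 1000,
    seed: int = 0,
) -> QMatrix:
    """Supervised ancestry proportions with component frequencies fixed.

    EM is run jointly over all individuals (each row is an independent
    problem sharing F). An individual with zero overlapping non-missing
    markers is flagged with NaN proportions.
    """
    shared = [m for m in model.marker_ids if m in set(G.marker_ids)]
    if not shared:
        raise PopdataError("no shared markers between genotypes and model")
    Gs = G.subset_markers(shared)
    order = pd.Index(model.marker_ids).get_indexer(shared)
    F = model.freqs[:, order]

    W = ~np.isnan(Gs.dosages)
    m_obs = W.sum(axis=1).astype(float)
    usable = m_obs > 0

    rng = np.random.default_rng(seed)
    K = model.K
    Q = rng.dirichlet(np.ones(K), size=len(Gs.samples))
    Q = np.clip(Q, 1e-9, None)
    Q /= Q.sum(axis=1, keepdims=True)
    Genc = np.where(W[usable], Gs.dosages[usable], -1.0)  # -1 = missing
    Qu = Q[usable]

    em_iter = _supervised_kernel()
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # kernel returns the log-likelihood of the CURRENT Q and its update
        Qn, new_ll = em_iter(Genc, Qu, F)
        if it > 1:
            _check_monotone(ll, new_ll)
            if abs(new_ll - ll) <= tol * max(1.0, abs(ll)):
                converged = True
                Qu, ll = Qn, new_ll
                break
        Qu, ll = Qn, new_ll

    out = np.full((len(Gs.samples), K), np.nan)
    out[usable] = Qu
    props = pd.DataFrame(out, index=Gs.samples, columns=model.component_names)
    return QMatrix(props, ll, it, converged)


# ---------------------------------------------------------------------------
# Joint estimation
# ---------------------------------------------------------------------------

def fit_admixture(
    G: GenotypeMatrix,
    K: int,
    fixed_labels: Mapping[str, str] | None = None,
    component_names: Sequence[str] | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
    seed: int = 0,
    F_init: np.ndarray | None = None,
    update_freqs: bool = True,
) -> tuple[QMatrix, AncestryModel]:
    """Joint EM over ancestry proportions Q and component frequencies F.

    If ``fixed_labels`` maps samples to component names, those rows of Q are
    pinned to indicators (supervised-with-references mode); the named
    components are matched by position in ``component_names`` (defaults to
    the sorted label set padded with "anc{k}" for unlabelled components).
    ``F_init`` (K x M) overrides the default pooled-frequency-plus-jitter
    initialization; with ``update_freqs=False`` the frequencies stay at
    their initial values and the fit reduces to supervised estimation.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    W, WG, W2G = _masked(G.dosages)
    m_obs = W.sum(axis=1).astype(float)
    n, M = W.shape

    if component_names is None:
        labelled = sorted(set((fixed_labels or {}).values()))
        if len(labelled) > K:
            raise ValueError(f"{len(labelled)} labelled components but K={K}")
        component_names = labelled + [
            f"anc{k}" for k in range(len(labelled), K)
        ]
    component_names = list(component_names)
    comp_index = {c: k for k, c in enumerate(component_names)}

    fixed_rows = np.full(n, -1)
    if fixed_labels:
        lookup = {s: i for i, s in enumerate(G.samples)}
        for sample, comp in fixed_labels.items():
            if comp not in comp_index:
                raise ValueError(f"label {comp!r} not among components")
            if sample not in lookup:
                raise PopdataError(f"labelled sample {sample!r} not in matrix")
            fixed_rows[lookup[sample]] = comp_index[comp]
        for comp, k in comp_index.items():
            if comp in set(fixed_labels.values()) and (fixed_rows == k).sum() == 0:
                raise ValueError(f"component {comp!r} has no labelled sample")

    rng = np.random.default_rng(seed)

    def _init() -> tuple[np.ndarray, np.ndarray]:
        Q = rng.dirichlet(np.ones(K), size=n)
        Q = np.clip(Q, 1e-9, None)
        Q /= Q.sum(axis=1, keepdims=True)
        if F_init is not None:
            F = np.asarray(F_init, dtype=float)
            if F.shape != (K, M):
                raise ValueError(f"F_init shape {F.shape} != ({K}, {M})")
        else:
            with np.errstate(invalid="ignore"):
                pooled = WG.sum(axis=0) / (2.0 * W.sum(axis=0))
            pooled = np.where(W.sum(axis=0) > 0, pooled, 0.5)
            F = pooled[None, :] + rng.uniform(-0.01, 0.01, size=(K, M))
        return Q, np.clip(F, EPS, 1 - EPS)

    def _pin(Q: np.ndarray) -> np.ndarray:
        for k in range(K):
            rows = fixed_rows == k
            if rows.any():
                Q[rows] = EPS / K
                Q[rows, k] = 1.0 - EPS * (K - 1) / K
        return Q / Q.sum(axis=1, keepdims=True)

    frozen = fixed_rows >= 0  # labelled rows keep their indicator q
    dead = m_obs == 0  # all-missing rows cannot be updated

    for attempt in range(2):
        Q, F = _init()
        Q = _pin(Q)
        A = Q @ F
        ll = _total_loglik(WG, W2G, A)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Qn = _em_q_step(WG, W2G, A, Q, F, np.maximum(m_obs, 1.0))
            Qn[frozen | dead] = Q[frozen | dead]
            Q = Qn
            if update_freqs:
                F = _em_f_step(WG, W2G, Q @ F, Q, F)
            A = Q @ F
            new_ll = _total_loglik(WG, W2G, A)
            if attempt == 0 and not np.isfinite(new_ll):
                break  # degenerate start; re-seed once
            _check_monotone(ll, new_ll)
            if abs(new_ll - ll) <= tol * max(1.0, abs(ll)):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        empty = (Q.max(axis=0) < 1e-3).any() if K > 1 else False
        if np.isfinite(ll) and not (attempt == 0 and empty):
            break
    else:  # pragma: no cover
        raise EMError("joint EM failed to produce a finite fit")

    props = pd.DataFrame(Q, index=G.samples, columns=component_names)
    model = AncestryModel(F, component_names, G.marker_ids)
    return QMatrix(props, ll, it, converged), model


def match_components(
    Q: QMatrix, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Resolve label switching: map each reference population to a component.

    Greedy bijective assignment maximizing the mean proportion of each
    population's labelled individuals on its assigned component.
    """
    pops = sorted(set(reference_labels.values()))
    comps = Q.components
    if len(pops) > len(comps):
        raise ValueError(f"{len(pops)} populations but only {len(comps)} components")
    means = pd.DataFrame(index=pops, columns=comps, dtype=float)
    for pop in pops:
        rows = [s for s, p in reference_labels.items() if p == pop]
        missing = [s for s in rows if s not in Q.proportions.index]
        if missing:
            raise PopdataError(f"labelled samples absent from Q: {missing[:5]}")
        means.loc[pop] = Q.proportions.loc[rows].mean(axis=0)
    assignment: dict[str, str] = {}
    free = set(comps)
    flat = means.stack().sort_values(ascending=False)
    for (pop, comp), _ in flat.items():
        if pop in assignment or comp not in free:
            continue
        assignment[pop] = comp
        free.discard(comp)
    return assignment


# ---------------------------------------------------------------------------
# Cross-validation over K
# ---------------------------------------------------------------------------

def cross_validation(
    G: GenotypeMatrix,
    K_values: Sequence[int],
    folds: int = 5,
    fixed_labels: Mapping[str, str] | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> CVResult:
    """Masked-marker cross-validation of the number of components K.

    Markers are partitioned into ``folds`` folds by a seeded shuffle. For
    each fold and each K, the model is fitted on the retained markers; the
    held-out markers' component frequencies are then estimated with Q
    frozen, by the q-weighted allele-frequency regression

        f_km = sum_i q_ik g_im / (2 sum_i q_ik)        (non-missing i)

    (equivalently, a single EM frequency pass from a pooled start),
    computed in leave-one-out form so each individual's masked dosages are
    predicted, as g_hat = 2 sum_k q_k f_km, from frequencies estimated on
    the OTHER individuals. Without the leave-one-out step the prediction
    is in-sample in F and the error decreases monotonically in K; with it,
    surplus components pay for their estimation noise and the error curve
    attains its minimum at the structure the data support. The error is
    the mean squared dosage difference over masked non-missing entries,
    averaged over folds — a transparent statistic, not the deviance-based
    criterion some admixture software reports, but it ranks K the same way.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    M = G.n_markers
    if M < folds:
        raise ValueError("fewer markers than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(M)
    fold_of = np.empty(M, dtype=int)
    fold_of[perm] = np.arange(M) % folds

    errors = {int(k): 0.0 for k in K_values}
    for fold in range(folds):
        held = fold_of == fold
        G_fit = GenotypeMatrix(
            G.dosages[:, ~held],
            G.markers.loc[~held].reset_index(drop=True),
            G.samples,
            G.labels,
        )
        d_held = G.dosages[:, held]
        W, WG, W2G = _masked(d_held)
        for k in errors:
            Q, _ = fit_admixture(
                G_fit,
                k,
                fixed_labels=fixed_labels,
                tol=tol,
                max_iter=max_iter,
                seed=int(rng.integers(2**31 - 1)),
            )
            Qa = Q.proportions.to_numpy()
            # q-weighted frequency regression, leave-one-out per individual
            S = Qa.T @ WG  # K x m_held: sum_i q_ik g_im over called entries
            T = Qa.T @ W  # K x m_held: sum_i q_ik over called entries
            g_hat = np.empty_like(d_held)
            for i in range(Qa.shape[0]):
                Si = S - np.outer(Qa[i], WG[i])
                Ti = T - np.outer(Qa[i], W[i])
                with np.errstate(invalid="ignore", divide="ignore"):
                    Fi = Si / (2.0 * Ti)
                Fi = np.clip(np.where(Ti > 0, Fi, 0.5), EPS, 1 - EPS)
                g_hat[i] = 2.0 * (Qa[i] @ Fi)
            errors[k] += float(np.mean((d_held[W] - g_hat[W]) ** 2))
    return CVResult({k: e / folds for k, e in errors.items()}, folds, seed)
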