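"""End-to-end panel validation on simulated cohorts.

This module wires the whole pipeline together the way a panel designer
would use it: simulate a structured cohort, compute reference allele
frequencies and per-marker informativeness from the reference individuals,
run the GA to pick a fixed-size panel, then compare supervised ancestry
estimates from the panel against estimates from the full candidate set.

Correlations are reported for the continental components at K=3 (the two
closely related sub-continental references pooled into one component by a
sample-size-weighted frequency average) and for the two sub-continental
components at K=4. High correlations mean the small panel loses little of
the ancestry information carried by the full marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import AncestryModel, estimate_q, pool_components
from .informativeness import in_table
from .panel_design import DesignConfig, GAConfig, Panel, ga_optimize
from .popdata import allele_frequencies
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort

POOLED_NAME = "AMR"


@dataclass
class PanelValidationResult:
    panel: Panel
    correlations: pd.Series  # EUR_K3, AMR_K3, AYM_K4, MAP_K4
    truth_correlations: pd.Series  # all-marker estimate vs generating Q


def _component_corr(
    q_a: pd.DataFrame, q_b: pd.DataFrame, pairs: dict[str, tuple[str, str]]
) -> dict[str, float]:
    out = {}
    for name, (ca, cb) in pairs.items():
        x, y = q_a[ca].to_numpy(), q_b[cb].to_numpy()
        ok = ~np.isnan(x) & ~np.isnan(y)
        out[name] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out


def validate_panel_on_cohort(
    cohort: SimulatedCohort,
    panel_size: int = 150,
    design: DesignConfig | None = None,
    seed: int = 0,
    est_tol: float = 1e-5,
) -> PanelValidationResult:
    """Design a panel on a simulated cohort and score it against all markers."""
    G = cohort.G
    labels = cohort.reference_labels
    F_ref = allele_frequencies(G.subset_samples(sorted(labels)), labels)
    T = in_table(F_ref)  # all pairwise comparisons
    cfg = design if design is not None else DesignConfig(panel_size=panel_size)
    panel = ga_optimize(F_ref, T, cfg, seed=seed)

    admixed = cohort.admixed_samples
    G_adm = G.subset_samples(admixed)
    counts = pd.Series(list(labels.values())).value_counts().to_dict()
    F_k3 = pool_components(F_ref, {POOLED_NAME: ["AYM", "MAP"]}, counts)
    k3_order = [p for p in F_k3.populations if p != POOLED_NAME] + [POOLED_NAME]

    est: dict[str, pd.DataFrame] = {}
    for tag, F in (("k4", F_ref), ("k3", F_k3)):
        comps = list(F.populations) if tag == "k4" else k3_order
        for scope, ids in (("all", None), ("panel", panel.marker_ids)):
            Fm = F if ids is None else F.subset_markers(ids)
            model = AncestryModel.from_frequency_table(Fm, comps)
            Gm = G_adm if ids is None else G_adm.subset_markers(ids)
            est[f"{tag}_{scope}"] = estimate_q(
                Gm, model, tol=est_tol, seed=seed
            ).proportions

    corr = _component_corr(
        est["k3_all"],
        est["k3_panel"],
        {"EUR_K3": ("EUR", "EUR"), "AMR_K3": (POOLED_NAME, POOLED_NAME)},
    )
    corr.update(
        _component_corr(
            est["k4_all"],
            est["k4_panel"],
            {"AYM_K4": ("AYM", "AYM"), "MAP_K4": ("MAP", "MAP")},
        )
    )

    true_q = cohort.true_Q.proportions.loc[admixed]
    truth = _component_corr(
        est["k4_all"],
        true_q,
        {c: (c, c) for c in ("EUR", "AFR", "AYM", "MAP")},
    )
    return PanelValidationResult(
        panel, pd.Series(corr), pd.Series(truth, name="vs_truth")
    )


def panel_validation_experiment(
    seeds: list[int],
    n_markers: int = 20_000,
    n_reference_per_pop: int = 60,
    n_admixed: int = 300,
    panel_size: int = 150,
    ga: GAConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-over-seeds panel-vs-full-set correlations.

    For each seed: simulate a fresh cohort, design a fresh panel, score it.
    Returns the per-component median correlations and the per-seed table.
    """
    rows = {}
    for seed in seeds:
        cfg = SimulationConfig(
            n_markers=n_markers,
            n_reference_per_pop=n_reference_per_pop,
            n_admixed=n_admixed,
            seed=seed,
        )
        cohort = simulate_cohort(cfg)
        design = DesignConfig(
            panel_size=panel_size, ga=ga if ga is not None else GAConfig()
        )
        res = validate_panel_on_cohort(cohort, panel_size, design, seed=seed)
        rows[seed] = res.correlations
    table = pd.DataFrame(rows).T
    return table.median(axis=0), table
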