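"""Replicated synthetic-study experiments.

These workflows tie the whole pipeline together on simulated invasions:
replicate studies across seeds, fit a set of proximity-variable variants
with a reduced algorithm panel, and summarize the regularities the method
is designed to expose — the gain over the no-proximity control, the decay
of skill with minimal recentness, the advantage of distance over presence
encoding — plus a forward test of the forecast substitution against the
simulator's future state.

Problem sizes here (10 replicates on the default 200 x 200 landscape,
three algorithms, three split repetitions) are chosen so a full run
completes in a few minutes on one core while leaving clear medians.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .design import assemble_model_matrix, sample_pseudoabsences
from .grid import cells_of
from .history import VariantSpec, build_hpv_layers
from .importance import boruta_importance, melt_results
from .models import (EmptyEnsembleError, build_ensemble, cross_validate,
                     evaluate_roc, results_to_frame)
from .scenarios import ScenarioStack, forecast_stack, project
from .simulate import InvasionConfig, LandscapeConfig, make_study

logger = logging.getLogger("hpvsdm")

#: Variants exercised in the replicated pattern experiment: the control,
#: the three distance variants and the three presence variants.
PATTERN_VARIANTS = ("No HPV", "5.D", "10.D", "25.D", "5.P", "10.P", "25.P")

#: Reduced algorithm panel for replicated runs: two strong learners and
#: the weak envelope, spanning the quality range.
REDUCED_ALGORITHMS = ("RF", "GBM", "SRE")


def _sub_seeds(seed: int, n: int, stream: int) -> list[int]:
    rng = np.random.default_rng([int(seed), stream])
    return [int(s) for s in rng.integers(2 ** 31, size=n)]


def run_replicate(seed: int, variants=PATTERN_VARIANTS,
                  algorithms=REDUCED_ALGORITHMS, n_pa: int = 1000,
                  n_repetitions: int = 3, gate: float = 0.7) -> pd.DataFrame:
    """One simulated study, fitted and evaluated for the given variants."""
    s_land, s_inv, s_pa, s_fit = _sub_seeds(seed, 4, 99)
    bundle = make_study(LandscapeConfig(seed=s_land),
                        InvasionConfig(seed=s_inv))
    grid = bundle.landscape_config.grid
    hpv = build_hpv_layers(bundle.census_records, grid,
                           bundle.invasion_config.response_year)
    pa = sample_pseudoabsences(bundle.mask, n_pa, bundle.response_points,
                               seed=s_pa)
    results = []
    for label in variants:
        variant = VariantSpec.parse(label)
        stack = dict(bundle.env_stack)
        for name in variant.hpv_layer_names():
            stack[name] = hpv[name]
        matrix = assemble_model_matrix(bundle.response_points, pa, stack)
        cv = cross_validate(variant.label, matrix, algorithms,
                            n_repetitions=n_repetitions, seed=s_fit)
        results.extend(cv.results)
        try:
            ens_results, _ = build_ensemble(cv, gate=gate)
            results.extend(ens_results)
        except EmptyEnsembleError as exc:
            logger.info("%s", exc)
    return results_to_frame(results)


def run_pattern_experiment(n_replicates: int = 10, seed: int = 0,
                           **kwargs) -> pd.DataFrame:
    """Replicate :func:`run_replicate` across independent invasions."""
    frames = []
    for rep, s in enumerate(_sub_seeds(seed, n_replicates, 7)):
        frame = run_replicate(s, **kwargs)
        frame["replicate"] = rep
        frames.append(frame)
        logger.info("pattern replicate %d/%d done", rep + 1, n_replicates)
    return pd.concat(frames, ignore_index=True)


def pattern_summary(frame: pd.DataFrame) -> dict[str, float]:
    """Median single-model TSS per variant plus pooled D/P medians."""
    single = frame[frame["group"] == "single"]
    med = single.groupby("variant")["tss"].median()
    out = {f"median_tss_{v}": float(med[v]) for v in med.index}
    out["median_tss_D_variants"] = float(
        single[single["variant"].isin(["5.D", "10.D", "25.D"])]["tss"]
        .median())
    out["median_tss_P_variants"] = float(
        single[single["variant"].isin(["5.P", "10.P", "25.P"])]["tss"]
        .median())
    return out


def ensemble_dominance(frame: pd.DataFrame) -> float:
    """Fraction of replicates where the median ensemble TSS is at least
    the median single-member TSS (of gate-passing variants)."""
    wins = 0
    reps = frame["replicate"].unique()
    for rep in reps:
        sub = frame[frame["replicate"] == rep]
        ens = sub[sub["group"] == "ensemble"]["tss"]
        single = sub[sub["group"] == "single"]["tss"]
        if len(ens) and ens.median() >= single.median():
            wins += 1
    return wins / len(reps)


def pipeline_importance(frame: pd.DataFrame, seed: int = 0,
                        max_iter: int = 100):
    """Shadow-feature meta-model of the replicated results table."""
    melted = melt_results(frame)
    return boruta_importance(melted, seed=seed, max_iter=max_iter)


def forecast_skill(seed: int = 0, horizon: int = 5, variant: str = "5.D",
                   algorithm: str = "RF", n_pa: int = 1000) -> float:
    """ROC AUC of the forecast map against the simulator's future state.

    Fits a model on the response snapshot with historical proximity
    layers, substitutes proximity-to-current-sites, projects, and scores
    the projection against the cells actually occupied ``horizon`` years
    after the response year.
    """
    s_land, s_inv, s_pa, s_fit = _sub_seeds(seed, 4, 17)
    base = InvasionConfig(seed=s_inv)
    ic = dataclasses.replace(base, end_year=base.response_year + horizon)
    bundle = make_study(LandscapeConfig(seed=s_land), ic)
    grid = bundle.landscape_config.grid
    vspec = VariantSpec.parse(variant)
    hpv = build_hpv_layers(bundle.census_records, grid, ic.response_year)
    layers = dict(bundle.env_stack)
    for name in vspec.hpv_layer_names():
        layers[name] = hpv[name]
    pa = sample_pseudoabsences(bundle.mask, n_pa, bundle.response_points,
                               seed=s_pa)
    matrix = assemble_model_matrix(bundle.response_points, pa, layers)
    cv = cross_validate(vspec.label, matrix, (algorithm,), n_repetitions=1,
                        seed=s_fit)
    model = cv.repetitions[0].models[algorithm]
    fc = forecast_stack(ScenarioStack(layers), bundle.response_points)
    prob = project(model, fc, matrix.predictor_names, name="forecast")
    future = bundle.yearly_occupancy[ic.end_year]
    occupied = np.zeros(grid.shape, dtype=int)
    rows, cols = cells_of(future[:, 0], future[:, 1], grid)
    occupied[rows, cols] = 1
    valid = prob.mask()
    return evaluate_roc(prob.values[valid].ravel(), occupied[valid].ravel())
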